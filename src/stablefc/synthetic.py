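"""Markov-switching zero-mean Gaussian simulator with known ground truth.

Emulates the structure of group-level neuroimaging inputs: several
sessions (one subject per session by default) of multichannel data in
which a hidden state switches according to a sticky Markov chain and
each state emits zero-mean Gaussian samples with its own full
covariance.  Functional-connectivity states differ only in covariance
structure, so the single ``separation`` dial controls how distinct the
state covariances are: at high separation every inference run recovers
the same states, while at low separation runs disagree, reproducing the
run-to-run variability of real resting-state fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .dataio import SessionedTimeSeries

__all__ = [
    "GroundTruth",
    "make_transition_matrix",
    "make_state_covariances",
    "simulate",
    "LOW_SEPARATION",
    "HIGH_SEPARATION",
]

#: Separation presets for the two study regimes.  ``HIGH_SEPARATION``
#: gives essentially unimodal inference (every run finds the truth);
#: ``LOW_SEPARATION`` is calibrated so that the mean between-run
#: similarity of independent single fits falls near 0.6, the regime in
#: which run-to-run instability of state estimates is pronounced.
HIGH_SEPARATION = 2.0
LOW_SEPARATION = 0.6


@dataclass
class GroundTruth:
    """True generating parameters and state path of a simulation."""

    true_transition: np.ndarray  # (K, K), rows sum to 1
    true_initial: np.ndarray  # (K,), simplex
    true_covariances: list[np.ndarray]  # K SPD (P, P) matrices
    true_path: np.ndarray  # (T_total,) int state labels in 0..K-1
    separation: float

    def indicator_series(self) -> np.ndarray:
        """Hard path as a (T x K) one-hot state time series."""
        K = self.true_transition.shape[0]
        return np.eye(K)[self.true_path]


def make_transition_matrix(K: int, stay_prob: float, seed: int = 0,
                           jitter: float = 0.0) -> np.ndarray:
    """Sticky K-state transition matrix with uniform off-diagonal mass.

    ``diag = stay_prob``; the remaining ``1 - stay_prob`` is spread
    uniformly over the other states, optionally perturbed by seeded
    Dirichlet jitter (``jitter`` in [0, 1) mixes in a random simplex
    draw) before renormalization.
    """
    if not 0 < stay_prob <= 1:
        raise ValueError("stay_prob must be in (0, 1]")
    A = np.full((K, K), (1.0 - stay_prob) / max(K - 1, 1))
    np.fill_diagonal(A, stay_prob)
    if jitter > 0 and K > 1:
        rng = np.random.default_rng(seed)
        for k in range(K):
            off = A[k] > 0
            off[k] = False
            noise = rng.dirichlet(np.ones(off.sum()))
            A[k, off] = (1 - jitter) * A[k, off] + jitter * (1 - stay_prob) * noise
        A /= A.sum(axis=1, keepdims=True)
    return A


def make_state_covariances(K: int, P: int, separation: float,
                           seed: int = 0) -> list[np.ndarray]:
    """K full covariance matrices whose mutual distance scales with ``separation``.

    A shared base SPD matrix is drawn once; each state then rotates the
    base eigenvectors by a random orthogonal flow and reweights the
    spectrum, both by an amount proportional to ``separation``.  With
    ``separation = 0`` all states share the base matrix exactly.
    """
    if P < 2:
        raise ValueError("need P >= 2 channels")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    B = rng.standard_normal((P, P))
    base = B @ B.T / P + np.eye(P)
    w, V = np.linalg.eigh(base)

    covs = []
    for _ in range(K):
        G = rng.standard_normal((P, P))
        S = (G - G.T) / np.sqrt(2 * P)  # skew-symmetric generator
        R = expm(separation * S)  # orthogonal rotation
        logw = rng.uniform(-1.0, 1.0, size=P)
        wk = w * np.exp(separation * logw)
        Vk = R @ V
        cov = (Vk * wk) @ Vk.T
        covs.append((cov + cov.T) / 2)
    return covs


def perturb_covariance(cov: np.ndarray, amount: float, seed: int = 0) -> np.ndarray:
    """A nearby SPD matrix: rotate and reweight ``cov`` by ``amount``.

    Used to plant *families* of barely distinguishable states — e.g.
    two variants of one connectivity pattern that a fit with too few
    states must merge, creating competing local optima of near-equal
    quality.
    """
    P = cov.shape[0]
    rng = np.random.default_rng(seed)
    w, V = np.linalg.eigh(cov)
    G = rng.standard_normal((P, P))
    R = expm(amount * (G - G.T) / np.sqrt(2 * P))
    wk = w * np.exp(amount * rng.uniform(-1.0, 1.0, size=P))
    Vk = R @ V
    out = (Vk * wk) @ Vk.T
    return (out + out.T) / 2


def make_occupancy_transition(K: int, stay_prob: float,
                              occupancy: np.ndarray) -> np.ndarray:
    """Sticky transition matrix whose stationary mass equals ``occupancy``.

    Constructed as ``stay_prob * I + (1 - stay_prob) * 1 w^T``: on each
    step the chain stays with probability ``stay_prob`` and otherwise
    redraws a state from the occupancy weights, so the stationary
    distribution is exactly ``w``.  Rare states (small weights) are the
    regime in which different inference runs disagree about *which*
    states exist at all.
    """
    occupancy = np.asarray(occupancy, dtype=np.float64)
    if occupancy.shape != (K,) or occupancy.min() <= 0:
        raise ValueError("occupancy must be K positive weights")
    if not 0 < stay_prob < 1:
        raise ValueError("stay_prob must be in (0, 1)")
    w = occupancy / occupancy.sum()
    # A = s*I + (1-s)*1 w^T has stationary distribution exactly w
    A = stay_prob * np.eye(K) + (1 - stay_prob) * w[None, :]
    return A


def simulate(K: int, P: int, session_lengths, stay_prob: float = 0.95,
             separation: float = HIGH_SEPARATION, seed: int = 0,
             jitter: float = 0.0, covariances: list[np.ndarray] | None = None,
             transition: np.ndarray | None = None,
             initial: np.ndarray | None = None):
    """Simulate sessioned Markov-switching Gaussian data.

    Each session starts from the initial distribution (the analogue of a
    recording discontinuity); subsequent states follow the transition
    matrix; observations are zero-mean Gaussian with the active state's
    covariance.  State covariances are drawn by
    :func:`make_state_covariances` unless an explicit list is given.
    Returns ``(SessionedTimeSeries, GroundTruth)``.
    """
    rng = np.random.default_rng(seed)
    if transition is None:
        A = make_transition_matrix(K, stay_prob, seed=seed, jitter=jitter)
    else:
        A = np.asarray(transition, dtype=np.float64)
        if A.shape != (K, K) or not np.allclose(A.sum(axis=1), 1.0):
            raise ValueError("transition must be a K x K stochastic matrix")
    if initial is None:
        pi = np.full(K, 1.0 / K)
    else:
        pi = np.asarray(initial, dtype=np.float64)
        if pi.shape != (K,) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("initial must be a K-simplex vector")
    if covariances is None:
        covs = make_state_covariances(K, P, separation, seed=seed)
    else:
        if len(covariances) != K:
            raise ValueError("need one covariance per state")
        covs = [np.asarray(c, dtype=np.float64) for c in covariances]
    chols = [np.linalg.cholesky(c) for c in covs]

    path_parts, data_parts = [], []
    for L in session_lengths:
        states = np.empty(int(L), dtype=np.int64)
        states[0] = rng.choice(K, p=pi)
        for t in range(1, int(L)):
            states[t] = rng.choice(K, p=A[states[t - 1]])
        z = rng.standard_normal((int(L), P))
        x = np.empty((int(L), P))
        for k in range(K):
            mask = states == k
            x[mask] = z[mask] @ chols[k].T
        path_parts.append(states)
        data_parts.append(x)

    ts = SessionedTimeSeries(np.vstack(data_parts), list(session_lengths))
    truth = GroundTruth(
        true_transition=A,
        true_initial=pi,
        true_covariances=covs,
        true_path=np.concatenate(path_parts),
        separation=float(separation),
    )
    return ts, truth
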