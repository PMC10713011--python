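"""Variational-Bayes inference of a Gaussian hidden Markov model.

Observation model: at each time point the active state k emits a
zero-mean multivariate Gaussian with full covariance Sigma_k, i.e.
``x_t | s_t = k ~ N(0, Sigma_k)``.  States therefore differ only in
their covariance structure, which is what makes the model a descriptor
of time-varying functional connectivity.  Hidden dynamics are a
first-order Markov chain with transition probabilities theta and
initial probabilities eta; the first time point of every session is
modeled with eta, never with theta, so recording discontinuities do not
contaminate the transition estimates.

Inference is mean-field variational Bayes with conjugate priors:
Dirichlet rows for theta and eta, and a Wishart posterior over each
state's precision.  The Wishart posterior over the precision of state k
is parametrized here by degrees of freedom ``nu_k`` and an *inverse*
scale matrix ``scale_k`` (so the Wishart scale matrix is
``scale_k^{-1}``); the expected precision is ``nu_k * scale_k^{-1}``
and the expected covariance is reported as its inverse,
``C_k = scale_k / nu_k``.  This convention makes the M-step additive:
``scale_k = scale0 + sum_t gamma_tk x_t x_t^T``.

The optimization alternates E- and M-steps and monitors the variational
free energy (negative evidence lower bound), which decomposes as the
KL divergences of all parameter posteriors from their priors minus the
log normalizer of the sub-normalized chain assembled from
``exp(E[log parameters])``; the sequence is non-increasing.  The only
randomness is the Dirichlet initialization of the responsibilities,
which is exactly the stochasticity whose run-to-run consequences the
ensemble machinery addresses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import digamma, gammaln, multigammaln

from ._fb import forward_backward
from .dataio import SessionedTimeSeries

__all__ = [
    "HMMPriors",
    "HMMPosterior",
    "HMMFit",
    "init_responsibilities",
    "e_step",
    "m_step",
    "free_energy",
    "fit_hmm",
]

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HMMPriors:
    """Conjugate priors for the K-state zero-mean Gaussian HMM.

    ``dirichlet_diag`` is the extra Dirichlet concentration placed on
    self-transitions on top of the ``dirichlet_off`` baseline (sticky
    prior); ``dirichlet_off`` alone is used for the initial-state
    Dirichlet.  ``wishart_nu0`` and ``wishart_scale0`` parametrize the
    Wishart prior over each state's precision in the inverse-scale
    convention described in the module docstring.
    """

    dirichlet_diag: float
    dirichlet_off: float
    wishart_nu0: float
    wishart_scale0: np.ndarray

    def __post_init__(self):
        if self.dirichlet_diag <= 0 or self.dirichlet_off <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        S0 = np.asarray(self.wishart_scale0, dtype=np.float64)
        if S0.ndim != 2 or S0.shape[0] != S0.shape[1]:
            raise ValueError("wishart_scale0 must be a square matrix")
        if not np.allclose(S0, S0.T):
            raise ValueError("wishart_scale0 must be symmetric")
        np.linalg.cholesky(S0)  # raises if not positive definite
        if self.wishart_nu0 <= S0.shape[0] - 1:
            raise ValueError("wishart_nu0 must exceed P - 1")
        self.wishart_scale0 = S0

    @classmethod
    def default(cls, ts: SessionedTimeSeries, dirichlet_diag: float = 10.0,
                dirichlet_off: float = 1.0) -> "HMMPriors":
        """Weakly informative defaults: nu0 = P + 2 and the diagonal of
        the empirical covariance as prior inverse scale."""
        P = ts.n_channels
        emp = np.cov(ts.data, rowvar=False)
        return cls(dirichlet_diag, dirichlet_off, P + 2.0,
                   np.diag(np.diag(np.atleast_2d(emp))))

    def trans_counts(self, K: int) -> np.ndarray:
        return np.full((K, K), self.dirichlet_off) + self.dirichlet_diag * np.eye(K)

    def init_counts(self, K: int) -> np.ndarray:
        return np.full(K, self.dirichlet_off)


@dataclass
class HMMPosterior:
    """Variational posterior parameters after an M-step."""

    trans_counts: np.ndarray  # (K, K) Dirichlet counts, one row per state
    init_counts: np.ndarray  # (K,) Dirichlet counts
    nu: np.ndarray  # (K,) Wishart degrees of freedom
    scale: np.ndarray  # (K, P, P) Wishart inverse-scale matrices

    @property
    def K(self) -> int:
        return self.trans_counts.shape[0]

    def expected_transition(self) -> np.ndarray:
        """Posterior-mean transition matrix (rows sum to 1)."""
        return self.trans_counts / self.trans_counts.sum(axis=1, keepdims=True)

    def expected_covariances(self) -> list[np.ndarray]:
        """``C_k = scale_k / nu_k`` (inverse of the expected precision)."""
        return [self.scale[k] / self.nu[k] for k in range(self.K)]


@dataclass
class HMMFit:
    """One inference run: posteriors, state time series, and trace."""

    K: int
    gamma: np.ndarray  # (T, K) state time series
    xi: np.ndarray  # (K, K) expected transition counts
    posterior: HMMPosterior
    free_energy_trace: np.ndarray
    seed: int
    converged: bool
    covariances: list[np.ndarray] = field(default=None)  # type: ignore

    def __post_init__(self):
        if self.covariances is None:
            self.covariances = self.posterior.expected_covariances()

    @property
    def final_free_energy(self) -> float:
        return float(self.free_energy_trace[-1])


def init_responsibilities(ts: SessionedTimeSeries, K: int, seed: int) -> np.ndarray:
    """Random initial responsibilities: each row ~ symmetric Dirichlet(1)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return np.ones((ts.n_timepoints, 1))
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(K), size=ts.n_timepoints)


def _expected_log_dirichlet(counts: np.ndarray) -> np.ndarray:
    """E[log p] for Dirichlet counts, along the last axis."""
    return digamma(counts) - digamma(counts.sum(axis=-1, keepdims=True))


def _emission_loglik(X: np.ndarray, post: HMMPosterior) -> np.ndarray:
    """(T, K) matrix of E_q[log N(x_t | 0, Lambda_k^{-1})]."""
    T, P = X.shape
    out = np.empty((T, post.K))
    for k in range(post.K):
        L = cho_factor(post.scale[k], lower=True)
        logdet_scale = 2.0 * np.log(np.diag(L[0])).sum()
        elogdet = (
            digamma((post.nu[k] - np.arange(P)) / 2.0).sum()
            + P * np.log(2.0)
            - logdet_scale
        )
        # quadratic form x^T E[Lambda] x with E[Lambda] = nu * scale^{-1}
        sol = cho_solve(L, X.T)
        quad = post.nu[k] * np.einsum("pt,pt->t", X.T, sol)
        out[:, k] = 0.5 * elogdet - 0.5 * quad - 0.5 * P * LOG2PI
    return out


def e_step(ts: SessionedTimeSeries, post: HMMPosterior):
    """Session-aware forward-backward under expected log parameters.

    Returns ``(gamma, xi, log_norm)`` where ``log_norm`` is the log
    normalizer of the sub-normalized chain (sum of log scaling
    constants plus the per-row likelihood shifts); ``xi`` excludes
    cross-session steps.
    """
    logb = _emission_loglik(ts.data, post)
    shift = logb.max(axis=1)
    b = np.exp(logb - shift[:, None])
    A = np.exp(_expected_log_dirichlet(post.trans_counts))
    pi = np.exp(_expected_log_dirichlet(post.init_counts))
    gamma, xi, logc = forward_backward(b, A, pi, ts.session_starts)
    return gamma, xi, logc + shift.sum()


def m_step(ts: SessionedTimeSeries, gamma: np.ndarray, xi: np.ndarray,
           priors: HMMPriors) -> HMMPosterior:
    """Conjugate posterior updates from expected sufficient statistics."""
    X = ts.data
    T, P = X.shape
    K = gamma.shape[1]
    Nk = gamma.sum(axis=0)
    for k in range(K):
        if Nk[k] < 10 * P:
            warnings.warn(
                f"state {k} is near-empty (responsibility {Nk[k]:.2f} < {10 * P}); "
                "posterior stays prior-dominated",
                RuntimeWarning,
                stacklevel=2,
            )
    trans = priors.trans_counts(K) + xi
    init = priors.init_counts(K) + gamma[ts.session_starts].sum(axis=0)
    nu = priors.wishart_nu0 + Nk
    scale = np.empty((K, P, P))
    for k in range(K):
        S = (X * gamma[:, k][:, None]).T @ X
        scale[k] = priors.wishart_scale0 + (S + S.T) / 2
    return HMMPosterior(trans, init, nu, scale)


def _kl_dirichlet(counts: np.ndarray, prior: np.ndarray) -> float:
    """KL(Dir(counts) || Dir(prior)) for one concentration vector."""
    a0, b0 = counts.sum(), prior.sum()
    return float(
        gammaln(a0)
        - gammaln(counts).sum()
        - gammaln(b0)
        + gammaln(prior).sum()
        + ((counts - prior) * (digamma(counts) - digamma(a0))).sum()
    )


def _kl_wishart(nu: float, scale: np.ndarray, nu0: float,
                scale0: np.ndarray) -> float:
    """KL between Wishart posteriors over precisions, inverse-scale
    parametrization (Wishart scale matrices are ``scale^{-1}``)."""
    P = scale.shape[0]
    Lq = cho_factor(scale, lower=True)
    logdet_q = 2.0 * np.log(np.diag(Lq[0])).sum()
    sign0, logdet_0 = np.linalg.slogdet(scale0)
    if sign0 <= 0:
        raise ValueError("prior scale matrix is not positive definite")
    # the P*log2 and log|W| parts of E[log|Lambda|] cancel against the
    # normalizers, leaving only the digamma sum in the last term
    psi_sum = digamma((nu - np.arange(P)) / 2.0).sum()
    tr = np.trace(cho_solve(Lq, scale0))
    return float(
        0.5 * nu0 * (logdet_q - logdet_0)
        + 0.5 * nu * (tr - P)
        + multigammaln(nu0 / 2.0, P)
        - multigammaln(nu / 2.0, P)
        + 0.5 * (nu - nu0) * psi_sum
    )


def _kl_total(post: HMMPosterior, priors: HMMPriors) -> float:
    K = post.K
    prior_trans = priors.trans_counts(K)
    kl = sum(_kl_dirichlet(post.trans_counts[k], prior_trans[k]) for k in range(K))
    kl += _kl_dirichlet(post.init_counts, priors.init_counts(K))
    kl += sum(
        _kl_wishart(post.nu[k], post.scale[k], priors.wishart_nu0,
                    priors.wishart_scale0)
        for k in range(K)
    )
    return kl


def free_energy(ts: SessionedTimeSeries, post: HMMPosterior,
                priors: HMMPriors) -> float:
    """Variational free energy of the model at the given posteriors.

    Equals (expected negative data log-likelihood minus state-path
    entropy) plus the KL of every parameter posterior from its prior;
    computed here as ``KL_total - log_norm`` with ``log_norm`` from a
    fresh E-step, which is the same quantity.  Lower is better; only
    differences across runs on the same data are meaningful.
    """
    _, _, log_norm = e_step(ts, post)
    return _kl_total(post, priors) - log_norm


def fit_hmm(ts: SessionedTimeSeries, K: int, priors: HMMPriors | None = None,
            seed: int = 0, max_iter: int = 500, tol: float = 1e-5) -> HMMFit:
    """Run one variational inference from a seeded random initialization.

    Alternates E- and M-steps until the per-iteration free-energy
    decrease falls below ``tol`` times the total decrease since the
    first iteration (an offset-invariant relative criterion) or
    ``max_iter`` is reached.  The result is fully determined by
    ``(data, K, priors, seed, max_iter, tol)``.
    """
    if priors is None:
        priors = HMMPriors.default(ts)
    if ts.n_timepoints < 10 * K * ts.n_channels:
        warnings.warn(
            f"only {ts.n_timepoints} time points for K={K}, P={ts.n_channels}; "
            "at least 10*K*P recommended",
            RuntimeWarning,
            stacklevel=2,
        )

    gamma = init_responsibilities(ts, K, seed)
    # initial transition statistics from consecutive responsibilities
    starts = ts.session_starts
    xi = np.einsum("tj,tk->jk", gamma[:-1][~starts[1:]], gamma[1:][~starts[1:]])
    post = m_step(ts, gamma, xi, priors)

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        gamma, xi, log_norm = e_step(ts, post)
        fe = _kl_total(post, priors) - log_norm
        if trace:
            if fe > trace[-1] + 1e-8 * max(1.0, abs(trace[-1])):
                raise FloatingPointError(
                    f"free energy increased ({trace[-1]} -> {fe}); "
                    "this indicates an implementation fault"
                )
            # relative to the total decrease so far, not to |F| itself:
            # F carries an arbitrary additive constant, so a criterion
            # based on its magnitude would be offset-dependent
            travelled = trace[0] - fe
            if travelled <= 0 or (trace[-1] - fe) <= tol * travelled:
                trace.append(fe)
                converged = True
                break
        trace.append(fe)
        post = m_step(ts, gamma, xi, priors)

    return HMMFit(
        K=K,
        gamma=gamma,
        xi=xi,
        posterior=post,
        free_energy_trace=np.asarray(trace),
        seed=seed,
        converged=converged,
    )
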