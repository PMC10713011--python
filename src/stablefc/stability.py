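"""Evaluation protocols: run-to-run similarity, stability curves, state metrics.

The central question is how reproducible a time-varying connectivity
estimate is across repeated inferences.  Three protocols answer it:

* pairwise similarities over all C(R, 2) pairs of runs in an ensemble
  (the histogram view of raw inference variability);
* the run-by-run similarity matrix with runs sorted by ascending free
  energy (do the best-ranked runs agree with each other?);
* repetition stability: repeat an entire procedure (best-ranked
  selection or hierarchical-clustered consensus) several times with
  fresh seeds for each ensemble size R on a grid, and summarize the
  between-repetition similarities per R.

Per-state dynamics are summarized by fractional occupancy, mean
lifetime (dwell time) of hard-path visits, and the switching rate;
visits never span session boundaries, mirroring the transition-model
reset at discontinuities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .alignment import align_states
from .dataio import SessionedTimeSeries
from .ensemble import RunEnsemble, run_ensemble, select_best
from .hc_hmm import hc_hmm
from .vbhmm import HMMPriors

__all__ = [
    "StabilityReport",
    "StateMetrics",
    "pairwise_similarities",
    "fe_sorted_similarity_matrix",
    "repetition_stability",
    "compare_methods",
    "state_metrics",
    "spatial_correspondence",
]

#: seed stride between protocol repetitions; larger than any sensible R
#: so that no two ensembles in one protocol share a run seed.
_REP_STRIDE = 10_000


@dataclass
class StabilityReport:
    """Between-repetition similarity scores per ensemble size R."""

    method: str  # "plain" | "br" | "hc"
    R_grid: list[int]
    n_repetitions: int
    similarities: dict[int, list[float]]  # R -> C(n_repetitions, 2) scores
    summaries: dict[int, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        for R, scores in self.similarities.items():
            s = np.asarray(scores, dtype=float)
            self.summaries[R] = {
                "min": float(s.min()),
                "mean": float(s.mean()),
                "max": float(s.max()),
                "sd": float(s.std(ddof=1)) if s.size > 1 else 0.0,
            }

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "R_grid": list(self.R_grid),
            "n_repetitions": self.n_repetitions,
            "similarities": {str(R): v for R, v in self.similarities.items()},
            "summaries": {str(R): v for R, v in self.summaries.items()},
        }


@dataclass
class StateMetrics:
    """Temporal characteristics of one state time series."""

    fractional_occupancy: np.ndarray  # (K,) column means, sums to 1
    mean_lifetime: np.ndarray  # (K,) mean visit duration in time points (nan if unvisited)
    switching_rate: float  # hard-state changes per within-session step


def pairwise_similarities(ensemble: RunEnsemble) -> list[float]:
    """Aligned similarity for every unordered pair of runs (C(R,2) scores)."""
    if ensemble.R < 2:
        raise ValueError("need at least two runs")
    gammas = [f.gamma for f in ensemble.fits]
    return [
        align_states(gammas[i], gammas[j]).similarity
        for i, j in combinations(range(ensemble.R), 2)
    ]


def fe_sorted_similarity_matrix(ensemble: RunEnsemble):
    """(R, R) similarity matrix with runs sorted by ascending free energy.

    Returns ``(matrix, order)``; the first row/column is the
    best-ranked run.
    """
    if ensemble.R < 2:
        raise ValueError("need at least two runs")
    order = np.argsort(ensemble.final_free_energies, kind="stable")
    gammas = [ensemble.fits[i].gamma for i in order]
    R = len(gammas)
    S = np.eye(R)
    for i, j in combinations(range(R), 2):
        s = align_states(gammas[i], gammas[j]).similarity
        S[i, j] = S[j, i] = s
    return S, order


def _method_series(ts, K, priors, method, R, base_seed, K_c, max_iter, tol):
    ens = run_ensemble(ts, K, priors=priors, R=R, base_seed=base_seed,
                       max_iter=max_iter, tol=tol)
    if method == "br":
        return select_best(ens).gamma
    if method == "hc":
        return hc_hmm(ens, K_c=K_c).S
    raise ValueError(f"unknown method {method!r}")


def repetition_stability(ts: SessionedTimeSeries, K: int, method: str,
                         R_grid, n_repetitions: int = 8, base_seed: int = 0,
                         priors: HMMPriors | None = None, K_c: int | None = None,
                         max_iter: int = 500, tol: float = 1e-5) -> StabilityReport:
    """Between-repetition stability of a procedure as a function of R.

    For each R in ``R_grid`` and each of ``n_repetitions`` repetitions,
    a fresh seeded ensemble of R runs is fit and reduced to one state
    time series by the chosen method (``"br"``: the best-ranked run's
    probabilities; ``"hc"``: the consensus cluster series).  Every pair
    of repetitions is then scored with the aligned similarity.
    """
    if method not in ("br", "hc"):
        raise ValueError("method must be 'br' or 'hc'")
    if priors is None:
        priors = HMMPriors.default(ts)
    sims: dict[int, list[float]] = {}
    rep_counter = 0
    for R in R_grid:
        series = []
        for _ in range(n_repetitions):
            seed = base_seed + rep_counter * _REP_STRIDE
            rep_counter += 1
            try:
                series.append(
                    _method_series(ts, K, priors, method, R, seed, K_c,
                                   max_iter, tol)
                )
            except Exception as exc:
                raise RuntimeError(
                    f"stability protocol failed at R={R}, "
                    f"repetition seed {seed}: {exc}"
                ) from exc
        sims[int(R)] = [
            align_states(series[i], series[j]).similarity
            for i, j in combinations(range(n_repetitions), 2)
        ]
    return StabilityReport(
        method=method,
        R_grid=[int(R) for R in R_grid],
        n_repetitions=n_repetitions,
        similarities=sims,
    )


def compare_methods(ts: SessionedTimeSeries, K: int, R: int,
                    n_repetitions: int = 8, base_seed: int = 0,
                    priors: HMMPriors | None = None, K_c: int | None = None,
                    max_iter: int = 500, tol: float = 1e-5) -> dict[str, list[float]]:
    """Paired best-ranked vs consensus stability from shared ensembles.

    Fits one ensemble per repetition and derives both methods' outputs
    from it, so the comparison is paired and costs half as many fits as
    two separate protocols.  Returns ``{"br": scores, "hc": scores}``.
    """
    if priors is None:
        priors = HMMPriors.default(ts)
    br_series, hc_series = [], []
    for rep in range(n_repetitions):
        ens = run_ensemble(ts, K, priors=priors, R=R,
                           base_seed=base_seed + rep * _REP_STRIDE,
                           max_iter=max_iter, tol=tol)
        br_series.append(select_best(ens).gamma)
        hc_series.append(hc_hmm(ens, K_c=K_c).S)
    pairs = list(combinations(range(n_repetitions), 2))
    return {
        "br": [align_states(br_series[i], br_series[j]).similarity for i, j in pairs],
        "hc": [align_states(hc_series[i], hc_series[j]).similarity for i, j in pairs],
    }


def state_metrics(gamma: np.ndarray,
                  sessions: list[tuple[int, int]] | None = None) -> StateMetrics:
    """Occupancy, mean lifetime and switching rate of a state series.

    Lifetimes and switches are computed on the hard path (per-row
    argmax, lowest index on ties), per session: a visit ends at a
    session boundary and a boundary is never counted as a switch.
    """
    gamma = np.asarray(gamma, dtype=float)
    T, K = gamma.shape
    if sessions is None:
        sessions = [(0, T)]
    occupancy = gamma.mean(axis=0)
    hard = gamma.argmax(axis=1)
    lifetimes: list[list[int]] = [[] for _ in range(K)]
    n_changes = 0
    for a, b in sessions:
        seg = hard[a:b]
        change_pts = np.flatnonzero(np.diff(seg) != 0)
        n_changes += len(change_pts)
        bounds = np.concatenate([[0], change_pts + 1, [len(seg)]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            lifetimes[seg[s]].append(e - s)
        if len(seg) == 0:
            raise ValueError("empty session interval")
    n_steps = T - len(sessions)
    mean_lt = np.array(
        [float(np.mean(v)) if v else np.nan for v in lifetimes]
    )
    return StateMetrics(
        fractional_occupancy=occupancy,
        mean_lifetime=mean_lt,
        switching_rate=n_changes / n_steps if n_steps > 0 else 0.0,
    )


def spatial_correspondence(covs_a: list[np.ndarray], covs_b: list[np.ndarray],
                           pairing: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation between aligned covariance matrices.

    For each aligned pair, the correlation is computed between the
    vectorized upper triangles (diagonal included) of the two matrices;
    one value per state pair.
    """
    if pairing is None:
        pairing = np.arange(len(covs_a))
    out = np.empty(len(covs_a))
    for k, (a_idx, b_idx) in enumerate(zip(range(len(covs_a)), pairing)):
        A, B = np.asarray(covs_a[a_idx]), np.asarray(covs_b[int(b_idx)])
        if A.shape != B.shape:
            raise ValueError("covariance shape mismatch")
        iu = np.triu_indices(A.shape[0])
        out[k] = np.corrcoef(A[iu], B[iu])[0, 1]
    return out
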