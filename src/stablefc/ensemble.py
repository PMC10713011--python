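"""Ensembles of seeded inference runs and best-ranked selection.

The inference is stochastic only through its seeded initialization, so
an ensemble of R runs with seeds ``base_seed, base_seed+1, ...`` is
fully reproducible and independent of how the runs are scheduled.  The
best-ranked procedure keeps the run with the lowest final free energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .dataio import SessionedTimeSeries
from .vbhmm import HMMFit, HMMPriors, fit_hmm

__all__ = ["RunEnsemble", "run_ensemble", "select_best"]


@dataclass
class RunEnsemble:
    """R independent fits of the same model to the same data."""

    fits: list[HMMFit]
    base_seed: int

    @property
    def R(self) -> int:
        return len(self.fits)

    @property
    def final_free_energies(self) -> np.ndarray:
        return np.array([f.final_free_energy for f in self.fits])


def _one_fit(ts, K, priors, seed, max_iter, tol):
    try:
        return fit_hmm(ts, K, priors=priors, seed=seed, max_iter=max_iter, tol=tol)
    except Exception as exc:
        raise RuntimeError(f"HMM run with seed {seed} failed: {exc}") from exc


def run_ensemble(ts: SessionedTimeSeries, K: int, priors: HMMPriors | None = None,
                 R: int = 10, base_seed: int = 0, workers: int = 1,
                 max_iter: int = 500, tol: float = 1e-5) -> RunEnsemble:
    """Run R seeded fits (seeds ``base_seed + i``); numerics are
    identical for any ``workers`` count."""
    if R < 1:
        raise ValueError("R must be >= 1")
    if priors is None:
        priors = HMMPriors.default(ts)  # resolve once so all runs share it
    seeds = [base_seed + i for i in range(R)]
    if workers == 1:
        fits = [_one_fit(ts, K, priors, s, max_iter, tol) for s in seeds]
    else:
        fits = Parallel(n_jobs=workers)(
            delayed(_one_fit)(ts, K, priors, s, max_iter, tol) for s in seeds
        )
    return RunEnsemble(fits=list(fits), base_seed=base_seed)


def select_best(ensemble: RunEnsemble) -> HMMFit:
    """Best-ranked run: minimum final free energy, lowest index on ties."""
    if ensemble.R == 0:
        raise ValueError("empty ensemble")
    return ensemble.fits[int(np.argmin(ensemble.final_free_energies))]
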