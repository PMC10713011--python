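"""Pairing states between two inference runs and scoring run similarity.

Two runs of the inference may find the same states under an arbitrary
relabeling, so before any comparison the states are paired by solving a
linear assignment problem (the Hungarian algorithm).  The co-activation
of state a in run i with state b in run j is the summed joint
probability ``sum_t Y1[t,a] * Y2[t,b]``; the optimal pairing maximizes
the total aligned co-activation, equivalently minimizes

    cost = T - sum_k overlap[k, perm[k]],     max_cost = T,

and the similarity of the two runs is ``1 - cost / max_cost``, a number
in [0, 1] that equals 1 exactly when the aligned state time series
co-activate at every time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["AlignmentResult", "overlap_matrix", "align_states"]

MAX_STATES = 64


@dataclass
class AlignmentResult:
    """Optimal state pairing between two runs."""

    permutation: np.ndarray  # perm[a] = paired state of run j for state a of run i
    overlap: np.ndarray  # (K, K) summed joint probabilities
    cost: float
    max_cost: float

    @property
    def similarity(self) -> float:
        return 1.0 - self.cost / self.max_cost


def overlap_matrix(Y1: np.ndarray, Y2: np.ndarray) -> np.ndarray:
    """Summed joint state probabilities: ``O[a, b] = sum_t Y1[t,a] Y2[t,b]``."""
    Y1 = np.asarray(Y1, dtype=np.float64)
    Y2 = np.asarray(Y2, dtype=np.float64)
    if Y1.shape != Y2.shape:
        raise ValueError(f"shape mismatch: {Y1.shape} vs {Y2.shape}")
    return Y1.T @ Y2


def align_states(Y1: np.ndarray, Y2: np.ndarray,
                 max_states: int = MAX_STATES) -> AlignmentResult:
    """Hungarian pairing of states between two runs.

    Maximizes the total aligned overlap; ties are resolved by the
    deterministic lowest-index behavior of the assignment solver.
    """
    O = overlap_matrix(Y1, Y2)
    K = O.shape[0]
    if K > max_states:
        raise ValueError(f"K={K} exceeds the guard limit of {max_states} states")
    T = Y1.shape[0]
    rows, cols = linear_sum_assignment(-O)
    perm = np.empty(K, dtype=np.int64)
    perm[rows] = cols
    aligned = float(O[rows, cols].sum())
    return AlignmentResult(
        permutation=perm, overlap=O, cost=float(T) - aligned, max_cost=float(T)
    )
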