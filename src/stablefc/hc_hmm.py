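"""Hierarchical-clustered consensus over an ensemble of inference runs.

All M = R x K state time series from an ensemble are stacked, their
pairwise Pearson correlation matrix P is converted to the distance
D = 1 - P, and Ward's agglomerative clustering is applied directly to
D.  Cutting the dendrogram at K_c clusters groups states that recur
across runs; each cluster yields

* a cluster state time series: the within-cluster mean of the member
  series, with rows rescaled afterwards so that cluster probabilities
  sum to 1 at every time point, and
* a cluster covariance: the fractional-occupancy-weighted average of
  the member states' covariance matrices, normalized by the summed
  occupancy so it is a convex combination (and hence itself a valid
  covariance on the same scale).

Ward linkage here follows the Lance-Williams recurrence applied to the
given distances as-is (the convention R calls "ward.D"), since the
correlation distance is not Euclidean; ties are broken by the lowest
member index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ensemble import RunEnsemble

__all__ = [
    "StateStack",
    "StateSimilarity",
    "ClusterModel",
    "stack_states",
    "state_similarity",
    "ward_cluster",
    "cut_merge_table",
    "fractional_occupancy",
    "cluster_series",
    "cluster_covariances",
    "hc_hmm",
]


@dataclass
class StateStack:
    """All state time series of an ensemble, column-stacked."""

    Y: np.ndarray  # (T, M) stacked state probability series
    source: list[tuple[int, int]]  # (run index, state index) per column

    @property
    def M(self) -> int:
        return self.Y.shape[1]


@dataclass
class StateSimilarity:
    """Pearson similarity P and distance D = 1 - P between stacked states."""

    P: np.ndarray
    D: np.ndarray


@dataclass
class ClusterModel:
    """Consensus model: assignment, merge tree, series S, covariances Q."""

    assignment: np.ndarray  # (M,) cluster label in 0..K_c-1 per stacked state
    merge_table: np.ndarray  # (M-1, 4): member a, member b, distance, size
    S: np.ndarray  # (T, K_c) rescaled cluster state series
    Q: list[np.ndarray]  # K_c cluster covariance matrices
    beta: np.ndarray  # (M,) fractional occupancy per stacked state
    cluster_sizes: np.ndarray  # (K_c,)


def stack_states(ensemble: RunEnsemble) -> StateStack:
    """Stack the R x K state time series columns with provenance."""
    T = ensemble.fits[0].gamma.shape[0]
    cols, source = [], []
    for r, fit in enumerate(ensemble.fits):
        if fit.gamma.shape[0] != T:
            raise ValueError("all runs must share the number of time points")
        for k in range(fit.K):
            cols.append(fit.gamma[:, k])
            source.append((r, k))
    return StateStack(Y=np.column_stack(cols), source=source)


def state_similarity(stack: StateStack) -> StateSimilarity:
    """Pairwise Pearson correlation between stacked state time series.

    A constant column (a state that never activates) has no defined
    correlation; it is assigned correlation 0 with every other state
    (distance 1) with a warning, so one dead state cannot sink the
    whole ensemble.
    """
    Y = stack.Y
    sd = Y.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} constant state time series; "
            "their correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    Z = Y - Y.mean(axis=0)
    denom = np.where(dead, 1.0, sd) * np.sqrt(Y.shape[0])
    Z = Z / denom
    P = Z.T @ Z
    P[dead, :] = 0.0
    P[:, dead] = 0.0
    np.fill_diagonal(P, 1.0)
    P = np.clip((P + P.T) / 2, -1.0, 1.0)
    np.fill_diagonal(P, 1.0)
    D = 1.0 - P
    np.fill_diagonal(D, 0.0)
    return StateSimilarity(P=P, D=D)


def ward_linkage(D: np.ndarray) -> np.ndarray:
    """Agglomerative Ward merge table from a precomputed distance matrix.

    Lance-Williams update applied to the distances as given:
    ``d(k, i+j) = ((n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) - n_k d(i,j))
    / (n_i+n_j+n_k)``.  Returns an (M-1, 4) table of
    ``(cluster a, cluster b, merge distance, merged size)`` where
    original elements are clusters ``0..M-1`` and the cluster created
    at step s gets id ``M + s``.  The pair with the smallest distance
    is merged at each step; ties go to the pair whose smallest member
    indices are lowest.
    """
    d = np.array(D, dtype=np.float64)
    M = d.shape[0]
    if M < 1:
        raise ValueError("empty distance matrix")
    np.fill_diagonal(d, np.inf)
    sizes = np.ones(M)
    ids = np.arange(M)
    active = np.ones(M, dtype=bool)
    merges = np.empty((max(M - 1, 0), 4))
    for step in range(M - 1):
        # slot index equals the smallest original member index of its
        # cluster (merges always keep the lower slot), so the row-major
        # argmin implements the lowest-member-index tie-break
        flat = np.argmin(np.where(active[:, None] & active[None, :], d, np.inf))
        i, j = divmod(int(flat), M)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        k = active.copy()
        k[[i, j]] = False
        tot = sizes[i] + sizes[j] + sizes[k]
        d_new = (
            (sizes[i] + sizes[k]) * d[i, k]
            + (sizes[j] + sizes[k]) * d[j, k]
            - sizes[k] * dij
        ) / tot
        d[i, k] = d_new
        d[k, i] = d_new
        active[j] = False
        d[j, :] = np.inf
        d[:, j] = np.inf
        merges[step] = (ids[i], ids[j], dij, sizes[i] + sizes[j])
        sizes[i] += sizes[j]
        ids[i] = M + step
    return merges


def cut_merge_table(merge_table: np.ndarray, M: int, K_c: int) -> np.ndarray:
    """Labels in ``0..K_c-1`` from the first ``M - K_c`` merges.

    Clusters are numbered by their smallest original member index.
    """
    parent = list(range(M))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    node_members = {i: i for i in range(M)}  # node id -> a representative leaf
    for s in range(M - K_c):
        a, b, _, _ = merge_table[s]
        ra, rb = find(node_members[int(a)]), find(node_members[int(b)])
        parent[max(ra, rb)] = min(ra, rb)
        node_members[M + s] = min(ra, rb)
    roots = [find(i) for i in range(M)]
    labels = {r: n for n, r in enumerate(sorted(set(roots)))}
    return np.array([labels[r] for r in roots], dtype=np.int64)


def ward_cluster(sim: StateSimilarity, K_c: int):
    """Ward clustering of the stacked states; returns ``(assignment,
    merge_table)`` with exactly K_c clusters."""
    M = sim.D.shape[0]
    if not 1 <= K_c <= M:
        raise ValueError(f"K_c must be in [1, {M}]")
    merge_table = ward_linkage(sim.D)
    return cut_merge_table(merge_table, M, K_c), merge_table


def fractional_occupancy(y: np.ndarray) -> float:
    """Mean activation probability of one state series over the dataset."""
    y = np.asarray(y)
    if y.min() < 0 or y.max() > 1:
        raise ValueError("state series values must lie in [0, 1]")
    return float(y.mean())


def cluster_series(stack: StateStack, assignment: np.ndarray) -> np.ndarray:
    """Within-cluster mean series, row-rescaled to sum to 1 per time point."""
    K_c = int(assignment.max()) + 1
    T = stack.Y.shape[0]
    S = np.empty((T, K_c))
    for c in range(K_c):
        members = assignment == c
        if not members.any():
            raise ValueError(f"cluster {c} is empty")
        S[:, c] = stack.Y[:, members].mean(axis=1)
    row_sums = S.sum(axis=1)
    if np.any(row_sums <= 0):
        raise AssertionError("zero total cluster probability at some time point")
    return S / row_sums[:, None]


def cluster_covariances(assignment: np.ndarray, covariances: list[np.ndarray],
                        beta: np.ndarray) -> list[np.ndarray]:
    """Occupancy-weighted convex combination of member covariances."""
    K_c = int(assignment.max()) + 1
    Q = []
    for c in range(K_c):
        members = np.flatnonzero(assignment == c)
        w = beta[members]
        if w.sum() <= 0:
            raise ValueError(f"cluster {c} has zero total occupancy")
        Q.append(
            sum(wi * covariances[m] for wi, m in zip(w, members)) / w.sum()
        )
    return Q


def hc_hmm(ensemble: RunEnsemble, K_c: int | None = None) -> ClusterModel:
    """Full consensus pipeline over an ensemble.

    ``K_c`` defaults to the number of states K of the individual runs.
    """
    if K_c is None:
        K_c = ensemble.fits[0].K
    stack = stack_states(ensemble)
    sim = state_similarity(stack)
    assignment, merge_table = ward_cluster(sim, K_c)
    beta = stack.Y.mean(axis=0)
    S = cluster_series(stack, assignment)
    covs = [ensemble.fits[r].covariances[k] for (r, k) in stack.source]
    Q = cluster_covariances(assignment, covs, beta)
    sizes = np.bincount(assignment, minlength=K_c)
    return ClusterModel(
        assignment=assignment,
        merge_table=merge_table,
        S=S,
        Q=Q,
        beta=beta,
        cluster_sizes=sizes,
    )
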