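"""Input/output and the sessioned time-series container.

Multichannel recordings (fMRI parcel time courses, MEG power envelopes,
synthetic data) are handled as a single concatenated matrix of shape
(time points x channels) together with a list of session intervals.
A "session" is any maximal stretch of temporally contiguous data: a
scanner run, one subject's recording, or a segment between artifact
excisions.  The hidden-Markov machinery never models a transition across
a session boundary, so the boundaries must survive every round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SessionedTimeSeries",
    "load_timeseries",
    "standardize",
    "write_state_series",
    "read_state_series",
    "write_covariances",
    "read_covariances",
    "write_report",
    "read_report",
]


@dataclass
class SessionedTimeSeries:
    """Concatenated multichannel time series with session structure.

    Parameters
    ----------
    data : ndarray, shape (T_total, P)
        Observations; rows are time points, columns channels/parcels.
    session_lengths : sequence of int
        Length of each session, in order.  Sessions tile ``[0, T_total)``
        as half-open intervals.
    subjects : sequence of int, optional
        Integer subject label per session.  Defaults to one subject per
        session (``0, 1, 2, ...``).
    """

    data: np.ndarray
    session_lengths: list[int]
    subjects: list[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (time x channels) matrix")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        self.session_lengths = [int(l) for l in self.session_lengths]
        if any(l < 2 for l in self.session_lengths):
            raise ValueError("every session must have length >= 2")
        if sum(self.session_lengths) != self.data.shape[0]:
            raise ValueError(
                f"session lengths sum to {sum(self.session_lengths)} "
                f"but the matrix has {self.data.shape[0]} rows"
            )
        if self.subjects is None:
            self.subjects = list(range(len(self.session_lengths)))
        else:
            self.subjects = [int(s) for s in self.subjects]
        if len(self.subjects) != len(self.session_lengths):
            raise ValueError("one subject label per session required")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_sessions(self) -> int:
        return len(self.session_lengths)

    @property
    def sessions(self) -> list[tuple[int, int]]:
        """Half-open ``[start, end)`` row intervals, one per session."""
        bounds = np.concatenate([[0], np.cumsum(self.session_lengths)])
        return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]

    @property
    def session_starts(self) -> np.ndarray:
        """Boolean mask over rows; True at the first row of each session."""
        mask = np.zeros(self.n_timepoints, dtype=bool)
        mask[np.concatenate([[0], np.cumsum(self.session_lengths)[:-1]])] = True
        return mask


def load_timeseries(matrix_path, session_index_path) -> SessionedTimeSeries:
    """Load a data matrix and its session index from disk.

    The matrix file is headerless delimited text (comma, tab or
    whitespace separated; one row per time point) or a NumPy ``.npy``
    array.  The session index is a text file with one session per line:
    either ``length`` or ``length,subject``.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".npy":
        data = np.load(matrix_path)
    else:
        with open(matrix_path) as fh:
            first = fh.readline()
        delim = "," if "," in first else ("\t" if "\t" in first else None)
        try:
            data = np.loadtxt(matrix_path, delimiter=delim, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"non-numeric cell in {matrix_path}: {exc}") from exc

    lengths, subjects, any_subject = [], [], False
    with open(session_index_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            lengths.append(int(parts[0]))
            if len(parts) > 1 and parts[1] != "":
                subjects.append(int(parts[1]))
                any_subject = True
            else:
                subjects.append(len(subjects))
    return SessionedTimeSeries(
        data, lengths, subjects=subjects if any_subject else None
    )


def standardize(ts: SessionedTimeSeries) -> SessionedTimeSeries:
    """Z-score each channel within each session (mean 0, SD 1).

    Standardizing per session removes session-level offset and scale
    differences before a group-level fit on the concatenation.  Raises
    if any channel is constant within a session.
    """
    out = ts.data.copy()
    for i, (a, b) in enumerate(ts.sessions):
        block = out[a:b]
        sd = block.std(axis=0)
        if np.any(sd == 0):
            bad = int(np.argmax(sd == 0))
            raise ValueError(f"zero-variance channel {bad} in session {i}")
        out[a:b] = (block - block.mean(axis=0)) / sd
    return SessionedTimeSeries(out, ts.session_lengths, subjects=list(ts.subjects))


# ---------------------------------------------------------------------------
# writers / readers


def write_state_series(gamma: np.ndarray, path) -> None:
    """Write a (T x K) state probability time series as headed CSV."""
    gamma = np.asarray(gamma)
    if gamma.ndim != 2 or gamma.shape[1] < 1:
        raise ValueError("state series must be a T x K matrix with K >= 1")
    cols = [f"state_{k + 1}" for k in range(gamma.shape[1])]
    pd.DataFrame(gamma, columns=cols).to_csv(path, index=False, float_format="%.17g")


def read_state_series(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=np.float64)


def write_covariances(covs, path) -> None:
    """Write a list of K (P x P) matrices as one long-format labeled CSV."""
    covs = [np.asarray(c) for c in covs]
    if len(covs) == 0:
        raise ValueError("no covariance matrices to write")
    rows = []
    for k, c in enumerate(covs):
        p = c.shape[0]
        ii, jj = np.meshgrid(range(p), range(p), indexing="ij")
        rows.append(
            pd.DataFrame(
                {
                    "state": k + 1,
                    "row": ii.ravel(),
                    "col": jj.ravel(),
                    "value": c.ravel(),
                }
            )
        )
    pd.concat(rows).to_csv(path, index=False, float_format="%.17g")


def read_covariances(path) -> list[np.ndarray]:
    df = pd.read_csv(path)
    out = []
    for k in sorted(df["state"].unique()):
        sub = df[df["state"] == k]
        p = int(sub["row"].max()) + 1
        c = np.zeros((p, p))
        c[sub["row"], sub["col"]] = sub["value"]
        out.append(c)
    return out


def write_report(report: dict, path) -> None:
    """Write a structured report (e.g. a stability report) as JSON."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
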