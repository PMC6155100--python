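"""Scan-level processing: nuisance regression, temporal filtering, connectivity.

A *scan* is one subject x paradigm acquisition, represented as a node x
timepoint matrix of mean regional signals together with its nuisance
regressors (task co-activation regressors, tissue signals, motion expansion,
frame-wise displacement). The processing contract is: regress nuisance, then
temporally filter, then correlate node pairs (Pearson), yielding one
symmetric unit-diagonal connectivity matrix per scan.

Edge indexing convention (shared by every module): 0-based, upper triangle,
row-major, i.e. edge k runs over pairs (0,1), (0,2), ..., (0,N-1), (1,2), ...
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .exceptions import ParameterError

__all__ = [
    "ScanTimeSeries",
    "ConnectivityMatrix",
    "regress_nuisance",
    "temporal_filter",
    "compute_connectivity",
    "vectorize_edges",
    "devectorize_edges",
    "n_edges",
    "edge_pairs",
    "edge_index",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ScanTimeSeries:
    """One subject-paradigm acquisition.

    Parameters
    ----------
    subject_id, paradigm_id:
        Identifiers; free-form strings.
    data:
        ``(n_nodes, n_timepoints)`` array of mean regional signals.
    sampling_interval:
        Repetition time in seconds.
    nuisance:
        ``(n_timepoints, n_regressors)`` array of nuisance regressors
        (task regressors, WM/CSF signals, 24 motion parameters, FD), or
        ``None``. The motion expansion is accepted as supplied columns;
        derivatives/squares are not computed here.
    paradigm_class:
        ``"rest"`` or ``"task"``; selects the default filter band downstream.
    """

    subject_id: str
    paradigm_id: str
    data: np.ndarray
    sampling_interval: float = 2.0
    nuisance: np.ndarray | None = None
    paradigm_class: str = "task"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("data must be a 2-D (nodes x timepoints) array")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError(
                f"scan {self.subject_id}/{self.paradigm_id}: non-finite values in data"
            )
        if self.sampling_interval <= 0:
            raise ParameterError("sampling_interval must be positive")
        if self.nuisance is not None:
            self.nuisance = np.asarray(self.nuisance, dtype=float)
            if self.nuisance.ndim != 2 or self.nuisance.shape[0] != self.n_timepoints:
                raise ParameterError(
                    "nuisance must be (n_timepoints, n_regressors), got "
                    f"{self.nuisance.shape} for {self.n_timepoints} timepoints"
                )
            if not np.all(np.isfinite(self.nuisance)):
                raise ParameterError("non-finite values in nuisance regressors")
            # regression must remain estimable
            if self.n_timepoints < 2 * (self.nuisance.shape[1] + 1):
                raise ParameterError(
                    f"{self.n_timepoints} timepoints cannot support "
                    f"{self.nuisance.shape[1]} nuisance regressors"
                )

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node Pearson correlation matrix with unit diagonal."""

    matrix: np.ndarray
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ParameterError("connectivity matrix must be square")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ParameterError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ParameterError("connectivity matrix must have unit diagonal")
        if np.nanmax(np.abs(m)) > 1 + 1e-8:
            raise ParameterError("correlations must lie in [-1, 1]")
        self.matrix = m
        if self.node_ids is None:
            self.node_ids = np.arange(m.shape[0])
        else:
            self.node_ids = np.asarray(self.node_ids)
            if self.node_ids.shape[0] != m.shape[0]:
                raise ParameterError("node_ids length does not match matrix")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# edge vectorization (canonical upper triangle)
# ---------------------------------------------------------------------------

def n_edges(n_nodes: int) -> int:
    """Number of undirected edges among ``n_nodes`` nodes: N(N-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


def edge_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) node index arrays for the canonical edge ordering (i < j)."""
    return np.triu_indices(n_nodes, k=1)


def edge_index(i: np.ndarray, j: np.ndarray, n_nodes: int) -> np.ndarray:
    """Vector position of edge (i, j), i < j, in the canonical ordering."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    if np.any(i >= j) or np.any(i < 0) or np.any(j >= n_nodes):
        raise ParameterError("edge indices must satisfy 0 <= i < j < n_nodes")
    return i * (2 * n_nodes - i - 1) // 2 + (j - i - 1)


def vectorize_edges(m: ConnectivityMatrix | np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Upper-triangle (row-major, i<j) vectorization of a symmetric matrix."""
    a = m.matrix if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ParameterError("expected a square matrix")
    if np.nanmax(np.abs(a - a.T)) > atol:
        raise ParameterError("matrix is asymmetric beyond tolerance")
    iu, ju = edge_pairs(a.shape[0])
    return a[iu, ju].copy()


def devectorize_edges(vec: np.ndarray, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_edges` (restores a symmetric matrix)."""
    vec = np.asarray(vec, dtype=float)
    e = vec.shape[0]
    # solve N(N-1)/2 = e
    n = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if n_edges(n) != e:
        raise ParameterError(f"vector length {e} is not N(N-1)/2 for any integer N")
    out = np.full((n, n), 0.0)
    iu, ju = edge_pairs(n)
    out[iu, ju] = vec
    out += out.T
    np.fill_diagonal(out, diagonal)
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _independent_columns(x: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Greedy left-to-right selection of linearly independent columns."""
    keep: list[int] = []
    q: list[np.ndarray] = []
    for k in range(x.shape[1]):
        v = x[:, k].astype(float)
        norm0 = np.linalg.norm(v)
        if norm0 == 0:
            continue
        for b in q:
            v = v - (b @ v) * b
        if np.linalg.norm(v) > tol * max(norm0, 1.0):
            q.append(v / np.linalg.norm(v))
            keep.append(k)
    return np.asarray(keep, dtype=int)


def regress_nuisance(ts: ScanTimeSeries, tol: float = 1e-10) -> ScanTimeSeries:
    """Residualize every node series on [intercept | nuisance regressors].

    Returns a new scan whose node series are ordinary least-squares residuals;
    each residual series is orthogonal to the intercept and to every retained
    regressor. Collinear regressor columns are dropped with a warning naming
    the dropped column indices.
    """
    t = ts.n_timepoints
    cols = [np.ones((t, 1))]
    if ts.nuisance is not None and ts.nuisance.shape[1] > 0:
        cols.append(ts.nuisance)
    x = np.hstack(cols)
    keep = _independent_columns(x, tol=tol)
    if keep.shape[0] < x.shape[1]:
        dropped = sorted(set(range(x.shape[1])) - set(keep.tolist()))
        # column 0 is the intercept; report nuisance column indices (0-based)
        warnings.warn(
            "rank-deficient nuisance design; dropped collinear column(s) "
            f"{[c - 1 for c in dropped]}",
            stacklevel=2,
        )
        x = x[:, keep]
    beta, *_ = np.linalg.lstsq(x, ts.data.T, rcond=None)
    resid = ts.data.T - x @ beta
    return replace(ts, data=resid.T, nuisance=ts.nuisance)


def temporal_filter(
    ts: ScanTimeSeries,
    low_hz: float,
    high_hz: float,
    order: int = 4,
) -> ScanTimeSeries:
    """Zero-phase Butterworth filtering of every node series.

    ``low_hz > 0`` with finite ``high_hz`` gives a band-pass; ``high_hz`` of
    ``inf`` (or >= Nyquist) gives a high-pass; ``low_hz == 0`` gives a
    low-pass. The filter is applied forward-backward (``sosfiltfilt``), so the
    effective order is doubled and the phase response is zero.
    """
    fs = 1.0 / ts.sampling_interval
    nyq = fs / 2.0
    if low_hz < 0 or high_hz <= low_hz:
        raise ParameterError(f"invalid band ({low_hz}, {high_hz}) Hz")
    if low_hz >= nyq:
        raise ParameterError(f"low cut {low_hz} Hz is at/above Nyquist ({nyq} Hz)")
    highpass = not np.isfinite(high_hz) or high_hz >= nyq * (1 - 1e-9)
    if low_hz == 0 and highpass:
        raise ParameterError("band (0, >=Nyquist) would be a no-op filter")
    if low_hz == 0:
        sos = _signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")
    elif highpass:
        sos = _signal.butter(order, low_hz, btype="highpass", fs=fs, output="sos")
    else:
        sos = _signal.butter(order, (low_hz, high_hz), btype="bandpass", fs=fs, output="sos")
    default_pad = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    padlen = min(default_pad, ts.n_timepoints - 1)
    out = _signal.sosfiltfilt(sos, ts.data, axis=1, padlen=padlen)
    return replace(ts, data=np.ascontiguousarray(out))


def compute_connectivity(ts: ScanTimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation between node series."""
    sd = ts.data.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ParameterError(
            f"zero-variance node series (node index {bad[0]}) in "
            f"{ts.subject_id}/{ts.paradigm_id}; drop the node before correlating"
        )
    r = np.corrcoef(ts.data)
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(matrix=r)
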