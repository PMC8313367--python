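"""Sliding-window functional connectivity.

Turns a region-of-interest (ROI) time series into a sequence of windowed
Fisher-Z correlation matrices: the time axis is swept with a rectangular
window of ``w`` repetition times (TRs) moved by ``step`` TRs, the Pearson
correlation between every pair of regions is computed inside each window,
and the correlations are variance-stabilized with the Fisher R-Z transform
z = arctanh(r).  Self-correlations (r = 1) would map to infinity, so the
diagonal is set to 0 by convention and excluded from all downstream vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "RoiTimeSeries",
    "WindowedFcSet",
    "window_starts",
    "window_length_from_seconds",
    "pearson_fc",
    "fisher_z",
    "fisher_z_inv",
    "build_windowed_fc",
    "vectorize_upper",
    "devectorize_upper",
    "window_variance",
]

#: correlations with |r| >= 1 - CLAMP are clamped before arctanh so Fisher-Z
#: output stays finite without materially distorting estimates
CLAMP = 1e-7


@dataclass
class RoiTimeSeries:
    """One subject's L x M matrix of region signals plus metadata.

    L rows are time points (sampled every ``tr_seconds``), M columns are
    regions.  Signals are in arbitrary units; only correlations are used.
    """

    subject_id: str
    group: str
    data: np.ndarray
    tr_seconds: float = 2.0
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("time series must be an L x M matrix with L > 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.region_labels:
            self.region_labels = [f"R{i + 1}" for i in range(self.data.shape[1])]
        if len(self.region_labels) != self.data.shape[1]:
            raise ValueError("region_labels length must match number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class WindowedFcSet:
    """Per-subject sequence of symmetric M x M Fisher-Z matrices.

    ``matrices`` has shape (N, M, M) with N = floor((L - w)/step) + 1;
    windows are half-open index ranges [start, start + w).  Diagonals are 0.
    """

    subject_id: str
    group: str
    window_length_tr: int
    step_tr: int
    matrices: np.ndarray
    window_start_indices: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]

    def vectors(self) -> np.ndarray:
        """(N, M(M-1)/2) array of upper-triangle feature vectors."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.matrices[:, iu[0], iu[1]]


def window_starts(L: int, w: int, step: int = 1) -> np.ndarray:
    """0-based start indices of half-open windows [start, start + w) in [0, L)."""
    if w < 1:
        raise ValueError("window length must be >= 1")
    if w > L:
        raise ValueError(f"window longer than series (w={w} > L={L})")
    if step < 1:
        raise ValueError("step must be >= 1")
    return np.arange(0, L - w + 1, step)


def window_length_from_seconds(seconds: float, tr_seconds: float) -> int:
    """Convert a window length in seconds to TRs, rounding to the nearest TR."""
    w = int(round(seconds / tr_seconds))
    if w < 1:
        raise ValueError("window shorter than one TR")
    return w


def pearson_fc(window: np.ndarray, window_index: int | None = None) -> np.ndarray:
    """Pearson correlation matrix of a w x M window of signals.

    Requires w >= 3 and every column non-constant within the window.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] < 3:
        raise ValueError("window must be a w x M matrix with w >= 3")
    sd = window.std(axis=0)
    if np.any(sd == 0):
        region = int(np.flatnonzero(sd == 0)[0])
        where = f" in window {window_index}" if window_index is not None else ""
        raise ValueError(f"region {region} is constant{where}; correlation undefined")
    r = np.corrcoef(window, rowvar=False)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r):
    """Fisher R-Z transform z = 1/2 ln((1+r)/(1-r)) = arctanh(r).

    Inputs with |r| >= 1 - 1e-7 are clamped to +/-(1 - 1e-7) so the output is
    finite; |r| > 1 beyond floating tolerance is an error.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-9):
        raise ValueError("correlation magnitude exceeds 1")
    out = np.arctanh(np.clip(arr, -(1 - CLAMP), 1 - CLAMP))
    return out if arr.ndim else float(out)


def fisher_z_inv(z):
    """Inverse Fisher transform r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return out if np.ndim(z) else float(out)


def build_windowed_fc(
    ts: RoiTimeSeries,
    w: int | None = None,
    step: int = 1,
    *,
    window_seconds: float | None = None,
) -> WindowedFcSet:
    """Sliding-window Fisher-Z connectivity for one subject.

    Exactly one of ``w`` (TRs) or ``window_seconds`` must be given; seconds
    are converted as w = round(seconds / tr_seconds).  Each window matrix is
    fisher_z(pearson correlation) with the diagonal forced to 0.
    """
    if (w is None) == (window_seconds is None):
        raise ValueError("give exactly one of w or window_seconds")
    if w is None:
        w = window_length_from_seconds(window_seconds, ts.tr_seconds)
    L, M = ts.data.shape
    starts = window_starts(L, w, step)
    if w < 3:
        raise ValueError("window must span at least 3 TRs for correlation")

    # (N, M, w) view, strided; no copy of the underlying series
    wins = sliding_window_view(ts.data, w, axis=0)[starts]
    centered = wins - wins.mean(axis=-1, keepdims=True)
    norms = np.sqrt(np.einsum("nmw,nmw->nm", centered, centered))
    bad = norms == 0
    if np.any(bad):
        n, m = np.argwhere(bad)[0]
        raise ValueError(
            f"region {ts.region_labels[m]} is constant in window {n}; "
            "correlation undefined"
        )
    r = np.einsum("niw,njw->nij", centered, centered) / (
        norms[:, :, None] * norms[:, None, :]
    )
    z = np.arctanh(np.clip(r, -(1 - CLAMP), 1 - CLAMP))
    idx = np.arange(M)
    z[:, idx, idx] = 0.0
    return WindowedFcSet(
        subject_id=ts.subject_id,
        group=ts.group,
        window_length_tr=w,
        step_tr=step,
        matrices=z,
        window_start_indices=starts,
    )


def vectorize_upper(matrix: np.ndarray) -> np.ndarray:
    """Row-major upper triangle (diagonal excluded) of a symmetric matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("input must be a square matrix")
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def devectorize_upper(vec: np.ndarray, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; restores a symmetric matrix."""
    vec = np.asarray(vec, dtype=float)
    e = vec.shape[0]
    m = int((1 + np.sqrt(1 + 8 * e)) / 2)
    if m * (m - 1) // 2 != e:
        raise ValueError(f"length {e} is not M(M-1)/2 for integer M")
    out = np.full((m, m), 0.0)
    iu = np.triu_indices(m, k=1)
    out[iu] = vec
    out += out.T
    np.fill_diagonal(out, diagonal)
    return out


def window_variance(fc_vector: np.ndarray) -> float:
    """Population variance of a vectorized window's FC entries."""
    v = np.asarray(fc_vector, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 entries")
    return float(np.var(v))
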