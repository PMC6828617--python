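"""Per-condition ROI-to-ROI Fisher-z connectivity maps and their vectorization.

For each condition the scans on which its HRF-convolved regressor dominates
are concatenated across runs; Pearson correlation over those pooled scans
gives an ROI x ROI matrix, Fisher z-transformed (z = atanh r, with r clipped
just inside +-1), diagonal set to 0. The strict lower triangle in row-major
order is the fixed feature space: n(n-1)/2 edges, e.g. 30,135 for a 246-node
parcellation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMap",
    "FeatureVector",
    "edge_index",
    "condition_scan_indices",
    "fc_map",
    "vectorize_lower_triangle",
    "devectorize",
    "fisher_z",
]

_R_CLIP = 1.0 - 1e-7
_TAU = 1e-6


@dataclass
class ConnectivityMap:
    subject_id: str | None
    condition_label: str
    z_matrix: np.ndarray
    n_scans_used: int

    def __post_init__(self) -> None:
        z = np.asarray(self.z_matrix, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z_matrix must be square")
        if not np.allclose(z, z.T, atol=1e-10):
            raise ValueError("z_matrix must be symmetric")
        if not np.all(np.isfinite(z)):
            raise ValueError("z_matrix must be finite")
        self.z_matrix = z

    @property
    def n_rois(self) -> int:
        return self.z_matrix.shape[0]


@dataclass(frozen=True)
class FeatureVector:
    """Strict-lower-triangle edge values with their fixed (i, j) index."""

    values: np.ndarray
    edge_index: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.edge_index):
            raise ValueError("values and edge_index lengths differ")


@lru_cache(maxsize=None)
def edge_index(n_rois: int) -> tuple[tuple[int, int], ...]:
    """Row-major strict lower triangle: (1,0), (2,0), (2,1), (3,0), ..."""
    return tuple((i, j) for i in range(1, n_rois) for j in range(i))


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilising z = atanh(r) with r clipped just inside +-1."""
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def condition_scan_indices(
    task_regressors: pd.DataFrame, condition: str, tau: float = _TAU
) -> np.ndarray:
    """Scans assigned to ``condition``: its regressor exceeds ``tau`` AND is
    the maximum across conditions (so HRF spill-over between nearby blocks
    never assigns a scan to two conditions). Raises if no scan qualifies."""
    if condition not in task_regressors.columns:
        raise KeyError(f"condition {condition!r} not among regressors")
    arr = task_regressors.to_numpy(dtype=float)
    col = task_regressors.columns.get_loc(condition)
    sel = (arr[:, col] > tau) & (arr[:, col] >= arr.max(axis=1))
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise ValueError(f"no scans assigned to condition {condition!r}")
    return idx


def fc_map(
    denoised_ts_by_run: Sequence[np.ndarray],
    scan_indices_by_run: Sequence[np.ndarray],
    condition: str,
    subject_id: str | None = None,
) -> ConnectivityMap:
    """Fisher-z connectivity over the condition's scans pooled across runs.

    Correlation is computed on the concatenated scans (not averaged per-run
    correlations). A zero-variance ROI gets r = 0 on all its pairs, with a
    warning; fewer than 3 pooled scans raises.
    """
    if len(denoised_ts_by_run) != len(scan_indices_by_run):
        raise ValueError("run counts differ between series and indices")
    data = np.vstack(
        [ts[idx] for ts, idx in zip(denoised_ts_by_run, scan_indices_by_run)]
    )
    n = data.shape[0]
    if n < 3:
        raise ValueError(f"condition {condition!r}: only {n} scans (< 3)")
    sd = data.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance ROI(s); their correlations set to 0"
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(data, rowvar=False)
        r[dead, :] = 0.0
        r[:, dead] = 0.0
    else:
        r = np.corrcoef(data, rowvar=False)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMap(
        subject_id=subject_id, condition_label=condition, z_matrix=z, n_scans_used=n
    )


def vectorize_lower_triangle(cm: ConnectivityMap | np.ndarray) -> FeatureVector:
    """Strict lower triangle (row-major) of a symmetric matrix as a feature
    vector; invertible via :func:`devectorize`."""
    M = cm.z_matrix if isinstance(cm, ConnectivityMap) else np.asarray(cm, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("matrix must be symmetric (beyond 1e-10)")
    n = M.shape[0]
    i, j = np.tril_indices(n, k=-1)
    return FeatureVector(values=M[i, j], edge_index=edge_index(n))


def devectorize(values: np.ndarray, n_rois: int) -> np.ndarray:
    """Symmetric matrix (zero diagonal) from a lower-triangle feature vector."""
    values = np.asarray(values, dtype=float)
    if len(values) != n_rois * (n_rois - 1) // 2:
        raise ValueError("length does not match n_rois(n_rois-1)/2")
    M = np.zeros((n_rois, n_rois))
    i, j = np.tril_indices(n_rois, k=-1)
    M[i, j] = values
    M[j, i] = values
    return M
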