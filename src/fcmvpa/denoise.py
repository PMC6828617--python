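"""Confound regression and band-pass filtering of ROI time series.

The denoising contract mirrors standard task-FC practice: ordinary least
squares regression of each ROI series on an intercept, the six rigid-body
motion parameters, nuisance (physiological) components, a first-order linear
trend, and the HRF-convolved task regressors — so that residual correlations
reflect connectivity rather than shared task co-activation — followed by
zero-phase band-pass filtering to 0.01-0.1 Hz. Regression and filtering are
applied per run; runs are only concatenated later, at the correlation stage.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .synthetic import BlockDesign, SubjectData, condition_regressors

__all__ = [
    "build_task_regressors",
    "build_confound_matrix",
    "regress_confounds",
    "bandpass_filter",
    "denoise_run",
    "denoise_subject",
]


def build_task_regressors(
    design: BlockDesign,
    tr: float | None = None,
    n_scans: int | None = None,
    run: int = 0,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """HRF-convolved unit-boxcar regressor per condition for one run.

    Columns are sorted condition keys (``emotion|stimulus_type``). A requested
    condition absent from the design yields an all-zero column with a warning.
    """
    if tr is not None and abs(tr - design.tr) > 1e-12:
        raise ValueError("tr disagrees with the design's TR")
    if n_scans is None:
        n_scans = design.n_scans_per_run
    blocks = design.runs[run]
    last_end = max((b.onset_s + b.duration_s for b in blocks), default=0.0)
    if n_scans * design.tr < last_end:
        raise ValueError("n_scans too small to cover the last block")
    regs = condition_regressors(design, run, n_scans)
    if conditions is not None:
        cols = {}
        for c in sorted(conditions):
            if c in regs.columns:
                cols[c] = regs[c].to_numpy()
            else:
                warnings.warn(f"condition {c!r} absent from design; zero regressor")
                cols[c] = np.zeros(n_scans)
        regs = pd.DataFrame(cols)
    return regs


def build_confound_matrix(
    subject_run_confounds: pd.DataFrame,
    design: BlockDesign,
    tr: float | None = None,
    n_scans: int | None = None,
    run: int = 0,
) -> pd.DataFrame:
    """Assemble the full nuisance design:
    ``[intercept | motion & components (as supplied) | linear_trend | task...]``.

    The linear trend is the centered scan index. Raises on length mismatch,
    duplicate column names, or a rank-deficient result.
    """
    if n_scans is None:
        n_scans = design.n_scans_per_run
    if len(subject_run_confounds) != n_scans:
        raise ValueError(
            f"confounds have {len(subject_run_confounds)} rows, expected {n_scans}"
        )
    task = build_task_regressors(design, tr, n_scans, run=run)
    trend = np.arange(n_scans, dtype=float)
    trend -= trend.mean()
    parts = [
        pd.DataFrame({"intercept": np.ones(n_scans)}),
        subject_run_confounds.reset_index(drop=True),
        pd.DataFrame({"linear_trend": trend}),
        task.add_prefix("task_"),
    ]
    X = pd.concat(parts, axis=1)
    if len(X.columns) != len(set(X.columns)):
        raise ValueError("duplicate confound column names")
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError("confound matrix is rank-deficient")
    return X


def regress_confounds(ts: np.ndarray, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """OLS residual of each ROI series on the confound matrix columns."""
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] != Xa.shape[0]:
        raise ValueError("time series and confound matrix row counts differ")
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise ValueError("confound matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(Xa, ts, rcond=None)
    return ts - Xa @ beta


def bandpass_filter(
    ts: np.ndarray, tr: float, low_hz: float = 0.01, high_hz: float = 0.1
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (order 4, applied forward-backward)."""
    fs = 1.0 / tr
    nyq = fs / 2.0
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz must be below the Nyquist frequency {nyq} Hz")
    ts = np.asarray(ts, dtype=float)
    if low_hz > 0:
        b, a = signal.butter(4, [low_hz, high_hz], btype="band", fs=fs)
    else:
        b, a = signal.butter(4, high_hz, btype="low", fs=fs)
    padlen = min(3 * max(len(a), len(b)), ts.shape[0] - 1)
    return signal.filtfilt(b, a, ts, axis=0, padlen=padlen)


def denoise_run(
    ts: np.ndarray,
    confounds: pd.DataFrame,
    design: BlockDesign,
    run: int,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> np.ndarray:
    """Regress the assembled confound matrix out of one run, then band-pass."""
    X = build_confound_matrix(confounds, design, n_scans=ts.shape[0], run=run)
    resid = regress_confounds(ts, X)
    return bandpass_filter(resid, design.tr, low_hz, high_hz)


def denoise_subject(
    subject: SubjectData,
    design: BlockDesign,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> SubjectData:
    """Denoise every run of a subject; returns a new SubjectData."""
    ts = [
        denoise_run(t, c, design, r, low_hz, high_hz)
        for r, (t, c) in enumerate(zip(subject.timeseries, subject.confounds))
    ]
    return SubjectData(
        subject_id=subject.subject_id, timeseries=ts, confounds=subject.confounds
    )
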