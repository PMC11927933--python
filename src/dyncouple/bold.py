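"""Minimal ROI-timeseries cleanup for resting-state BOLD.

Operates on region-of-interest (ROI) timeseries that have already been
extracted from preprocessed images.  Three steps, in a configurable but
logged order: per-ROI centering and variance normalisation, zero-phase
temporal bandpass to the resting-state band (0.01-0.08 Hz), and ordinary
least-squares removal of a 24-parameter motion nuisance set (the six rigid
body parameters, their one-scan lags, and both sets squared).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

logger = logging.getLogger(__name__)

NETWORKS = ("DMN", "ECN", "SN")

#: canonical 12-ROI hub set across the three intrinsic connectivity networks
DEFAULT_NETWORKS: dict[str, str] = {
    "mPFC": "DMN", "vPCC": "DMN", "dPCC": "DMN", "lAG": "DMN", "rAG": "DMN",
    "ldlPFC": "ECN", "rdlPFC": "ECN", "lPPC": "ECN", "rPPC": "ECN",
    "dACC": "SN", "lAI": "SN", "rAI": "SN",
}


@dataclass
class RoiTimeseries:
    """ROI BOLD timeseries: ``values`` is (n_trs, n_rois), one column per ROI."""

    values: np.ndarray
    roi_labels: tuple[str, ...]
    tr: float
    network_of: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_labels = tuple(self.roi_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_trs, n_rois)")
        if self.values.shape[1] != len(self.roi_labels):
            raise ValueError("roi_labels length does not match values")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("ROI labels must be unique")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("timeseries contains non-finite values")

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def column(self, roi: str) -> np.ndarray:
        return self.values[:, self.roi_labels.index(roi)]

    def with_values(self, values: np.ndarray) -> "RoiTimeseries":
        return RoiTimeseries(values, self.roi_labels, self.tr, dict(self.network_of))


@dataclass
class ConfoundTable:
    """Six rigid-body motion parameters per TR (translations mm, rotations rad)."""

    motion6: np.ndarray

    def __post_init__(self) -> None:
        self.motion6 = np.asarray(self.motion6, dtype=float)
        if self.motion6.ndim != 2 or self.motion6.shape[1] != 6:
            raise ValueError(
                f"motion6 must be (n_trs, 6); got {self.motion6.shape}"
            )


def center_and_scale(ts: RoiTimeseries) -> RoiTimeseries:
    """Standardise each ROI series to mean 0, sd 1 (ddof = 0)."""
    if ts.n_trs < 2:
        raise ValueError("need at least 2 TRs")
    mu = ts.values.mean(axis=0)
    sd = ts.values.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [ts.roi_labels[i] for i in flat]
        raise ValueError(f"zero-variance ROI(s): {names}")
    return ts.with_values((ts.values - mu) / sd)


def bandpass(ts: RoiTimeseries, lo: float = 0.01, hi: float = 0.08,
             order: int = 4) -> RoiTimeseries:
    """Zero-phase Butterworth bandpass of each ROI series.

    Applied forward and backward (``filtfilt``) so no phase shift is
    introduced; effective attenuation order is twice ``order``.
    """
    nyq = 0.5 / ts.tr
    if not (0 < lo < hi < nyq):
        raise ValueError(
            f"band ({lo}, {hi}) Hz must satisfy 0 < lo < hi < Nyquist ({nyq:g} Hz)"
        )
    b, a = _butter_band(order, lo / nyq, hi / nyq)
    filtered = filtfilt(b, a, ts.values, axis=0)
    return ts.with_values(filtered)


@lru_cache(maxsize=32)
def _butter_band(order: int, lo_norm: float, hi_norm: float):
    return butter(order, [lo_norm, hi_norm], btype="band")


def build_friston24(motion6: ConfoundTable) -> np.ndarray:
    """24-parameter motion regressor set: [m(t), m(t-1), m(t)^2, m(t-1)^2].

    The first row of the lagged blocks is zero-filled (no previous scan).
    """
    m = motion6.motion6
    if m.shape[0] < 2:
        raise ValueError("need at least 2 TRs")
    lag = np.zeros_like(m)
    lag[1:] = m[:-1]
    out = np.hstack([m, lag, m**2, lag**2])
    assert out.shape[1] == 24
    return out


def nuisance_regress(ts: RoiTimeseries, regressors: np.ndarray) -> RoiTimeseries:
    """OLS residuals of each ROI series on ``regressors`` plus an intercept."""
    X = np.asarray(regressors, dtype=float)
    if X.ndim != 2 or X.shape[0] != ts.n_trs:
        raise ValueError(
            f"regressors must be ({ts.n_trs}, k); got {X.shape}"
        )
    if X.shape[1] >= ts.n_trs:
        raise ValueError("more regressors than timepoints")
    design = np.column_stack([np.ones(ts.n_trs), X])
    # rank check with column attribution via the R diagonal
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = design.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if np.any(diag < tol):
        bad = np.flatnonzero(diag < tol) - 1  # shift past intercept
        raise ValueError(
            f"rank-deficient nuisance design; collinear column(s) {bad.tolist()}"
        )
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    resid = ts.values - design @ beta
    return ts.with_values(resid)


def preprocess(
    ts: RoiTimeseries,
    confounds: ConfoundTable | None = None,
    lo: float = 0.01,
    hi: float = 0.08,
    order: int = 4,
    steps: Sequence[str] = ("center", "bandpass", "regress"),
) -> RoiTimeseries:
    """Run the cleanup pipeline in the given step order.

    With ``confounds=None`` the regression step is a pass-through (zero
    nuisance), which keeps the stage order intact for simulated data.
    """
    for step in steps:
        if step == "center":
            ts = center_and_scale(ts)
        elif step == "bandpass":
            ts = bandpass(ts, lo=lo, hi=hi, order=order)
        elif step == "regress":
            if confounds is None:
                logger.debug("no confounds supplied; regression pass-through")
                continue
            ts = nuisance_regress(ts, build_friston24(confounds))
        else:
            raise ValueError(f"unknown preprocessing step {step!r}")
    return ts
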