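"""Gaussian tapered sliding-window functional connectivity and its coupling
with an EEG band-power timeseries.

The window scheme is a Gaussian taper of full width at half maximum (FWHM)
27.78 epochs inside a 60-epoch (108 s at TR = 1.8 s) window that slides in
1-TR increments, which for a 306-epoch run yields 247 windows overlapping by
106.2 s.  Per window, functional connectivity (FC) is the taper-weighted
Pearson correlation between two ROI series; the taper enters as observation
weights so each correlation emphasises the window center without rescaling
the signal.  The coupling statistic is then the ordinary Pearson correlation
across windows between the FC timeseries and the window-aligned power
timeseries, Fisher-Z transformed for group statistics.  A positive lag
shifts the fMRI series later relative to the EEG, reflecting hemodynamic
sluggishness.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .bold import RoiTimeseries
from .eeg import PowerSeries

logger = logging.getLogger(__name__)

Pair = tuple[str, str]

DEFAULT_WINDOW_EPOCHS = 60
DEFAULT_STEP_EPOCHS = 1
DEFAULT_FWHM_EPOCHS = 27.78
DEFAULT_MAX_LAG = 5

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def gaussian_taper(length_epochs: int, fwhm_epochs: float) -> np.ndarray:
    """Gaussian taper with peak 1 at the window center.

    ``w[i] = exp(-(i - c)^2 / (2 sigma^2))`` with ``c = (length - 1)/2`` and
    ``sigma = fwhm / (2 sqrt(2 ln 2))``.
    """
    if length_epochs < 2:
        raise ValueError("window length must be >= 2 epochs")
    if fwhm_epochs <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm_epochs / _FWHM_TO_SIGMA
    i = np.arange(length_epochs, dtype=float)
    c = (length_epochs - 1) / 2.0
    return np.exp(-((i - c) ** 2) / (2.0 * sigma**2))


@dataclass
class WindowScheme:
    """Sliding-window grid: start indices plus the shared Gaussian taper."""

    n_epochs: int
    length_epochs: int = DEFAULT_WINDOW_EPOCHS
    step_epochs: int = DEFAULT_STEP_EPOCHS
    fwhm_epochs: float = DEFAULT_FWHM_EPOCHS
    tr: float = 1.8
    taper: np.ndarray = field(init=False)
    starts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_epochs < self.length_epochs:
            raise ValueError(
                f"series of {self.n_epochs} epochs shorter than window "
                f"({self.length_epochs})"
            )
        if self.step_epochs < 1:
            raise ValueError("step must be >= 1 epoch")
        self.taper = gaussian_taper(self.length_epochs, self.fwhm_epochs)
        n_win = (self.n_epochs - self.length_epochs) // self.step_epochs + 1
        self.starts = np.arange(n_win) * self.step_epochs

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def duration_seconds(self) -> float:
        return self.length_epochs * self.tr

    @property
    def overlap_seconds(self) -> float:
        return (self.length_epochs - self.step_epochs) * self.tr


def make_window_scheme(
    n_epochs: int,
    length: int = DEFAULT_WINDOW_EPOCHS,
    step: int = DEFAULT_STEP_EPOCHS,
    fwhm: float = DEFAULT_FWHM_EPOCHS,
    tr: float = 1.8,
) -> WindowScheme:
    """Build the sliding-window scheme for an ``n_epochs``-long run."""
    return WindowScheme(n_epochs, length, step, fwhm, tr)


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation; invariant to rescaling the weights."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.shape == y.shape == w.shape) or x.ndim != 1:
        raise ValueError("x, y, w must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    xc = x - wn @ x
    yc = y - wn @ y
    vx = wn @ xc**2
    vy = wn @ yc**2
    # tolerance catches constant series whose centering leaves rounding dust
    eps2 = (10 * np.finfo(float).eps) ** 2
    if vx <= eps2 * max(wn @ x**2, 1.0) or vy <= eps2 * max(wn @ y**2, 1.0):
        which = "x" if vx <= eps2 * max(wn @ x**2, 1.0) else "y"
        raise ValueError(f"zero weighted variance in {which}")
    r = (wn @ (xc * yc)) / math.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class FcSeries:
    """Per-window functional connectivity for one ROI pair."""

    pair: Pair
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        ok = self.values[np.isfinite(self.values)]
        if ok.size and (np.any(ok > 1.0) or np.any(ok < -1.0)):
            raise ValueError("correlation values outside [-1, 1]")

    @property
    def n_windows(self) -> int:
        return len(self.values)


def fc_timeseries(
    ts: RoiTimeseries,
    scheme: WindowScheme,
    pairs: Sequence[Pair],
    weighted: bool = True,
    max_missing_frac: float = 0.05,
) -> dict[Pair, FcSeries]:
    """Sliding-window FC timeseries for each requested ROI pair.

    Each window's value is the taper-weighted (or plain, ``weighted=False``)
    Pearson correlation of the two ROI series inside the window.  Degenerate
    windows (zero variance) become NaN; more than ``max_missing_frac``
    missing windows in a pair is an error.
    """
    if ts.n_trs != scheme.n_epochs:
        raise ValueError(
            f"timeseries has {ts.n_trs} TRs but scheme expects {scheme.n_epochs}"
        )
    labels = list(ts.roi_labels)
    rois = sorted({r for p in pairs for r in p})
    missing = [r for r in rois if r not in labels]
    if missing:
        raise KeyError(f"ROIs not present: {missing}")
    cols = [labels.index(r) for r in rois]
    L = scheme.length_epochs
    w = scheme.taper if weighted else np.ones(L)
    wn = w / w.sum()

    # (n_windows, n_sel, L) view of every window for the involved ROIs
    X = sliding_window_view(ts.values[:, cols], L, axis=0)[:: scheme.step_epochs]
    mu = X @ wn  # (n_windows, n_sel)
    Xc = X - mu[..., None]
    var = (Xc**2) @ wn
    pos = {r: i for i, r in enumerate(rois)}

    out: dict[Pair, FcSeries] = {}
    for pair in pairs:
        ia, ib = pos[pair[0]], pos[pair[1]]
        cov = (Xc[:, ia, :] * Xc[:, ib, :]) @ wn
        denom = var[:, ia] * var[:, ib]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, cov / np.sqrt(denom), np.nan)
        n_bad = int(np.isnan(r).sum())
        if n_bad:
            logger.warning(
                "pair %s: %d degenerate window(s) set to missing", pair, n_bad
            )
            if n_bad > max_missing_frac * scheme.n_windows:
                raise ValueError(
                    f"pair {pair}: {n_bad}/{scheme.n_windows} windows degenerate"
                )
        out[pair] = FcSeries(pair, np.clip(r, -1.0, 1.0))
    return out


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform z = atanh(r)."""
    r = float(r)
    if not abs(r) < 1.0:
        raise ValueError(f"|r| must be < 1 for Fisher Z; got {r}")
    return math.atanh(r)


@dataclass
class CouplingRecord:
    """FC-power coupling for one subject/session/pair/band/lag."""

    r: float
    z: float
    lag_trs: int = 0
    pair: Pair | None = None
    band: str | None = None
    subject: str | None = None
    session: str | None = None
    n_windows: int = 0


def couple(
    fc,
    power,
    lag_trs: int = 0,
    min_overlap: int = 10,
) -> CouplingRecord:
    """Pearson coupling between an FC timeseries and a power timeseries.

    Positive ``lag_trs`` shifts the fMRI (FC) series later relative to the
    EEG power series: ``power[t]`` is paired with ``fc[t + lag]``.  Negative
    lags are rejected.  Missing windows are dropped pairwise.
    """
    pair = getattr(fc, "pair", None)
    band = getattr(power, "band", None)
    fcv = np.asarray(fc.values if isinstance(fc, FcSeries) else fc, dtype=float)
    pv = np.asarray(
        power.values if isinstance(power, PowerSeries) else power, dtype=float
    )
    if fcv.shape != pv.shape or fcv.ndim != 1:
        raise ValueError("fc and power must be 1-D series on the same window grid")
    if lag_trs < 0:
        raise ValueError("negative lags are rejected; fMRI lags EEG, not vice versa")
    if lag_trs >= len(fcv):
        raise ValueError("lag exceeds series length")
    x = pv[: len(pv) - lag_trs] if lag_trs else pv
    y = fcv[lag_trs:]
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < min_overlap:
        raise ValueError(
            f"only {len(x)} overlapping windows after lag {lag_trs}; "
            f"need >= {min_overlap}"
        )
    xc = x - x.mean()
    yc = y - y.mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx == 0 or vy == 0:
        raise ValueError("constant series; coupling undefined")
    r = float(np.clip((xc @ yc) / math.sqrt(vx * vy), -1.0, 1.0))
    z = fisher_z(r)  # raises on |r| == 1 by contract
    return CouplingRecord(
        r=r, z=z, lag_trs=lag_trs, pair=pair, band=band, n_windows=len(x)
    )


def adjusted_coupling(z_intra: float, z_extra: Sequence[float]) -> float:
    """Intra-network coupling adjusted for the mean extra-network coupling."""
    z_extra = np.asarray(z_extra, dtype=float)
    if z_extra.size == 0:
        raise ValueError("extra-network coupling set must be non-empty")
    return float(z_intra - z_extra.mean())


def network_pairs(network_of: Mapping[str, str], network: str = "DMN") -> list[Pair]:
    """All unordered ROI pairs within one network, in label-sorted order."""
    rois = sorted(r for r, n in network_of.items() if n == network)
    return list(itertools.combinations(rois, 2))


def cross_network_pairs(
    network_of: Mapping[str, str],
    network: str = "DMN",
    others: Sequence[str] = ("ECN", "SN"),
) -> list[Pair]:
    """All pairs of one ``network`` ROI with any ROI of the ``others`` networks."""
    a = sorted(r for r, n in network_of.items() if n == network)
    b = sorted(r for r, n in network_of.items() if n in others)
    return [(x, y) for x in a for y in b]
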