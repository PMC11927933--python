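"""Per-epoch EEG band power via multitaper spectral estimation.

The resting EEG is segmented into epochs of one fMRI repetition time (TR)
each, centered on the volume onsets, so that every epoch maps onto one BOLD
sample.  For each epoch and channel a multitaper power spectral density is
estimated with K discrete prolate spheroidal (DPSS) tapers, band power is
integrated over the band of interest and normalised by the mean power of the
global spectrum (1-40 Hz), pooled over an occipitoparietal channel group,
and finally smoothed with the same Gaussian taper that defines the
sliding-window functional-connectivity grid so that the power timeseries is
sampled on exactly the same window centers as the connectivity timeseries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import scipy.fft
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import windows

logger = logging.getLogger(__name__)

#: right occipitoparietal channel group pooled for the alpha power timeseries
OCCIPITOPARIETAL: tuple[str, ...] = ("P4", "P6", "P8", "PO4", "PO8", "O2")

#: default time-bandwidth product; with K = 3 tapers this follows the
#: standard K = 2*NW - 1 pairing.
DEFAULT_NW = 2.0
DEFAULT_N_TAPERS = 3


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi] in Hz, inclusive at both edges."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi, got ({self.lo}, {self.hi})"
            )


ALPHA_BAND = BandDefinition("alpha", 8.0, 12.0)
THETA_BAND = BandDefinition("theta", 4.0, 7.0)
BETA_BAND = BandDefinition("beta", 13.0, 17.0)
GLOBAL_BAND = BandDefinition("global", 1.0, 40.0)

DEFAULT_BANDS: dict[str, BandDefinition] = {
    "alpha": ALPHA_BAND,
    "theta": THETA_BAND,
    "beta": BETA_BAND,
}


@dataclass
class EpochedEEG:
    """Epoched EEG: ``data`` is (n_channels, n_epochs, n_samples) in microvolts.

    One epoch spans one TR; ``n_samples`` must equal ``round(fs * tr)``.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_channels, n_epochs, n_samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length does not match data")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0 or self.tr <= 0:
            raise ValueError("fs and tr must be positive")
        if self.data.shape[2] != round(self.fs * self.tr):
            raise ValueError(
                f"epoch length {self.data.shape[2]} != round(fs*tr) = "
                f"{round(self.fs * self.tr)}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, labels: Sequence[str]) -> list[int]:
        """Indices of ``labels``; raises listing every absent channel."""
        missing = [c for c in labels if c not in self.channel_labels]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        return [self.channel_labels.index(c) for c in labels]


@dataclass
class PowerSeries:
    """Normalised band power, per epoch or per sliding window."""

    band: str
    values: np.ndarray
    pooled_channels: tuple[str, ...] = field(default_factory=tuple)
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("power values must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("power values must be non-negative")


@lru_cache(maxsize=8)
def _dpss(n_samples: int, nw: float, k: int) -> np.ndarray:
    # unit-energy tapers (L2 norm 1) so eigenspectra are directly comparable
    return windows.dpss(n_samples, nw, Kmax=k, norm=2)


def multitaper_psd_array(
    data: np.ndarray,
    fs: float,
    n_tapers: int = DEFAULT_N_TAPERS,
    nw: float = DEFAULT_NW,
    demean: bool = True,
    max_freq: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper PSD over the trailing axis of ``data`` (batched).

    Returns ``(freqs, psd)`` with ``psd.shape == data.shape[:-1] + (n_freqs,)``.
    The estimate is the mean of the K DPSS eigenspectra, one-sided, in
    units of power per Hz.  ``max_freq`` truncates the returned grid (the
    spectrum above it is simply not evaluated, e.g. beyond the 1-40 Hz
    normalisation band).
    """
    data = np.asarray(data)
    if data.dtype.kind != "f":
        data = data.astype(float)
    n = data.shape[-1]
    if n < 8:
        raise ValueError(f"epoch too short ({n} samples; need >= 8)")
    if n_tapers < 1:
        raise ValueError("n_tapers must be >= 1")
    if demean:
        data = data - data.mean(axis=-1, keepdims=True)
    tapers = _dpss(n, nw, n_tapers).astype(data.dtype)  # (k, n)
    tapered = data[..., None, :] * tapers  # (..., k, n)
    spec = scipy.fft.rfft(tapered, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    nyq_bin = spec.shape[-1] - 1
    if max_freq is not None:
        kmax = int(np.searchsorted(freqs, max_freq, side="right"))
        spec = np.ascontiguousarray(spec[..., :kmax])
        freqs = freqs[:kmax]
    # |spec|^2 via a contiguous real view (fast path for large batches)
    v = spec.view(data.dtype)
    v *= v
    psd = v[..., 0::2] + v[..., 1::2]
    psd /= data.dtype.type(fs)
    # one-sided: double everything except DC (and Nyquist when n is even)
    hi = min(nyq_bin, psd.shape[-1]) if n % 2 == 0 else psd.shape[-1]
    psd[..., 1:hi] *= 2.0
    psd = psd.mean(axis=-2)
    return freqs, psd


def multitaper_psd(
    epoch: np.ndarray,
    fs: float,
    n_tapers: int = DEFAULT_N_TAPERS,
    nw: float = DEFAULT_NW,
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper PSD of a single epoch (1-D array of samples)."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 1:
        raise ValueError("epoch must be 1-D")
    return multitaper_psd_array(epoch, fs, n_tapers=n_tapers, nw=nw)


def band_mask(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Boolean mask of frequency bins with lo <= f <= hi (inclusive)."""
    return (freqs >= band.lo) & (freqs <= band.hi)


def band_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    band: BandDefinition,
    global_band: BandDefinition = GLOBAL_BAND,
):
    """Normalised band power: mean PSD over ``band`` / mean PSD over ``global_band``.

    Works on a single PSD or on a batch with frequency on the last axis.
    """
    freqs = np.asarray(freqs)
    nyq = freqs[-1]
    if band.hi > nyq:
        raise ValueError(f"band {band.name!r} exceeds Nyquist ({nyq} Hz)")
    bmask = band_mask(freqs, band)
    gmask = band_mask(freqs, global_band)
    if not bmask.any() or not gmask.any():
        raise ValueError("band contains no frequency bins")
    psd = np.asarray(psd, dtype=float)
    gmean = psd[..., gmask].mean(axis=-1)
    if np.any(gmean <= 0):
        bad = np.argwhere(np.atleast_1d(gmean) <= 0).ravel().tolist()
        raise ZeroDivisionError(
            f"zero global-spectrum power; cannot normalise (flat indices {bad})"
        )
    return psd[..., bmask].mean(axis=-1) / gmean


def pool_channels(
    power_by_channel: Mapping[str, np.ndarray],
    channels: Sequence[str] = OCCIPITOPARIETAL,
) -> np.ndarray:
    """Arithmetic mean of per-epoch power across ``channels``."""
    missing = [c for c in channels if c not in power_by_channel]
    if missing:
        raise KeyError(f"channels not present: {missing}")
    stacked = np.stack([np.asarray(power_by_channel[c], dtype=float) for c in channels])
    return stacked.mean(axis=0)


def band_power_series(
    eeg: EpochedEEG,
    band: BandDefinition,
    channels: Sequence[str] = OCCIPITOPARIETAL,
    global_band: BandDefinition = GLOBAL_BAND,
    n_tapers: int = DEFAULT_N_TAPERS,
    nw: float = DEFAULT_NW,
) -> PowerSeries:
    """Pooled, normalised per-epoch band power for one band.

    Convenience wrapper: multitaper PSD per channel/epoch, band power with
    global-spectrum normalisation, then pooling across the channel group.
    """
    series = multi_band_power_series(
        eeg, [band], channels=channels, global_band=global_band,
        n_tapers=n_tapers, nw=nw,
    )
    return series[band.name]


def multi_band_power_series(
    eeg: EpochedEEG,
    bands: Sequence[BandDefinition],
    channels: Sequence[str] = OCCIPITOPARIETAL,
    global_band: BandDefinition = GLOBAL_BAND,
    n_tapers: int = DEFAULT_N_TAPERS,
    nw: float = DEFAULT_NW,
) -> dict[str, PowerSeries]:
    """Pooled normalised power for several bands from one PSD pass."""
    idx = eeg.channel_index(channels)
    fmax = max([global_band.hi] + [b.hi for b in bands])
    freqs, psd = multitaper_psd_array(
        eeg.data[idx], eeg.fs, n_tapers=n_tapers, nw=nw,
        max_freq=fmax + 1.0,  # small margin keeps the band edges inclusive
    )  # (n_sel, n_epochs, n_freqs)
    out: dict[str, PowerSeries] = {}
    for band in bands:
        bp = band_power(freqs, psd, band, global_band)  # (n_sel, n_epochs)
        out[band.name] = PowerSeries(
            band=band.name,
            values=bp.mean(axis=0),
            pooled_channels=tuple(channels),
            smoothed=False,
        )
    return out


def smooth_power_series(per_epoch_power, scheme, band: str = "power",
                        pooled_channels: Sequence[str] = ()) -> PowerSeries:
    """Window-align a per-epoch power series with the scheme's Gaussian taper.

    For each sliding window the value is the taper-weighted average of the
    epoch powers inside that window (weights normalised to unit sum), so the
    output lives on exactly the same window grid as the FC timeseries.  No
    hemodynamic-response convolution is applied: the power amplitudes are
    deliberately preserved undistorted.
    """
    if isinstance(per_epoch_power, PowerSeries):
        if per_epoch_power.smoothed:
            raise ValueError("series is already window-aligned")
        band = per_epoch_power.band
        pooled_channels = per_epoch_power.pooled_channels
        values = per_epoch_power.values
    else:
        values = np.asarray(per_epoch_power, dtype=float)
    length = scheme.length_epochs
    if values.shape[0] < length:
        raise ValueError(
            f"series length {values.shape[0]} shorter than window ({length})"
        )
    w = scheme.taper / scheme.taper.sum()
    smoothed = sliding_window_view(values, length)[:: scheme.step_epochs] @ w
    return PowerSeries(
        band=band,
        values=smoothed,
        pooled_channels=tuple(pooled_channels),
        smoothed=True,
    )
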