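"""Synthetic EEG-fMRI study generator with known ground truth.

The generator realises the statistical structure the downstream analysis is
designed to detect: a slow (< 0.02 Hz) latent arousal-like state s(t) that
simultaneously modulates (a) the instantaneous correlation of selected
posterior-DMN ROI pairs, rho(t) = base + m * beta * s(t), and (b) the
amplitude of a 10 Hz occipitoparietal alpha rhythm, a(t) = a0 * (1 + gamma
* s(t)).  The group x session multiplier m injects the stimulation effect:
active-post sessions receive the full positive coupling, sham-post a slight
negative drift, and both pre sessions none, mirroring a pre/post stimulation
design with 16 subjects per arm and 306 one-TR epochs per session.

BOLD samples are drawn per TR by Cholesky mixing of the instantaneous
correlation matrix (exact control of rho(t)), then band-limited to the
resting-state band.  EEG epochs carry the alpha sinusoid with random phase
on the occipitoparietal channels, theta and beta rhythms whose amplitudes
wax and wane on their own slow envelopes, and band-limited 1/f
background noise on every channel -- together these make the 1-40 Hz
normalisation of band power non-trivial without leaking the alpha
modulation into the neighbouring bands.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.fft


from .bold import DEFAULT_NETWORKS, RoiTimeseries, bandpass
from .coupling import Pair
from .eeg import OCCIPITOPARIETAL, EpochedEEG

logger = logging.getLogger(__name__)

_RHO_CLIP = 0.99

#: group x session multipliers on the injected coupling: no coupling before
#: stimulation, full effect in active-post, a slight decline in sham-post.
DEFAULT_SESSION_EFFECTS: dict[tuple[str, str], float] = {
    ("active", "pre"): 0.0,
    ("active", "post"): 1.0,
    ("sham", "pre"): 0.0,
    ("sham", "post"): -0.3,
}


@dataclass
class SimConfig:
    """Study-level simulation parameters (defaults define the study conditions)."""

    n_subjects_per_group: int = 16
    n_epochs: int = 306
    tr: float = 1.8
    eeg_fs: float = 250.0
    roi_networks: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_NETWORKS)
    )
    base_correlation: float = 0.3
    coupling_gain_bold: float = 0.3  # beta: rho modulation per unit latent state
    coupling_gain_alpha: float = 0.5  # gamma: alpha-amplitude modulation per unit
    target_pairs: tuple[Pair, ...] = (("vPCC", "lAG"), ("vPCC", "rAG"))
    session_effects: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SESSION_EFFECTS)
    )
    latent_cutoff_hz: float = 0.02
    noise_sd: float = 1.0
    noise_highpass_hz: float = 0.5  # cleaned-EEG filter edges for the 1/f background
    noise_lowpass_hz: float = 45.0
    # a0 (microvolts): sized so the alpha rhythm carries only a few percent
    # of the 1-40 Hz mean power -- strong enough to track the latent state,
    # weak enough that the global-spectrum normalisation does not bleed the
    # alpha modulation into the theta/beta normalised power
    alpha_amp: float = 0.25
    alpha_freq: float = 10.0
    # theta/beta rhythms with independent slow amplitude envelopes: real EEG
    # band power waxes and wanes on its own; without this, window smoothing
    # would leave the normalisation leak of the alpha modulation as the only
    # coherent signal in the neighbouring bands
    theta_amp: float = 0.35
    theta_freq: float = 6.0
    beta_amp: float = 0.35
    beta_freq: float = 15.0
    rhythm_env_gain: float = 0.5
    amp_floor_frac: float = 0.05
    eeg_channels: tuple[str, ...] = OCCIPITOPARIETAL + ("Cz",)
    bold_band: tuple[float, float] = (0.01, 0.08)
    eeg_dtype: str = "float32"  # EEG amplitudes need no more than single precision
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if self.n_epochs < 2:
            raise ValueError("n_epochs must be >= 2")
        if not -1 < self.base_correlation < 1:
            raise ValueError("base_correlation must lie in (-1, 1)")
        n_samp = self.eeg_fs * self.tr
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError(
                f"eeg_fs * tr = {n_samp} must be an integer number of samples"
            )
        self.roi_networks = dict(self.roi_networks)
        self.eeg_channels = tuple(self.eeg_channels)
        self.bold_band = tuple(self.bold_band)
        self.target_pairs = tuple(tuple(p) for p in self.target_pairs)
        self.session_effects = {
            tuple(k): float(v) for k, v in dict(self.session_effects).items()
        }
        rois = set(self.roi_networks)
        for a, b in self.target_pairs:
            if a not in rois or b not in rois:
                raise ValueError(f"target pair ({a}, {b}) not among the ROIs")

    @property
    def n_rois(self) -> int:
        return len(self.roi_networks)

    @property
    def roi_labels(self) -> tuple[str, ...]:
        return tuple(self.roi_networks)

    @property
    def n_samples_per_epoch(self) -> int:
        return round(self.eeg_fs * self.tr)


@dataclass
class SimTruth:
    """Ground truth of one simulated session, for parameter-recovery tests."""

    latent_state: np.ndarray
    true_rho: dict[Pair, np.ndarray]
    true_alpha_amp: np.ndarray
    true_coupling_sign: dict[Pair, int]
    n_rho_clipped: int = 0
    n_psd_repaired: int = 0


def simulate_latent_state(
    n_epochs: int, cutoff_hz: float = 0.02, tr: float = 1.8, seed: int = 0
) -> np.ndarray:
    """Slow latent state: brick-wall low-passed white noise, re-standardised.

    White noise is band-limited on the run's own DFT grid (all power strictly
    below ``cutoff_hz``; an analog filter would leak transition-band power
    through the finite-window periodogram), then standardised to zero mean
    and unit sd.  Deterministic for a fixed seed.
    """
    if n_epochs < 2:
        raise ValueError("n_epochs must be >= 2")
    nyq = 0.5 / tr
    if not 0 < cutoff_hz < nyq:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist = {nyq:g} Hz)"
        )
    freqs = np.fft.rfftfreq(n_epochs, d=tr)
    keep = (freqs > 0) & (freqs < cutoff_hz)
    if not keep.any():
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is below the frequency resolution "
            f"1/(n*tr) = {freqs[1]:g} Hz; no slow modes available"
        )
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_epochs)
    spec = np.fft.rfft(white)
    spec[~keep] = 0.0
    slow = np.fft.irfft(spec, n=n_epochs)
    sd = slow.std()
    if sd == 0:
        raise ValueError("degenerate latent state (zero variance)")
    return (slow - slow.mean()) / sd


def alpha_amplitude(latent: np.ndarray, config: SimConfig) -> np.ndarray:
    """Per-epoch alpha amplitude a0 * (1 + gamma * s), floored at a small positive value."""
    gain = config.coupling_gain_alpha
    raw = 1.0 + gain * np.asarray(latent, dtype=float)
    floored = np.maximum(raw, config.amp_floor_frac)
    n_clip = int((raw < config.amp_floor_frac).sum())
    if n_clip:
        logger.warning(
            "alpha amplitude floored in %d epoch(s) (gamma*|s| >= 1)", n_clip
        )
    return config.alpha_amp * floored


def _session_multiplier(config: SimConfig, group: str, session: str) -> float:
    key = (group, session)
    if key not in config.session_effects:
        raise KeyError(f"no session effect configured for {key}")
    return config.session_effects[key]


def simulate_bold(
    latent: np.ndarray,
    config: SimConfig,
    group: str = "active",
    session: str = "post",
    seed: int = 0,
) -> tuple[RoiTimeseries, SimTruth]:
    """Draw ROI BOLD samples with instantaneous correlation base + m*beta*s(t).

    Per TR the sample vector is L(t) @ eps with L(t) the Cholesky factor of
    the instantaneous correlation matrix; target pairs carry the modulated
    correlation, all other pairs the constant base.  The output is then
    band-limited to the resting-state band by zero-phase filtering.
    """
    latent = np.asarray(latent, dtype=float)
    n = latent.shape[0]
    if n != config.n_epochs:
        raise ValueError(
            f"latent length {n} != configured n_epochs {config.n_epochs}"
        )
    m = _session_multiplier(config, group, session)
    effect = m * config.coupling_gain_bold
    labels = config.roi_labels
    idx = {r: i for i, r in enumerate(labels)}
    k = config.n_rois

    C0 = np.full((k, k), config.base_correlation)
    np.fill_diagonal(C0, 1.0)
    C = np.broadcast_to(C0, (n, k, k)).copy()

    true_rho: dict[Pair, np.ndarray] = {}
    n_clipped = 0
    for a, b in config.target_pairs:
        raw = config.base_correlation + effect * latent
        rho = np.clip(raw, -_RHO_CLIP, _RHO_CLIP)
        n_clipped += int((raw != rho).sum())
        ia, ib = idx[a], idx[b]
        C[:, ia, ib] = rho
        C[:, ib, ia] = rho
        true_rho[(a, b)] = rho
    if n_clipped:
        logger.warning(
            "instantaneous correlation clipped at +/-%.2f in %d TR-pair(s)",
            _RHO_CLIP, n_clipped,
        )

    n_repaired = 0
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        # nearest-PSD repair of the offending TRs only (large modulated
        # correlations are the only way the matrix can lose definiteness)
        if true_rho:
            peak = np.max(np.abs(np.stack(list(true_rho.values()))), axis=0)
            candidates = np.flatnonzero(peak > 0.7)
        else:  # pragma: no cover - unreachable with target pairs configured
            candidates = np.arange(n)
        n_repaired = _repair_psd(C, candidates)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            n_repaired += _repair_psd(C, np.arange(n))
            L = np.linalg.cholesky(C)
        logger.warning(
            "indefinite correlation matrix in %d TR(s); eigenvalues clipped",
            n_repaired,
        )

    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n, k))
    values = np.einsum("tij,tj->ti", L, eps)

    ts = RoiTimeseries(values, labels, config.tr, dict(config.roi_networks))
    lo, hi = config.bold_band
    ts = bandpass(ts, lo=lo, hi=hi)

    sign = int(np.sign(effect * config.coupling_gain_alpha))
    truth = SimTruth(
        latent_state=latent,
        true_rho=true_rho,
        true_alpha_amp=alpha_amplitude(latent, config),
        true_coupling_sign={p: sign for p in config.target_pairs},
        n_rho_clipped=n_clipped,
        n_psd_repaired=n_repaired,
    )
    return ts, truth


def _repair_psd(C: np.ndarray, candidates: np.ndarray) -> int:
    """Eigen-clip the indefinite matrices among ``C[candidates]`` in place."""
    if candidates.size == 0:
        return 0
    eigmin = np.linalg.eigvalsh(C[candidates])[:, 0]
    bad = candidates[eigmin < 1e-9]
    if bad.size == 0:
        return 0
    w, V = np.linalg.eigh(C[bad])
    w = np.clip(w, 1e-6, None)
    fixed = V @ (w[..., None] * np.swapaxes(V, -1, -2))
    d = np.sqrt(np.diagonal(fixed, axis1=-2, axis2=-1))
    fixed = fixed / d[..., :, None] / d[..., None, :]
    C[bad] = fixed
    return int(bad.size)


def simulate_eeg(latent: np.ndarray, config: SimConfig, seed: int = 0) -> EpochedEEG:
    """Epoched EEG: latent-modulated alpha on occipitoparietal channels, plus
    theta/beta rhythms with independent slow envelopes and 1/f background.

    Every epoch of an occipitoparietal channel contains a 10 Hz sinusoid of
    amplitude a0 * (1 + gamma * s(t)) with a fresh random phase, together
    with theta and beta sinusoids whose amplitudes follow their own slow
    latent envelopes (independent of s, shared across channels -- the
    spontaneous waxing and waning of band power).  Other channels carry an
    unmodulated alpha of amplitude a0.  All channels add independent
    band-limited 1/f background noise of sd ``noise_sd``.
    """
    latent = np.asarray(latent, dtype=float)
    n_ep = latent.shape[0]
    n_samp = config.n_samples_per_epoch
    fs = config.eeg_fs
    dtype = np.dtype(config.eeg_dtype)
    rng = np.random.default_rng(seed)

    amp = alpha_amplitude(latent, config).astype(dtype)
    t = (np.arange(n_samp) / fs).astype(dtype)
    omega = dtype.type(2.0 * math.pi * config.alpha_freq)
    phase = rng.uniform(0.0, 2.0 * math.pi, size=n_ep).astype(dtype)
    modulated_wave = amp[:, None] * np.sin(omega * t[None, :] + phase[:, None])
    phase_bg = rng.uniform(0.0, 2.0 * math.pi, size=n_ep).astype(dtype)
    background_wave = dtype.type(config.alpha_amp) * np.sin(
        omega * t[None, :] + phase_bg[:, None]
    )
    for freq, a_b in ((config.theta_freq, config.theta_amp),
                      (config.beta_freq, config.beta_amp)):
        if a_b == 0:
            continue
        env_seed = int(rng.integers(0, 2**31))
        env = simulate_latent_state(
            n_ep, config.latent_cutoff_hz, config.tr, env_seed
        )
        a_env = a_b * np.maximum(
            1.0 + config.rhythm_env_gain * env, config.amp_floor_frac
        )
        ph = rng.uniform(0.0, 2.0 * math.pi, size=n_ep).astype(dtype)
        om = dtype.type(2.0 * math.pi * freq)
        modulated_wave += a_env.astype(dtype)[:, None] * np.sin(
            om * t[None, :] + ph[:, None]
        )

    channels = tuple(config.eeg_channels)
    n_ch = len(channels)
    noise = _pink_noise(
        rng, (n_ch, n_ep), n_samp, config.noise_sd, dtype, fs=fs,
        highpass_hz=config.noise_highpass_hz,
        lowpass_hz=config.noise_lowpass_hz,
    )

    data = noise
    modulated = set(OCCIPITOPARIETAL)
    for ci, ch in enumerate(channels):
        data[ci] += modulated_wave if ch in modulated else background_wave
    return EpochedEEG(data=data, fs=fs, channel_labels=channels, tr=config.tr)


def _pink_noise(
    rng: np.random.Generator,
    lead_shape: tuple[int, ...],
    n: int,
    sd: float,
    dtype=np.float64,
    fs: float = 250.0,
    highpass_hz: float = 0.5,
    lowpass_hz: float = 45.0,
) -> np.ndarray:
    """Band-limited 1/f-power noise per epoch; exact target per-sample sd.

    Each epoch is synthesised independently on its own DFT grid with power
    between the high-pass and low-pass edges of cleaned EEG; the epoch
    length (1.8 s) makes the grid's first bin ~0.56 Hz, so nothing below
    the 0.5 Hz high-pass is representable anyway.
    """
    dtype = np.dtype(dtype)
    if sd == 0:
        return np.zeros(lead_shape + (n,), dtype=dtype)
    n_bins = n // 2 + 1
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    k0 = max(int(np.searchsorted(f, highpass_hz)), 1)
    k1 = int(np.searchsorted(f, lowpass_hz, side="right"))
    k1 = min(k1, n_bins - 1)  # keep Nyquist zero so the variance is exact
    if k1 <= k0:
        raise ValueError("noise band contains no frequency bins")
    amp = f[k0:k1] ** -0.5
    # irfft of unit-variance complex bins: var(x) = (2/N^2) * sum(amp^2)
    scale = sd * n / (2.0 * math.sqrt(np.sum(amp**2)))
    ctype = np.complex64 if dtype == np.float32 else np.complex128
    z = np.zeros(lead_shape + (n_bins,), dtype=ctype)
    gauss = rng.standard_normal(lead_shape + (k1 - k0, 2), dtype=dtype)
    z[..., k0:k1] = gauss.view(ctype)[..., 0]
    z[..., k0:k1] *= (amp * scale).astype(dtype)
    return scipy.fft.irfft(z, n=n, axis=-1)


@dataclass
class SubjectSession:
    subject: str
    group: str
    session: str
    eeg: EpochedEEG
    bold: RoiTimeseries
    truth: SimTruth


@dataclass
class StudyBundle:
    """One simulated study: per subject x session data plus the design table."""

    config: SimConfig
    design: pd.DataFrame
    entries: dict[tuple[str, str], SubjectSession]

    def __iter__(self):
        return iter(self.entries.values())


SESSIONS = ("pre", "post")


def simulate_study(config: SimConfig | None = None) -> StudyBundle:
    """Simulate the full two-group pre/post study from one master seed."""
    if config is None:
        config = SimConfig()
    master = np.random.default_rng(config.seed)
    rows = []
    entries: dict[tuple[str, str], SubjectSession] = {}
    for group, prefix in (("active", "A"), ("sham", "S")):
        for i in range(config.n_subjects_per_group):
            subject = f"{prefix}{i + 1:02d}"
            for session in SESSIONS:
                s_lat, s_bold, s_eeg = master.integers(0, 2**31, size=3)
                latent = simulate_latent_state(
                    config.n_epochs, config.latent_cutoff_hz, config.tr, int(s_lat)
                )
                ts, truth = simulate_bold(
                    latent, config, group, session, int(s_bold)
                )
                eeg = simulate_eeg(latent, config, int(s_eeg))
                entries[(subject, session)] = SubjectSession(
                    subject, group, session, eeg, ts, truth
                )
                rows.append({"subject": subject, "group": group, "session": session})
    design = pd.DataFrame(rows, columns=["subject", "group", "session"])
    return StudyBundle(config=config, design=design, entries=entries)


def null_config(config: SimConfig | None = None, **overrides) -> SimConfig:
    """A zero-effect copy of ``config``: both groups generatively identical."""
    cfg = config if config is not None else SimConfig()
    effects = {k: 0.0 for k in cfg.session_effects}
    return replace(cfg, session_effects=effects, **overrides)
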