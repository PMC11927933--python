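"""Run configuration: every stage parameter with its analysis default.

The defaults are the canonical analysis settings: alpha 8-12 Hz, theta
4-7 Hz, low beta 13-17 Hz, global normalisation band 1-40 Hz; a 60-epoch
Gaussian window (FWHM 27.78 epochs) sliding in 1-TR steps; TR 1.8 s;
resting-state bandpass 0.01-0.08 Hz; EEG-to-fMRI lags 0-5 TRs; FDR level
0.05.  Configs load from YAML; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .coupling import (
    DEFAULT_FWHM_EPOCHS,
    DEFAULT_STEP_EPOCHS,
    DEFAULT_WINDOW_EPOCHS,
)
from .eeg import DEFAULT_N_TAPERS, DEFAULT_NW, OCCIPITOPARIETAL, BandDefinition
from .synth import SimConfig


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


@dataclass
class PowerParams:
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "alpha": (8.0, 12.0),
            "theta": (4.0, 7.0),
            "beta": (13.0, 17.0),
        }
    )
    global_band: tuple[float, float] = (1.0, 40.0)
    channels: tuple[str, ...] = OCCIPITOPARIETAL
    n_tapers: int = DEFAULT_N_TAPERS
    nw: float = DEFAULT_NW

    def __post_init__(self) -> None:
        self.bands = {k: tuple(v) for k, v in dict(self.bands).items()}
        self.global_band = tuple(self.global_band)
        self.channels = tuple(self.channels)
        for name, (lo, hi) in self.bands.items():
            BandDefinition(name, lo, hi)  # validates
        BandDefinition("global", *self.global_band)
        if self.n_tapers < 1:
            raise ConfigError("power.n_tapers must be >= 1")

    def band_definitions(self) -> list[BandDefinition]:
        return [BandDefinition(n, lo, hi) for n, (lo, hi) in self.bands.items()]

    def global_definition(self) -> BandDefinition:
        return BandDefinition("global", *self.global_band)


@dataclass
class PreprocParams:
    lo: float = 0.01
    hi: float = 0.08
    order: int = 4
    steps: tuple[str, ...] = ("center", "bandpass", "regress")

    def __post_init__(self) -> None:
        self.steps = tuple(self.steps)
        if not 0 < self.lo < self.hi:
            raise ConfigError("preproc band must satisfy 0 < lo < hi")
        if self.order < 1:
            raise ConfigError("preproc.order must be >= 1")


@dataclass
class WindowParams:
    length_epochs: int = DEFAULT_WINDOW_EPOCHS
    step_epochs: int = DEFAULT_STEP_EPOCHS
    fwhm_epochs: float = DEFAULT_FWHM_EPOCHS

    def __post_init__(self) -> None:
        if self.length_epochs < 2:
            raise ConfigError("window.length_epochs must be >= 2")
        if self.step_epochs < 1:
            raise ConfigError("window.step_epochs must be >= 1")
        if self.fwhm_epochs <= 0:
            raise ConfigError("window.fwhm_epochs must be positive")


@dataclass
class CouplingParams:
    lags: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    weighted: bool = True
    pairs: str = "dmn"  # 'dmn', 'dmn+extra', or explicit in the API

    def __post_init__(self) -> None:
        self.lags = tuple(int(l) for l in self.lags)
        if any(l < 0 for l in self.lags):
            raise ConfigError("coupling.lags must be non-negative")
        if self.pairs not in ("dmn", "dmn+extra"):
            raise ConfigError("coupling.pairs must be 'dmn' or 'dmn+extra'")


@dataclass
class StatsParams:
    alpha: float = 0.05
    band: str = "alpha"
    lag: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("stats.alpha must lie in (0, 1)")


@dataclass
class RunConfig:
    seed: int = 0
    simulation: SimConfig = field(default_factory=SimConfig)
    power: PowerParams = field(default_factory=PowerParams)
    preproc: PreprocParams = field(default_factory=PreprocParams)
    window: WindowParams = field(default_factory=WindowParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    stats: StatsParams = field(default_factory=StatsParams)

    def __post_init__(self) -> None:
        # simulation inherits the master seed unless set explicitly
        if self.simulation.seed != self.seed and self.simulation.seed == 0:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)


_SECTION_TYPES = {
    "simulation": SimConfig,
    "power": PowerParams,
    "preproc": PreprocParams,
    "window": WindowParams,
    "coupling": CouplingParams,
    "stats": StatsParams,
}


def _build(cls, mapping: Mapping, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def _normalise_sim_mapping(mapping: dict) -> dict:
    out = dict(mapping)
    if "session_effects" in out and out["session_effects"] is not None:
        eff = out["session_effects"]
        flat = {}
        for k, v in eff.items():
            if isinstance(v, Mapping):  # nested {group: {session: value}}
                for sess, val in v.items():
                    flat[(str(k), str(sess))] = float(val)
            else:
                flat[tuple(k)] = float(v)
        out["session_effects"] = flat
    if "target_pairs" in out and out["target_pairs"] is not None:
        out["target_pairs"] = tuple(tuple(p) for p in out["target_pairs"])
    return out


def load_config(path) -> RunConfig:
    """Load a YAML run config; missing sections get the analysis defaults."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_mapping(raw, context=str(path))


def config_from_mapping(raw: Mapping, context: str = "config") -> RunConfig:
    unknown = set(raw) - set(_SECTION_TYPES) - {"seed"}
    if unknown:
        raise ConfigError(f"{context}: unknown section(s) {sorted(unknown)}")
    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    for name, cls in _SECTION_TYPES.items():
        if name in raw and raw[name] is not None:
            section = dict(raw[name])
            if name == "simulation":
                section = _normalise_sim_mapping(section)
            kwargs[name] = _build(cls, section, f"{context}.{name}")
    return RunConfig(**kwargs)


def config_to_mapping(cfg: RunConfig) -> dict:
    """Serialisable mapping (inverse of :func:`config_from_mapping`)."""
    out: dict = {"seed": cfg.seed}
    for name in _SECTION_TYPES:
        section = dataclasses.asdict(getattr(cfg, name))
        if name == "simulation":
            nested: dict[str, dict[str, float]] = {}
            for (group, sess), v in section["session_effects"].items():
                nested.setdefault(group, {})[sess] = v
            section["session_effects"] = nested
            section["target_pairs"] = [list(p) for p in section["target_pairs"]]
            section["eeg_channels"] = list(section["eeg_channels"])
            section["bold_band"] = list(section["bold_band"])
        out[name] = _listify(section)
    return out


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_mapping(cfg), sort_keys=True), encoding="utf-8"
    )
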