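"""Orchestration: simulate -> preprocess -> power -> coupling -> stats.

The stage functions live in their own modules; this module wires them into
one reproducible run on a :class:`~dyncouple.synth.StudyBundle` (or on data
loaded from disk via :mod:`dyncouple.io`) and writes the result tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as dio
from .bold import RoiTimeseries, preprocess
from .config import RunConfig, config_to_mapping
from .coupling import (
    Pair,
    cross_network_pairs,
    adjusted_coupling,
    couple,
    fc_timeseries,
    make_window_scheme,
    network_pairs,
)
from .eeg import EpochedEEG, multi_band_power_series, smooth_power_series
from .stats import contrast_table, coupling_change_matrix, delta_z
from .synth import StudyBundle, simulate_study

logger = logging.getLogger(__name__)


def resolve_pairs(spec, network_of: Mapping[str, str]) -> list[Pair]:
    """Expand a pair spec: 'dmn', 'dmn+extra', or an explicit pair list."""
    if spec == "dmn":
        return network_pairs(network_of, "DMN")
    if spec == "dmn+extra":
        return network_pairs(network_of, "DMN") + cross_network_pairs(
            network_of, "DMN", ("ECN", "SN")
        )
    return [tuple(p) for p in spec]


def session_records(
    eeg: EpochedEEG,
    bold: RoiTimeseries,
    cfg: RunConfig,
    pairs: Sequence[Pair],
    subject: str = "",
    session: str = "",
    bands=None,
) -> list[dict]:
    """Coupling records for one subject-session over pairs x bands x lags."""
    ts = preprocess(
        bold, None, lo=cfg.preproc.lo, hi=cfg.preproc.hi,
        order=cfg.preproc.order, steps=cfg.preproc.steps,
    )
    scheme = make_window_scheme(
        ts.n_trs, cfg.window.length_epochs, cfg.window.step_epochs,
        cfg.window.fwhm_epochs, ts.tr,
    )
    fc = fc_timeseries(ts, scheme, pairs, weighted=cfg.coupling.weighted)
    band_defs = bands if bands is not None else cfg.power.band_definitions()
    raw_power = multi_band_power_series(
        eeg, band_defs, channels=cfg.power.channels,
        global_band=cfg.power.global_definition(),
        n_tapers=cfg.power.n_tapers, nw=cfg.power.nw,
    )
    smoothed = {
        name: smooth_power_series(series, scheme)
        for name, series in raw_power.items()
    }
    records = []
    for band_name, power in smoothed.items():
        for pair in pairs:
            for lag in cfg.coupling.lags:
                rec = couple(fc[pair], power, lag_trs=lag)
                records.append(
                    {
                        "subject": subject,
                        "session": session,
                        "band": band_name,
                        "pair": pair,
                        "lag_trs": lag,
                        "r": rec.r,
                        "z": rec.z,
                    }
                )
    return records


def analyze_study(
    bundle: StudyBundle,
    cfg: RunConfig | None = None,
    pairs: Sequence[Pair] | str | None = None,
    bands=None,
) -> pd.DataFrame:
    """Coupling records for every subject x session of a study bundle."""
    cfg = cfg if cfg is not None else RunConfig(seed=bundle.config.seed)
    network_of = dict(bundle.config.roi_networks)
    pair_list = resolve_pairs(
        pairs if pairs is not None else cfg.coupling.pairs, network_of
    )
    rows: list[dict] = []
    for entry in bundle:
        rows.extend(
            session_records(
                entry.eeg, entry.bold, cfg, pair_list,
                subject=entry.subject, session=entry.session, bands=bands,
            )
        )
    df = pd.DataFrame(rows)
    return df.merge(
        bundle.design[["subject", "group"]].drop_duplicates(), on="subject"
    )


def study_contrasts(
    records: pd.DataFrame,
    band: str = "alpha",
    lag: int = 0,
    family: Sequence[Pair] | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Double contrasts with FDR and follow-ups for one band/lag family."""
    sub = records[(records["band"] == band) & (records["lag_trs"] == lag)]
    if sub.empty:
        raise ValueError(f"no records for band {band!r} at lag {lag}")
    deltas = delta_z(sub)
    return contrast_table(deltas, family=family, q=q)


def adjusted_records(
    records: pd.DataFrame, network_of: Mapping[str, str]
) -> pd.DataFrame:
    """Adjusted coupling: intra-DMN z minus the mean extra-DMN z.

    Requires records for both the intra-DMN pairs and the DMN x (ECN u SN)
    pairs (run the coupling stage with pairs='dmn+extra').
    """
    def canon(pair):
        return tuple(sorted(pair))

    intra = {canon(p) for p in network_pairs(network_of, "DMN")}
    extra = {canon(p) for p in cross_network_pairs(network_of, "DMN", ("ECN", "SN"))}
    pair_key = records["pair"].map(canon)
    if not extra <= set(pair_key.unique()):
        raise ValueError("records lack extra-DMN pairs; rerun with pairs='dmn+extra'")
    keys = ["subject", "session", "band", "lag_trs"]
    extra_mean = (
        records[pair_key.isin(extra)]
        .groupby(keys)["z"]
        .mean()
        .rename("z_extra_mean")
        .reset_index()
    )
    out = records[pair_key.isin(intra)].merge(extra_mean, on=keys)
    out["z"] = [
        adjusted_coupling(zi, [ze]) for zi, ze in zip(out["z"], out["z_extra_mean"])
    ]
    out["r"] = np.nan  # adjusted values live on the z scale only
    return out.drop(columns="z_extra_mean")


@dataclass
class StudyResult:
    records: pd.DataFrame
    contrasts: dict[tuple[str, int], pd.DataFrame]
    change_matrix: pd.DataFrame
    design: pd.DataFrame
    config: RunConfig
    out_dir: Path | None = None
    files: list[Path] = field(default_factory=list)


def run_all(cfg: RunConfig, out_dir=None) -> StudyResult:
    """Full reproducible run: simulate the study, analyse it, write tables."""
    bundle = simulate_study(cfg.simulation)
    records = analyze_study(bundle, cfg)
    network_of = dict(cfg.simulation.roi_networks)
    family = network_pairs(network_of, "DMN")
    contrasts: dict[tuple[str, int], pd.DataFrame] = {}
    for band in cfg.power.bands:
        for lag in cfg.coupling.lags:
            contrasts[(band, lag)] = study_contrasts(
                records, band=band, lag=lag, family=family, q=cfg.stats.alpha
            )
    primary = records[
        (records["band"] == cfg.stats.band)
        & (records["lag_trs"] == cfg.stats.lag)
    ]
    change = coupling_change_matrix(delta_z(primary))

    result = StudyResult(
        records=records, contrasts=contrasts, change_matrix=change,
        design=bundle.design, config=cfg,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files = []
        p = out_dir / "design.tsv"
        dio.write_design_tsv(p, bundle.design)
        files.append(p)
        p = out_dir / "coupling.tsv"
        dio.write_coupling_tsv(p, records)
        files.append(p)
        for (band, lag), table in contrasts.items():
            p = out_dir / f"contrasts_{band}_lag{lag}.tsv"
            dio.write_contrast_tsv(p, table)
            files.append(p)
        p = out_dir / "change_matrix.tsv"
        cm = change.copy()
        cm["pair"] = cm["pair"].map(dio.pair_to_str)
        dio._frame_to_tsv(cm, p)
        files.append(p)
        p = out_dir / "provenance.json"
        dio.write_provenance(p, config_to_mapping(cfg), seeds={"master": cfg.seed})
        files.append(p)
        result.out_dir = out_dir
        result.files = files
    return result
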