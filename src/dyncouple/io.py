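"""Table and container I/O.

Canonical table dialect: tab-delimited UTF-8 text with a header row, '.'
decimal separator and floats printed with ``%.17g`` so that write/read
round-trips are lossless and byte-identical across runs.  The epoched EEG
container is a flat little-endian float64 binary alongside a JSON sidecar
describing shape, sampling rate and channel names.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bold import ConfoundTable, RoiTimeseries
from .eeg import EpochedEEG

FLOAT_FMT = "%.17g"


class TableFormatError(ValueError):
    """Malformed delimited table (ragged row, non-numeric cell, no header)."""


def _format_numeric_table(header: Sequence[str], values: np.ndarray) -> str:
    lines = ["\t".join(header)]
    for row in np.atleast_2d(values):
        lines.append("\t".join(FLOAT_FMT % v for v in row))
    return "\n".join(lines) + "\n"


def read_numeric_tsv(path) -> tuple[list[str], np.ndarray]:
    """Read a numeric TSV; errors name the offending line (1-based)."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.replace("\r\n", "\n").replace("\r", "\n").split("\n")]
    while lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise TableFormatError(f"{path}: empty file (missing header)")
    header = lines[0].split("\t")
    try:
        float(header[0])
    except ValueError:
        pass
    else:
        raise TableFormatError(f"{path}: line 1 looks numeric; header row required")
    n_cols = len(header)
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != n_cols:
            raise TableFormatError(
                f"{path}: line {i}: {len(cells)} cells, expected {n_cols}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise TableFormatError(f"{path}: line {i}: non-numeric cell ({exc})")
    return header, np.asarray(rows, dtype=float)


def write_roi_tsv(path, ts: RoiTimeseries) -> None:
    """ROI timeseries as TSV (header = ROI labels) plus a JSON sidecar."""
    path = Path(path)
    path.write_text(
        _format_numeric_table(ts.roi_labels, ts.values), encoding="utf-8"
    )
    sidecar = {
        "tr": ts.tr,
        "networks": dict(ts.network_of),
        "roi_labels": list(ts.roi_labels),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_roi_tsv(path, tr: float | None = None,
                 networks: Mapping[str, str] | None = None) -> RoiTimeseries:
    """Read an ROI timeseries TSV; TR/networks come from the sidecar if present."""
    path = Path(path)
    header, values = read_numeric_tsv(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
        tr = tr if tr is not None else meta.get("tr")
        networks = networks if networks is not None else meta.get("networks", {})
    if tr is None:
        raise ValueError(f"{path}: TR not given and no sidecar found")
    return RoiTimeseries(values, tuple(header), float(tr), dict(networks or {}))


def write_confounds_tsv(path, confounds: ConfoundTable) -> None:
    header = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    Path(path).write_text(
        _format_numeric_table(header, confounds.motion6), encoding="utf-8"
    )


def read_confounds_tsv(path) -> ConfoundTable:
    _, values = read_numeric_tsv(path)
    return ConfoundTable(values)


def write_series_tsv(path, values: np.ndarray, column: str = "value",
                     index_name: str = "index") -> None:
    """A single named series with its integer index (epoch or window)."""
    values = np.asarray(values, dtype=float)
    body = np.column_stack([np.arange(len(values), dtype=float), values])
    Path(path).write_text(
        _format_numeric_table([index_name, column], body), encoding="utf-8"
    )


def _frame_to_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT,
              lineterminator="\n")


def write_design_tsv(path, design: pd.DataFrame) -> None:
    _frame_to_tsv(design[["subject", "group", "session"]], path)


def read_design_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"subject", "group", "session"} - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def pair_to_str(pair) -> str:
    return f"{pair[0]}~{pair[1]}"


def str_to_pair(s: str):
    a, _, b = s.partition("~")
    if not b:
        raise TableFormatError(f"malformed ROI pair {s!r} (expected 'a~b')")
    return (a, b)


def write_coupling_tsv(path, records: pd.DataFrame) -> None:
    df = records.copy()
    if df["pair"].map(lambda p: not isinstance(p, str)).any():
        df["pair"] = df["pair"].map(pair_to_str)
    cols = ["subject", "session", "band", "pair", "lag_trs", "r", "z"]
    _frame_to_tsv(df[cols], path)


def read_coupling_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    df["pair"] = df["pair"].map(str_to_pair)
    return df


def write_contrast_tsv(path, table: pd.DataFrame) -> None:
    df = table.copy()
    if df["pair"].map(lambda p: not isinstance(p, str)).any():
        df["pair"] = df["pair"].map(pair_to_str)
    _frame_to_tsv(df, path)


def write_truth_tsv(path, truth) -> None:
    """Ground-truth per-epoch series: latent state, alpha amplitude, rho per pair."""
    cols = ["latent_state", "true_alpha_amp"]
    data = [truth.latent_state, truth.true_alpha_amp]
    for pair, rho in truth.true_rho.items():
        cols.append(f"rho_{pair_to_str(pair)}")
        data.append(rho)
    body = np.column_stack(data)
    Path(path).write_text(_format_numeric_table(cols, body), encoding="utf-8")


def write_eeg(stem, eeg: EpochedEEG) -> None:
    """Flat float64 binary (C order) + JSON sidecar."""
    stem = Path(stem)
    data = np.ascontiguousarray(eeg.data, dtype="<f8")
    data.tofile(stem.with_suffix(".dat"))
    sidecar = {
        "fs": eeg.fs,
        "tr": eeg.tr,
        "channel_labels": list(eeg.channel_labels),
        "n_channels": eeg.n_channels,
        "n_epochs": eeg.n_epochs,
        "n_samples": eeg.n_samples,
        "dtype": "<f8",
        "order": "C",
    }
    stem.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_eeg(stem) -> EpochedEEG:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text(encoding="utf-8"))
    shape = (meta["n_channels"], meta["n_epochs"], meta["n_samples"])
    data = np.fromfile(stem.with_suffix(".dat"), dtype=meta["dtype"]).reshape(shape)
    return EpochedEEG(
        data=data, fs=meta["fs"], channel_labels=tuple(meta["channel_labels"]),
        tr=meta["tr"],
    )


def write_provenance(path, config: Mapping, seeds: Mapping | None = None,
                     warnings: Sequence[str] = ()) -> None:
    """Deterministic provenance record: config snapshot, seeds, warnings.

    Intentionally carries no wall-clock timestamps so repeated runs with the
    same config produce byte-identical artifacts.
    """
    from . import __version__

    record = {
        "package": "dyncouple",
        "version": __version__,
        "config": _jsonable(config),
        "seeds": _jsonable(seeds or {}),
        "warnings": list(warnings),
    }
    Path(path).write_text(
        json.dumps(record, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
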