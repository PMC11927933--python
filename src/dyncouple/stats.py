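"""Group statistics for pre/post stimulation coupling changes.

Per subject the Fisher-Z coupling change Delta z = z_post - z_pre is formed;
the double contrast Post-Pre_(Active-Sham) is a two-sample t test of these
changes between groups, corrected across the family of within-DMN ROI pairs
with the Benjamini-Hochberg false-discovery-rate step-up.  Surviving pairs
are unpacked with one-tailed one-sample follow-up tests per group, which are
protected by the significant double contrast and therefore uncorrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def delta_z(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject coupling change z_post - z_pre.

    ``records`` needs columns subject, group, session ('pre'/'post'), band,
    pair, lag_trs, z.  Returns one row per subject/band/pair/lag with the
    change in ``delta_z``.  A subject missing either session is an error.
    """
    required = {"subject", "group", "session", "band", "pair", "lag_trs", "z"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    keys = ["subject", "group", "band", "pair", "lag_trs"]
    wide = records.pivot_table(
        index=keys, columns="session", values="z", aggfunc="first"
    )
    for sess in ("pre", "post"):
        if sess not in wide.columns or wide[sess].isna().any():
            bad = (
                wide.index.get_level_values("subject")[wide[sess].isna()].unique()
                if sess in wide.columns
                else records["subject"].unique()
            )
            raise ValueError(f"missing {sess!r} session for subject(s): {list(bad)}")
    out = wide.reset_index()
    out["delta_z"] = out["post"] - out["pre"]
    return out[keys + ["delta_z"]]


@dataclass
class DoubleContrastResult:
    t: float
    p: float
    welch: bool  # True when the homogeneity check failed and Welch was used


def double_contrast(
    delta_active: np.ndarray,
    delta_sham: np.ndarray,
    homogeneity_alpha: float = 0.05,
) -> DoubleContrastResult:
    """Two-sample t test of coupling changes, active minus sham.

    Pooled-variance Student's t by default; when a Levene check rejects
    variance homogeneity the Welch statistic is used instead and flagged.
    """
    a = np.asarray(delta_active, dtype=float)
    s = np.asarray(delta_sham, dtype=float)
    if len(a) < 2 or len(s) < 2:
        raise ValueError("need at least 2 subjects per group")
    if a.std(ddof=1) == 0 and s.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups; t undefined")
    welch = False
    if len(a) > 2 and len(s) > 2 and a.std() > 0 and s.std() > 0:
        _, p_lev = sps.levene(a, s)
        welch = bool(p_lev < homogeneity_alpha)
    res = sps.ttest_ind(a, s, equal_var=not welch)
    return DoubleContrastResult(t=float(res.statistic), p=float(res.pvalue), welch=welch)


def fdr_bh(p_values: Sequence[float], q: float = 0.05):
    """Benjamini-Hochberg step-up: adjusted p values and rejection mask."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def followup_simple(delta_group: np.ndarray, direction: str) -> tuple[float, float]:
    """One-sample t of the group's coupling change against 0, one-tailed.

    ``direction='increase'`` tests mean > 0, ``'decrease'`` tests mean < 0.
    """
    d = np.asarray(delta_group, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 subjects")
    if d.std(ddof=1) == 0:
        raise ValueError("zero variance; t undefined")
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    alt = "greater" if direction == "increase" else "less"
    res = sps.ttest_1samp(d, 0.0, alternative=alt)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AssumptionFlags:
    normal_active_p: float | None
    normal_sham_p: float | None
    homogeneity_p: float | None
    normality_ok: bool | None
    homogeneity_ok: bool | None
    assessable: bool


def assumption_checks(
    delta_active: np.ndarray,
    delta_sham: np.ndarray,
    alpha: float = 0.05,
) -> AssumptionFlags:
    """Diagnostic Shapiro-Wilk normality and Levene homogeneity checks.

    Never blocks the analysis; degenerate input yields a not-assessable flag.
    """
    a = np.asarray(delta_active, dtype=float)
    s = np.asarray(delta_sham, dtype=float)
    if len(a) < 3 or len(s) < 3 or a.std() == 0 or s.std() == 0:
        return AssumptionFlags(None, None, None, None, None, assessable=False)
    _, pa = sps.shapiro(a)
    _, ps = sps.shapiro(s)
    _, ph = sps.levene(a, s)
    return AssumptionFlags(
        normal_active_p=float(pa),
        normal_sham_p=float(ps),
        homogeneity_p=float(ph),
        normality_ok=bool(pa >= alpha and ps >= alpha),
        homogeneity_ok=bool(ph >= alpha),
        assessable=True,
    )


def contrast_table(
    deltas: pd.DataFrame,
    family: Sequence | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Double contrasts across a family of ROI pairs with BH-FDR and follow-ups.

    ``deltas`` holds one band/lag family: columns subject, group, pair,
    delta_z.  ``family`` restricts/orders the tested pairs (default: all
    pairs present).  Follow-up one-tailed tests are populated only for pairs
    whose double contrast survives FDR; their directions are read from each
    group's mean change and recorded.
    """
    required = {"subject", "group", "pair", "delta_z"}
    missing = required - set(deltas.columns)
    if missing:
        raise ValueError(f"deltas missing columns: {sorted(missing)}")
    pairs = list(family) if family is not None else sorted(deltas["pair"].unique())
    rows = []
    for pair in pairs:
        sub = deltas[deltas["pair"] == pair]
        a = sub.loc[sub["group"] == "active", "delta_z"].to_numpy()
        s = sub.loc[sub["group"] == "sham", "delta_z"].to_numpy()
        dc = double_contrast(a, s)
        flags = assumption_checks(a, s)
        rows.append(
            {
                "pair": pair,
                "t_double": dc.t,
                "p_double": dc.p,
                "welch": dc.welch,
                "mean_delta_active": a.mean(),
                "mean_delta_sham": s.mean(),
                "normality_ok": flags.normality_ok,
                "homogeneity_ok": flags.homogeneity_ok,
                "_a": a,
                "_s": s,
            }
        )
    table = pd.DataFrame(rows)
    p_adj, reject = fdr_bh(table["p_double"].to_numpy(), q=q)
    table["p_fdr"] = p_adj
    table["significant"] = reject
    for col in ("dir_active", "dir_sham"):
        table[col] = None
    for col in ("t_active", "p_active_1t", "t_sham", "p_sham_1t"):
        table[col] = np.nan
    for i in table.index[table["significant"]]:
        a = table.at[i, "_a"]
        s = table.at[i, "_s"]
        da = "increase" if a.mean() >= 0 else "decrease"
        ds = "increase" if s.mean() >= 0 else "decrease"
        ta, pa = followup_simple(a, da)
        tsn, psn = followup_simple(s, ds)
        table.loc[i, ["dir_active", "dir_sham"]] = [da, ds]
        table.loc[i, ["t_active", "p_active_1t", "t_sham", "p_sham_1t"]] = [
            ta, pa, tsn, psn,
        ]
    return table.drop(columns=["_a", "_s"])


def coupling_change_matrix(deltas: pd.DataFrame) -> pd.DataFrame:
    """Mean Post-Pre coupling change per group per pair (report table)."""
    return (
        deltas.groupby(["pair", "group"])["delta_z"]
        .mean()
        .unstack("group")
        .reset_index()
    )
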