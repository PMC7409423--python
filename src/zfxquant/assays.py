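"""In-vitro assay analytics: 2^-ΔΔCt relative expression and CCK-8 viability.

qRT-PCR quantifies a transcript relative to a reference gene (here typically
GAPDH) and a control group via the comparative-Ct method:

    ΔCt   = Ct_target - Ct_reference          (per sample)
    ΔΔCt  = ΔCt - mean(ΔCt of control group)
    fold  = 2^(-ΔΔCt)

Knockdown efficiency is the percent reduction of the mean treated fold
relative to the mean control fold.  CCK-8 viability time-courses are
blank-corrected optical densities at 450 nm, summarized per group as
mean ± SEM at each timepoint, optionally normalized to each sample's t=0
value.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CT_COLUMNS = [
    "sample_id",
    "group",
    "target_gene",
    "reference_gene",
    "ct_target",
    "ct_reference",
    "replicate",
]

VIABILITY_COLUMNS = ["sample_id", "group", "time_h", "od450", "is_blank"]


def ddct_fold_change(ct_table: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Per-sample 2^-ΔΔCt fold changes against a control group.

    Parameters
    ----------
    ct_table
        Long-format table with at least ``group, ct_target, ct_reference``
        (see :data:`CT_COLUMNS`).  Rows missing either Ct are excluded with a
        log message and returned flagged.
    control_group
        Group whose mean ΔCt is the ΔΔCt baseline; must have at least one
        usable row.

    Returns
    -------
    DataFrame
        Input columns plus ``dct, ddct, fold_change, excluded``.
    """
    df = ct_table.copy()
    for col in ("group", "ct_target", "ct_reference"):
        if col not in df.columns:
            raise ValueError(f"Ct table is missing column {col!r}")
    df["excluded"] = ~(
        np.isfinite(df["ct_target"].astype(float))
        & np.isfinite(df["ct_reference"].astype(float))
    )
    if df["excluded"].any():
        bad = df.loc[df["excluded"], "sample_id"] if "sample_id" in df else df.index[df["excluded"]]
        log.warning("excluding %d sample(s) with missing Ct: %s", df["excluded"].sum(), list(bad))

    df["dct"] = df["ct_target"].astype(float) - df["ct_reference"].astype(float)
    control = df.loc[(df["group"] == control_group) & ~df["excluded"], "dct"]
    if control.empty:
        raise ValueError(f"control group {control_group!r} has no usable samples")
    df["ddct"] = df["dct"] - control.mean()
    df["fold_change"] = np.where(df["excluded"], np.nan, 2.0 ** (-df["ddct"]))
    return df


def knockdown_efficiency(
    fold_changes: pd.DataFrame, treated_group: str, control_group: str
) -> float:
    """Percent knockdown: ``(1 - mean treated fold / mean control fold) * 100``.

    Dividing by the control mean fold keeps the result exact even when the
    control replicates scatter (their arithmetic-mean fold then exceeds 1
    slightly); with identical control replicates it reduces to
    ``(1 - mean treated fold) * 100``.  A mean treated fold above the control
    returns a negative efficiency with a warning (the knockdown failed).
    """
    usable = fold_changes.loc[~fold_changes.get("excluded", False).astype(bool)]
    means = {}
    for name in (treated_group, control_group):
        vals = usable.loc[usable["group"] == name, "fold_change"].dropna()
        if vals.empty:
            raise ValueError(f"group {name!r} has no usable fold changes")
        means[name] = float(vals.mean())
    eff = (1.0 - means[treated_group] / means[control_group]) * 100.0
    if eff < 0:
        warnings.warn(
            f"mean fold of {treated_group!r} exceeds control: knockdown failed "
            f"(efficiency {eff:.1f}%)",
            stacklevel=2,
        )
    return eff


def viability_curves(
    table: pd.DataFrame,
    blank_correct: bool = True,
    normalize: bool = False,
) -> pd.DataFrame:
    """Blank-corrected per-group viability summaries at each timepoint.

    Parameters
    ----------
    table
        Long-format OD450 readings (see :data:`VIABILITY_COLUMNS`); rows with
        ``is_blank`` true are blank wells sharing the plate.
    blank_correct
        Subtract the mean blank OD at the same timepoint from every sample
        well.  Requires at least one blank per timepoint.
    normalize
        Divide each sample's corrected series by its corrected t=0 value, so
        every series starts at 1.0.  Samples whose corrected t=0 value is
        not positive are flagged and dropped from the summaries with a
        warning.

    Returns
    -------
    DataFrame
        One row per (group, time_h) with ``n, mean, sem``.
    """
    df = table.copy()
    if "is_blank" not in df.columns:
        df["is_blank"] = False
    df["is_blank"] = df["is_blank"].astype(bool)
    samples = df.loc[~df["is_blank"]].copy()
    samples["corrected"] = samples["od450"].astype(float)

    if blank_correct:
        blanks = df.loc[df["is_blank"]]
        if blanks.empty:
            raise ValueError("blank correction requested but no blank wells present")
        blank_means = blanks.groupby("time_h")["od450"].mean()
        missing = set(samples["time_h"]) - set(blank_means.index)
        if missing:
            raise ValueError(f"no blank wells at timepoint(s) {sorted(missing)}")
        samples["corrected"] -= samples["time_h"].map(blank_means).astype(float)

    if normalize:
        t0 = samples["time_h"].min()
        base = samples.loc[samples["time_h"] == t0].set_index("sample_id")["corrected"]
        bad = base[base <= 0].index
        if len(bad):
            warnings.warn(
                f"dropping sample(s) with non-positive corrected t={t0} OD: {list(bad)}",
                stacklevel=2,
            )
            samples = samples[~samples["sample_id"].isin(bad)]
            base = base.drop(bad)
        samples["corrected"] = samples["corrected"] / samples["sample_id"].map(base)

    out = (
        samples.groupby(["group", "time_h"])["corrected"]
        .agg(n="count", mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    return out


def normalized_series(table: pd.DataFrame, sample_id: str) -> pd.Series:
    """One sample's blank-corrected series normalized to its t=0 value."""
    df = table.copy()
    df["is_blank"] = df.get("is_blank", False)
    blanks = df.loc[df["is_blank"].astype(bool)].groupby("time_h")["od450"].mean()
    s = df.loc[df["sample_id"] == sample_id].set_index("time_h")["od450"].astype(float)
    if not blanks.empty:
        s = s - blanks.reindex(s.index).fillna(0.0)
    return (s / s.loc[s.index.min()]).sort_index()
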