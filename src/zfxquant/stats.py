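"""Group-comparison statistics for assay and xenograft readouts.

The assay's statistical vocabulary is deliberately plain: unpaired two-sided
Student's t-tests (pooled variance), group summaries as mean ± SEM, and the
conventional significance stars.  Welch's correction and Holm adjustment are
available behind flags but off by default, matching how such readouts are
conventionally reported.  The 2x2 knockdown-by-drug design additionally gets
an additive-scale interaction estimate, labeled exploratory, alongside the
pairwise comparisons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist


class DegenerateVarianceError(ValueError):
    """Both samples are constant with unequal means: t is infinite."""


def significance_stars(p: float) -> str:
    """Conventional star notation: ``***`` p<0.001, ``**`` p<0.01, ``*`` p<0.05."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SEM summary of one group (SEM = sd(ddof=1)/sqrt(n))."""

    group_name: str
    n: int
    mean: float
    sem: float
    values: tuple = ()

    def __str__(self) -> str:
        return f"{self.group_name}: {self.mean:.4g} ± {self.sem:.4g} (n={self.n})"


@dataclass(frozen=True)
class ComparisonResult:
    """One two-sample comparison."""

    group_a: str
    group_b: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_a: float
    mean_b: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def _summary(values: np.ndarray, name: str) -> GroupSummary:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    if n == 0:
        return GroupSummary(name, 0, math.nan, math.nan)
    sem = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return GroupSummary(name, n, float(values.mean()), sem, tuple(values))


def students_t_test(
    values_a,
    values_b,
    name_a: str = "a",
    name_b: str = "b",
    welch: bool = False,
) -> ComparisonResult:
    """Unpaired two-sided Student's t-test.

    Pooled-variance (equal-variance) by default; ``welch=True`` uses Welch's
    unequal-variance statistic with Satterthwaite degrees of freedom.  The
    statistic is computed from the closed form and the p-value from the t
    distribution's survival function.

    Degenerate input (zero variance in both samples): equal means give
    ``t = 0, p = 1``; unequal means raise :class:`DegenerateVarianceError`.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least two values")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)

    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            return _degenerate_t(name_a, name_b, ma, mb, float(na + nb - 2))
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = (ma - mb) / math.sqrt(se2)
    else:
        df = float(na + nb - 2)
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        if pooled == 0:
            return _degenerate_t(name_a, name_b, ma, mb, df)
        t = (ma - mb) / math.sqrt(pooled * (1.0 / na + 1.0 / nb))

    p = 2.0 * float(t_dist.sf(abs(t), df))
    return ComparisonResult(name_a, name_b, float(t), float(df), min(p, 1.0), float(ma), float(mb))


def _degenerate_t(name_a, name_b, ma, mb, df) -> ComparisonResult:
    if ma != mb:
        raise DegenerateVarianceError(
            "zero variance in both samples with unequal means"
        )
    return ComparisonResult(name_a, name_b, 0.0, df, 1.0, float(ma), float(mb))


def summarize_groups(
    table: pd.DataFrame,
    metric: str,
    group_col: str = "group_label",
) -> list[GroupSummary]:
    """Per-group n / mean / SEM for one metric column.

    Missing values are dropped per group; a group left empty yields
    ``n=0`` with missing mean.  Unknown metric or group column raises.
    """
    for col in (metric, group_col):
        if col not in table.columns:
            raise KeyError(f"table has no column {col!r}")
    return [
        _summary(sub[metric].to_numpy(), str(name))
        for name, sub in table.groupby(group_col, sort=True)
    ]


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    group_a: str,
    group_b: str,
    group_col: str = "group_label",
    welch: bool = False,
) -> ComparisonResult:
    """Student's t between two named groups of a metrics table."""
    va = table.loc[table[group_col] == group_a, metric].to_numpy()
    vb = table.loc[table[group_col] == group_b, metric].to_numpy()
    return students_t_test(va, vb, group_a, group_b, welch=welch)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment (optional; no correction is the default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


@dataclass(frozen=True)
class InteractionEstimate:
    """Additive-scale 2x2 interaction contrast (exploratory).

    estimate = mean[kd, drug] - mean[kd, vehicle] - mean[nc, drug]
               + mean[nc, vehicle]; the standard error pools the within-cell
    variance over all four cells.
    """

    estimate: float
    se: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    label: str = "exploratory"


def combination_contrast(
    table: pd.DataFrame,
    metric: str,
    knockdown_col: str = "knockdown",
    drug_col: str = "drug",
    control_levels: tuple[str, str] = ("NC", "vehicle"),
    welch: bool = False,
) -> tuple[list[ComparisonResult], InteractionEstimate]:
    """Pairwise t-tests plus interaction estimate for a 2x2 design.

    The two factors must each have exactly two levels (e.g. knockdown in
    {NC, si}, drug in {vehicle, afatinib}) and every cell needs n >= 2.
    Pairwise comparisons (uncorrected, as conventionally reported) are: each
    treated cell vs the double control, and the double treatment vs each
    single treatment.  The interaction contrast is additive-scale and labeled
    exploratory — it augments, never replaces, the pairwise output.
    """
    for col in (metric, knockdown_col, drug_col):
        if col not in table.columns:
            raise KeyError(f"table has no column {col!r}")
    kd_levels = sorted(table[knockdown_col].unique(), key=lambda x: x != control_levels[0])
    drug_levels = sorted(table[drug_col].unique(), key=lambda x: x != control_levels[1])
    if len(kd_levels) != 2 or len(drug_levels) != 2:
        raise ValueError("combination design needs exactly two levels per factor")

    cells: dict[tuple[str, str], np.ndarray] = {}
    for kd, dr in itertools.product(kd_levels, drug_levels):
        v = table.loc[
            (table[knockdown_col] == kd) & (table[drug_col] == dr), metric
        ].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise ValueError(f"design cell ({kd}, {dr}) has n < 2")
        cells[(kd, dr)] = v

    nc, veh = control_levels
    kd_t = kd_levels[1]
    dr_t = drug_levels[1]
    pairs = [
        ((nc, dr_t), (nc, veh)),
        ((kd_t, veh), (nc, veh)),
        ((kd_t, dr_t), (nc, veh)),
        ((kd_t, dr_t), (nc, dr_t)),
        ((kd_t, dr_t), (kd_t, veh)),
    ]
    comparisons = [
        students_t_test(
            cells[a], cells[b], name_a=f"{a[0]}/{a[1]}", name_b=f"{b[0]}/{b[1]}", welch=welch
        )
        for a, b in pairs
    ]

    est = (
        cells[(kd_t, dr_t)].mean()
        - cells[(kd_t, veh)].mean()
        - cells[(nc, dr_t)].mean()
        + cells[(nc, veh)].mean()
    )
    ns = {k: len(v) for k, v in cells.items()}
    df = float(sum(ns.values()) - 4)
    pooled = sum((len(v) - 1) * v.var(ddof=1) for v in cells.values()) / df
    se = math.sqrt(pooled * sum(1.0 / n for n in ns.values()))
    if se == 0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat = est / se
        p = min(2.0 * float(t_dist.sf(abs(t_stat), df)), 1.0)
    interaction = InteractionEstimate(float(est), float(se), float(t_stat), df, p)
    return comparisons, interaction
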