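"""Group-level statistics for the longitudinal study design.

The comparison plan mirrors a gate-then-follow-up scheme: per imaging site,
one-way ANOVA across the four groups at baseline and at month 7; where the
month-7 ANOVA is significant, unpaired two-sided Mann-Whitney U follow-ups
(within-group month 0 vs 7; control vs each UVR group at month 7; UVR
control vs each treated group at month 7), with extreme outliers removed per
group/site/month cell beforehand using quartile fences at 3x the IQR.
Raw p-values are reported without multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .io import GROUPS

METRICS = ("thickness_um", "mu_mm_inv", "pigmentation")

#: Exact Mann-Whitney null enumeration is used when the samples are tie-free
#: and the product of sample sizes is at most this.
EXACT_LIMIT = 400

_RECORD_COLS = ["mouse_id", "group", "site", "month", "value"]


@dataclass
class MetricSeries:
    """Long-format per-volume metric values (one row per mouse/site/month)."""

    metric: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValidationError(f"metric must be one of {METRICS}")
        missing = [c for c in _RECORD_COLS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"records missing columns {missing}")
        dup = self.records.duplicated(subset=["mouse_id", "site", "month"])
        if dup.any():
            raise ValidationError("one value per (mouse, site, month) required")


@dataclass
class ComparisonResult:
    """One statistical test: what was compared, the statistic and p-value."""

    test: str  # "anova" | "mann_whitney"
    groups: tuple[str, ...]
    site: str
    months: tuple[int, ...]
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...] = ()
    n_outliers_removed: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value must lie in [0, 1]")


def iqr_filter(
    values: Sequence[float], k: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Remove values outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation between order statistics. Fewer than
    4 values pass through unchanged (with a warning) since quartiles are not
    meaningful there. Order of kept values is preserved.
    """
    if k <= 0:
        raise ValidationError("IQR multiplier k must be positive")
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn("fewer than 4 values: IQR filter passed through", stacklevel=2)
        return values, np.empty(0)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    keep = (values >= q1 - k * iqr) & (values <= q3 + k * iqr)
    return values[keep], values[~keep]


def one_way_anova(
    groups: Sequence[Sequence[float]],
    group_labels: tuple[str, ...] = (),
    site: str = "",
    months: tuple[int, ...] = (),
) -> ComparisonResult:
    """Classic one-way ANOVA F test across two or more groups.

    Degenerate convention: when every group has zero within-group variance,
    equal means give F=0, p=1 and unequal means give F=inf, p=0.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValidationError("ANOVA needs >= 2 groups with >= 2 values each")
    if all(a.var() == 0 for a in arrays):
        means = [a.mean() for a in arrays]
        if np.ptp(means) == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
    else:
        f_stat, p = sps.f_oneway(*arrays)
    return ComparisonResult(
        test="anova",
        groups=group_labels or tuple(f"group{i}" for i in range(len(arrays))),
        site=site,
        months=months,
        statistic=float(f_stat),
        p_value=float(p),
        n_per_group=tuple(a.size for a in arrays),
    )


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    group_labels: tuple[str, str] = ("a", "b"),
    site: str = "",
    months: tuple[int, ...] = (),
    n_outliers_removed: tuple[int, int] = (0, 0),
) -> ComparisonResult:
    """Two-sided unpaired Mann-Whitney U test.

    The exact null distribution is used for tie-free samples with
    ``n_a * n_b <= 400``; otherwise the normal approximation with tie and
    continuity correction. A U statistic exactly at the null center reports
    p = 1 (symmetric-null convention).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and a.size * b.size <= EXACT_LIMIT) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = 1.0 if res.statistic == a.size * b.size / 2 else float(res.pvalue)
    return ComparisonResult(
        test="mann_whitney",
        groups=group_labels,
        site=site,
        months=months,
        statistic=float(res.statistic),
        p_value=min(p, 1.0),
        n_per_group=(a.size, b.size),
        n_outliers_removed=n_outliers_removed,
    )


def _cell(df: pd.DataFrame, group: str, site: str, month: int) -> np.ndarray:
    sel = (df["group"] == group) & (df["site"] == site) & (df["month"] == month)
    return df.loc[sel, "value"].to_numpy(dtype=float)


def _filtered_cell(df: pd.DataFrame, group: str, site: str, month: int, k: float):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept, removed = iqr_filter(_cell(df, group, site, month), k)
    return kept, removed.size


def run_comparison_plan(
    series: MetricSeries, alpha: float = 0.05, iqr_k: float = 3.0
) -> list[ComparisonResult]:
    """Run the full gate-then-follow-up comparison plan on one metric.

    Per site: ANOVA across the four groups at month 0 and at month 7;
    Mann-Whitney follow-ups only at sites whose month-7 ANOVA p < alpha.
    Follow-ups: each group month 0 vs 7 (4 tests), control vs each UVR group
    at month 7 (3), UVR control vs each treated group at month 7 (2). The
    IQR filter is applied per group/site/month cell before each
    Mann-Whitney test (and only there).
    """
    df = series.records
    sites = sorted(df["site"].unique())
    for site in sites:
        for group in GROUPS:
            for month in (0, 7):
                if _cell(df, group, site, month).size == 0:
                    raise ValidationError(
                        f"missing data for group={group} site={site} month={month}"
                    )
    results: list[ComparisonResult] = []
    for site in sites:
        gate = None
        for month in (0, 7):
            res = one_way_anova(
                [_cell(df, g, site, month) for g in GROUPS],
                group_labels=GROUPS,
                site=site,
                months=(month,),
            )
            results.append(res)
            if month == 7:
                gate = res
        if not gate.p_value < alpha:
            continue
        cells = {
            (g, m): _filtered_cell(df, g, site, m, iqr_k)
            for g in GROUPS
            for m in (0, 7)
        }
        for g in GROUPS:  # within-group change over time
            (a, ra), (b, rb) = cells[(g, 0)], cells[(g, 7)]
            results.append(
                mann_whitney_u(a, b, (g, g), site, (0, 7), (ra, rb))
            )
        uvr_groups = [g for g in GROUPS if g != "control"]
        for g in uvr_groups:  # control vs each UVR group at month 7
            (a, ra), (b, rb) = cells[("control", 7)], cells[(g, 7)]
            results.append(
                mann_whitney_u(a, b, ("control", g), site, (7,), (ra, rb))
            )
        for g in ("uvr_nmn", "uvr_pl"):  # treatment effect vs UVR control
            (a, ra), (b, rb) = cells[("uvr_control", 7)], cells[(g, 7)]
            results.append(
                mann_whitney_u(a, b, ("uvr_control", g), site, (7,), (ra, rb))
            )
    return results


def longitudinal_summary(
    series: MetricSeries,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly group means and a per-group/site linear trend.

    Returns ``(means, trends)``: means indexed by (group, site, month);
    trends carry the OLS slope (per month) and intercept fitted on the
    individual records of each group/site.
    """
    df = series.records
    if df["month"].nunique() < 2:
        raise ValidationError("longitudinal summary needs >= 2 months")
    means = (
        df.groupby(["group", "site", "month"])["value"].mean().rename("mean_value")
    ).reset_index()
    rows = []
    for (group, site), sub in df.groupby(["group", "site"]):
        slope, intercept = np.polyfit(
            sub["month"].to_numpy(dtype=float), sub["value"].to_numpy(dtype=float), 1
        )
        rows.append(
            {"group": group, "site": site, "slope": slope, "intercept": intercept}
        )
    return means, pd.DataFrame(rows)


def results_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results into one row per test."""
    return pd.DataFrame(
        [
            {
                "test": r.test,
                "groups": "|".join(r.groups),
                "site": r.site,
                "months": "|".join(str(m) for m in r.months),
                "statistic": r.statistic,
                "p_value": r.p_value,
                "n_per_group": "|".join(str(n) for n in r.n_per_group),
                "n_outliers_removed": "|".join(
                    str(n) for n in r.n_outliers_removed
                ),
            }
            for r in results
        ]
    )
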