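"""Group-contrast statistics for amyloid-positive vs amyloid-negative.

Three contrast metrics quantify how strongly a marker separates the
groups: the relative median difference, the relative mean difference
(both in percent of the negative group, positive-minus-negative), and
Cohen's d with the pooled standard deviation.  Robust group summaries use
the median and the MAD scaled by 1.4826 (consistent with the sd under
normality); group comparisons use the two-tailed Mann-Whitney test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ANALYTES, RATIOS, CohortTable

__all__ = [
    "EffectResult",
    "MAD_SCALE",
    "relative_median_difference",
    "relative_mean_difference",
    "cohens_d",
    "scaled_mad",
    "rank_sum_test",
    "effect_result",
    "group_summary_table",
]

MAD_SCALE = 1.4826

METRICS = ("median_diff_pct", "mean_diff_pct", "cohens_d")

#: Table-2-style default variable set: duplicate-mean analyte levels + ratios
DEFAULT_VARIABLES = tuple(ANALYTES) + tuple(RATIOS)


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float
    mad: float


@dataclass(frozen=True)
class EffectResult:
    """One contrast metric for one variable, with per-group summaries."""

    metric: str
    value: float
    variable: str
    positive: GroupSummary
    negative: GroupSummary


def _as_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError(f"{name} group is empty")
    return arr


def relative_median_difference(pos, neg) -> float:
    """100 * (median(pos) - median(neg)) / median(neg)."""
    pos, neg = _as_array(pos, "positive"), _as_array(neg, "negative")
    med_neg = np.median(neg)
    if med_neg == 0:
        raise ValueError("negative-group median is zero; relative difference undefined")
    return float(100.0 * (np.median(pos) - med_neg) / med_neg)


def relative_mean_difference(pos, neg) -> float:
    """100 * (mean(pos) - mean(neg)) / mean(neg)."""
    pos, neg = _as_array(pos, "positive"), _as_array(neg, "negative")
    mean_neg = neg.mean()
    if mean_neg == 0:
        raise ValueError("negative-group mean is zero; relative difference undefined")
    return float(100.0 * (pos.mean() - mean_neg) / mean_neg)


def cohens_d(pos, neg) -> float:
    """Standardized mean difference (pos - neg) with pooled sd, no
    small-sample (Hedges) correction."""
    pos, neg = _as_array(pos, "positive"), _as_array(neg, "negative")
    n1, n2 = pos.size, neg.size
    if n1 < 2 or n2 < 2:
        raise ValueError("cohens_d needs >= 2 observations per group")
    pooled_var = ((n1 - 1) * pos.var(ddof=1) + (n2 - 1) * neg.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("pooled sd is zero; cohens_d undefined")
    return float((pos.mean() - neg.mean()) / np.sqrt(pooled_var))


def scaled_mad(values) -> float:
    """1.4826 * median(|x - median(x)|)."""
    x = _as_array(values, "values")
    return float(MAD_SCALE * np.median(np.abs(x - np.median(x))))


def rank_sum_test(pos, neg, alternative: str = "two-sided") -> float:
    """Mann-Whitney p-value.

    Exact enumeration when the combined sample is small (n1+n2 <= 16) and
    tie-free; otherwise the normal approximation with continuity and tie
    correction.
    """
    pos, neg = _as_array(pos, "positive"), _as_array(neg, "negative")
    combined = np.concatenate([pos, neg])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 16 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(pos, neg, alternative=alternative, method=method)
    return float(res.pvalue)


def _summary(values) -> GroupSummary:
    x = _as_array(values, "group")
    return GroupSummary(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else float("nan"),
        median=float(np.median(x)),
        mad=scaled_mad(x),
    )


def effect_result(metric: str, pos, neg, variable: str = "") -> EffectResult:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    fn = {
        "median_diff_pct": relative_median_difference,
        "mean_diff_pct": relative_mean_difference,
        "cohens_d": cohens_d,
    }[metric]
    return EffectResult(
        metric=metric,
        value=fn(pos, neg),
        variable=variable,
        positive=_summary(pos),
        negative=_summary(neg),
    )


def group_summary_table(
    cohort: CohortTable,
    labels,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-variable group summary in the conventional biomarker-table layout.

    One row per requested variable with medians, scaled MADs, means, sds per
    group and the two-tailed rank-sum p-value.  P-values are deliberately
    not adjusted for multiple comparisons (exploratory-table convention).
    Unclassified subjects are omitted from the statistics; a requested
    variable that is absent from the cohort yields a row flagged
    ``absent=True`` rather than being dropped silently.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cohort):
        raise ValueError("labels length must match cohort size")
    measures = cohort.measurements().reset_index(drop=True)
    variables = list(variables) if variables is not None else list(DEFAULT_VARIABLES)
    pos_mask, neg_mask = labels == "positive", labels == "negative"
    n_unclassified = int(len(labels) - pos_mask.sum() - neg_mask.sum())
    rows = []
    for var in variables:
        if var not in measures.columns:
            rows.append({"variable": var, "absent": True})
            continue
        pos = measures.loc[pos_mask, var]
        neg = measures.loc[neg_mask, var]
        s_pos, s_neg = _summary(pos), _summary(neg)
        rows.append(
            {
                "variable": var,
                "absent": False,
                "n_neg": s_neg.n,
                "median_neg": s_neg.median,
                "mad_neg": s_neg.mad,
                "mean_neg": s_neg.mean,
                "sd_neg": s_neg.sd,
                "n_pos": s_pos.n,
                "median_pos": s_pos.median,
                "mad_pos": s_pos.mad,
                "mean_pos": s_pos.mean,
                "sd_pos": s_pos.sd,
                "p_value": rank_sum_test(pos, neg),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["n_unclassified"] = n_unclassified
    return table
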