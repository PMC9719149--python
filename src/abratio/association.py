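"""Association between the two detection read-outs.

Concentrations span a wide right-skewed range, so Pearson correlations are
computed on log2-transformed values; 42/40 ratios are narrow and may be
correlated untransformed or on the log scale (both policies provided).
Method-comparison lines between the two read-outs use Deming regression —
an errors-in-variables fit appropriate when both variables carry
measurement error — with error-variance ratio lambda (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ANALYTES, RATIOS, CohortTable

__all__ = [
    "DemingFit",
    "CorrelationMatrix",
    "log2_pearson",
    "deming_fit",
    "correlation_matrix",
]

#: transform presets: concentrations log2, ratios raw (heatmap convention)
#: vs everything log2 (pairwise-scatter convention)
PRESETS = ("concentrations_log2", "all_log2")


@dataclass(frozen=True)
class DemingFit:
    slope: float
    intercept: float
    lam: float


@dataclass
class CorrelationMatrix:
    variables: list[str]
    matrix: pd.DataFrame
    transforms: dict[str, str]
    #: variables with zero variance whose correlations are undefined
    undefined: list[str]


def log2_pearson(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p on log2-transformed positive vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("log2_pearson needs >= 3 paired finite values")
    bad = np.flatnonzero((x <= 0) | (y <= 0))
    if bad.size:
        raise ValueError(f"non-positive values at indices {bad.tolist()}; cannot log-transform")
    r, p = stats.pearsonr(np.log2(x), np.log2(y))
    return float(r), float(p)


def deming_fit(x, y, lam: float = 1.0) -> DemingFit:
    """Closed-form Deming (errors-in-variables) regression of y on x.

    ``lam`` is the ratio of the y-error variance to the x-error variance;
    lam=1 is orthogonal regression.  The slope solves the errors-in-variables
    normal equations::

        slope = (s_yy - lam*s_xx + sqrt((s_yy - lam*s_xx)^2 + 4*lam*s_xy^2)) / (2*s_xy)

    and the line passes through the centroid.
    """
    if not lam > 0:
        raise ValueError("lambda must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("deming_fit needs >= 3 paired finite values")
    sxx = x.var(ddof=1)
    syy = y.var(ddof=1)
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxx == 0:
        raise ValueError("x has zero variance")
    if sxy == 0:
        if np.isclose(syy, lam * sxx):
            raise ValueError("slope undefined: zero covariance with matched variances")
        # uncorrelated: the EIV solution degenerates to slope 0 (syy < lam*sxx)
        # or an infinite slope (syy > lam*sxx)
        if syy > lam * sxx:
            raise ValueError("slope undefined (vertical line): zero covariance, y-dominant variance")
        slope = 0.0
    else:
        term = syy - lam * sxx
        slope = (term + np.sqrt(term**2 + 4 * lam * sxy**2)) / (2 * sxy)
    intercept = float(y.mean() - slope * x.mean())
    return DemingFit(slope=float(slope), intercept=intercept, lam=lam)


def _transform_map(variables, transforms) -> dict[str, str]:
    if isinstance(transforms, dict):
        return {v: transforms.get(v, "none") for v in variables}
    if transforms == "all_log2":
        return {v: "log2" for v in variables}
    if transforms == "concentrations_log2":
        return {v: ("none" if v in RATIOS else "log2") for v in variables}
    raise ValueError(f"transforms must be a dict or one of {PRESETS}")


def correlation_matrix(
    cohort: CohortTable,
    variables=None,
    transforms="concentrations_log2",
) -> CorrelationMatrix:
    """All pairwise Pearson correlations with a per-variable transform policy.

    Default policy log2-transforms concentrations and leaves ratios raw.
    Constant variables produce NaN off-diagonal entries and are listed in
    ``undefined`` rather than failing the whole matrix.
    """
    measures = cohort.measurements()
    variables = list(variables) if variables is not None else list(ANALYTES) + list(RATIOS)
    missing = [v for v in variables if v not in measures.columns]
    if missing:
        raise KeyError(f"unknown variables: {missing}")
    tmap = _transform_map(variables, transforms)
    data = {}
    for v in variables:
        col = measures[v].to_numpy(dtype=float)
        if tmap[v] == "log2":
            if np.nanmin(col) <= 0:
                raise ValueError(f"variable {v!r} has non-positive values; cannot log2")
            col = np.log2(col)
        data[v] = col
    undefined = [v for v, col in data.items() if np.nanstd(col) == 0]
    k = len(variables)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = variables[i], variables[j]
            if vi in undefined or vj in undefined:
                mat[i, j] = mat[j, i] = np.nan
            else:
                r, _ = stats.pearsonr(data[vi], data[vj])
                mat[i, j] = mat[j, i] = r
    return CorrelationMatrix(
        variables=variables,
        matrix=pd.DataFrame(mat, index=variables, columns=variables),
        transforms=tmap,
        undefined=undefined,
    )
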