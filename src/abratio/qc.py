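"""Replicate-level quality control.

Subjects are excluded when any analyte's duplicate reads disagree by more
than a CV bound (default: strictly greater than 20%), or when an analyte
has only a single usable read and duplicates are required.  The CV of a
duplicate pair uses the sample (n-1) standard deviation, i.e. |a-b|/sqrt(2)
over the mean for n=2, matching common assay-QC practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import ANALYTES, CohortTable, replicate_columns

__all__ = ["QCConfig", "QCReport", "replicate_cv", "apply_exclusions"]


@dataclass(frozen=True)
class QCConfig:
    cv_threshold_pct: float = 20.0
    require_duplicates: bool = True

    def __post_init__(self) -> None:
        if not self.cv_threshold_pct > 0:
            raise ValueError("cv_threshold_pct must be > 0")


@dataclass
class QCReport:
    """Per-subject QC outcome and exclusion tallies.

    ``per_subject`` has columns subject_id, worst_cv_pct, worst_analyte,
    has_singleton, excluded, reason (high_cv | singleton | none).
    """

    per_subject: pd.DataFrame
    n_input: int
    n_included: int
    n_excluded: int
    config: QCConfig

    def __post_init__(self) -> None:
        assert self.n_included + self.n_excluded == self.n_input


def replicate_cv(reads: Sequence[float]) -> float:
    """Percent CV of replicate reads: 100 * sample sd (ddof=1) / mean.

    Raises ``ValueError`` for fewer than two finite reads (a singleton is a
    QC signal of its own, not a CV) and for a non-positive mean.
    """
    arr = np.asarray([r for r in np.ravel(reads) if np.isfinite(r)], dtype=float)
    if arr.size < 2:
        raise ValueError(f"replicate_cv needs >= 2 finite reads, got {arr.size}")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError(f"non-positive mean read {mean!r}")
    return 100.0 * arr.std(ddof=1) / mean


def apply_exclusions(
    cohort: CohortTable, qc: QCConfig | None = None
) -> tuple[CohortTable, QCReport]:
    """Apply the duplicate-CV and singleton exclusion rules.

    A subject is excluded iff any analyte's duplicate CV is strictly above
    the threshold, or (when duplicates are required) any analyte has fewer
    than two finite reads.  The included table preserves subject order; the
    rule is idempotent on its own output.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    qc = qc or QCConfig()
    rows = []
    for _, subject in cohort.df.iterrows():
        worst_cv = -np.inf
        worst_analyte = None
        singleton = False
        for analyte in ANALYTES:
            reads = subject[replicate_columns(analyte)].to_numpy(dtype=float)
            finite = reads[np.isfinite(reads)]
            if finite.size < 2:
                singleton = True
                continue
            cv = replicate_cv(finite)
            if cv > worst_cv:
                worst_cv, worst_analyte = cv, analyte
        high_cv = worst_cv > qc.cv_threshold_pct
        excluded = high_cv or (singleton and qc.require_duplicates)
        reason = "high_cv" if high_cv else ("singleton" if excluded else "none")
        rows.append(
            {
                "subject_id": subject["subject_id"],
                "worst_cv_pct": worst_cv if np.isfinite(worst_cv) else np.nan,
                "worst_analyte": worst_analyte,
                "has_singleton": singleton,
                "excluded": excluded,
                "reason": reason,
            }
        )
    report_df = pd.DataFrame(rows)
    keep = ~report_df["excluded"].to_numpy()
    included = CohortTable(
        cohort.df.loc[keep].reset_index(drop=True),
        {**cohort.provenance, "qc": {"n_excluded": int((~keep).sum())}},
    )
    report = QCReport(
        per_subject=report_df,
        n_input=len(cohort),
        n_included=int(keep.sum()),
        n_excluded=int((~keep).sum()),
        config=qc,
    )
    return included, report
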