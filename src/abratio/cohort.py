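"""Cohort container and delimited-text IO.

A cohort is a wide per-subject table: one row per participant, duplicate
immunoassay reads in paired ``<analyte>_r1`` / ``<analyte>_r2`` columns for
the eight analytes ({CSF, plasma IP-eluate} x {AβX-40, AβX-42, Aβ1-40,
Aβ1-42}), plus optional covariates.  CSF concentrations are pg/mL; plasma
IP-eluate concentrations are relative (the immunoprecipitation recovery is
unknown), which is immaterial for ratio-based analysis.

Left-censored covariate values (clinical pTau181 reported as "<15.6") are
parsed to the floor value with a companion ``*_censored`` flag.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "RATIOS",
    "CohortTable",
    "read_cohort",
]

#: matrix_family_cterm; family "abx" = N-terminus-agnostic (6E10-style),
#: "ab1" = Asp(1)-specific (3D6-style)
ANALYTES: tuple[str, ...] = (
    "csf_abx_40",
    "csf_abx_42",
    "csf_ab1_40",
    "csf_ab1_42",
    "plasma_abx_40",
    "plasma_abx_42",
    "plasma_ab1_40",
    "plasma_ab1_42",
)

#: derived 42/40 ratio names -> (numerator analyte, denominator analyte)
RATIOS: dict[str, tuple[str, str]] = {
    "csf_abx_ratio": ("csf_abx_42", "csf_abx_40"),
    "csf_ab1_ratio": ("csf_ab1_42", "csf_ab1_40"),
    "plasma_abx_ratio": ("plasma_abx_42", "plasma_abx_40"),
    "plasma_ab1_ratio": ("plasma_ab1_42", "plasma_ab1_40"),
}

REPLICATE_SUFFIXES = ("_r1", "_r2")

_CENSORED_COLUMNS = ("p_tau181",)
_CENSOR_RE = re.compile(r"^\s*<\s*([0-9.]+)\s*$")


def replicate_columns(analyte: str) -> list[str]:
    return [analyte + s for s in REPLICATE_SUFFIXES]


def required_columns() -> list[str]:
    cols = ["subject_id"]
    for analyte in ANALYTES:
        cols.extend(replicate_columns(analyte))
    return cols


@dataclass
class CohortTable:
    """Per-subject cohort table plus provenance.

    ``df`` holds one row per subject; ``provenance`` records how the table
    came to be (generator config hash and seed, or the source file path).
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in required_columns() if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table is missing required columns: {missing}")
        if self.df["subject_id"].duplicated().any():
            dupes = self.df.loc[self.df["subject_id"].duplicated(), "subject_id"]
            raise ValueError(f"duplicate subject_ids: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), dict(self.provenance))

    def analyte_mean(self, analyte: str) -> pd.Series:
        """Per-subject mean of the duplicate reads of one analyte."""
        if analyte not in ANALYTES:
            raise KeyError(f"unknown analyte {analyte!r}")
        return self.df[replicate_columns(analyte)].mean(axis=1, skipna=True)

    def ratio(self, name: str) -> pd.Series:
        """Per-subject 42/40 ratio from duplicate-mean concentrations."""
        num, den = RATIOS[name]
        return self.analyte_mean(num) / self.analyte_mean(den)

    def measurements(self) -> pd.DataFrame:
        """Duplicate-mean concentrations and ratios, one column per variable.

        This is the per-subject analysis table every downstream statistic
        operates on (group summaries, correlations, ROC scores).
        """
        out = pd.DataFrame({"subject_id": self.df["subject_id"]})
        for analyte in ANALYTES:
            out[analyte] = self.analyte_mean(analyte)
        for name in RATIOS:
            out[name] = self.ratio(name)
        return out.set_index("subject_id")

    # ------------------------------------------------------------------ IO

    def write(self, path: str | Path, sep: str = "\t") -> None:
        """Write the cohort as delimited text plus a JSON provenance sidecar.

        Censored covariates round-trip as ``<floor`` strings.
        """
        path = Path(path)
        df = self.df.copy()
        for col in _CENSORED_COLUMNS:
            flag = f"{col}_censored"
            if col in df.columns and flag in df.columns:
                df[col] = [
                    f"<{v:g}" if c else v for v, c in zip(df[col], df[flag])
                ]
                df = df.drop(columns=[flag])
        df.to_csv(path, sep=sep, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.provenance, indent=2, sort_keys=True))


def _parse_censored(df: pd.DataFrame) -> pd.DataFrame:
    for col in _CENSORED_COLUMNS:
        if col not in df.columns:
            continue
        flag = f"{col}_censored"
        values = []
        censored = []
        for raw in df[col]:
            if isinstance(raw, str) and (m := _CENSOR_RE.match(raw)):
                values.append(float(m.group(1)))
                censored.append(True)
            else:
                values.append(np.nan if raw in ("", None) else float(raw))
                censored.append(False)
        df[col] = values
        if flag not in df.columns:
            # keep the flag adjacent to its value column for stable round-trips
            df.insert(df.columns.get_loc(col) + 1, flag, censored)
    return df


def read_cohort(path: str | Path, sep: str = "\t") -> CohortTable:
    """Read a delimited-text cohort file written by :meth:`CohortTable.write`.

    Raises ``ValueError`` naming the missing columns if the header is not a
    valid cohort schema, and naming the offending line for non-numeric reads.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    missing = [c for c in required_columns() if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing mandatory columns: {missing}")
    df = _parse_censored(df)
    for analyte in ANALYTES:
        for col in replicate_columns(analyte):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                # +2: header line plus 1-based numbering
                lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
                raise ValueError(
                    f"non-numeric reads in column {col!r} at line(s) {lines}"
                )
            df[col] = coerced
    provenance: dict = {"source": str(path)}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        provenance.update(json.loads(sidecar.read_text()))
    return CohortTable(df, provenance)


def config_hash(config_dict: Mapping) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
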