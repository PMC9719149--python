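"""Two-compartment dilution model for the plasma Aβ42/40 amyloid contrast.

Circulating amyloid-β is a mixture of peptide released from the central
nervous system (CNS) and peptide produced by peripheral tissues.  Amyloid
pathology selectively lowers the Aβ42/40 ratio of the CNS pool (by roughly
half in CSF), while the peripheral pool is assumed unaffected.  The
contrast measurable in plasma is therefore the CSF contrast diluted in
proportion to the CNS share of the *detected* plasma signal.

A detection antibody that requires the free N-terminal aspartate Asp(1)
(e.g. 3D6) does not see the N-terminally truncated or elongated variants,
which originate predominantly from the periphery.  Excluding them enriches
the CNS share of the detected pool and so accentuates the measurable
plasma contrast relative to an N-terminus-agnostic read-out (e.g. 6E10).

With ``f_cns`` the CNS-derived fraction of total plasma Aβ, ``f_ntx`` the
fraction of *peripheral* plasma Aβ not starting at Asp(1), and ``r_csf``
the relative CSF ratio reduction in amyloid-positive subjects, the model
predicts a plasma ratio decrease of

    nterm_agnostic : f_cns * r_csf
    asp1_specific  : f_cns / (1 - f_ntx * (1 - f_cns)) * r_csf

The defaults (0.30, 0.30, 0.50) give 15% and 19% respectively.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DetectionMode",
    "RoundingMode",
    "MixingParams",
    "MixingPrediction",
    "WorkedExample",
    "detected_cns_fraction",
    "predict_plasma_decrease",
    "worked_example",
    "sensitivity_grid",
]


class DetectionMode(str, Enum):
    """How the detection antibody treats N-terminal Aβ variants."""

    NTERM_AGNOSTIC = "nterm_agnostic"
    ASP1_SPECIFIC = "asp1_specific"


class RoundingMode(str, Enum):
    """Arithmetic mode for intermediate quantities.

    ``EXACT`` carries full precision.  ``TWO_DECIMAL`` rounds the detected
    CNS fraction to two decimals before multiplying by ``r_csf``, which
    reproduces the conventional back-of-the-envelope presentation of the
    model (0.38 x 50% = 19%).
    """

    EXACT = "exact"
    TWO_DECIMAL = "two_decimal"


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class MixingParams:
    """Parameters of the two-compartment dilution model.

    Parameters
    ----------
    f_cns
        Fraction of total plasma Aβ originating from the CNS (dimensionless,
        0-1).  Default 0.30, the midpoint of isotope-labeling-kinetics based
        estimates.
    f_ntx
        Fraction of *peripheral* plasma Aβ whose N-terminus is not Asp(1)
        (0-1).  Default 0.30, the upper end of the 20-30% ballpark from
        2D-Western-blot surveys of plasma Aβ species.
    r_csf
        Relative reduction of the CSF Aβ42/40 ratio in amyloid-positive
        subjects (0-1).  Default 0.50.
    detection_mode
        Whether the simulated read-out detects all N-terminal variants or
        only Asp(1) species.
    rounding_mode
        See :class:`RoundingMode`.
    """

    f_cns: float = 0.30
    f_ntx: float = 0.30
    r_csf: float = 0.50
    detection_mode: DetectionMode = DetectionMode.NTERM_AGNOSTIC
    rounding_mode: RoundingMode = RoundingMode.EXACT

    def __post_init__(self) -> None:
        _check_fraction("f_cns", self.f_cns)
        _check_fraction("f_ntx", self.f_ntx)
        _check_fraction("r_csf", self.r_csf)
        object.__setattr__(self, "detection_mode", DetectionMode(self.detection_mode))
        object.__setattr__(self, "rounding_mode", RoundingMode(self.rounding_mode))

    def with_mode(
        self,
        detection_mode: DetectionMode | str | None = None,
        rounding_mode: RoundingMode | str | None = None,
    ) -> "MixingParams":
        """Return a copy with detection and/or rounding mode replaced."""
        kwargs = {}
        if detection_mode is not None:
            kwargs["detection_mode"] = DetectionMode(detection_mode)
        if rounding_mode is not None:
            kwargs["rounding_mode"] = RoundingMode(rounding_mode)
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MixingPrediction:
    """Model output: CNS share of the detected pool and plasma contrast."""

    detected_cns_fraction: float
    predicted_decrease_pct: float
    params: MixingParams


@dataclass(frozen=True)
class WorkedExample:
    """Mass-budget breakdown of the model for a given total detected amount.

    All masses in ng.  ``detected_ng`` is the Aβ1-40 plus Aβ1-42 amount seen
    by an Asp(1)-specific assay after the non-Asp(1) peripheral species are
    excluded; percentages follow the configured rounding mode.
    """

    total_ng: float
    cns_ng: float
    peripheral_ng: float
    nonasp1_ng: float
    detected_ng: float
    detected_cns_pct: float
    predicted_decrease_pct: float
    params: MixingParams


def detected_cns_fraction(params: MixingParams) -> float:
    """CNS-derived fraction of the *detected* plasma Aβ pool.

    Under N-terminus-agnostic detection the whole pool is seen and the CNS
    share is simply ``f_cns``.  Under Asp(1)-specific detection the
    peripheral non-Asp(1) species drop out of the denominator::

        f_cns / (1 - f_ntx * (1 - f_cns))

    (CNS Aβ is assumed to carry Asp(1) throughout.)
    """
    if params.detection_mode is DetectionMode.NTERM_AGNOSTIC:
        frac = params.f_cns
    elif params.f_cns == 0.0:
        # no CNS contribution regardless of what detection excludes
        # (also covers f_ntx = 1, where the detected pool itself vanishes)
        frac = 0.0
    else:
        # denominator >= f_cns > 0 for valid fractions; it can still
        # underflow to 0 when f_ntx = 1 and f_cns is subnormal, where the
        # analytic limit f_cns / f_cns = 1 applies
        denom = 1.0 - params.f_ntx * (1.0 - params.f_cns)
        frac = min(params.f_cns / denom, 1.0) if denom > 0 else 1.0
    if params.rounding_mode is RoundingMode.TWO_DECIMAL:
        frac = min(round(frac, 2), 1.0)
    return frac


def predict_plasma_decrease(params: MixingParams) -> MixingPrediction:
    """Predicted relative decrease (%) of the plasma Aβ42/40 ratio.

    The plasma contrast is the CSF contrast ``r_csf`` scaled by the CNS
    share of the detected pool, so it can never exceed ``100 * r_csf``.
    """
    frac = detected_cns_fraction(params)
    return MixingPrediction(
        detected_cns_fraction=frac,
        predicted_decrease_pct=100.0 * frac * params.r_csf,
        params=params,
    )


def worked_example(total_ng: float, params: MixingParams) -> WorkedExample:
    """Mass budget for ``total_ng`` of measured plasma Aβ40 plus Aβ42.

    Splits the total into CNS and peripheral portions, removes the
    non-Asp(1) peripheral species, and reports the CNS share of what an
    Asp(1)-specific assay detects together with the implied plasma ratio
    decrease.  At the defaults and 100 ng: 30 ng CNS, 70 ng peripheral,
    21 ng non-Asp(1), 79 ng detected, 38% CNS share, 19% predicted decrease.
    """
    if not total_ng > 0:
        raise ValueError(f"total_ng must be positive, got {total_ng!r}")
    cns_ng = params.f_cns * total_ng
    peripheral_ng = total_ng - cns_ng
    nonasp1_ng = params.f_ntx * peripheral_ng
    detected_ng = total_ng - nonasp1_ng
    asp1 = params.with_mode(detection_mode=DetectionMode.ASP1_SPECIFIC)
    frac = detected_cns_fraction(asp1)
    return WorkedExample(
        total_ng=total_ng,
        cns_ng=cns_ng,
        peripheral_ng=peripheral_ng,
        nonasp1_ng=nonasp1_ng,
        detected_ng=detected_ng,
        detected_cns_pct=100.0 * frac,
        predicted_decrease_pct=100.0 * frac * params.r_csf,
        params=asp1,
    )


def sensitivity_grid(
    f_cns_values: Sequence[float] | Iterable[float],
    f_ntx_values: Sequence[float] | Iterable[float],
    r_csf_values: Sequence[float] | Iterable[float],
    detection_modes: Sequence[DetectionMode | str] = (
        DetectionMode.NTERM_AGNOSTIC,
        DetectionMode.ASP1_SPECIFIC,
    ),
    rounding_mode: RoundingMode | str = RoundingMode.EXACT,
) -> pd.DataFrame:
    """Evaluate the model over a cartesian grid of parameter values.

    Returns one row per (f_cns, f_ntx, r_csf, detection_mode) combination
    with the detected CNS fraction and the predicted decrease.
    """
    f_cns_values = list(f_cns_values)
    f_ntx_values = list(f_ntx_values)
    r_csf_values = list(r_csf_values)
    detection_modes = [DetectionMode(m) for m in detection_modes]
    if not (f_cns_values and f_ntx_values and r_csf_values and detection_modes):
        raise ValueError("sensitivity_grid requires non-empty parameter ranges")
    rows = []
    for fc, fn, rc, mode in itertools.product(
        f_cns_values, f_ntx_values, r_csf_values, detection_modes
    ):
        pred = predict_plasma_decrease(
            MixingParams(
                f_cns=fc,
                f_ntx=fn,
                r_csf=rc,
                detection_mode=mode,
                rounding_mode=RoundingMode(rounding_mode),
            )
        )
        rows.append(
            {
                "f_cns": fc,
                "f_ntx": fn,
                "r_csf": rc,
                "detection_mode": mode.value,
                "detected_cns_fraction": pred.detected_cns_fraction,
                "predicted_decrease_pct": pred.predicted_decrease_pct,
            }
        )
    return pd.DataFrame(rows)
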