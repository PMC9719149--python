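"""Synthetic cohort generator.

Emulates the statistical structure of a memory-clinic cohort measured with
two closely related Aβ multiplex immunoassays (N-terminus-agnostic vs
Asp(1)-specific detection) in CSF and in plasma IP-eluates:

* a clearly bimodal CSF AβX-42/X-40 ratio (two normal components,
  amyloid-negative 0.082 ± 0.0055, amyloid-positive 0.033 ± 0.0056);
* plasma 42/40 ratios whose amyloid contrast follows the two-compartment
  dilution model (:mod:`abratio.mixing`) — ~15% decrease for the agnostic
  read-out and ~19% for the Asp(1)-specific read-out at the defaults;
* within-subject coupling of the two read-outs through shared latent true
  concentrations;
* duplicate technical replicates with a configurable CV, and injectable QC
  violations (high-CV duplicate pairs, singleton reads).

Absolute plasma levels are relative IP-eluate concentrations seeded from
observed cohort medians (agnostic Aβ40 ~300, Asp1 share ~0.48, negative
agnostic ratio ~0.077, Asp1/agnostic ratio scale ~1.44).  Covariates (age,
sex, ApoE4, tau) are generated for schema completeness only and never feed
back into the analytes.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ANALYTES, CohortTable, config_hash, replicate_columns
from .mixing import DetectionMode, MixingParams, predict_plasma_decrease

__all__ = ["CohortConfig", "generate_cohort", "inject_qc_violations"]

GENERATOR_VERSION = "1"


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Group sizes and the CSF ratio components default to the reference
    cohort summaries; the plasma contrast is *derived* from ``mixing`` so
    the generator and the forward model cannot drift apart.  Between-subject
    spreads for plasma ratios are approximations reconstructed from robust
    summary statistics (medians/MADs), not directly reported variances.
    """

    n_neg: int = 37
    n_pos: int = 36
    # CSF 42/40 ratio mixture components (N-terminus-agnostic read-out)
    csf_neg_ratio_mean: float = 0.082
    csf_neg_ratio_sd: float = 0.0055
    csf_pos_ratio_mean: float = 0.033
    csf_pos_ratio_sd: float = 0.0056
    # CSF Aβ40 level (pg/mL), log-scale
    csf_ab40_logmean: float = 8.74
    csf_ab40_logsd: float = 0.37
    #: CSF Asp1 ratio / agnostic ratio (antibody calibration offset)
    csf_asp1_ratio_scale: float = 1.20
    #: CSF Asp1 Aβ40 / agnostic Aβ40 (CSF Aβ is almost all Asp(1))
    csf_ab40_asp1_share: float = 0.90
    # plasma IP-eluate levels (relative units), log-scale
    plasma_ab40_x_logmean: float = math.log(300.0)
    plasma_ab40_x_logsd: float = 0.20
    plasma_ab40_asp1_share: float = 0.48
    plasma_neg_ratio_x_mean: float = 0.077
    #: plasma Asp1 ratio / agnostic ratio in amyloid-negative subjects
    plasma_asp1_ratio_scale: float = 1.44
    # between-subject plasma-ratio noise (lognormal sd, relative scale):
    # a latent component shared by both read-outs plus per-read-out jitter
    ratio_shared_rel_sd: float = 0.065
    ratio_indep_rel_sd: float = 0.02
    #: small lognormal jitter on Asp1-scaled CSF quantities
    csf_jitter_rel_sd: float = 0.02
    #: dilution-model parameters driving the amyloid-positive plasma contrast
    mixing: MixingParams = field(default_factory=MixingParams)
    #: target technical CV of duplicate reads (%)
    replicate_cv_pct: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neg < 2 or self.n_pos < 2:
            raise ValueError("group sizes must be >= 2")
        for name in (
            "csf_neg_ratio_sd",
            "csf_pos_ratio_sd",
            "csf_ab40_logsd",
            "plasma_ab40_x_logsd",
            "ratio_shared_rel_sd",
            "ratio_indep_rel_sd",
            "csf_jitter_rel_sd",
            "replicate_cv_pct",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "csf_neg_ratio_mean",
            "csf_pos_ratio_mean",
            "plasma_neg_ratio_x_mean",
            "csf_asp1_ratio_scale",
            "plasma_asp1_ratio_scale",
            "csf_ab40_asp1_share",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.plasma_ab40_asp1_share <= 1):
            raise ValueError("plasma_ab40_asp1_share must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mixing"]["detection_mode"] = self.mixing.detection_mode.value
        d["mixing"]["rounding_mode"] = self.mixing.rounding_mode.value
        return d


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Normal draws truncated to (0, 1) — ratios are physical fractions."""
    if sd == 0:
        return np.full(n, mean)
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _lognormal_jitter(rng: np.random.Generator, rel_sd: float, n: int) -> np.ndarray:
    """Multiplicative jitter with median 1 and log-sd ~= rel_sd."""
    if rel_sd == 0:
        return np.ones(n)
    return np.exp(rng.normal(0.0, rel_sd, n))


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Draw a full synthetic cohort per ``config`` (deterministic in seed).

    The amyloid-positive plasma ratio means are reduced by the dilution
    model's *exact* predicted decrease for the respective detection mode, so
    the configured model parameters define the ground-truth plasma contrast
    the downstream pipeline should recover.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_neg + config.n_pos
    status = np.array(["negative"] * config.n_neg + ["positive"] * config.n_pos)

    # ---- CSF -----------------------------------------------------------
    ratio_x_csf = np.concatenate(
        [
            _truncated_normal(rng, config.csf_neg_ratio_mean, config.csf_neg_ratio_sd, config.n_neg),
            _truncated_normal(rng, config.csf_pos_ratio_mean, config.csf_pos_ratio_sd, config.n_pos),
        ]
    )
    ratio_1_csf = ratio_x_csf * config.csf_asp1_ratio_scale * _lognormal_jitter(
        rng, config.csf_jitter_rel_sd, n
    )
    csf_ab40_x = np.exp(rng.normal(config.csf_ab40_logmean, config.csf_ab40_logsd, n))
    csf_ab42_x = ratio_x_csf * csf_ab40_x
    csf_ab40_1 = csf_ab40_x * config.csf_ab40_asp1_share * _lognormal_jitter(
        rng, config.csf_jitter_rel_sd, n
    )
    csf_ab42_1 = ratio_1_csf * csf_ab40_1

    # ---- plasma --------------------------------------------------------
    dec_x = predict_plasma_decrease(
        config.mixing.with_mode(detection_mode=DetectionMode.NTERM_AGNOSTIC, rounding_mode="exact")
    ).predicted_decrease_pct
    dec_1 = predict_plasma_decrease(
        config.mixing.with_mode(detection_mode=DetectionMode.ASP1_SPECIFIC, rounding_mode="exact")
    ).predicted_decrease_pct
    pos = status == "positive"
    mean_x = np.where(pos, config.plasma_neg_ratio_x_mean * (1 - dec_x / 100.0),
                      config.plasma_neg_ratio_x_mean)
    neg_mean_1 = config.plasma_neg_ratio_x_mean * config.plasma_asp1_ratio_scale
    mean_1 = np.where(pos, neg_mean_1 * (1 - dec_1 / 100.0), neg_mean_1)

    shared = rng.normal(0.0, 1.0, n)  # latent biology common to both read-outs
    ratio_x_pl = mean_x * np.exp(
        config.ratio_shared_rel_sd * shared + rng.normal(0.0, config.ratio_indep_rel_sd, n)
    )
    ratio_1_pl = mean_1 * np.exp(
        config.ratio_shared_rel_sd * shared + rng.normal(0.0, config.ratio_indep_rel_sd, n)
    )
    plasma_ab40_x = np.exp(rng.normal(config.plasma_ab40_x_logmean, config.plasma_ab40_x_logsd, n))
    plasma_ab40_1 = plasma_ab40_x * config.plasma_ab40_asp1_share * _lognormal_jitter(
        rng, config.csf_jitter_rel_sd, n
    )
    plasma_ab42_x = ratio_x_pl * plasma_ab40_x
    plasma_ab42_1 = ratio_1_pl * plasma_ab40_1

    true_conc = {
        "csf_abx_40": csf_ab40_x,
        "csf_abx_42": csf_ab42_x,
        "csf_ab1_40": csf_ab40_1,
        "csf_ab1_42": csf_ab42_1,
        "plasma_abx_40": plasma_ab40_x,
        "plasma_abx_42": plasma_ab42_x,
        "plasma_ab1_40": plasma_ab40_1,
        "plasma_ab1_42": plasma_ab42_1,
    }

    # ---- duplicate technical reads ------------------------------------
    cv = config.replicate_cv_pct / 100.0
    sigma_t = math.sqrt(math.log1p(cv * cv))  # lognormal sd giving sd/mean ~= cv
    data: dict[str, np.ndarray] = {}
    for analyte in ANALYTES:
        truth = true_conc[analyte]
        for col in replicate_columns(analyte):
            data[col] = truth * np.exp(rng.normal(0.0, sigma_t, n)) if sigma_t else truth.copy()

    # ---- covariates (schema completeness only) -------------------------
    age = np.where(pos, rng.normal(71.6, 7.2, n), rng.normal(67.1, 7.8, n)).round(1)
    sex = np.where(rng.random(n) < np.where(pos, 0.61, 0.54), "F", "M")
    apoe4 = rng.random(n) < np.where(pos, 0.75, 0.22)
    t_tau = np.where(
        pos,
        np.exp(rng.normal(math.log(550.0), 0.55, n)),
        np.exp(rng.normal(math.log(215.0), 0.35, n)),
    )
    p_tau = np.where(
        pos,
        np.exp(rng.normal(math.log(74.0), 0.40, n)),
        np.exp(rng.normal(math.log(38.0), 0.28, n)),
    )
    p_tau_censored = p_tau < 15.6
    p_tau = np.where(p_tau_censored, 15.6, p_tau)

    order = rng.permutation(n)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(n)],
            "true_status": status[order],
            "age": age[order],
            "sex": sex[order],
            "apoe4": apoe4[order],
            "t_tau": np.round(t_tau[order], 1),
            "p_tau181": np.round(p_tau[order], 1),
            "p_tau181_censored": p_tau_censored[order],
            **{col: vals[order] for col, vals in data.items()},
        }
    )
    provenance = {
        "generator": f"abratio-synthetic-cohort-v{GENERATOR_VERSION}",
        "config_hash": config_hash(config.to_dict()),
        "seed": config.seed,
    }
    return CohortTable(df, provenance)


def inject_qc_violations(
    cohort: CohortTable,
    n_high_cv: int,
    n_singleton: int,
    seed: int = 0,
    cv_target_pct: float = 40.0,
) -> CohortTable:
    """Corrupt a copy of ``cohort`` with QC-relevant defects.

    Exactly ``n_high_cv`` subjects get one randomly chosen analyte's
    duplicate pair spread to a CV of ``cv_target_pct`` (default well above
    the 20% exclusion bound), and exactly ``n_singleton`` further subjects
    lose the second read of one plasma analyte.  The affected subject sets
    are disjoint and deterministic under ``seed``.
    """
    if n_high_cv < 0 or n_singleton < 0:
        raise ValueError("violation counts must be >= 0")
    if n_high_cv + n_singleton > len(cohort):
        raise ValueError(
            f"cannot corrupt {n_high_cv + n_singleton} subjects in a cohort of {len(cohort)}"
        )
    out = cohort.copy()
    if n_high_cv + n_singleton == 0:
        return out
    rng = np.random.default_rng(seed)
    rows = rng.choice(len(out.df), size=n_high_cv + n_singleton, replace=False)
    # duplicate pair (m(1+delta), m(1-delta)) has CV = delta*sqrt(2)*100/1
    delta = cv_target_pct / 100.0 / math.sqrt(2.0)
    if delta >= 1.0:
        raise ValueError("cv_target_pct too large for a positive-read pair")
    plasma_analytes = [a for a in ANALYTES if a.startswith("plasma_")]
    for row in rows[:n_high_cv]:
        analyte = ANALYTES[rng.integers(len(ANALYTES))]
        c1, c2 = replicate_columns(analyte)
        m = (out.df.at[row, c1] + out.df.at[row, c2]) / 2.0
        out.df.at[row, c1] = m * (1 + delta)
        out.df.at[row, c2] = m * (1 - delta)
    for row in rows[n_high_cv:]:
        analyte = plasma_analytes[rng.integers(len(plasma_analytes))]
        out.df.at[row, replicate_columns(analyte)[1]] = np.nan
    out.provenance = dict(out.provenance)
    out.provenance["qc_violations"] = {
        "n_high_cv": n_high_cv,
        "n_singleton": n_singleton,
        "seed": seed,
    }
    return out
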