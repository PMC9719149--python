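"""End-to-end study pipeline.

Runs the full analysis flow — ingest or simulate a cohort, QC-filter it,
dichotomize subjects on the CSF 42/40 ratio via the mixture model,
summarize groups, contrast the two plasma read-outs with three effect
metrics, test the contrast difference by .632 bootstrap, compare the
markers' ROC AUCs with the DeLong test, compute the association block, and
attach the dilution-model context — and collects everything in a single
machine-readable report.

A single global seed deterministically derives per-stage seeds (stage-name
CRC hashing), so a stage re-run in isolation reproduces its in-pipeline
result, and the whole report is byte-identical under the same config+seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .association import correlation_matrix, deming_fit, log2_pearson
from .bootstrap import BootstrapConfig, bootstrap_effect_difference
from .classification import classification_stats, delong_paired_test, roc_curve
from .cohort import CohortTable, config_hash, read_cohort
from .effects import METRICS, effect_result, group_summary_table
from .mixing import DetectionMode, MixingParams, predict_plasma_decrease
from .mixture import classify, fit_two_component_mixture
from .qc import QCConfig, apply_exclusions
from .simulate import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "StudyReport", "run_pipeline", "read_cohort"]

logger = logging.getLogger("abratio.pipeline")

#: the two paired plasma markers being compared (A = agnostic, B = Asp1)
MARKER_A = "plasma_abx_ratio"
MARKER_B = "plasma_ab1_ratio"

#: Deming/correlation pairs mirroring the read-out comparison panels
DEMING_PAIRS = (
    ("csf_abx_40", "csf_ab1_40"),
    ("csf_abx_42", "csf_ab1_42"),
    ("csf_abx_ratio", "csf_ab1_ratio"),
    ("plasma_abx_40", "plasma_ab1_40"),
    ("plasma_abx_42", "plasma_ab1_42"),
    ("plasma_abx_ratio", "plasma_ab1_ratio"),
)


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (base_seed * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Exactly one of ``input_path`` / ``simulate`` must be provided."""

    input_path: str | None = None
    simulate: CohortConfig | None = None
    qc: QCConfig | None = None
    qc_enabled: bool = True
    dichotomize_on: str = "csf_abx_ratio"
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    bootstrap_metrics: tuple[str, ...] = METRICS
    mixing: MixingParams = field(default_factory=MixingParams)
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("provide exactly one of input_path or simulate")


@dataclass
class StudyReport:
    """All stage outputs plus provenance; ``stages`` maps stage name to a
    JSON-serializable payload or to {'skipped': reason} / {'error': msg}."""

    stages: dict[str, Any]
    provenance: dict[str, Any]

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(
            {"provenance": self.provenance, "stages": self.stages},
            indent=indent,
            sort_keys=True,
            default=_jsonify,
        )

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "study_report.json"
        path.write_text(self.to_json())
        return path


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records", double_precision=10))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (set, tuple)):
        return list(obj)
    if hasattr(obj, "value"):  # Enum
        return obj.value
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _round6(x: float) -> float:
    return float(f"{x:.6g}")


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute all stages in order, recording failures without aborting
    independent downstream stages."""
    stages: dict[str, Any] = {}

    # ---- cohort ---------------------------------------------------------
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=stage_seed(config.seed, "simulate"))
        cohort = generate_cohort(sim)
        source = {"simulated": True, "config_hash": cohort.provenance["config_hash"]}
    else:
        cohort = read_cohort(config.input_path)
        source = {"simulated": False, "path": config.input_path}
    stages["cohort"] = {**source, "n_subjects": len(cohort)}
    logger.info("cohort: %d subjects", len(cohort))

    # ---- QC -------------------------------------------------------------
    if config.qc_enabled:
        cohort, qc_report = apply_exclusions(cohort, config.qc)
        stages["qc"] = {
            "n_input": qc_report.n_input,
            "n_included": qc_report.n_included,
            "n_excluded": qc_report.n_excluded,
            "excluded": qc_report.per_subject.loc[
                qc_report.per_subject["excluded"], ["subject_id", "reason"]
            ].to_dict(orient="records"),
        }
        logger.info("qc: %d -> %d subjects", qc_report.n_input, qc_report.n_included)
    else:
        stages["qc"] = {"skipped": "qc disabled in config"}

    measures = cohort.measurements()

    # ---- dichotomization ------------------------------------------------
    labels = None
    try:
        fit = fit_two_component_mixture(
            measures[config.dichotomize_on], seed=stage_seed(config.seed, "dichotomize")
        )
        labels = classify(measures[config.dichotomize_on], fit.threshold)
        stages["dichotomization"] = {
            "variable": config.dichotomize_on,
            "weights": [_round6(w) for w in fit.weights],
            "means": [_round6(m) for m in fit.means],
            "sds": [_round6(s) for s in fit.sds],
            "threshold": _round6(fit.threshold),
            "log_likelihood": _round6(fit.log_likelihood),
            "converged": fit.converged,
            "n_positive": int(np.sum(labels == "positive")),
            "n_negative": int(np.sum(labels == "negative")),
            "labels": {sid: lab for sid, lab in zip(measures.index, labels)},
        }
    except Exception as err:  # noqa: BLE001 - stage failures are recorded
        stages["dichotomization"] = {"error": str(err)}
        logger.warning("dichotomization failed: %s", err)

    dependent = ("group_summary", "effects", "bootstrap", "roc")
    if labels is None:
        for name in dependent:
            stages[name] = {"skipped": "dichotomization failed"}
    else:
        pos_mask = labels == "positive"
        neg_mask = labels == "negative"
        a = measures[MARKER_A].to_numpy()
        b = measures[MARKER_B].to_numpy()

        try:
            table = group_summary_table(cohort, labels)
            stages["group_summary"] = {
                "table": table,
                "n_unclassified": table.attrs["n_unclassified"],
            }
        except Exception as err:  # noqa: BLE001
            stages["group_summary"] = {"error": str(err)}

        try:
            effects = {}
            for marker, scores in ((MARKER_A, a), (MARKER_B, b)):
                effects[marker] = {
                    metric: _round6(
                        effect_result(metric, scores[pos_mask], scores[neg_mask], marker).value
                    )
                    for metric in METRICS
                }
            stages["effects"] = effects
        except Exception as err:  # noqa: BLE001
            stages["effects"] = {"error": str(err)}

        try:
            boot = {}
            for metric in config.bootstrap_metrics:
                bc = dataclasses.replace(
                    config.bootstrap,
                    metric=metric,
                    seed=stage_seed(config.seed, f"bootstrap:{metric}"),
                )
                res = bootstrap_effect_difference(a, b, labels, bc)
                boot[metric] = {
                    "observed_difference": _round6(res.observed_difference),
                    "mean": _round6(res.mean),
                    "sd": _round6(res.sd),
                    "normality_p": _round6(res.normality_p) if np.isfinite(res.normality_p) else None,
                    "p_less": _round6(res.p_less),
                    "p_greater": _round6(res.p_greater),
                    "p_two_sided": _round6(res.p_two_sided),
                    "p_value": _round6(res.p_value),
                    "alternative": bc.alternative,
                    "degenerate": res.degenerate,
                    "n_redrawn": res.n_redrawn,
                }
            stages["bootstrap"] = boot
        except Exception as err:  # noqa: BLE001
            stages["bootstrap"] = {"error": str(err)}

        try:
            rocs = {}
            for marker, scores in ((MARKER_A, a), (MARKER_B, b)):
                roc = roc_curve(scores, labels, marker=marker)
                cstats = classification_stats(scores, labels)
                rocs[marker] = {
                    "auc": _round6(roc.auc),
                    "n_pos": roc.n_pos,
                    "n_neg": roc.n_neg,
                    "youden": {
                        k: (_round6(v) if isinstance(v, float) else v)
                        for k, v in dataclasses.asdict(cstats).items()
                    },
                }
            cmp_res = delong_paired_test(a, b, labels)
            rocs["delong"] = {
                "delta_auc": _round6(cmp_res.delta_auc),
                "z": _round6(cmp_res.z),
                "p": _round6(cmp_res.p),
                "degenerate": cmp_res.degenerate,
            }
            stages["roc"] = rocs
        except Exception as err:  # noqa: BLE001
            stages["roc"] = {"error": str(err)}

    # ---- association (independent of dichotomization) -------------------
    try:
        corr = correlation_matrix(cohort)
        demings = {}
        for xvar, yvar in DEMING_PAIRS:
            x = measures[xvar].to_numpy()
            y = measures[yvar].to_numpy()
            fit_d = deming_fit(np.log2(x), np.log2(y))
            r, p = log2_pearson(x, y)
            demings[f"{yvar}~{xvar}"] = {
                "slope": _round6(fit_d.slope),
                "intercept": _round6(fit_d.intercept),
                "pearson_r_log2": _round6(r),
                "pearson_p": _round6(p),
            }
        stages["association"] = {
            "correlations": corr.matrix.round(6),
            "variables": corr.variables,
            "undefined": corr.undefined,
            "deming": demings,
        }
    except Exception as err:  # noqa: BLE001
        stages["association"] = {"error": str(err)}

    # ---- dilution-model context ----------------------------------------
    agn = predict_plasma_decrease(
        config.mixing.with_mode(detection_mode=DetectionMode.NTERM_AGNOSTIC)
    )
    asp1 = predict_plasma_decrease(
        config.mixing.with_mode(detection_mode=DetectionMode.ASP1_SPECIFIC)
    )
    stages["mixing_model"] = {
        "f_cns": config.mixing.f_cns,
        "f_ntx": config.mixing.f_ntx,
        "r_csf": config.mixing.r_csf,
        "predicted_decrease_pct": {
            "nterm_agnostic": _round6(agn.predicted_decrease_pct),
            "asp1_specific": _round6(asp1.predicted_decrease_pct),
        },
    }

    cfg_dict = dataclasses.asdict(config)
    provenance = {
        "abratio_version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(cfg_dict),
    }
    report = StudyReport(stages=stages, provenance=provenance)
    if config.out_dir:
        report.write(config.out_dir)
    return report
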