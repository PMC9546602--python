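"""End-to-end study orchestration.

Two analysis styles mirror the two stages of a bias-decomposition study:

* ``exploratory_style`` — participants are classified by the D-score
  threshold rule, counts are aggregated within each bias-direction
  subsample, and the group-level ML fit runs the planned constraint
  contrasts (equal ACs; each AC against zero).
* ``confirmatory_style`` — the beta-MPT hierarchy is fit under both model
  specifications, participants are classified by which specification the
  T1 posterior-predictive fit favors, and each direction's subsample is
  refit under its own specification to produce posterior-difference
  contrasts with 95% equal-tailed intervals.

Every report number is traceable to a serialized intermediate artifact
(count tables, fit summaries, classification files) written in the same
run; a machine-readable run log records seeds, thresholds, convergence
flags, and the participant counts excluded at every stage.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dscore import (
    BiasClassification,
    ClassificationConfig,
    ScoringConfig,
    classify_by_d,
    compute_d,
    describe_subsamples,
)
from .explicit_bias import ThermometerRecord, classify_thermo, thermo_stats
from .fit_bayes import (
    FitClassification,
    HierarchicalConfig,
    classify_by_fit,
    contrast_posterior,
    fit_hierarchical,
    param_vs_zero,
    t1_fit,
)
from .fit_ml import Constraint, OptimizerConfig, constraint_test, fit_ml
from .iat_data import SessionRecord, read_sessions, tabulate_counts, write_counts
from .quad_core import ActivationMap, BiasDirection, QuadSpecification

__all__ = ["StudyConfig", "StudyResult", "run_study", "compare_directions"]


@dataclass(frozen=True)
class StudyConfig:
    mode: str = "exploratory_style"  # or "confirmatory_style"
    output_dir: str | Path = "study_out"
    seed: int = 0
    d_threshold: float = 0.15
    ppp_fit_threshold: float = 0.05
    ppp_tie_epsilon: float = 0.01
    near_zero_delta: float = 0.005
    activation_map: ActivationMap = ActivationMap.FACES_AND_WORDS
    scoring: ScoringConfig = ScoringConfig()
    optimizer: OptimizerConfig = OptimizerConfig()
    hierarchical: HierarchicalConfig = HierarchicalConfig()

    def __post_init__(self) -> None:
        if self.mode not in ("exploratory_style", "confirmatory_style"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class StudyResult:
    status: str  # "ok" | "failed"
    failed_stage: str | None
    output_dir: Path
    descriptives: pd.DataFrame | None = None
    ml_contrasts: pd.DataFrame | None = None
    bayes_contrasts: pd.DataFrame | None = None
    explicit_summary: pd.DataFrame | None = None
    classifications: pd.DataFrame | None = None
    log: dict = field(default_factory=dict)


def _dscore_stage(sessions, config):
    rows = []
    for s in sessions:
        res = compute_d(s, config.scoring)
        cls = (
            classify_by_d(res.d, s.status_role,
                          ClassificationConfig(config.d_threshold)).value
            if not res.excluded
            else "excluded"
        )
        rows.append(
            {
                "participant_id": s.participant_id,
                "status_role": s.status_role.value,
                "d": res.d,
                "excluded": res.excluded,
                "exclusion_reason": res.exclusion_reason.value
                if res.exclusion_reason
                else "",
                "classification": cls,
            }
        )
    return pd.DataFrame(rows)


def _ml_contrast_rows(table, spec, label, config):
    baseline = fit_ml(table, spec, Constraint.NONE, config.optimizer)
    rows = []
    names = {
        Constraint.EQUAL_ACS: "favored_positive_vs_disfavored_negative",
        Constraint.AC_A_ZERO: "favored_positive_vs_zero",
        Constraint.AC_B_ZERO: "disfavored_negative_vs_zero",
    }
    for constraint, contrast_name in names.items():
        res = constraint_test(table, spec, constraint, config.optimizer, baseline)
        rows.append(
            {
                "subsample": label,
                "contrast": contrast_name,
                "delta_chi2": res.delta_chi2,
                "p": res.p_value,
                "w": res.w,
                "significant_05": res.significant_05,
                "significant_01": res.significant_01,
                "boundary_null": res.boundary_null,
                "ac_a_hat": baseline.params.ac_a,
                "ac_b_hat": baseline.params.ac_b,
                "baseline_gof": baseline.gof_stat,
                "baseline_w": baseline.w,
                "n_total": baseline.n_total,
                "degenerate_ac_warning": baseline.degenerate_ac_warning,
            }
        )
    return rows


def run_study(
    sessions: Sequence[SessionRecord] | str | Path,
    config: StudyConfig = StudyConfig(),
) -> StudyResult:
    """Run the configured analysis end to end, writing report tables.

    ``sessions`` is either an in-memory list or a path to a delimited
    trial file.  On a stage failure, partial outputs are retained and the
    result is marked failed with the failing stage named.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = StudyResult(status="ok", failed_stage=None, output_dir=outdir)
    log: dict = {
        "version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "thresholds": {
            "d_threshold": config.d_threshold,
            "ppp_fit_threshold": config.ppp_fit_threshold,
            "ppp_tie_epsilon": config.ppp_tie_epsilon,
            "near_zero_delta": config.near_zero_delta,
        },
        "stages": [],
    }
    result.log = log

    def fail(stage: str, exc: Exception) -> StudyResult:
        result.status = "failed"
        result.failed_stage = stage
        log["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
        return result

    # -- load
    try:
        if isinstance(sessions, (str, Path)):
            sessions = read_sessions(sessions)
        sessions = list(sessions)
        log["n_sessions"] = len(sessions)
        log["stages"].append("load")
    except Exception as exc:
        return fail("load", exc)

    # -- D-scores (run in both modes; confirmatory reports them as a check)
    try:
        dframe = _dscore_stage(sessions, config)
        dframe.to_csv(outdir / "dscores.csv", index=False)
        log["n_excluded_d"] = int(dframe["excluded"].sum())
        log["stages"].append("dscore")
    except Exception as exc:
        return fail("dscore", exc)

    if config.mode == "exploratory_style":
        try:
            kept = dframe[~dframe.excluded]
            grouped = {
                BiasClassification(c): kept.loc[kept.classification == c, "d"].tolist()
                for c in (
                    "outgroup_biased",
                    "ingroup_biased",
                    "unclassified",
                )
            }
            stats_by = describe_subsamples(grouped)
            desc = pd.DataFrame(
                [
                    {"subsample": cls.value, **dataclasses.asdict(st)}
                    for cls, st in stats_by.items()
                ]
            )
            desc.to_csv(outdir / "descriptives.csv", index=False)
            result.descriptives = desc
            log["stages"].append("descriptives")
        except Exception as exc:
            return fail("descriptives", exc)

        try:
            by_id = {s.participant_id: s for s in sessions}
            rows = []
            for label, direction in (
                ("outgroup_biased", BiasDirection.OUTGROUP_BIAS),
                ("ingroup_biased", BiasDirection.INGROUP_BIAS),
            ):
                ids = dframe.loc[dframe.classification == label, "participant_id"]
                subsample = [by_id[i] for i in ids]
                log[f"n_{label}"] = len(subsample)
                if not subsample:
                    continue
                table = tabulate_counts(subsample)
                write_counts(table, outdir / f"counts_{label}.csv")
                spec = QuadSpecification(direction, config.activation_map)
                rows.extend(_ml_contrast_rows(table, spec, label, config))
            contrasts = pd.DataFrame(rows)
            contrasts.to_csv(outdir / "ml_contrasts.csv", index=False)
            result.ml_contrasts = contrasts
            log["stages"].append("ml_contrasts")
        except Exception as exc:
            return fail("ml_contrasts", exc)
    else:  # confirmatory_style
        try:
            tables = [tabulate_counts(s) for s in sessions]
            ids = [s.participant_id for s in sessions]
            spec_out = QuadSpecification(BiasDirection.OUTGROUP_BIAS,
                                         config.activation_map)
            spec_in = QuadSpecification(BiasDirection.INGROUP_BIAS,
                                        config.activation_map)
            fit_out = fit_hierarchical(tables, spec_out, config.hierarchical, ids)
            fit_in = fit_hierarchical(tables, spec_in, config.hierarchical, ids)
            log["convergence"] = {
                "outgroup_spec": {"converged": fit_out.converged,
                                  "max_rhat": max(fit_out.rhat.values())},
                "ingroup_spec": {"converged": fit_in.converged,
                                 "max_rhat": max(fit_in.rhat.values())},
            }
            labels = classify_by_fit(
                tables, fit_out, fit_in,
                tie_epsilon=config.ppp_tie_epsilon,
                fit_threshold=config.ppp_fit_threshold,
                t1_seed=config.seed + 17,
            )
            cframe = pd.DataFrame({"participant_id": ids, "classification": labels})
            cframe.to_csv(outdir / "fit_classifications.csv", index=False)
            result.classifications = cframe
            log["n_excluded_dual_fit"] = int(sum(1 for l in labels
                                                 if l == FitClassification.EXCLUDED))
            log["stages"].append("dual_fit_classification")
        except Exception as exc:
            return fail("dual_fit_classification", exc)

        try:
            rows = []
            for label, spec in (
                (FitClassification.OUTGROUP_BIASED, spec_out),
                (FitClassification.INGROUP_BIASED, spec_in),
            ):
                sub = [t for t, l in zip(tables, labels) if l == label]
                sub_ids = [i for i, l in zip(ids, labels) if l == label]
                log[f"n_{label}"] = len(sub)
                if len(sub) < 2:
                    continue
                refit = fit_hierarchical(sub, spec, config.hierarchical, sub_ids)
                contrast = contrast_posterior(refit, "ac_a", "ac_b")
                dist_a, bci_a = param_vs_zero(refit, "ac_a", config.near_zero_delta)
                dist_b, bci_b = param_vs_zero(refit, "ac_b", config.near_zero_delta)
                rows.append(
                    {
                        "subsample": label,
                        "contrast": "favored_positive_vs_disfavored_negative",
                        "mean_difference": contrast.mean_difference,
                        "bci_low": contrast.bci_low,
                        "bci_high": contrast.bci_high,
                        "excludes_zero": contrast.excludes_zero,
                        "ac_a_distinguishable": dist_a,
                        "ac_a_bci_low": bci_a[0],
                        "ac_a_bci_high": bci_a[1],
                        "ac_b_distinguishable": dist_b,
                        "ac_b_bci_low": bci_b[0],
                        "ac_b_bci_high": bci_b[1],
                        "converged": refit.converged,
                        "n_participants": len(sub),
                    }
                )
            contrasts = pd.DataFrame(rows)
            contrasts.to_csv(outdir / "bayes_contrasts.csv", index=False)
            result.bayes_contrasts = contrasts
            log["stages"].append("bayes_contrasts")
        except Exception as exc:
            return fail("bayes_contrasts", exc)

    # -- explicit bias (whenever thermometers are present)
    try:
        records = {}
        for s in sessions:
            if s.thermometer_ingroup is None or s.thermometer_outgroup is None:
                continue
            rec = ThermometerRecord(s.thermometer_ingroup, s.thermometer_outgroup)
            records.setdefault(classify_thermo(rec), []).append(rec)
        if records:
            summary = thermo_stats(records)
            frame = pd.DataFrame(
                [
                    {"subsample": cls.value, **dataclasses.asdict(st)}
                    for cls, st in summary.items()
                ]
            )
            frame.to_csv(outdir / "explicit_summary.csv", index=False)
            result.explicit_summary = frame
        log["stages"].append("explicit")
    except Exception as exc:
        return fail("explicit", exc)

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return result


def compare_directions(
    outgroup_report: pd.DataFrame, ingroup_report: pd.DataFrame
) -> pd.DataFrame:
    """Juxtapose favored-positive vs disfavored-negative contrasts across
    the two bias directions (the positive-negative asymmetry summary).

    Accepts the per-direction contrast tables produced by
    :func:`run_study` (either the ML or the Bayesian form).
    """
    for name, frame in (("outgroup", outgroup_report), ("ingroup", ingroup_report)):
        if frame is None or len(frame) == 0:
            raise ValueError(f"missing {name}-biased subsample report")
    combined = pd.concat(
        [outgroup_report.assign(direction="outgroup_bias"),
         ingroup_report.assign(direction="ingroup_bias")],
        ignore_index=True,
    )
    mask = combined["contrast"] == "favored_positive_vs_disfavored_negative"
    return combined[mask].reset_index(drop=True)
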