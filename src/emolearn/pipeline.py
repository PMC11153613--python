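"""End-to-end orchestration: cohort -> task simulation -> RL fitting ->
behavioural statistics -> MRS statistics -> prediction, with every stage's
tables persisted and a consolidated JSON + text report.

A single global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence([seed, stage_index])``, so any stage can be
re-run in isolation and the full bundle is byte-identical for a fixed
config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import behavior, cohort, mrs, predict, rl, task

log = logging.getLogger("emolearn")

STAGE_SEEDS = {"cohort": 1, "task": 2, "rl": 3, "mrs": 4}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the global seed."""
    return int(np.random.SeedSequence([seed, STAGE_SEEDS[stage]]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    seed: int = 0
    cohort_config: cohort.CohortConfig = field(default_factory=cohort.CohortConfig)
    task_config: task.TaskConfig = field(default_factory=task.TaskConfig)
    param_map: dict | None = None  # default group x visit agent parameters
    effect_config: mrs.EffectConfig = field(default_factory=mrs.EffectConfig)
    alpha: float = 0.05
    bonferroni_alpha: float = behavior.BONFERRONI_ALPHA
    classification_threshold: float = 0.5
    n_fit_starts: int = 10
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        for thr in (self.alpha, self.bonferroni_alpha, self.classification_threshold):
            if thr <= 0:
                raise ValueError("all thresholds must be positive")


def run_all(config: RunConfig | None = None) -> dict:
    """Execute the full pipeline on a synthetic cohort; return the bundle.

    The bundle maps artifact names to DataFrames / dicts; when
    ``config.out_dir`` is set every table is written as CSV and the report
    as JSON + text.
    """
    config = RunConfig() if config is None else config
    bundle: dict = {"seed": config.seed}

    log.info("stage cohort: generating %d+%d participants",
             config.cohort_config.n_resistant, config.cohort_config.n_responsive)
    participants, labels = cohort.generate_cohort(
        config.cohort_config, seed=stage_seed(config.seed, "cohort")
    )
    analysed = labels.loc[labels["label"] != "unclassified"]
    bundle["participants"], bundle["labels"] = participants, labels

    log.info("stage task: simulating trials")
    trials = task.simulate_visits(
        analysed, param_map=config.param_map, config=config.task_config,
        seed=stage_seed(config.seed, "task"),
    )
    bundle["trials"] = trials

    log.info("stage rl: fitting %d cells", trials.groupby(
        ["participant_id", "visit", "condition"]).ngroups)
    fits, flagged = rl.fit_cohort(
        trials, n_starts=config.n_fit_starts, seed=stage_seed(config.seed, "rl")
    )
    bundle["rl_fits"], bundle["trials_flagged"] = fits, flagged

    log.info("stage behavior")
    props = fits.merge(analysed[["participant_id", "label"]], on="participant_id").rename(
        columns={"label": "group"}
    )
    bundle["proportions"] = props
    bundle["cell_summaries"] = behavior.cell_summaries(props)
    bundle["chance_tests"] = behavior.chance_tests(props, adjusted_alpha=config.bonferroni_alpha)
    bundle["behavior_anova"] = behavior.mixed_anova_2x2x2(props)
    scores = behavior.emotional_bias(flagged).merge(
        analysed[["participant_id", "label"]], on="participant_id"
    ).rename(columns={"label": "group"})
    bundle["bias_scores"] = scores
    bundle["bias_anova"] = behavior.bias_anova(scores)

    log.info("stage mrs")
    metabolites, roi = mrs.generate_mrs_roi_data(
        analysed, config.effect_config, seed=stage_seed(config.seed, "mrs")
    )
    bundle["metabolites"], bundle["roi_betas"] = metabolites, roi
    included, excluded = mrs.qc_filter(metabolites)
    bundle["mrs_included"], bundle["mrs_excluded"] = included, excluded
    log.info("QC: %d rows kept, %d excluded", len(included), len(excluded))
    bundle["glutamate_anova"] = mrs.glutamate_anova(included, analysed)
    bundle["creatine_stability"] = mrs.creatine_stability(included)
    bundle["coupling"] = mrs.mpfc_glutamate_coupling(metabolites, roi, analysed)

    log.info("stage predict")
    features = predict.build_features(roi, metabolites, fits, analysed)
    bundle["features"] = features
    fit = predict.fit_logistic(features, scale=True)
    bundle["logistic_fit"] = fit
    bundle["prediction_report"] = predict.classify_and_report(
        fit, features, threshold=config.classification_threshold
    )
    fit_raw = predict.fit_logistic(features, scale=False)
    bundle["logistic_fit_raw"] = fit_raw

    if config.out_dir is not None:
        persist_bundle(bundle, Path(config.out_dir))
    return bundle


def sex_chi2(participants: pd.DataFrame, labels: pd.DataFrame) -> dict:
    """Pearson chi-squared (no continuity correction) on sex x group counts."""
    merged = participants.drop_duplicates("participant_id").merge(labels, on="participant_id")
    merged = merged.loc[merged["label"].isin(["resistant", "responsive"])]
    table = pd.crosstab(merged["label"], merged["sex"])
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "df": int(dof), "p": float(p)}


def make_report(bundle: dict) -> dict:
    """Consolidated JSON-serialisable summary of every pipeline stage."""
    report: dict = {"seed": bundle.get("seed")}

    def anova_section(df: pd.DataFrame | None) -> list | None:
        if df is None:
            return None
        return df[["Source", "F", "df1", "df2", "p", "np2"]].round(6).to_dict("records")

    if "labels" in bundle:
        counts = bundle["labels"]["label"].value_counts().to_dict()
        report["cohort"] = {"group_counts": counts}
        if "participants" in bundle:
            report["cohort"]["sex_chi2"] = sex_chi2(bundle["participants"], bundle["labels"])
    if "cell_summaries" in bundle:
        report["ideal_choice_cells"] = bundle["cell_summaries"].round(4).to_dict("records")
        report["chance_tests"] = bundle["chance_tests"].round(5).to_dict("records")
        report["behavior_anova"] = anova_section(bundle.get("behavior_anova"))
    if "bias_scores" in bundle:
        mean, se = behavior.overall_bias_mean(bundle["bias_scores"])
        report["emotional_bias"] = {"mean": round(mean, 4), "se": round(se, 4)}
        report["bias_anova"] = anova_section(bundle.get("bias_anova"))
    if "glutamate_anova" in bundle:
        report["glutamate_anova"] = anova_section(bundle["glutamate_anova"])
        report["creatine_stability"] = bundle["creatine_stability"]
        coup = bundle["coupling"]
        report["coupling"] = {
            g: {k: coup[g][k] for k in ("r", "n", "p")} for g in ("responsive", "resistant")
            if g in coup
        }
        if "comparison" in coup:
            c = coup["comparison"]
            report["coupling"]["fisher_z"] = {"Z": c.Z, "p": c.p}
    if "prediction_report" in bundle:
        r = bundle["prediction_report"]
        report["prediction"] = {
            "nagelkerke_r2": round(r.nagelkerke_r2, 4),
            "sensitivity_pct": r.sensitivity_pct,
            "specificity_pct": r.specificity_pct,
            "accuracy_pct": r.accuracy_pct,
            "confusion": {"tp": r.tp, "fn": r.fn, "tn": r.tn, "fp": r.fp},
            "coefficients": r.coefficients,
            "separation": r.separation,
        }
    else:
        report["prediction"] = None
    return report


def report_text(report: dict) -> str:
    """Human-readable rendering of the consolidated report."""
    lines = [f"emolearn pipeline report (seed {report.get('seed')})", "=" * 44]
    if "cohort" in report:
        lines.append(f"cohort: {report['cohort']['group_counts']}")
        if "sex_chi2" in report["cohort"]:
            s = report["cohort"]["sex_chi2"]
            lines.append(f"sex x group chi2({s['df']}) = {s['chi2']:.3f}, p = {s['p']:.3f}")
    if "ideal_choice_cells" in report:
        lines.append("\nideal-choice proportions (group x visit x condition):")
        for c in report["ideal_choice_cells"]:
            lines.append(
                f"  {c['group']:<10} visit {c['visit']} {c['condition']:<9}"
                f" n={c['n']:<3} M={c['mean']:.3f} SD={c['sd']:.3f}"
            )
    if report.get("emotional_bias"):
        b = report["emotional_bias"]
        lines.append(f"\nemotional bias: M = {b['mean']:.3f} (SE {b['se']:.3f})")
    if report.get("coupling"):
        lines.append("\nmPFC-glutamate coupling at visit C:")
        for g in ("responsive", "resistant"):
            if g in report["coupling"]:
                c = report["coupling"][g]
                lines.append(f"  {g}: r_s({c['n']}) = {c['r']:.3f}, p = {c['p']:.4f}")
        if "fisher_z" in report["coupling"]:
            f = report["coupling"]["fisher_z"]
            lines.append(f"  Fisher Z = {f['Z']:.3f}, p = {f['p']:.4f}")
    if report.get("prediction"):
        p = report["prediction"]
        lines.append(
            f"\nprediction: Nagelkerke R2 = {p['nagelkerke_r2']:.3f}; "
            f"sensitivity {p['sensitivity_pct']}%, specificity {p['specificity_pct']}%, "
            f"accuracy {p['accuracy_pct']}%"
        )
    return "\n".join(lines) + "\n"


def persist_bundle(bundle: dict, out_dir: Path) -> None:
    """Write every table as CSV and the consolidated report as JSON + text."""
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out_dir / f"{name}.csv", index=False)
    report = make_report(bundle)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=_jsonable))
    (out_dir / "report.txt").write_text(report_text(report))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
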