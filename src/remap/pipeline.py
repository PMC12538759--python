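"""End-to-end pipeline: score -> stratify -> impute -> model -> statistics.

``run_pipeline`` executes the full analysis sequence on a cohort (synthetic
by default, or read from CSVs):

1.  acquire inputs (simulate, or read item-level + biomarker CSVs),
2.  score questionnaires to scale scores,
3.  compute BSL->T3 differentials and rule-stratify participants with
    evaluable endpoint data,
4.  missingness report over the per-timepoint model-feature matrix,
5.  chained-equation imputation of that matrix (all participants jointly),
    with a kNN comparison table,
6.  full-feature multinomial model + repeated stratified CV + coefficient
    summary,
7.  L1 feature selection,
8.  refined model on the selected features + CV + coefficient summary,
9.  prediction of participants without rule labels (the "non-completers"),
10. combined rule-based + predicted class counts,
11. longitudinal time effects, Dunnett baseline comparisons, and per-family
    BKY FDR for every outcome (questionnaires and log2 biomarkers),
12. biomarker-vs-clinical correlation of BSL->T3 differentials.

Every stochastic stage receives a seed derived from one master seed via
named substreams, so a config reruns to identical artifacts.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as remap_io
from .imputation import (
    FeatureBounds,
    FeatureTable,
    compare_imputation_methods,
    impute_chained,
    missingness_table,
)
from .longitudinal import (
    BiomarkerSeries,
    LongitudinalOutcome,
    annotate_family_fdr,
    correlate_differentials,
    dunnett_baseline_comparisons,
    fit_time_effect,
    log2_series,
    residual_qq,
)
from .responder_model import (
    ModelConfig,
    cross_validate_repeated,
    fit_multinomial,
    predict_statuses,
    select_features_l1,
    summarize_coefficients,
)
from .stratification import MODEL_FEATURES, Thresholds, stratify_cohort
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort

STAGES = (
    "inputs", "score", "stratify", "missingness", "impute", "model_full",
    "select_features", "model_refined", "predict", "combine", "longitudinal",
    "correlate",
)

_FEATURE_BOUNDS = {
    "BAS": FeatureBounds(0, 100, step=10),
    "MFI_aggregate": FeatureBounds(20, 100),
    "SF36_PCS": FeatureBounds(-np.inf, np.inf),
}
_FEATURE_BOUNDS.update(
    {f: FeatureBounds(4, 20) for f in MODEL_FEATURES if f.startswith("MFI_")
     and f != "MFI_aggregate"}
)
_FEATURE_BOUNDS.update(
    {f: FeatureBounds(0, 100) for f in ("SF36_VT", "SF36_SF", "SF36_RP")}
)

#: outcome families for the per-panel BKY FDR pass
OUTCOME_FAMILIES = {
    "BAS": ["BAS"],
    "SSS": ["SSS_fatigue", "SSS_disturbed_sleep", "SSS_PEM", "SSS_OI"],
    "MFI": ["MFI_general_fatigue", "MFI_physical_fatigue", "MFI_reduced_activity",
            "MFI_reduced_motivation", "MFI_mental_fatigue", "MFI_aggregate"],
    "SF36": ["SF36_PF", "SF36_RP", "SF36_BP", "SF36_GH", "SF36_VT", "SF36_SF",
             "SF36_RE", "SF36_MH", "SF36_PCS", "SF36_MCS"],
    "biomarkers": ["log2_BECLIN1", "log2_pSer258_ATG13"],
}

#: better-health direction per feature prefix
def _direction(feature: str) -> int:
    return -1 if feature.startswith(("MFI_", "SSS_", "log2_pSer258")) else 1


def derive_seed(master: int, name: str) -> int:
    """Named substream seed below 2**31, stable across runs."""
    return int(
        np.random.SeedSequence([master, zlib.crc32(name.encode())]).generate_state(1)[0]
        % (2 ** 31)
    )


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig | None = None  # None -> trial-shaped default
    items_csv: str | None = None  # read instead of simulating
    biomarkers_csv: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    model: ModelConfig = field(default_factory=ModelConfig)
    impute_max_iter: int = 10
    compare_imputers: bool = True
    l1_C: float = 0.2  # lasso strength: keeps ~half the features at trial scale
    fdr_alpha: float = 0.05
    min_timepoints_for_model: tuple[str, ...] = ("BSL", "T1")
    run_longitudinal: bool = True  # the mixed-model stage; skippable for
    # classification-only runs on very large synthetic cohorts


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, bundle: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.bundle = bundle  # partial artifacts up to the failure


def _model_matrix(scored: pd.DataFrame) -> FeatureTable:
    """Participant x (timepoint:feature) matrix of the model features."""
    sub = scored[scored["feature"].isin(MODEL_FEATURES)]
    wide = sub.pivot_table(
        index="participant_id", columns=["timepoint", "feature"], values="value",
        aggfunc="first",
    )
    cols, bounds = [], {}
    for tp in ("BSL", "T1", "T2", "T3"):
        for feat in MODEL_FEATURES:
            name = f"{tp}:{feat}"
            if (tp, feat) in wide.columns:
                cols.append(wide[(tp, feat)].rename(name))
            else:
                cols.append(pd.Series(np.nan, index=wide.index, name=name))
            bounds[name] = _FEATURE_BOUNDS.get(feat, FeatureBounds())
    data = pd.concat(cols, axis=1)
    return FeatureTable(data, bounds)


def _differential_table(completed: FeatureTable) -> FeatureTable:
    """T3 - BSL differentials of the model features from a completed
    per-timepoint matrix."""
    data = {}
    for feat in MODEL_FEATURES:
        data[feat] = completed.data[f"T3:{feat}"] - completed.data[f"BSL:{feat}"]
    return FeatureTable(pd.DataFrame(data))


def run_pipeline(config: PipelineConfig = PipelineConfig(),
                 cohort: SyntheticCohort | None = None) -> dict:
    """Execute all stages; returns the result bundle (a dict of artifacts
    keyed by stage output name, plus a manifest)."""
    bundle: dict = {"stages_completed": [], "seed": config.seed}
    stage = "inputs"
    try:
        # 1 — inputs
        validation = remap_io.ValidationReport()
        if cohort is None and config.items_csv is None:
            cohort_cfg = config.cohort or CohortConfig(
                seed=derive_seed(config.seed, "cohort")
            )
            cohort = generate_cohort(cohort_cfg)
        if cohort is not None:
            items = cohort.items
            biomarkers = dict(cohort.biomarkers)
            bundle["truth"] = cohort.truth
        else:
            items, validation = remap_io.read_items_csv(config.items_csv, validation)
            biomarkers = {}
            if config.biomarkers_csv:
                biomarkers, validation = remap_io.read_biomarkers_csv(
                    config.biomarkers_csv, validation
                )
        bundle["stages_completed"].append(stage)

        # 2 — score
        stage = "score"
        scored, validation = remap_io.score_items(items, validation)
        bundle["scored"] = scored
        bundle["validation"] = validation
        bundle["stages_completed"].append(stage)

        # 3 — differentials + rule stratification
        stage = "stratify"
        strat = stratify_cohort(scored, config.thresholds)
        bundle["labels_rule"] = strat["labels"]
        bundle["counts_rule"] = strat["counts"]
        bundle["needs_prediction"] = strat["needs_prediction"]
        bundle["differentials_observed"] = strat["differentials"]
        bundle["stages_completed"].append(stage)

        # 4 — missingness
        stage = "missingness"
        matrix = _model_matrix(scored)
        # restrict to participants with the minimum timepoint coverage
        have = [
            pid for pid in matrix.data.index
            if all(
                matrix.data.loc[pid, [f"{tp}:{f}" for f in MODEL_FEATURES]].notna().any()
                for tp in config.min_timepoints_for_model
            )
        ]
        matrix = FeatureTable(matrix.data.loc[have], dict(matrix.bounds))
        bundle["missingness"] = missingness_table(matrix)
        bundle["stages_completed"].append(stage)

        # 5 — imputation (jointly over rule-labeled and unlabeled participants)
        stage = "impute"
        completed, imp_report = impute_chained(
            matrix, max_iter=config.impute_max_iter,
            seed=derive_seed(config.seed, "impute"),
        )
        bundle["imputation_report"] = imp_report
        if config.compare_imputers:
            bundle["imputer_comparison"] = compare_imputation_methods(
                matrix, seed=derive_seed(config.seed, "impute-compare")
            )
        diffs = _differential_table(completed)
        bundle["differentials_completed"] = diffs
        bundle["stages_completed"].append(stage)

        # 6 — full-feature model + CV
        stage = "model_full"
        labels = bundle["labels_rule"].set_index("participant_id")["status"]
        train_ids = [p for p in diffs.data.index if p in labels.index]
        predict_ids = [p for p in diffs.data.index if p not in labels.index]
        train_table = FeatureTable(diffs.data.loc[train_ids])
        y = labels.loc[train_ids].tolist()
        model_cfg = replace(config.model, seed=derive_seed(config.seed, "model"))
        # a very small rule class cannot support the configured fold count;
        # degrade the split count (>= 2) rather than abort the analysis
        min_class = min(pd.Series(y).value_counts())
        if min_class < model_cfg.cv_splits:
            model_cfg = replace(model_cfg, cv_splits=max(2, int(min_class)))
        model_full = fit_multinomial(train_table, y, model_cfg,
                                     expected_classes=sorted(set(y)))
        bundle["model_full"] = model_full
        bundle["coefficients_full"] = summarize_coefficients(
            model_full, train_table, y,
            seed=derive_seed(config.seed, "wald-full"),
        )
        bundle["cv_full"] = cross_validate_repeated(train_table, y, model_cfg)
        bundle["stages_completed"].append(stage)

        # 7 — L1 selection
        stage = "select_features"
        selected = select_features_l1(
            train_table, y, replace(model_cfg, C=config.l1_C)
        )
        bundle["selected_features"] = selected
        bundle["stages_completed"].append(stage)

        # 8 — refined model
        stage = "model_refined"
        refined_table = FeatureTable(train_table.data[selected])
        model_refined = fit_multinomial(refined_table, y, model_cfg,
                                        expected_classes=sorted(set(y)))
        bundle["model_refined"] = model_refined
        bundle["coefficients_refined"] = summarize_coefficients(
            model_refined, refined_table, y,
            seed=derive_seed(config.seed, "wald-refined"),
        )
        bundle["cv_refined"] = cross_validate_repeated(refined_table, y, model_cfg)
        bundle["stages_completed"].append(stage)

        # 9 — predict non-completers
        stage = "predict"
        if predict_ids:
            pred_table = FeatureTable(diffs.data.loc[predict_ids, selected])
            pred, proba = predict_statuses(model_refined, pred_table)
            bundle["predictions"] = pd.DataFrame(
                {
                    "participant_id": predict_ids, "status": pred,
                    "provenance": "model_predicted",
                    **{
                        f"p_{c}": proba[:, i]
                        for i, c in enumerate(model_refined.classes)
                    },
                }
            )
        else:
            bundle["predictions"] = pd.DataFrame(
                columns=["participant_id", "status", "provenance"]
            )
        bundle["stages_completed"].append(stage)

        # 10 — combined counts
        stage = "combine"
        combined = pd.concat(
            [
                bundle["labels_rule"][["participant_id", "status", "provenance"]],
                bundle["predictions"][["participant_id", "status", "provenance"]],
            ],
            ignore_index=True,
        )
        bundle["labels_combined"] = combined
        bundle["counts_combined"] = combined["status"].value_counts().to_dict()
        bundle["stages_completed"].append(stage)

        # 11 — longitudinal statistics
        stage = "longitudinal"
        if not config.run_longitudinal:
            outcomes = {}
        else:
            outcomes = _build_outcomes(scored, biomarkers)
        time_effects, pairwise, qq_tables = [], [], {}
        dunnett_seed = derive_seed(config.seed, "dunnett")
        for fam, members in OUTCOME_FAMILIES.items():
            fam_effects, fam_pairwise = [], []
            for name in members:
                if name not in outcomes:
                    continue
                out = outcomes[name]
                try:
                    te = fit_time_effect(out)
                except ValueError:
                    continue
                fam_effects.append(te)
                fam_pairwise.extend(
                    dunnett_baseline_comparisons(out, seed=dunnett_seed)
                )
                resid = _within_subject_residuals(out)
                if len(resid) >= 3:
                    qq_tables[name] = residual_qq(resid)
            annotate_family_fdr(fam_effects, fam_pairwise, config.fdr_alpha)
            time_effects.extend(fam_effects)
            pairwise.extend(fam_pairwise)
        bundle["time_effects"] = time_effects
        bundle["pairwise"] = pairwise
        bundle["qq_tables"] = qq_tables
        bundle["fold_changes"] = {
            analyte: log2_series(
                BiomarkerSeries(analyte, wide)
            )["fold_changes"]
            for analyte, wide in biomarkers.items()
        }
        bundle["stages_completed"].append(stage)

        # 12 — biomarker correlations
        stage = "correlate"
        bundle["correlations"] = _correlations(
            bundle["differentials_observed"], biomarkers
        )
        bundle["stages_completed"].append(stage)
    except Exception as err:  # keep partial artifacts for post-mortem
        raise PipelineStageError(stage, err, bundle) from err

    bundle["manifest"] = {
        "stages": list(bundle["stages_completed"]),
        "seed": config.seed,
        "n_participants_model": len(bundle.get("differentials_completed",
                                               FeatureTable(pd.DataFrame())).data),
        "selected_features": bundle.get("selected_features", []),
    }
    return bundle


def _build_outcomes(
    scored: pd.DataFrame, biomarkers: dict[str, pd.DataFrame]
) -> dict[str, LongitudinalOutcome]:
    outcomes: dict[str, LongitudinalOutcome] = {}
    for feature, sub in scored.groupby("feature"):
        wide = sub.pivot_table(index="participant_id", columns="timepoint",
                               values="value", aggfunc="first")
        try:
            outcomes[feature] = LongitudinalOutcome(
                feature, wide, improvement_direction=_direction(feature)
            )
        except ValueError:
            continue
    for analyte, wide in biomarkers.items():
        name = f"log2_{analyte}"
        log2 = log2_series(BiomarkerSeries(analyte, wide))["log2"]
        outcomes[name] = LongitudinalOutcome(
            name, log2, improvement_direction=_direction(name)
        )
    return outcomes


def _within_subject_residuals(outcome: LongitudinalOutcome) -> np.ndarray:
    """Residuals after removing participant and timepoint means (the
    additive model whose normality the QQ table checks)."""
    wide = outcome.data
    arr = wide.to_numpy(dtype=float)
    grand = np.nanmean(arr)
    row = np.nanmean(arr, axis=1, keepdims=True)
    col = np.nanmean(arr, axis=0, keepdims=True)
    resid = arr - row - col + grand
    return resid[~np.isnan(resid)]


def _correlations(diffs: pd.DataFrame, biomarkers: dict[str, pd.DataFrame]
                  ) -> pd.DataFrame:
    rows = []
    clinical_features = [
        c for c in diffs.columns if not c.startswith("log2_")
    ] if len(diffs) else []
    for analyte, wide in biomarkers.items():
        log2 = log2_series(BiomarkerSeries(analyte, wide))["log2"]
        if "BSL" not in log2.columns or "T3" not in log2.columns:
            continue
        bio_diff = log2["T3"] - log2["BSL"]
        for feature in clinical_features:
            entry = correlate_differentials(
                diffs[feature], bio_diff, clinical_name=feature,
                analyte=f"log2_{analyte}",
            )
            rows.append(entry.to_dict())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# artifact output


def _versioned(path: Path) -> None:
    """Move an existing file aside (name.1, name.2, ...) instead of
    clobbering it."""
    if not path.exists():
        return
    n = 1
    while path.with_name(f"{path.name}.{n}").exists():
        n += 1
    path.rename(path.with_name(f"{path.name}.{n}"))


def _write(path: Path, writer) -> str:
    path.parent.mkdir(parents=True, exist_ok=True)
    _versioned(path)
    writer(path)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    return digest


def write_results(bundle: dict, out_dir: str | Path) -> dict[str, str]:
    """Write the bundle's artifacts as CSV/JSON; returns file -> sha256.

    Existing files are versioned aside, never overwritten. A human-readable
    ``summary.txt`` and a ``manifest.json`` (stage list, seed, hashes) are
    always produced.
    """
    out = Path(out_dir)
    hashes: dict[str, str] = {}

    def csv(name: str, df: pd.DataFrame, index=False):
        hashes[name] = _write(out / name, lambda p: df.to_csv(p, index=index))

    def js(name: str, obj):
        hashes[name] = _write(out / name, lambda p: remap_io.write_json(obj, p))

    if "scored" in bundle:
        csv("scored.csv", bundle["scored"])
    if "validation" in bundle and len(bundle["validation"]):
        csv("validation.csv", bundle["validation"].to_frame())
    if "labels_rule" in bundle:
        csv("labels_rule.csv", bundle["labels_rule"])
        js("counts_rule.json", bundle["counts_rule"])
    if "differentials_observed" in bundle and len(bundle["differentials_observed"]):
        csv("differentials_observed.csv", bundle["differentials_observed"],
            index=True)
    if "missingness" in bundle:
        js("missingness.json", bundle["missingness"].to_dict())
    if "imputation_report" in bundle:
        js("imputation_report.json", bundle["imputation_report"].to_dict())
    if "imputer_comparison" in bundle:
        csv("imputer_comparison.csv", bundle["imputer_comparison"])
    if "differentials_completed" in bundle:
        csv("differentials_completed.csv", bundle["differentials_completed"].data,
            index=True)
    for key in ("model_full", "model_refined"):
        if key in bundle:
            js(f"{key}.json", bundle[key].to_dict())
    for key in ("coefficients_full", "coefficients_refined"):
        if key in bundle:
            csv(f"{key}.csv", bundle[key])
    for key in ("cv_full", "cv_refined"):
        if key in bundle:
            js(f"{key}.json", bundle[key].to_dict())
            csv(f"{key}_confusion.csv", bundle[key].confusion, index=True)
            csv(f"{key}_calibration.csv", bundle[key].calibration)
    if "selected_features" in bundle:
        js("selected_features.json", bundle["selected_features"])
    if "predictions" in bundle and len(bundle["predictions"]):
        csv("predictions.csv", bundle["predictions"])
    if "labels_combined" in bundle:
        csv("labels_combined.csv", bundle["labels_combined"])
        js("counts_combined.json", bundle["counts_combined"])
    if "time_effects" in bundle:
        csv("time_effects.csv",
            pd.DataFrame([t.to_dict() for t in bundle["time_effects"]]))
    if "pairwise" in bundle:
        csv("pairwise.csv", pd.DataFrame([p.to_dict() for p in bundle["pairwise"]]))
    for name, qq in bundle.get("qq_tables", {}).items():
        csv(f"qq_{name}.csv", qq)
    if "fold_changes" in bundle:
        js("fold_changes.json", bundle["fold_changes"])
    if "correlations" in bundle and len(bundle["correlations"]):
        csv("correlations.csv", bundle["correlations"])

    summary = _summary_text(bundle)
    hashes["summary.txt"] = _write(out / "summary.txt",
                                   lambda p: p.write_text(summary))
    manifest = dict(bundle.get("manifest", {}))
    manifest["files"] = hashes
    js("manifest.json", manifest)
    return hashes


def _summary_text(bundle: dict) -> str:
    lines = ["pipeline summary", "================"]
    lines.append(f"stages completed: {', '.join(bundle.get('stages_completed', []))}")
    if "counts_rule" in bundle:
        lines.append(f"rule-based counts: {bundle['counts_rule']}")
    if "predictions" in bundle and len(bundle["predictions"]):
        vc = bundle["predictions"]["status"].value_counts().to_dict()
        lines.append(f"model-predicted counts: {vc}")
    if "counts_combined" in bundle:
        lines.append(f"combined counts: {bundle['counts_combined']}")
    if "cv_full" in bundle:
        lines.append(
            f"full model CV accuracy: {bundle['cv_full'].mean_accuracy:.3f} "
            f"(SD {bundle['cv_full'].sd_accuracy:.3f})"
        )
    if "selected_features" in bundle:
        lines.append(f"L1-selected features: {bundle['selected_features']}")
    if "cv_refined" in bundle:
        lines.append(
            f"refined model CV accuracy: {bundle['cv_refined'].mean_accuracy:.3f} "
            f"(SD {bundle['cv_refined'].sd_accuracy:.3f})"
        )
    if "fold_changes" in bundle:
        for analyte, fc in bundle["fold_changes"].items():
            for tp, d in fc.items():
                lines.append(
                    f"{analyte} {tp} vs BSL: fold change {d['fold_change']:.2f} "
                    f"(n={d['n_pairs']})"
                )
    return "\n".join(lines) + "\n"
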