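#!/usr/bin/env python
"""Imputation, responder-prediction model, and non-completer prediction.

Builds the participant x (timepoint : feature) matrix of the model
features (BAS, MFI domains + aggregate, SF-36 RP/VT/SF/PCS), reports
missingness, fills it by chained equations (with a kNN comparison),
computes completed differentials, then:

  * fits the full-feature L2 multinomial model with repeated stratified
    3x5 cross-validation and Wald coefficient/odds-ratio summaries,
  * selects features by L1 and refits the refined model,
  * predicts the responder status of participants without rule labels,
  * writes the combined rule + predicted class counts.

Artifacts land under results/ (missingness.json, imputer_comparison.csv,
coefficients_*.csv, cv_*.json, predictions.csv, counts_combined.json).
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from remap.imputation import compare_imputation_methods, impute_chained, missingness_table
from remap.pipeline import PipelineConfig, derive_seed, _differential_table, _model_matrix
from remap.responder_model import (
    ModelConfig,
    cross_validate_repeated,
    fit_multinomial,
    predict_statuses,
    select_features_l1,
    summarize_coefficients,
)
from remap.imputation import FeatureTable

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    scored_path = args.out / "scored.csv"
    labels_path = args.out / "labels_rule.csv"
    if not scored_path.exists() or not labels_path.exists():
        raise SystemExit("run steps 02 and 03 first")

    scored = pd.read_csv(scored_path)
    labels = pd.read_csv(labels_path).set_index("participant_id")["status"]

    matrix = _model_matrix(scored)
    cfg = PipelineConfig(seed=args.seed)
    have = [
        pid for pid in matrix.data.index
        if all(
            matrix.data.loc[pid].filter(like=f"{tp}:").notna().any()
            for tp in cfg.min_timepoints_for_model
        )
    ]
    matrix = FeatureTable(matrix.data.loc[have], dict(matrix.bounds))
    miss = missingness_table(matrix)
    print(f"model matrix: {matrix.data.shape[0]} participants x "
          f"{matrix.data.shape[1]} cells, "
          f"{miss.total_missing_fraction:.1%} missing")
    with open(args.out / "missingness.json", "w") as fh:
        json.dump(miss.to_dict(), fh, indent=2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comparison = compare_imputation_methods(
            matrix, seed=derive_seed(args.seed, "impute-compare")
        )
        comparison.to_csv(args.out / "imputer_comparison.csv", index=False)
        worst = comparison["max_abs_mean_diff"].max()
        print(f"chained vs kNN imputation: max per-feature completed-mean "
              f"difference {worst:.3f}; chained equations used downstream")
        completed, _ = impute_chained(
            matrix, seed=derive_seed(args.seed, "impute")
        )
    diffs = _differential_table(completed)

    train_ids = [p for p in diffs.data.index if p in labels.index]
    predict_ids = [p for p in diffs.data.index if p not in labels.index]
    train = FeatureTable(diffs.data.loc[train_ids])
    y = labels.loc[train_ids].tolist()
    mcfg = ModelConfig(seed=derive_seed(args.seed, "model"))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = fit_multinomial(train, y, mcfg, expected_classes=sorted(set(y)))
        summarize_coefficients(
            full, train, y, seed=derive_seed(args.seed, "wald-full")
        ).to_csv(args.out / "coefficients_full.csv", index=False)
        cv_full = cross_validate_repeated(train, y, mcfg)
        selected = select_features_l1(train, y, ModelConfig(
            seed=mcfg.seed, C=cfg.l1_C))
        refined_table = FeatureTable(train.data[selected])
        refined = fit_multinomial(refined_table, y, mcfg,
                                  expected_classes=sorted(set(y)))
        summarize_coefficients(
            refined, refined_table, y, seed=derive_seed(args.seed, "wald-ref")
        ).to_csv(args.out / "coefficients_refined.csv", index=False)
        cv_ref = cross_validate_repeated(refined_table, y, mcfg)

    print(f"full model CV accuracy:    {cv_full.mean_accuracy:.3f} "
          f"(SD {cv_full.sd_accuracy:.3f})")
    print(f"L1-selected features:      {selected}")
    print(f"refined model CV accuracy: {cv_ref.mean_accuracy:.3f} "
          f"(SD {cv_ref.sd_accuracy:.3f})")
    for key, cv in (("cv_full", cv_full), ("cv_refined", cv_ref)):
        with open(args.out / f"{key}.json", "w") as fh:
            json.dump(cv.to_dict(), fh, indent=2)

    if predict_ids:
        pred_table = FeatureTable(diffs.data.loc[predict_ids, selected])
        pred, proba = predict_statuses(refined, pred_table)
        pd.DataFrame({"participant_id": predict_ids, "status": pred}).to_csv(
            args.out / "predictions.csv", index=False
        )
        counts_pred = pd.Series(pred).value_counts().to_dict()
        print(f"predicted {len(pred)} non-completers: {counts_pred}")
    else:
        counts_pred = {}
        print("no non-completers to predict")

    combined = labels.value_counts().to_dict()
    for k, v in counts_pred.items():
        combined[k] = combined.get(k, 0) + v
    with open(args.out / "counts_combined.json", "w") as fh:
        json.dump(combined, fh, indent=2)
    print(f"combined class counts (rule + predicted): {combined}")


if __name__ == "__main__":
    main()
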