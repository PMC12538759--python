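#!/usr/bin/env python
"""Longitudinal time effects for every questionnaire and biomarker outcome.

For each outcome (BAS, four SSS symptoms, five MFI domains + aggregate,
eight SF-36 subscales + PCS/MCS, and the two log2 biomarkers): a
random-intercept REML time effect with Geisser-Greenhouse-corrected
degrees of freedom, Dunnett-adjusted comparisons of each timepoint vs
baseline, and a per-family BKY two-stage FDR pass. Also writes biomarker
fold changes and residual QQ tables.

Artifacts: results/time_effects.csv, results/pairwise.csv,
results/fold_changes.json, results/qq/*.csv.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from remap import io as rio
from remap.longitudinal import BiomarkerSeries, log2_series
from remap.pipeline import (
    OUTCOME_FAMILIES,
    _build_outcomes,
    _within_subject_residuals,
    derive_seed,
)
from remap.longitudinal import (
    annotate_family_fdr,
    dunnett_baseline_comparisons,
    fit_time_effect,
    residual_qq,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    scored_path = args.out / "scored.csv"
    bio_path = args.out / "cohort" / "biomarkers.csv"
    if not scored_path.exists():
        raise SystemExit("run step 02 first")

    scored = pd.read_csv(scored_path)
    biomarkers = {}
    if bio_path.exists():
        biomarkers, _ = rio.read_biomarkers_csv(bio_path)

    outcomes = _build_outcomes(scored, biomarkers)
    time_rows, pair_rows = [], []
    (args.out / "qq").mkdir(parents=True, exist_ok=True)
    seed = derive_seed(args.seed, "dunnett")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for family, members in OUTCOME_FAMILIES.items():
            effects, pairwise = [], []
            for name in members:
                if name not in outcomes:
                    continue
                out = outcomes[name]
                try:
                    te = fit_time_effect(out)
                except ValueError:
                    continue
                effects.append(te)
                pairwise.extend(dunnett_baseline_comparisons(out, seed=seed))
                resid = _within_subject_residuals(out)
                if len(resid) >= 3:
                    residual_qq(resid).to_csv(
                        args.out / "qq" / f"{name}.csv", index=False
                    )
            annotate_family_fdr(effects, pairwise)
            time_rows += [t.to_dict() for t in effects]
            pair_rows += [p.to_dict() for p in pairwise]
            sig = [t["outcome"] for t in time_rows[-len(effects):]
                   if t["q"] is not None and t["q"] < 0.05]
            print(f"{family}: {len(effects)} outcomes, "
                  f"significant time effect (q<0.05) for {sig or 'none'}")

    pd.DataFrame(time_rows).to_csv(args.out / "time_effects.csv", index=False)
    pd.DataFrame(pair_rows).to_csv(args.out / "pairwise.csv", index=False)

    fold = {}
    for analyte, wide in biomarkers.items():
        fc = log2_series(BiomarkerSeries(analyte, wide))["fold_changes"]
        fold[analyte] = fc
        for tp, d in fc.items():
            print(f"{analyte} {tp} vs BSL: fold change "
                  f"{d['fold_change']:.2f} (n={d['n_pairs']})")
    with open(args.out / "fold_changes.json", "w") as fh:
        json.dump(fold, fh, indent=2)


if __name__ == "__main__":
    main()
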