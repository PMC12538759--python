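#!/usr/bin/env python
"""Association of biomarker log2 changes with clinical differentials.

For each (questionnaire feature, analyte) pair, computes the Spearman
correlation and companion OLS regression of the baseline-to-T3
differentials: does a larger rise in BECLIN-1 (or fall in pSer258-ATG13)
track larger clinical improvement?

Artifact: results/correlations.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from remap import io as rio
from remap.pipeline import _correlations

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    diff_path = args.out / "differentials.csv"
    bio_path = args.out / "cohort" / "biomarkers.csv"
    if not diff_path.exists() or not bio_path.exists():
        raise SystemExit("run steps 01-03 first")

    diffs = pd.read_csv(diff_path, index_col="participant_id")
    biomarkers, _ = rio.read_biomarkers_csv(bio_path)
    corr = _correlations(diffs, biomarkers)
    corr.to_csv(args.out / "correlations.csv", index=False)

    sig = corr.dropna(subset=["rs", "p"])
    sig = sig[sig["p"] < 0.05].sort_values("p")
    print(f"{len(corr)} feature-analyte pairs tested; "
          f"{len(sig)} with p < 0.05:")
    for _, row in sig.head(12).iterrows():
        print(f"  {row['analyte']:22s} vs {row['clinical_feature']:24s} "
              f"rs={row['rs']:+.2f} p={row['p']:.3g} n={row['n']}")


if __name__ == "__main__":
    main()
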