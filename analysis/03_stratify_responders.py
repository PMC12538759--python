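#!/usr/bin/env python
"""Rule-based responder stratification of the scored cohort.

Computes baseline-to-T3 differentials and applies the MCID decision rules
(SF-36 two-of-four criteria, MFI domain/aggregate rules, BAS +10) to every
participant with evaluable endpoint data. Writes:

    results/labels_rule.csv          per-participant instrument ratings +
                                     overall status
    results/counts_rule.json         class counts
    results/differentials.csv        observed differential vectors

Participants without any evaluable instrument (no T3 data) are listed for
model-based prediction in step 04.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from remap.stratification import stratify_cohort

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--scored", type=Path, default=ROOT / "results" / "scored.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    if not args.scored.exists():
        raise SystemExit(f"{args.scored} not found - run 02_score_questionnaires.py")

    scored = pd.read_csv(args.scored)
    out = stratify_cohort(scored)
    args.out.mkdir(parents=True, exist_ok=True)
    out["labels"].to_csv(args.out / "labels_rule.csv", index=False)
    out["differentials"].to_csv(args.out / "differentials.csv")
    with open(args.out / "counts_rule.json", "w") as fh:
        json.dump(out["counts"], fh, indent=2)

    print(f"rule-stratified {len(out['labels'])} participants: {out['counts']}")
    print(f"{len(out['needs_prediction'])} participants lack evaluable T3 data "
          "and await model prediction (step 04)")


if __name__ == "__main__":
    main()
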