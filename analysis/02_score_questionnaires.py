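#!/usr/bin/env python
"""Score the raw questionnaire items into scale scores.

Reads results/cohort/items.csv, applies the published scoring rules
(SF-36 RAND v1 recode-and-average with norm-based PCS/MCS, MFI-20
reverse-and-sum, BAS/SSS validation), and writes:

    results/scored.csv       long scored table (participant, timepoint,
                             feature, value)
    results/validation.csv   every rejected or unscorable row, with reason

Run after 01_simulate_cohort.py (or point --items at your own file).
"""

import argparse
from pathlib import Path

from remap import io as rio

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--items", type=Path,
                    default=ROOT / "results" / "cohort" / "items.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    if not args.items.exists():
        raise SystemExit(f"{args.items} not found - run 01_simulate_cohort.py first")

    items, report = rio.read_items_csv(args.items)
    scored, report = rio.score_items(items, report)
    args.out.mkdir(parents=True, exist_ok=True)
    scored.to_csv(args.out / "scored.csv", index=False)
    if len(report):
        report.to_frame().to_csv(args.out / "validation.csv", index=False)

    n_forms = len(items)
    print(f"scored {n_forms} forms into {len(scored)} feature values")
    print(f"validation findings: {len(report)} "
          f"({'see validation.csv' if len(report) else 'none'})")
    for feat in ("BAS", "MFI_aggregate", "SF36_PCS"):
        sub = scored[scored["feature"] == feat]
        by_tp = sub.groupby("timepoint")["value"].mean().round(1).to_dict()
        print(f"  mean {feat} by timepoint: {by_tp}")


if __name__ == "__main__":
    main()
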