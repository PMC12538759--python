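"""Readers, writers, and validation for the long-format cohort tables.

Three delimited-text layouts are understood:

* **item-level** — ``participant_id, timepoint, instrument, item_id,
  response``: raw questionnaire answers, scored via ``remap.instruments``;
* **scale-level** — ``participant_id, timepoint, feature, value``:
  precomputed scale scores under the canonical feature names (``BAS``,
  ``MFI_<domain>``, ``MFI_aggregate``, ``SF36_<subscale>``, ``SF36_PCS``,
  ``SF36_MCS``, ``SSS_<symptom>``);
* **biomarker** — ``participant_id, timepoint, analyte, concentration``
  (pg/mL).

Validation never silently drops data: every rejected or repaired row is
enumerated in the returned report with its reason. Only an unreadable file
is a hard failure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import instruments as instr
from .instruments import Instrument, ItemResponseSet, Timepoint

#: accepted spellings of the four timepoints
TIMEPOINT_ALIASES = {
    "BSL": "BSL", "BASELINE": "BSL", "BL": "BSL", "DAY0": "BSL",
    "T1": "T1", "DAY36": "T1",
    "T2": "T2", "DAY60": "T2",
    "T3": "T3", "DAY90": "T3",
}


@dataclass
class ValidationReport:
    entries: list[dict] = field(default_factory=list)

    def add(self, source: str, reason: str, **context) -> None:
        self.entries.append({"source": source, "reason": reason, **context})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _canon_timepoint(label, report: ValidationReport, source: str) -> str | None:
    key = str(label).strip().upper().replace(" ", "")
    tp = TIMEPOINT_ALIASES.get(key)
    if tp is None:
        report.add(source, f"unknown timepoint label {label!r}", label=str(label))
    return tp


def read_items_csv(path: str | Path, report: ValidationReport | None = None
                   ) -> tuple[list[ItemResponseSet], ValidationReport]:
    """Read an item-level CSV into per-(participant, timepoint, instrument)
    response sets, collecting every rejected row in the validation report."""
    report = report if report is not None else ValidationReport()
    source = str(path)
    df = pd.read_csv(path, dtype=str)
    required = ["participant_id", "timepoint", "instrument", "item_id", "response"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing column(s) {missing}")
    groups: dict[tuple[str, str, str], dict[str, int]] = {}
    for idx, row in df.iterrows():
        tp = _canon_timepoint(row["timepoint"], report, source)
        if tp is None:
            continue
        try:
            instrument = Instrument(str(row["instrument"]).strip().upper())
        except ValueError:
            report.add(source, f"unknown instrument {row['instrument']!r}", row=int(idx))
            continue
        try:
            response = int(float(row["response"]))
        except (TypeError, ValueError):
            report.add(source, f"non-numeric response {row['response']!r}", row=int(idx))
            continue
        key = (str(row["participant_id"]), tp, instrument.value)
        bucket = groups.setdefault(key, {})
        item_id = str(row["item_id"]).strip()
        if item_id in bucket:
            report.add(
                source,
                f"duplicate (participant, timepoint, item): {key + (item_id,)}; "
                "second occurrence dropped",
                row=int(idx),
            )
            continue
        bucket[item_id] = response
    items = [
        ItemResponseSet(pid, Timepoint(tp), Instrument(ins), responses)
        for (pid, tp, ins), responses in groups.items()
    ]
    return items, report


def read_scores_csv(path: str | Path, report: ValidationReport | None = None
                    ) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a scale-level CSV into the canonical long scored table."""
    report = report if report is not None else ValidationReport()
    source = str(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "feature": str})
    required = ["participant_id", "timepoint", "feature", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing column(s) {missing}")
    rows = []
    seen = set()
    for idx, row in df.iterrows():
        tp = _canon_timepoint(row["timepoint"], report, source)
        if tp is None:
            continue
        value = pd.to_numeric(row["value"], errors="coerce")
        if pd.isna(value):
            report.add(source, f"non-numeric value {row['value']!r}", row=int(idx))
            continue
        key = (row["participant_id"], tp, row["feature"])
        if key in seen:
            report.add(
                source, f"duplicate (participant, timepoint, feature): {key}; "
                "second occurrence dropped", row=int(idx),
            )
            continue
        seen.add(key)
        rows.append(
            {
                "participant_id": row["participant_id"], "timepoint": tp,
                "feature": row["feature"], "value": float(value),
            }
        )
    return (
        pd.DataFrame(rows, columns=["participant_id", "timepoint", "feature", "value"]),
        report,
    )


def read_biomarkers_csv(path: str | Path, report: ValidationReport | None = None
                        ) -> tuple[dict[str, pd.DataFrame], ValidationReport]:
    """Read a biomarker CSV into per-analyte wide (participant x timepoint)
    concentration tables."""
    report = report if report is not None else ValidationReport()
    source = str(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "analyte": str})
    required = ["participant_id", "timepoint", "analyte", "concentration"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing column(s) {missing}")
    rows = []
    seen = set()
    for idx, row in df.iterrows():
        tp = _canon_timepoint(row["timepoint"], report, source)
        if tp is None:
            continue
        value = pd.to_numeric(row["concentration"], errors="coerce")
        if pd.isna(value):
            report.add(source, f"non-numeric concentration {row['concentration']!r}",
                       row=int(idx))
            continue
        key = (row["participant_id"], tp, row["analyte"])
        if key in seen:
            report.add(source, f"duplicate biomarker row {key}; second dropped",
                       row=int(idx))
            continue
        seen.add(key)
        rows.append(
            {"participant_id": row["participant_id"], "timepoint": tp,
             "analyte": row["analyte"], "concentration": float(value)}
        )
    long = pd.DataFrame(rows)
    out: dict[str, pd.DataFrame] = {}
    if len(long):
        for analyte, sub in long.groupby("analyte"):
            out[analyte] = sub.pivot_table(
                index="participant_id", columns="timepoint",
                values="concentration", aggfunc="first",
            )
    return out, report


def score_items(
    items: list[ItemResponseSet], report: ValidationReport | None = None
) -> tuple[pd.DataFrame, ValidationReport]:
    """Score item-level response sets into the canonical long scored table.

    Unscorable forms (e.g. partial MFI-20) are recorded in the validation
    report and contribute no rows; SF-36 subscales killed by the half-scale
    rule are simply absent.
    """
    report = report if report is not None else ValidationReport()
    rows = []

    def emit(pid, tp, feature, value):
        if value is not None:
            rows.append(
                {"participant_id": pid, "timepoint": tp, "feature": feature,
                 "value": float(value)}
            )

    for irs in items:
        pid, tp = irs.participant_id, irs.timepoint.value
        where = f"{pid}/{tp}/{irs.instrument.value}"
        try:
            if irs.instrument is Instrument.BAS:
                emit(pid, tp, "BAS", instr.validate_bas(irs).value)
            elif irs.instrument is Instrument.MFI20:
                profile = instr.score_mfi(irs)
                for domain, score in profile.domains.items():
                    emit(pid, tp, f"MFI_{domain}", score)
                emit(pid, tp, "MFI_aggregate", profile.aggregate)
            elif irs.instrument is Instrument.SF36:
                profile = instr.score_sf36(irs)
                for sub, score in profile.subscales.items():
                    emit(pid, tp, f"SF36_{sub}", score)
                emit(pid, tp, "SF36_PCS", profile.pcs)
                emit(pid, tp, "SF36_MCS", profile.mcs)
            elif irs.instrument is Instrument.SSS:
                profile = instr.score_sss(irs)
                for symptom, sev in profile.severities.items():
                    emit(pid, tp, f"SSS_{symptom}", sev)
                if profile.missing_required:
                    report.add(where,
                               f"missing required SSS symptom(s): "
                               f"{profile.missing_required}")
        except (instr.ScoringError, instr.SchemaError) as err:
            report.add(where, str(err))
    return (
        pd.DataFrame(rows, columns=["participant_id", "timepoint", "feature", "value"]),
        report,
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
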