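"""MCID-based responder stratification from baseline-to-T3 differentials.

Participants are stratified by comparing each instrument's change from
baseline (BSL) to the 90-day endpoint (T3) against minimal clinically
important differences (MCIDs):

* **SF-36**: criteria ``dVT >= +3``, ``dSF >= +3``, ``dRP >= +3``,
  ``dPCS >= +2``; two or more met -> responder, exactly one -> partial
  responder, none -> non-responder.
* **MFI**: responder if three or more of the five fatigue domains improved
  by at least 2 points (``d <= -2``), or exactly two domains did and the
  aggregate improved by at least 10 (``d <= -10``); partial responder if
  exactly two domains improved by >= 2, or one domain did and the aggregate
  change lies strictly in (-10, 0); otherwise non-responder.
* **BAS**: ``d >= +10`` -> responder, ``d <= 0`` -> non-responder. The BAS
  moves on a decade grid, so no partial-responder stratum exists; a
  non-grid differential in (0, 10) (possible only for pre-scored input) is
  classified non-responder with a warning.
* **Overall**: responder if >= 2 instrument ratings are "responder"; else
  partial responder if any rating is better than "non-responder"; else
  non-responder. An instrument whose endpoints are missing is
  ``not_evaluable`` and contributes nothing.

All differentials are T3 - BSL on the instrument's native scale; the
improvement direction is instrument-specific (positive for BAS and SF-36,
negative for MFI and SSS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .instruments import MFI_DOMAINS


class InstrumentRating(str, Enum):
    responder = "responder"
    partial_responder = "partial_responder"
    non_responder = "non_responder"
    not_evaluable = "not_evaluable"


class Status(str, Enum):
    responder = "responder"
    partial_responder = "partial_responder"
    non_responder = "non_responder"


class Provenance(str, Enum):
    rule_based = "rule_based"
    model_predicted = "model_predicted"


#: canonical feature names for differential vectors and the model table
MFI_FEATURES = tuple(f"MFI_{d}" for d in MFI_DOMAINS) + ("MFI_aggregate",)
SF36_RULE_FEATURES = ("SF36_VT", "SF36_SF", "SF36_RP", "SF36_PCS")
MODEL_FEATURES = ("BAS",) + MFI_FEATURES + SF36_RULE_FEATURES


@dataclass(frozen=True)
class OverallStatus:
    status: Status
    provenance: Provenance = Provenance.rule_based


@dataclass(frozen=True)
class DifferentialVector:
    """Signed per-feature change (T3 value - BSL value).

    ``values`` maps canonical feature names to the differential; a feature
    with a missing endpoint is absent (or ``None``).
    """

    values: Mapping[str, float | None]

    def get(self, feature: str) -> float | None:
        return self.values.get(feature)

    def has(self, *features: str) -> bool:
        return all(self.values.get(f) is not None for f in features)


@dataclass(frozen=True)
class Thresholds:
    """MCID thresholds; defaults are the trial's values."""

    sf36_subscale: float = 3.0  # dVT/dSF/dRP >= +3
    sf36_pcs: float = 2.0  # dPCS >= +2
    mfi_domain: float = -2.0  # domain d <= -2
    mfi_aggregate: float = -10.0  # aggregate d <= -10
    bas_responder: float = 10.0  # dBAS >= +10


DEFAULT_THRESHOLDS = Thresholds()


def compute_differentials(
    baseline: Mapping[str, float | None], t3: Mapping[str, float | None]
) -> DifferentialVector:
    """T3 - BSL per feature; a differential exists only if both ends do."""
    values: dict[str, float | None] = {}
    for feature in set(baseline) | set(t3):
        b, t = baseline.get(feature), t3.get(feature)
        values[feature] = None if b is None or t is None else float(t) - float(b)
    return DifferentialVector(values=values)


def rate_sf36(
    diff: DifferentialVector, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> InstrumentRating:
    if not diff.has(*SF36_RULE_FEATURES):
        return InstrumentRating.not_evaluable
    met = sum(
        [
            diff.get("SF36_VT") >= thresholds.sf36_subscale,
            diff.get("SF36_SF") >= thresholds.sf36_subscale,
            diff.get("SF36_RP") >= thresholds.sf36_subscale,
            diff.get("SF36_PCS") >= thresholds.sf36_pcs,
        ]
    )
    if met >= 2:
        return InstrumentRating.responder
    if met == 1:
        return InstrumentRating.partial_responder
    return InstrumentRating.non_responder


def rate_mfi(
    diff: DifferentialVector, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> InstrumentRating:
    if not diff.has(*MFI_FEATURES):
        return InstrumentRating.not_evaluable
    n_domains = sum(
        diff.get(f"MFI_{d}") <= thresholds.mfi_domain for d in MFI_DOMAINS
    )
    agg = diff.get("MFI_aggregate")
    if n_domains >= 3 or (n_domains == 2 and agg <= thresholds.mfi_aggregate):
        return InstrumentRating.responder
    if n_domains == 2 or (n_domains == 1 and thresholds.mfi_aggregate < agg < 0):
        return InstrumentRating.partial_responder
    return InstrumentRating.non_responder


def rate_bas(
    diff: DifferentialVector, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> InstrumentRating:
    if not diff.has("BAS"):
        return InstrumentRating.not_evaluable
    d = diff.get("BAS")
    if d >= thresholds.bas_responder:
        return InstrumentRating.responder
    if 0 < d < thresholds.bas_responder:
        # unreachable on the decade grid; possible for pre-scored input
        warnings.warn(
            f"BAS differential {d} lies in the unreachable (0, "
            f"{thresholds.bas_responder}) gap; classified non_responder",
            stacklevel=2,
        )
    return InstrumentRating.non_responder


def combine_ratings(
    sf36: InstrumentRating, mfi: InstrumentRating, bas: InstrumentRating
) -> OverallStatus:
    """Overall status from the three instrument ratings.

    ``not_evaluable`` ratings count toward nothing; at least one rating must
    be evaluable. A single "responder" rating (with no second one) counts as
    overall partial responder, preserving the responder > partial > non
    ordering.
    """
    ratings = [r for r in (sf36, mfi, bas) if r is not InstrumentRating.not_evaluable]
    if not ratings:
        raise ValueError(
            "all instrument ratings are not_evaluable; "
            "route this participant to model prediction"
        )
    n_resp = sum(r is InstrumentRating.responder for r in ratings)
    if n_resp >= 2:
        return OverallStatus(Status.responder)
    if n_resp == 1 or any(r is InstrumentRating.partial_responder for r in ratings):
        return OverallStatus(Status.partial_responder)
    return OverallStatus(Status.non_responder)


def classify_differentials(
    diff: DifferentialVector, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[OverallStatus, dict[str, InstrumentRating]]:
    """Apply all three instrument rules and combine."""
    ratings = {
        "SF36": rate_sf36(diff, thresholds),
        "MFI": rate_mfi(diff, thresholds),
        "BAS": rate_bas(diff, thresholds),
    }
    return combine_ratings(ratings["SF36"], ratings["MFI"], ratings["BAS"]), ratings


def stratify_cohort(
    scores: pd.DataFrame, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> dict:
    """Rule-based stratification of a scored cohort.

    Parameters
    ----------
    scores
        Long-format table with columns ``participant_id``, ``timepoint``,
        ``feature``, ``value`` holding scored endpoints (at least BSL and T3
        rows for the rule features).

    Returns
    -------
    dict with:
      ``labels`` — DataFrame (participant_id, SF36/MFI/BAS rating, status,
      provenance) for participants with evaluable T3 data;
      ``counts`` — dict status -> count;
      ``needs_prediction`` — participant ids without any evaluable rating
      (e.g. no T3 data), to be routed to the model;
      ``differentials`` — DataFrame of the per-participant differentials.
    """
    required = {"participant_id", "timepoint", "feature", "value"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores table must have columns {sorted(required)}")
    wide = scores.pivot_table(
        index="participant_id", columns=["timepoint", "feature"], values="value",
        aggfunc="first",
    )
    rows, diff_rows, needs_prediction = [], [], []
    for pid in wide.index:
        bsl = wide.loc[pid].get("BSL", pd.Series(dtype=float))
        t3 = wide.loc[pid].get("T3", pd.Series(dtype=float))
        diff = compute_differentials(
            {k: (None if pd.isna(v) else v) for k, v in bsl.items()},
            {k: (None if pd.isna(v) else v) for k, v in t3.items()},
        )
        diff_rows.append({"participant_id": pid, **dict(diff.values)})
        try:
            overall, ratings = classify_differentials(diff, thresholds)
        except ValueError:
            needs_prediction.append(pid)
            continue
        rows.append(
            {
                "participant_id": pid,
                "SF36": ratings["SF36"].value,
                "MFI": ratings["MFI"].value,
                "BAS": ratings["BAS"].value,
                "status": overall.status.value,
                "provenance": overall.provenance.value,
            }
        )
    labels = pd.DataFrame(
        rows,
        columns=["participant_id", "SF36", "MFI", "BAS", "status", "provenance"],
    )
    counts = {s.value: int((labels["status"] == s.value).sum()) for s in Status}
    return {
        "labels": labels,
        "counts": counts,
        "needs_prediction": needs_prediction,
        "differentials": pd.DataFrame(diff_rows).set_index("participant_id")
        if diff_rows
        else pd.DataFrame(),
    }
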