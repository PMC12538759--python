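"""Scoring of the trial's four patient-reported outcome instruments.

The primary endpoints of the cohort are four self-report instruments:

* **SF-36 (RAND 36-Item Health Survey 1.0)** — 36 items recoded to a 0-100
  scale and averaged into eight subscales (PF, RP, BP, GH, VT, SF, RE, MH;
  higher = better health), plus the norm-based Physical and Mental Component
  Summary scores (PCS/MCS) scaled to the US general population
  (mean 50, SD 10).
* **MFI-20 (Multidimensional Fatigue Inventory)** — twenty 1-5 items in five
  four-item domains, each scored 4-20 after reverse-keying the positively
  phrased items (higher = worse fatigue); the aggregate is the sum of the
  five domains (20-100).
* **BAS (Bell Activity Scale)** — a single functional-ability rating from 0
  ("severe symptoms on a continuous basis") to 100 (asymptomatic) in steps
  of ten.
* **SSS (Specific Symptom Severity inventory)** — 0-10 severity per symptom,
  covering at least the four hallmark ME/CFS symptoms: fatigue, disturbed
  sleep, post-exertional malaise (PEM), and orthostatic intolerance (OI).

The recode tables, the MFI reverse key, and the 1990 US-population norms and
factor-score coefficients ship as versioned JSON data files rather than code
constants so they can be audited and swapped.

All scorers are pure functions of their inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Mapping


class Timepoint(str, Enum):
    BSL = "BSL"
    T1 = "T1"
    T2 = "T2"
    T3 = "T3"


TIMEPOINT_ORDER = [Timepoint.BSL, Timepoint.T1, Timepoint.T2, Timepoint.T3]


class Instrument(str, Enum):
    SF36 = "SF36"
    MFI20 = "MFI20"
    BAS = "BAS"
    SSS = "SSS"


class SchemaError(ValueError):
    """Input violates the instrument's item schema (unknown item id etc.)."""


class ScoringError(ValueError):
    """Item responses cannot be scored (missing or out-of-range items)."""


SSS_REQUIRED = ("fatigue", "disturbed_sleep", "PEM", "OI")
SF36_SUBSCALES = ("PF", "RP", "BP", "GH", "VT", "SF", "RE", "MH")
MFI_DOMAINS = (
    "general_fatigue",
    "physical_fatigue",
    "reduced_activity",
    "reduced_motivation",
    "mental_fatigue",
)


@lru_cache(maxsize=None)
def load_constants(name: str) -> dict:
    """Load a bundled instrument constants file (e.g. ``sf36_rand_v1``)."""
    path = resources.files("remap.data").joinpath(f"{name}.json")
    with path.open("r", encoding="utf-8") as fh:
        return json.load(fh)


@dataclass(frozen=True)
class ItemResponseSet:
    """Raw item responses of one participant at one timepoint.

    ``responses`` maps item id (string) to the raw integer response; a
    missing item is simply absent from the map (or mapped to ``None``).
    """

    participant_id: str
    timepoint: Timepoint
    instrument: Instrument
    responses: Mapping[str, int | None]

    def present(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.responses.items() if v is not None}

    def missing_items(self, expected: set[str]) -> set[str]:
        return expected - set(self.present())


@dataclass(frozen=True)
class MFIProfile:
    """Five MFI-20 domain scores (4-20 each) plus their sum (20-100)."""

    domains: Mapping[str, int]

    @property
    def aggregate(self) -> int:
        return sum(self.domains.values())


@dataclass(frozen=True)
class SF36Profile:
    """Eight SF-36 subscales (0-100; ``None`` = undefined) and PCS/MCS."""

    subscales: Mapping[str, float | None]
    pcs: float | None = None
    mcs: float | None = None

    def defined(self) -> bool:
        return all(self.subscales.get(s) is not None for s in SF36_SUBSCALES)


@dataclass(frozen=True)
class SSSProfile:
    """Symptom severity map, 0-10 per symptom, higher = more severe."""

    severities: Mapping[str, int]
    missing_required: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class BASLevel:
    """Bell Activity Scale value: 0-100 on the decade grid."""

    value: int


# ---------------------------------------------------------------------------
# MFI-20


def score_mfi(items: ItemResponseSet) -> MFIProfile:
    """Score an MFI-20 form into five domain scores and their aggregate.

    Positively phrased items are reverse-keyed (``6 - response``) so that
    every item contributes 1 (no fatigue) to 5 (severe fatigue); each domain
    is the sum of its four items. Partial forms are rejected: the MFI has no
    published half-scale rule and the trial treats partial MFI forms as
    missing.
    """
    if items.instrument is not Instrument.MFI20:
        raise SchemaError(f"expected MFI20 items, got {items.instrument}")
    key = load_constants("mfi20_key")
    reverse = set(key["reverse_keyed"])
    expected = {str(i) for i in range(1, 21)}
    got = items.present()
    unknown = set(got) - expected
    if unknown:
        raise SchemaError(f"unknown MFI-20 item id(s): {sorted(unknown)}")
    missing = sorted(expected - set(got), key=int)
    if missing:
        raise ScoringError(f"missing MFI-20 item(s): {missing}")
    for item, resp in got.items():
        if not 1 <= resp <= 5:
            raise ScoringError(f"MFI-20 item {item} response {resp} outside 1-5")
    domains = {}
    for domain, item_ids in key["domains"].items():
        total = 0
        for i in item_ids:
            resp = got[str(i)]
            total += (6 - resp) if i in reverse else resp
        domains[domain] = total
    return MFIProfile(domains=domains)


# ---------------------------------------------------------------------------
# SF-36


def score_sf36_subscales(items: ItemResponseSet) -> SF36Profile:
    """Score SF-36 v1 items into the eight 0-100 subscales.

    Each item is recoded to 0-100 via the bundled RAND v1 table; a subscale
    is the mean of its non-missing recoded items and is undefined (``None``)
    when more than half of its items are missing (half-scale rule).
    """
    if items.instrument is not Instrument.SF36:
        raise SchemaError(f"expected SF36 items, got {items.instrument}")
    table = load_constants("sf36_rand_v1")
    recode = table["recode"]
    got = items.present()
    unknown = set(got) - set(recode)
    if unknown:
        raise SchemaError(f"unknown SF-36 item id(s): {sorted(unknown)}")
    recoded: dict[str, float] = {}
    for item, resp in got.items():
        try:
            recoded[item] = float(recode[item][str(resp)])
        except KeyError:
            raise ScoringError(
                f"SF-36 item {item} response {resp} outside its legal range"
            ) from None
    subscales: dict[str, float | None] = {}
    for name, item_ids in table["subscales"].items():
        values = [recoded[i] for i in item_ids if i in recoded]
        if len(values) * 2 >= len(item_ids) and values:
            subscales[name] = sum(values) / len(values)
        else:
            subscales[name] = None
    return SF36Profile(subscales=subscales)


def compute_sf36_components(profile: SF36Profile) -> tuple[float | None, float | None]:
    """Norm-based PCS and MCS from the eight subscales.

    Each subscale is z-scored against the bundled 1990 US general-population
    means/SDs, combined with the orthogonal factor-score coefficients, and
    rescaled to the T-score metric (mean 50, SD 10). Undefined if any
    subscale is undefined.
    """
    if not profile.defined():
        return (None, None)
    norms = load_constants("sf36_norms_1990")
    z = {
        s: (profile.subscales[s] - norms["means"][s]) / norms["sds"][s]
        for s in SF36_SUBSCALES
    }
    pcs = 50.0 + 10.0 * sum(z[s] * norms["pcs_coefficients"][s] for s in SF36_SUBSCALES)
    mcs = 50.0 + 10.0 * sum(z[s] * norms["mcs_coefficients"][s] for s in SF36_SUBSCALES)
    return (pcs, mcs)


def score_sf36(items: ItemResponseSet) -> SF36Profile:
    """Subscales plus PCS/MCS (components only when all subscales defined)."""
    profile = score_sf36_subscales(items)
    pcs, mcs = compute_sf36_components(profile)
    return SF36Profile(subscales=profile.subscales, pcs=pcs, mcs=mcs)


# ---------------------------------------------------------------------------
# SSS and BAS


def score_sss(items: ItemResponseSet) -> SSSProfile:
    """Validate SSS severities (0-10 integers); identity mapping otherwise.

    The four hallmark symptoms are required and flagged if absent; extra
    symptoms pass through untouched.
    """
    if items.instrument is not Instrument.SSS:
        raise SchemaError(f"expected SSS items, got {items.instrument}")
    got = items.present()
    for symptom, value in got.items():
        if not 0 <= value <= 10:
            raise ScoringError(f"SSS symptom {symptom!r} severity {value} outside 0-10")
    missing = tuple(s for s in SSS_REQUIRED if s not in got)
    return SSSProfile(severities=got, missing_required=missing)


def validate_bas(items: ItemResponseSet) -> BASLevel:
    """Validate the single Bell Activity Scale value (0-100, step 10)."""
    if items.instrument is not Instrument.BAS:
        raise SchemaError(f"expected BAS items, got {items.instrument}")
    got = items.present()
    if len(got) != 1:
        raise ScoringError(f"BAS expects exactly one value, got {len(got)}")
    value = next(iter(got.values()))
    if not 0 <= value <= 100:
        raise ScoringError(f"BAS value {value} outside 0-100")
    if value % 10 != 0:
        raise ScoringError(f"BAS value {value} is not a multiple of 10")
    return BASLevel(value=value)
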