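"""Trial-shaped synthetic cohort generator.

Emulates the structure of the rapamycin ME/CFS cohort so the scoring,
stratification, imputation, modelling, and longitudinal modules can all be
exercised without any external data:

* four timepoints (BSL, T1, T2, T3) with staged dropout shaped like the
  trial's attrition (86 enrolled -> 70 -> 55 -> 40 completers),
* three latent responder classes with class-specific mean improvements on
  each instrument's native scale (interim timepoints realize a configured
  fraction of the T3 effect),
* item-level questionnaire responses sampled so that scoring them
  reproduces the latent scale targets (exactly for MFI/BAS/SSS, within one
  recoded-item quantum for SF-36),
* plasma biomarker series (BECLIN-1 up, pSer258-ATG13 down on the log2
  scale) coupled to each participant's realized clinical improvement via a
  Gaussian copula,
* item-level MCAR missingness on top of dropout.

Everything is driven by one seed through named substreams, so identical
configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .instruments import (
    MFI_DOMAINS,
    SF36_SUBSCALES,
    SSS_REQUIRED,
    Instrument,
    ItemResponseSet,
    Timepoint,
    load_constants,
)

TIMEPOINTS = ("BSL", "T1", "T2", "T3")
CLASSES = ("non_responder", "partial_responder", "responder")

SF36_FEATURES = tuple(f"SF36_{s}" for s in SF36_SUBSCALES)
MFI_FEATURES = tuple(f"MFI_{d}" for d in MFI_DOMAINS)
SSS_FEATURES = tuple(f"SSS_{s}" for s in SSS_REQUIRED)
ALL_FEATURES = ("BAS",) + MFI_FEATURES + SF36_FEATURES + SSS_FEATURES


def _default_baseline_means() -> dict[str, float]:
    out = {"BAS": 37.0}
    out.update({f: 15.0 for f in MFI_FEATURES})
    out.update(
        {
            "SF36_PF": 40.0, "SF36_RP": 15.0, "SF36_BP": 45.0, "SF36_GH": 30.0,
            "SF36_VT": 25.0, "SF36_SF": 40.0, "SF36_RE": 60.0, "SF36_MH": 62.0,
        }
    )
    out.update({f: 7.0 for f in SSS_FEATURES})
    return out


def _default_baseline_sds() -> dict[str, float]:
    out = {"BAS": 15.0}
    out.update({f: 2.5 for f in MFI_FEATURES})
    out.update({f: 16.0 for f in SF36_FEATURES})
    out.update({f: 1.5 for f in SSS_FEATURES})
    return out


def _default_class_effects() -> dict[str, dict[str, float]]:
    """Mean T3 change per class on each feature's native scale."""
    resp = {"BAS": 15.0}
    resp.update({f: -4.0 for f in MFI_FEATURES})
    resp.update({f: 10.0 for f in SF36_FEATURES})
    resp.update({"SF36_VT": 12.0, "SF36_SF": 12.0, "SF36_RP": 15.0})
    resp.update({f: -4.0 for f in SSS_FEATURES})
    partial = {"BAS": 3.0}
    partial.update({f: -1.2 for f in MFI_FEATURES})
    partial.update({f: 1.5 for f in SF36_FEATURES})
    partial.update({"SF36_VT": 4.0})
    partial.update({f: -2.5 for f in SSS_FEATURES})
    # non-responders drift slightly worse ("no change in symptoms" dropouts)
    non = {"BAS": -5.0}
    non.update({f: 0.8 for f in MFI_FEATURES})
    non.update({f: -4.0 for f in SF36_FEATURES})
    non.update({f: 0.5 for f in SSS_FEATURES})
    return {"responder": resp, "partial_responder": partial, "non_responder": non}


def _default_residual_sds() -> dict[str, float]:
    out = {"BAS": 8.0}
    out.update({f: 1.2 for f in MFI_FEATURES})
    out.update({f: 7.0 for f in SF36_FEATURES})
    out.update({f: 1.2 for f in SSS_FEATURES})
    return out


@dataclass(frozen=True)
class BiomarkerParams:
    """log2-scale parameters of one plasma analyte."""

    baseline_log2_mean: float
    baseline_log2_sd: float
    class_t3_shift: Mapping[str, float]  # mean log2 change at T3 per class
    noise_sd: float = 0.4
    rho: float = 0.5  # copula corr of log2 change with clinical improvement


def _default_biomarkers() -> dict[str, BiomarkerParams]:
    return {
        # BECLIN-1 rises with improving autophagy flux (~1.4-1.5-fold by T2-T3)
        "BECLIN1": BiomarkerParams(
            baseline_log2_mean=7.6, baseline_log2_sd=0.8,
            class_t3_shift={
                "responder": 1.0, "partial_responder": 0.55, "non_responder": 0.1,
            },
            rho=0.5,
        ),
        # mTOR-driven pSer258-ATG13 falls under rapamycin
        "pSer258_ATG13": BiomarkerParams(
            baseline_log2_mean=7.3, baseline_log2_sd=0.9,
            class_t3_shift={
                "responder": -1.8, "partial_responder": -1.2, "non_responder": -0.3,
            },
            rho=-0.5,
        ),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults are the trial-shaped profile.

    Sample size, attrition, and the responder-class mix follow the study's
    structure (86 treated, 70/55/40 reaching T1/T2/T3; final class mix
    about 18/35/17 of 70). Baseline scale locations and class effect sizes
    are chosen to put the cohort where a moderately-to-severely affected
    ME/CFS population sits on each instrument.
    """

    n_enrolled: int = 86
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "non_responder": 18 / 70, "partial_responder": 35 / 70,
            "responder": 17 / 70,
        }
    )
    baseline_means: Mapping[str, float] = field(default_factory=_default_baseline_means)
    baseline_sds: Mapping[str, float] = field(default_factory=_default_baseline_sds)
    class_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_class_effects
    )
    residual_sds: Mapping[str, float] = field(default_factory=_default_residual_sds)
    interim_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"T1": 0.4, "T2": 0.75, "T3": 1.0}
    )
    improvement_cv: float = 0.35  # spread of the shared improvement factor
    biomarkers: Mapping[str, BiomarkerParams] = field(default_factory=_default_biomarkers)
    dropout_hazards: tuple[float, float, float] = (16 / 86, 15 / 70, 15 / 55)
    dropout_class_weights: Mapping[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in CLASSES}
    )
    item_missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if any(sd <= 0 for sd in self.baseline_sds.values()):
            raise ValueError("baseline SDs must be positive")
        if any(not 0 <= h <= 1 for h in self.dropout_hazards):
            raise ValueError("dropout hazards must lie in [0, 1]")
        if not 0 <= self.item_missing_rate < 1:
            raise ValueError("item_missing_rate must lie in [0, 1)")
        for b in self.biomarkers.values():
            if abs(b.rho) > 1:
                raise ValueError("|rho| must be <= 1")
        bounds = _feature_bounds()
        for feat, mean in self.baseline_means.items():
            lo, hi = bounds[feat]
            if not lo <= mean <= hi:
                raise ValueError(f"baseline mean of {feat} off-scale: {mean}")


def well_separated_config(n: int = 1000, seed: int = 0, **overrides) -> CohortConfig:
    """A profile with wide class margins and small noise, so the true class
    is recoverable nearly deterministically from the rule thresholds."""
    resp = {"BAS": 20.0}
    resp.update({f: -5.0 for f in MFI_FEATURES})
    resp.update({f: 12.0 for f in SF36_FEATURES})
    resp.update({"SF36_VT": 15.0, "SF36_SF": 15.0, "SF36_RP": 18.0})
    resp.update({f: -4.0 for f in SSS_FEATURES})
    # partial: one SF-36 criterion and one MFI domain, BAS flat
    partial = {f: 0.0 for f in ALL_FEATURES}
    partial.update({"SF36_VT": 10.0, "MFI_general_fatigue": -4.0,
                    "SSS_fatigue": -1.5})
    non = {f: 0.0 for f in ALL_FEATURES}
    sds = {"BAS": 2.0}
    sds.update({f: 0.3 for f in MFI_FEATURES})
    sds.update({f: 0.8 for f in SF36_FEATURES})
    sds.update({f: 0.3 for f in SSS_FEATURES})
    kwargs = dict(
        n_enrolled=n,
        class_effects={
            "responder": resp, "partial_responder": partial, "non_responder": non,
        },
        residual_sds=sds,
        improvement_cv=0.05,
        dropout_hazards=(0.0, 0.0, 0.0),
        item_missing_rate=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@dataclass
class SyntheticCohort:
    items: list[ItemResponseSet]
    biomarkers: dict[str, pd.DataFrame]  # analyte -> wide pg/mL table
    truth: pd.DataFrame  # participant_id, true_class, dropout_after
    latent_targets: pd.DataFrame  # long: participant, timepoint, feature, target
    config: CohortConfig

    def items_long(self) -> pd.DataFrame:
        rows = []
        for irs in self.items:
            for item_id, resp in irs.responses.items():
                if resp is not None:
                    rows.append(
                        {
                            "participant_id": irs.participant_id,
                            "timepoint": irs.timepoint.value,
                            "instrument": irs.instrument.value,
                            "item_id": item_id,
                            "response": int(resp),
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=["participant_id", "timepoint", "instrument", "item_id",
                     "response"],
        )

    def biomarkers_long(self) -> pd.DataFrame:
        rows = []
        for analyte, wide in self.biomarkers.items():
            for pid in wide.index:
                for tp in wide.columns:
                    v = wide.loc[pid, tp]
                    if pd.notna(v):
                        rows.append(
                            {
                                "participant_id": pid, "timepoint": tp,
                                "analyte": analyte, "concentration": float(v),
                            }
                        )
        return pd.DataFrame(
            rows,
            columns=["participant_id", "timepoint", "analyte", "concentration"],
        )


# ---------------------------------------------------------------------------
# feature grids


def _feature_bounds() -> dict[str, tuple[float, float]]:
    out = {"BAS": (0.0, 100.0)}
    out.update({f: (4.0, 20.0) for f in MFI_FEATURES})
    out.update({f: (0.0, 100.0) for f in SF36_FEATURES})
    out.update({f: (0.0, 10.0) for f in SSS_FEATURES})
    return out


def _snap(feature: str, value: float) -> float:
    lo, hi = _feature_bounds()[feature]
    value = float(np.clip(value, lo, hi))
    if feature == "BAS":
        return float(np.round(value / 10.0) * 10.0)
    if feature.startswith(("MFI_", "SSS_")):
        return float(np.round(value))
    return value  # SF-36 targets stay continuous; items quantize them


# ---------------------------------------------------------------------------
# item synthesis from scale targets


def _compose_sum(rng: np.random.Generator, n_items: int, total: int,
                 per_item_max: int) -> np.ndarray:
    """Random composition: n_items values in [1, per_item_max] summing to
    ``total``; uniform over increments, not over compositions."""
    vals = np.ones(n_items, dtype=int)
    remaining = total - n_items
    while remaining > 0:
        open_idx = np.flatnonzero(vals < per_item_max)
        vals[rng.choice(open_idx)] += 1
        remaining -= 1
    return vals


def items_from_scale_targets(
    instrument: Instrument,
    target,
    seed: int | np.random.Generator = 0,
    participant_id: str = "synthetic",
    timepoint: Timepoint = Timepoint.BSL,
) -> ItemResponseSet:
    """Sample a legal item-response vector scoring to ``target``.

    ``target`` is an int for BAS, a symptom->severity map for SSS, a
    domain->score map (all five domains) for MFI-20, and a subscale->score
    map (all eight subscales) for SF-36. MFI/BAS/SSS round-trips are exact;
    SF-36 subscales land within one recoded-item quantum of the target.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if instrument is Instrument.BAS:
        t = int(target)
        if not (0 <= t <= 100 and t % 10 == 0):
            near = int(np.clip(round(t / 10.0) * 10, 0, 100))
            raise ValueError(f"unattainable BAS target {target}; nearest: {near}")
        return ItemResponseSet(participant_id, timepoint, instrument, {"bas": t})
    if instrument is Instrument.SSS:
        responses = {}
        for symptom, sev in dict(target).items():
            s = int(sev)
            if not 0 <= s <= 10:
                near = int(np.clip(s, 0, 10))
                raise ValueError(
                    f"unattainable SSS target {sev} for {symptom}; nearest: {near}"
                )
            responses[symptom] = s
        return ItemResponseSet(participant_id, timepoint, instrument, responses)
    if instrument is Instrument.MFI20:
        key = load_constants("mfi20_key")
        reverse = set(key["reverse_keyed"])
        responses = {}
        for domain in MFI_DOMAINS:
            t = int(target[domain])
            if not 4 <= t <= 20:
                near = int(np.clip(t, 4, 20))
                raise ValueError(
                    f"unattainable MFI target {target[domain]} for {domain}; "
                    f"nearest: {near}"
                )
            contributions = _compose_sum(rng, 4, t, 5)
            for item, c in zip(key["domains"][domain], contributions):
                responses[str(item)] = int(6 - c) if item in reverse else int(c)
        return ItemResponseSet(participant_id, timepoint, instrument, responses)
    if instrument is Instrument.SF36:
        table = load_constants("sf36_rand_v1")
        responses: dict[str, int] = {}
        for sub in SF36_SUBSCALES:
            t = float(target[sub])
            if not 0.0 <= t <= 100.0:
                raise ValueError(
                    f"unattainable SF-36 target {t} for {sub}; "
                    f"nearest: {float(np.clip(t, 0, 100))}"
                )
            item_ids = list(table["subscales"][sub])
            rng.shuffle(item_ids)
            m = len(item_ids)
            chosen_sum = 0.0
            for j, item in enumerate(item_ids):
                grid = table["recode"][item]
                remaining = m - j
                ideal = (t * m - chosen_sum) / remaining
                raw, best = None, None
                for resp, recoded in grid.items():
                    err = abs(recoded - ideal)
                    if best is None or err < best:
                        raw, best = resp, err
                responses[item] = int(raw)
                chosen_sum += grid[raw]
        # item 2 (health transition) belongs to no subscale
        responses["2"] = int(rng.integers(1, 6))
        return ItemResponseSet(participant_id, timepoint, instrument, responses)
    raise ValueError(f"unknown instrument {instrument}")


# ---------------------------------------------------------------------------
# cohort generation


def _draw_targets(config: CohortConfig, rng: np.random.Generator) -> tuple:
    """Latent scale targets and biomarker log2 values for every
    participant x timepoint, pre-dropout."""
    n = config.n_enrolled
    classes = np.asarray(
        rng.choice(
            list(config.class_proportions),
            size=n,
            p=list(config.class_proportions.values()),
        )
    )
    # shared improvement factor and copula partners
    z_clin = rng.standard_normal(n)
    g = np.maximum(0.0, 1.0 + config.improvement_cv * z_clin)
    target_rows, bio = [], {}
    baselines = {
        f: rng.normal(config.baseline_means[f], config.baseline_sds[f], size=n)
        for f in ALL_FEATURES
    }
    t3_change = {}
    for f in ALL_FEATURES:
        effect = np.array([config.class_effects[c][f] for c in classes])
        noise = rng.normal(0.0, config.residual_sds[f], size=n)
        t3_change[f] = effect * g + noise
    pids = [f"P{i:04d}" for i in range(1, n + 1)]
    for i, pid in enumerate(pids):
        for tp in TIMEPOINTS:
            frac = 0.0 if tp == "BSL" else config.interim_fractions[tp]
            for f in ALL_FEATURES:
                raw = baselines[f][i] + frac * t3_change[f][i]
                target_rows.append(
                    {
                        "participant_id": pid, "timepoint": tp, "feature": f,
                        "target": _snap(f, raw),
                    }
                )
    for analyte, params in config.biomarkers.items():
        z_b = params.rho * z_clin + np.sqrt(1 - params.rho ** 2) * rng.standard_normal(n)
        base = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, size=n)
        shift_mean = np.array([params.class_t3_shift[c] for c in classes])
        shift = shift_mean + params.noise_sd * z_b
        wide = {}
        for tp in TIMEPOINTS:
            frac = 0.0 if tp == "BSL" else config.interim_fractions[tp]
            jitter = rng.normal(0.0, 0.1, size=n)
            wide[tp] = 2.0 ** (base + frac * shift + jitter)
        bio[analyte] = pd.DataFrame(wide, index=pids)
    truth = pd.DataFrame({"participant_id": pids, "true_class": classes})
    return pids, truth, pd.DataFrame(target_rows), bio


def apply_dropout_and_missingness(
    cohort: SyntheticCohort, config: CohortConfig | None = None
) -> SyntheticCohort:
    """Censor participants after a sampled dropout timepoint and apply
    item-level MCAR missingness. Interval hazards may be class-weighted
    (e.g. 'no change in symptoms' dropouts concentrating in
    non-responders)."""
    config = config or cohort.config
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xD0D0]).generate_state(1)[0]
    )
    truth = cohort.truth.set_index("participant_id")
    dropout_after: dict[str, str] = {}
    for pid in truth.index:
        cls = truth.loc[pid, "true_class"]
        w = config.dropout_class_weights.get(cls, 1.0)
        reached = "BSL"
        for tp, hazard in zip(("T1", "T2", "T3"), config.dropout_hazards):
            if rng.random() < min(1.0, hazard * w):
                break
            reached = tp
        dropout_after[pid] = reached
    order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    kept_items = []
    for irs in cohort.items:
        if order[irs.timepoint.value] > order[dropout_after[irs.participant_id]]:
            continue
        if config.item_missing_rate > 0:
            responses = {
                k: (None if rng.random() < config.item_missing_rate else v)
                for k, v in irs.responses.items()
            }
            irs = ItemResponseSet(
                irs.participant_id, irs.timepoint, irs.instrument, responses
            )
        kept_items.append(irs)
    biomarkers = {}
    for analyte, wide in cohort.biomarkers.items():
        wide = wide.copy()
        for pid in wide.index:
            for tp in wide.columns:
                if order[tp] > order[dropout_after[pid]]:
                    wide.loc[pid, tp] = np.nan
        biomarkers[analyte] = wide
    truth_out = cohort.truth.copy()
    truth_out["dropout_after"] = truth_out["participant_id"].map(dropout_after)
    targets = cohort.latent_targets
    keep = targets.apply(
        lambda r: order[r["timepoint"]] <= order[dropout_after[r["participant_id"]]],
        axis=1,
    )
    return SyntheticCohort(
        items=kept_items, biomarkers=biomarkers, truth=truth_out,
        latent_targets=targets[keep].reset_index(drop=True), config=config,
    )


def generate_cohort(config: CohortConfig = CohortConfig()) -> SyntheticCohort:
    """Draw a full synthetic cohort: classes, latent trajectories, items,
    biomarkers, then dropout and missingness. Deterministic given the seed."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xC0FF]).generate_state(1)[0]
    )
    pids, truth, targets, bio = _draw_targets(config, rng)
    item_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x17E5]).generate_state(1)[0]
    )
    tmap = targets.set_index(["participant_id", "timepoint", "feature"])["target"]
    items: list[ItemResponseSet] = []
    for pid in pids:
        for tp in TIMEPOINTS:
            tp_enum = Timepoint(tp)
            get = lambda f: tmap.loc[(pid, tp, f)]
            items.append(
                items_from_scale_targets(
                    Instrument.BAS, get("BAS"), item_rng, pid, tp_enum
                )
            )
            items.append(
                items_from_scale_targets(
                    Instrument.MFI20,
                    {d: get(f"MFI_{d}") for d in MFI_DOMAINS},
                    item_rng, pid, tp_enum,
                )
            )
            items.append(
                items_from_scale_targets(
                    Instrument.SF36,
                    {s: get(f"SF36_{s}") for s in SF36_SUBSCALES},
                    item_rng, pid, tp_enum,
                )
            )
            items.append(
                items_from_scale_targets(
                    Instrument.SSS,
                    {s: get(f"SSS_{s}") for s in SSS_REQUIRED},
                    item_rng, pid, tp_enum,
                )
            )
    full = SyntheticCohort(
        items=items, biomarkers=bio, truth=truth, latent_targets=targets,
        config=config,
    )
    return apply_dropout_and_missingness(full, config)
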