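"""Longitudinal symptom and biomarker statistics.

Each outcome (a questionnaire scale or a log2 biomarker concentration) is
observed per participant at up to four timepoints (BSL, T1, T2, T3). The
analysis mirrors a repeated-measures workflow with missing data:

* **Time effect** — a participant-random-intercept model with a fixed
  timepoint effect, fitted by REML when data are incomplete; on complete
  balanced data the F-test equals classical repeated-measures ANOVA. The
  F-test's degrees of freedom are scaled by the Greenhouse-Geisser epsilon
  to correct for non-sphericity (epsilon estimated from the complete-case
  covariance).
* **Dunnett many-to-one comparisons** — paired mean changes of each later
  timepoint vs baseline, adjusted with the equicorrelated (rho = 1/2)
  multivariate-t many-to-one distribution evaluated by seeded quasi-Monte
  Carlo integration; simultaneous 95% CIs from the same critical point.
* **BKY two-stage FDR** — the adaptive two-stage linear step-up of
  Benjamini, Krieger & Yekutieli at alpha = 0.05, applied per analysis
  family (a figure panel's time effects plus its pairwise comparisons).
* **Biomarkers** — plasma concentrations (pg/mL) are log2-transformed
  (values at or below the detection floor are replaced by floor/2 and
  flagged); fold changes vs baseline are 2**(mean paired log2 difference).
* **Associations** — Spearman correlation (exact permutation p for n <= 9,
  t-approximation otherwise) and ordinary least-squares regression of the
  baseline-to-T3 clinical differentials against biomarker log2 differentials.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import multivariate_t

from .instruments import Timepoint

TIMEPOINTS = [t.value for t in Timepoint]


@dataclass
class LongitudinalOutcome:
    """One outcome, wide: rows = participants, columns = timepoints."""

    name: str
    data: pd.DataFrame  # columns subset of TIMEPOINTS, NaN = missing
    improvement_direction: int = 1  # +1: higher is better; -1: lower is better

    def __post_init__(self) -> None:
        extra = set(self.data.columns) - set(TIMEPOINTS)
        if extra:
            raise ValueError(f"unknown timepoint column(s): {sorted(extra)}")
        self.data = self.data[[t for t in TIMEPOINTS if t in self.data.columns]]

    def usable_timepoints(self, min_n: int = 3) -> list[str]:
        return [t for t in self.data.columns if self.data[t].notna().sum() >= min_n]


@dataclass
class TimeEffectResult:
    outcome: str
    f_stat: float
    df_num: float  # GG-scaled numerator df
    df_den: float  # GG-scaled denominator df
    epsilon: float
    p_value: float
    q_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "F": self.f_stat, "df_num": self.df_num,
            "df_den": self.df_den, "epsilon": self.epsilon, "p": self.p_value,
            "q": self.q_value,
        }


@dataclass
class PairwiseResult:
    outcome: str
    timepoint: str
    mean_change: float
    ci_low: float
    ci_high: float
    n_pairs: int
    t_stat: float
    p_raw: float
    p_adjusted: float
    q_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "timepoint": self.timepoint,
            "mean_change": self.mean_change, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "n_pairs": self.n_pairs,
            "t": self.t_stat, "p_raw": self.p_raw,
            "p_dunnett": self.p_adjusted, "q": self.q_value,
        }


@dataclass
class BiomarkerSeries:
    """Plasma analyte concentrations (pg/mL), wide participant x timepoint."""

    analyte: str
    concentrations: pd.DataFrame
    detection_floor: float = 0.0

    def __post_init__(self) -> None:
        if (self.concentrations.dropna(how="all") < 0).any().any():
            raise ValueError(f"negative concentration in {self.analyte}")


@dataclass
class CorrelationEntry:
    clinical_feature: str
    analyte: str
    rs: float | None
    p_value: float | None
    slope: float | None
    intercept: float | None
    n: int
    flag: str = ""

    def to_dict(self) -> dict:
        return {
            "clinical_feature": self.clinical_feature, "analyte": self.analyte,
            "rs": self.rs, "p": self.p_value, "slope": self.slope,
            "intercept": self.intercept, "n": self.n, "flag": self.flag,
        }


# ---------------------------------------------------------------------------
# Greenhouse-Geisser epsilon


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity-correction epsilon from a k x k
    covariance of the repeated measures; 1/(k-1) <= epsilon <= 1."""
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1] or S.shape[0] < 2:
        raise ValueError("covariance must be k x k with k >= 2")
    eigs = np.linalg.eigvalsh((S + S.T) / 2)
    if eigs.min() < -1e-8 * max(1.0, abs(eigs).max()):
        raise ValueError("covariance is not positive semidefinite")
    k = S.shape[0]
    C = np.eye(k) - np.ones((k, k)) / k
    D = C @ S @ C  # double-centered
    tr = np.trace(D)
    denom = (k - 1) * np.sum(D * D)
    if denom <= 0:
        return 1.0  # degenerate (e.g. constant data): treat as spherical
    eps = tr * tr / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


# ---------------------------------------------------------------------------
# time effect


def fit_time_effect(outcome: LongitudinalOutcome, min_n: int = 3) -> TimeEffectResult:
    """F-test of the timepoint effect with Geisser-Greenhouse-scaled dfs.

    Complete balanced data are fitted as a two-way (participant + time)
    ANOVA, which is the REML solution for the random-intercept model; with
    missing values a mixed model is fitted by REML and the time effect is
    tested by a Wald F. Epsilon comes from the complete-case covariance.
    """
    tps = outcome.usable_timepoints(min_n)
    if len(tps) < 2:
        raise ValueError(
            f"outcome {outcome.name!r} has <2 timepoints with >= {min_n} participants"
        )
    wide = outcome.data[tps]
    wide = wide.loc[wide.notna().sum(axis=1) >= 2]  # need within-subject info
    k = len(tps)
    long = wide.reset_index(names="participant").melt(
        id_vars="participant", var_name="time", value_name="value"
    ).dropna()
    values = long["value"].to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        return TimeEffectResult(outcome.name, 0.0, float(k - 1),
                                float(len(wide) - 1), 1.0, 1.0)

    complete = wide.dropna()
    if len(complete) >= 2:
        eps = gg_epsilon(np.cov(complete.to_numpy(dtype=float), rowvar=False))
    else:
        warnings.warn(
            f"{outcome.name}: <2 complete cases; epsilon set to 1", stacklevel=2
        )
        eps = 1.0

    n_subj = long["participant"].nunique()
    n_obs = len(long)
    balanced = len(complete) == len(wide) and n_obs == n_subj * k
    if balanced:
        f_stat = _balanced_time_f(complete.to_numpy(dtype=float))
    else:
        f_stat = _mixed_time_f(long)
    df_num = eps * (k - 1)
    df_den = eps * (n_obs - n_subj - (k - 1))
    p = float(stats.f.sf(f_stat, df_num, df_den))
    return TimeEffectResult(outcome.name, float(f_stat), float(df_num),
                            float(df_den), float(eps), p)


def _balanced_time_f(Y: np.ndarray) -> float:
    """Two-way (subject + time) ANOVA F for the time effect via statsmodels."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    n, k = Y.shape
    df = pd.DataFrame(
        {
            "value": Y.ravel(),
            "subject": np.repeat(np.arange(n), k).astype(str),
            "time": np.tile(np.arange(k), n).astype(str),
        }
    )
    fit = ols("value ~ C(subject) + C(time)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    return float(table.loc["C(time)", "F"])


def _mixed_time_f(long: pd.DataFrame) -> float:
    """Wald F of the time effect from a REML random-intercept model."""
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance warnings
        model = smf.mixedlm("value ~ C(time)", data=long, groups=long["participant"])
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=True, method="powell")
    names = [n for n in fit.fe_params.index if n.startswith("C(time)")]
    beta = fit.fe_params[names].to_numpy()
    cov = fit.cov_params().loc[names, names].to_numpy()
    q = len(names)
    return float(beta @ np.linalg.solve(cov, beta) / q)


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons


def _dunnett_max_t_cdf(t: float, k: int, df: float, seed: int) -> float:
    """P(max_i |T_i| <= t) for k equicorrelated (rho=1/2) t variates,
    by seeded quasi-Monte Carlo integration (error well below 1e-4)."""
    if t <= 0:
        return 0.0
    corr = np.full((k, k), 0.5)
    np.fill_diagonal(corr, 1.0)
    rng = np.random.default_rng(seed)
    val = multivariate_t.cdf(
        np.full(k, t), loc=np.zeros(k), shape=corr, df=df,
        lower_limit=np.full(k, -t), random_state=rng,
        maxpts=200_000 * k,
    )
    return float(np.clip(val, 0.0, 1.0))


@lru_cache(maxsize=256)
def _dunnett_critical(k: int, df: float, alpha: float, seed: int) -> float:
    """Simultaneous two-sided critical point: P(max |T_i| <= c) = 1 - alpha."""
    if k == 1:
        return float(stats.t.ppf(1 - alpha / 2, df))
    from scipy.optimize import brentq

    lo = stats.t.ppf(1 - alpha / 2, df)
    hi = stats.t.ppf(1 - alpha / (2 * k), df)  # Bonferroni bound
    f = lambda c: _dunnett_max_t_cdf(c, k, df, seed) - (1 - alpha)
    if f(lo) > 0:
        return float(lo)
    if f(hi) < 0:
        return float(hi)
    return float(brentq(f, lo, hi, xtol=1e-4))


def dunnett_baseline_comparisons(
    outcome: LongitudinalOutcome,
    alpha: float = 0.05,
    seed: int = 0,
    baseline: str = "BSL",
) -> list[PairwiseResult]:
    """Paired changes of each later timepoint vs baseline, Dunnett-adjusted.

    Adjusted p-values and simultaneous CIs come from the equicorrelated
    (rho = 1/2) many-to-one multivariate-t distribution; a single comparison
    degenerates to the paired t-test. Adjusted p-values are clipped into
    the mathematically exact [p_raw, min(1, k * p_raw)] sandwich to absorb
    quadrature noise.
    """
    if baseline not in outcome.data.columns:
        raise ValueError(f"baseline timepoint {baseline!r} absent")
    later = [t for t in outcome.data.columns if t != baseline]
    comps = []
    for t in later:
        paired = outcome.data[[baseline, t]].dropna()
        if len(paired) < 2:
            warnings.warn(
                f"{outcome.name}: timepoint {t} has <2 paired observations; dropped",
                stacklevel=2,
            )
            continue
        d = (paired[t] - paired[baseline]).to_numpy(dtype=float)
        comps.append((t, d))
    if not comps:
        return []
    k = len(comps)
    df = float(min(len(d) for _, d in comps) - 1)
    results = []
    crit = _dunnett_critical(k, df, alpha, seed)
    for t, d in comps:
        n = len(d)
        mean = float(d.mean())
        se = float(d.std(ddof=1) / np.sqrt(n))
        if se == 0:
            tstat, p_raw = (np.inf if mean != 0 else 0.0), (0.0 if mean != 0 else 1.0)
        else:
            tstat = mean / se
            p_raw = float(2 * stats.t.sf(abs(tstat), n - 1))
        if k == 1:
            p_adj = p_raw
        else:
            p_adj = 1.0 - _dunnett_max_t_cdf(abs(tstat), k, df, seed)
            p_adj = float(np.clip(p_adj, p_raw, min(1.0, k * p_raw)))
        results.append(
            PairwiseResult(
                outcome=outcome.name, timepoint=t, mean_change=mean,
                ci_low=mean - crit * se, ci_high=mean + crit * se,
                n_pairs=n, t_stat=float(tstat), p_raw=p_raw, p_adjusted=p_adj,
            )
        )
    return results


# ---------------------------------------------------------------------------
# BKY two-stage FDR


def bky_two_stage(pvalues, alpha: float = 0.05) -> dict:
    """Benjamini-Krieger-Yekutieli two-stage adaptive step-up.

    Stage 1: linear (BH) step-up at alpha' = alpha / (1 + alpha) giving r1
    rejections; if r1 = 0 nothing is rejected, if r1 = m everything is.
    Stage 2: re-run the linear step-up at alpha' * m / (m - r1). q-values
    are the monotone adjusted p-values of the operative stage and may fall
    below the raw p (the adaptive scaling m0/m < 1), unlike plain BH.
    """
    p = np.asarray(list(pvalues), dtype=float)
    m = len(p)
    if m == 0:
        return {"q_values": np.array([]), "rejected": np.array([], dtype=bool),
                "m0_hat": 0}
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    alpha_prime = alpha / (1 + alpha)

    def _bh_reject(pv: np.ndarray, level: float) -> np.ndarray:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order]
        thresh = level * np.arange(1, m + 1) / m
        below = np.nonzero(ranked <= thresh)[0]
        out = np.zeros(m, dtype=bool)
        if len(below):
            out[order[: below.max() + 1]] = True
        return out

    def _bh_q(pv: np.ndarray, scale: float) -> np.ndarray:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order]
        q = ranked * m * scale / np.arange(1, m + 1)
        q = np.minimum.accumulate(q[::-1])[::-1]
        q = np.clip(q, 0.0, 1.0)
        out = np.empty(m)
        out[order] = q
        return out

    r1 = int(_bh_reject(p, alpha_prime).sum())
    if r1 == 0:
        return {
            "q_values": _bh_q(p, scale=(1 + alpha)),
            "rejected": np.zeros(m, dtype=bool),
            "m0_hat": m,
        }
    if r1 == m:
        return {
            "q_values": _bh_q(p, scale=0.0), "rejected": np.ones(m, dtype=bool),
            "m0_hat": 0,
        }
    m0 = m - r1
    q = _bh_q(p, scale=(1 + alpha) * m0 / m)
    rejected = _bh_reject(p, alpha_prime * m / m0)
    return {"q_values": q, "rejected": rejected, "m0_hat": m0}


def annotate_family_fdr(
    time_effects: list[TimeEffectResult],
    pairwise: list[PairwiseResult],
    alpha: float = 0.05,
) -> None:
    """One BKY pass over an analysis family, writing q-values in place.

    A family is a figure panel's tests: the time-effect p's plus all
    Dunnett-adjusted pairwise p's, globally corrected together.
    """
    items: list = list(time_effects) + list(pairwise)
    if not items:
        return
    ps = [
        r.p_value if isinstance(r, TimeEffectResult) else r.p_adjusted for r in items
    ]
    qs = bky_two_stage(ps, alpha)["q_values"]
    for r, q in zip(items, qs):
        if isinstance(r, TimeEffectResult):
            r.q_value = float(q)
        else:
            r.q_value = float(q)


# ---------------------------------------------------------------------------
# biomarkers


def log2_series(series: BiomarkerSeries, baseline: str = "BSL") -> dict:
    """log2-transform concentrations and compute fold changes vs baseline.

    Values at or below the detection floor are replaced by floor/2 before
    the transform and flagged. Fold change per timepoint is
    2**(mean paired log2 difference vs baseline), i.e. the geometric mean
    ratio among participants observed at both timepoints.
    """
    conc = series.concentrations.astype(float)
    if (conc.fillna(1.0) < 0).any().any():
        raise ValueError("negative concentration")
    floor = series.detection_floor
    flagged = pd.DataFrame(False, index=conc.index, columns=conc.columns)
    if floor > 0:
        flagged = conc.notna() & (conc <= floor)
        conc = conc.mask(flagged, floor / 2.0)
    elif (conc == 0).any().any():
        raise ValueError(
            "zero concentration with no detection floor configured; "
            "set detection_floor to enable floor/2 substitution"
        )
    log2 = np.log2(conc)
    fold = {}
    if baseline in log2.columns:
        for t in log2.columns:
            if t == baseline:
                continue
            paired = log2[[baseline, t]].dropna()
            if len(paired):
                delta = float((paired[t] - paired[baseline]).mean())
                fold[t] = {"mean_log2_diff": delta, "fold_change": float(2.0 ** delta),
                           "n_pairs": int(len(paired))}
    return {"log2": log2, "fold_changes": fold, "floored": flagged}


# ---------------------------------------------------------------------------
# correlation of differentials


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rs_obs: float) -> float:
    """Exact two-sided permutation p for Spearman's rs (n <= 9)."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        rs_all = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rs_all) >= abs(rs_obs) - 1e-12))


def correlate_differentials(
    clinical: pd.Series,
    biomarker: pd.Series,
    clinical_name: str = "",
    analyte: str = "",
) -> CorrelationEntry:
    """Spearman rs + OLS of clinical vs biomarker BSL->T3 differentials.

    Pairwise-complete deletion; ties get average ranks; the p-value is an
    exact permutation p for n <= 9 and the t-approximation otherwise. The
    companion OLS regresses the clinical differential on the biomarker
    log2 differential.
    """
    paired = pd.concat([clinical, biomarker], axis=1, keys=["clin", "bio"]).dropna()
    n = len(paired)
    if n < 4:
        return CorrelationEntry(clinical_name, analyte, None, None, None, None,
                                n, flag="fewer than 4 complete pairs")
    x = paired["bio"].to_numpy(dtype=float)
    y = paired["clin"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationEntry(clinical_name, analyte, None, None, None, None,
                                n, flag="zero variance")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rs = float(stats.pearsonr(rx, ry).statistic)
    if n <= 9:
        p = _spearman_exact_p(rx, ry, rs)
    else:
        if abs(rs) >= 1.0:
            p = 0.0
        else:
            t = rs * np.sqrt((n - 2) / (1 - rs * rs))
            p = float(2 * stats.t.sf(abs(t), n - 2))
    reg = stats.linregress(x, y)
    return CorrelationEntry(
        clinical_name, analyte, rs, p, float(reg.slope), float(reg.intercept), n
    )


def residual_qq(residuals) -> pd.DataFrame:
    """Ordered residuals vs standard-normal quantiles at positions
    (i - 0.5)/n, as a table ready for QQ plotting."""
    r = np.sort(np.asarray(list(residuals), dtype=float))
    n = len(r)
    if n < 3:
        raise ValueError("need at least 3 residuals")
    pos = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {"theoretical": stats.norm.ppf(pos), "observed": r, "position": pos}
    )
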