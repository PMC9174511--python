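"""Trauma-exposure epidemiology: prevalence, gender contrasts, regression.

Covers the descriptive-epidemiology layer of the pipeline: uncorrected
Pearson chi-square contrasts on 2x2 tables (male/female x exposed/case),
prevalence point estimates with Wilson score intervals, reconstruction of
group denominators from printed count/percent pairs, and multinomial
logistic regression of the screening diagnosis (none / PTSD / cPTSD) on the
six exposure-class-by-period indicators, optionally adjusted for gender,
nationality and parental education.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

DIAGNOSIS_ORDER = ("none", "PTSD", "cPTSD")


# ---------------------------------------------------------------------------
# Contingency tables and prevalence
# ---------------------------------------------------------------------------


def pearson_chi2(table) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square on a 2x2 table.

    Returns (statistic, df=1, p).  No continuity correction — the convention
    under which the published gender contrasts reproduce.
    """
    T = np.asarray(table, dtype=float)
    if T.shape != (2, 2):
        raise ValueError("pearson_chi2 expects a 2x2 table")
    if (T < 0).any():
        raise ValueError("counts must be nonnegative")
    row = T.sum(axis=1)
    col = T.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row or column margin; chi-square undefined")
    E = np.outer(row, col) / T.sum()
    stat = float(((T - E) ** 2 / E).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, 1, p


@dataclass(frozen=True)
class PrevalenceEstimate:
    k: int
    n: int
    point: float      # percent
    ci_low: float     # percent
    ci_high: float    # percent


def prevalence_ci(k: int, n: int, level: float = 0.95) -> PrevalenceEstimate:
    """Prevalence in percent with a Wilson score interval."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("cases must lie in 0..n")
    point = 100.0 * k / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if k == 0 else float(100 * max(centre - half, 0.0))
    hi = 100.0 if k == n else float(100 * min(centre + half, 1.0))
    return PrevalenceEstimate(k=int(k), n=int(n), point=float(point),
                              ci_low=lo, ci_high=hi)


def reconstruct_denominator(count: int, percent: float) -> tuple[int, float]:
    """Group denominator implied by a printed count/percent pair.

    Returns (n, residual) where n = round(100 * count / percent) and residual
    is the percent-scale rounding error |100 * count / n - percent|.
    """
    if count < 0:
        raise ValueError("count must be nonnegative")
    if percent <= 0 or percent > 100:
        raise ValueError("percent must lie in (0, 100]")
    n = int(round(100.0 * count / percent))
    residual = abs(100.0 * count / n - percent) if n else np.inf
    return n, float(residual)


def feasible_denominators(count: int, percent: float, decimals: int = 2) -> list[int]:
    """All denominators consistent with a printed count/percent pair.

    A denominator n is feasible when 100*count/n rounds back to the printed
    percent at its printed precision.  Printed percentages only pin the
    denominator to an interval; when several rows share a denominator the
    intersection of their feasible sets recovers it exactly.
    """
    if percent <= 0:
        raise ValueError("percent must be positive")
    centre = 100.0 * count / percent
    lo = max(count, int(np.floor(centre * 0.9)))
    hi = int(np.ceil(centre * 1.1)) + 1
    return [
        n for n in range(lo, hi)
        if round(100.0 * count / n, decimals) == round(percent, decimals)
    ]


def two_sample_t(x, y) -> tuple[float, float]:
    """Unequal-variance (Welch) two-sample t-test; (statistic, p)."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Multinomial logistic regression
# ---------------------------------------------------------------------------


@dataclass
class MultinomialFit:
    categories: tuple           # outcome levels, reference first
    predictors: list            # design-matrix column names (incl. intercept)
    coef: pd.DataFrame          # predictors x non-reference categories
    cov: np.ndarray             # covariance of the stacked coefficients
    loglik: float
    converged: bool
    n: int
    separation_flag: bool


def fit_multinomial(y, X: pd.DataFrame, add_intercept: bool = True) -> MultinomialFit:
    """Maximum-likelihood multinomial logit with 'none' as reference.

    ``y`` holds categories from {none, PTSD, cPTSD} (unused levels are
    dropped); ``X`` is the design matrix.  Suspiciously large coefficients
    (|b| > 15) raise a separation flag but estimates are still returned.
    """
    y = pd.Series(y).astype(str).reset_index(drop=True)
    X = pd.DataFrame(X).reset_index(drop=True).astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    levels = [c for c in DIAGNOSIS_ORDER if c in set(y)]
    if len(levels) < 2:
        raise ValueError("outcome must have at least two observed categories")
    codes = y.map({lvl: i for i, lvl in enumerate(levels)}).to_numpy()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.MNLogit(codes, X.to_numpy())
    res = model.fit(method="newton", maxiter=200, disp=False)
    coef = pd.DataFrame(
        res.params, index=list(X.columns), columns=list(levels[1:])
    )
    separation = bool((np.abs(res.params) > 15).any())
    return MultinomialFit(
        categories=tuple(levels),
        predictors=list(X.columns),
        coef=coef,
        cov=np.asarray(res.cov_params()),
        loglik=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        n=int(len(y)),
        separation_flag=separation,
    )


def odds_ratios(fit: MultinomialFit, level: float = 0.95) -> pd.DataFrame:
    """Wald odds ratios per predictor x outcome: OR = exp(b), CI =
    exp(b +/- z * se).  Degenerate (zero-se) intervals are flagged."""
    if fit.cov is None:
        raise ValueError("fit lacks a coefficient covariance matrix")
    z = stats.norm.ppf(0.5 + level / 2.0)
    k = len(fit.predictors)
    se = np.sqrt(np.diag(fit.cov)).reshape(len(fit.categories) - 1, k).T
    rows = []
    for j, cat in enumerate(fit.categories[1:]):
        for i, pred in enumerate(fit.predictors):
            b, s = float(fit.coef.iloc[i, j]), float(se[i, j])
            rows.append(
                {
                    "outcome": cat,
                    "predictor": pred,
                    "coef": b,
                    "se": s,
                    "OR": float(np.exp(b)),
                    "ci_low": float(np.exp(b - z * s)),
                    "ci_high": float(np.exp(b + z * s)),
                    "degenerate_ci": s == 0.0,
                }
            )
    return pd.DataFrame(rows)


EXPOSURE_PREDICTORS = [
    "intentional_childhood",
    "intentional_adolescence",
    "intentional_six_months",
    "unintentional_childhood",
    "unintentional_adolescence",
    "unintentional_six_months",
]

ADJUSTMENT_COVARIATES = ["female", "non_italian", "parental_education"]


def build_design(scored: pd.DataFrame, adjusted: bool = False) -> tuple[pd.Series, pd.DataFrame]:
    """Outcome and design matrix for the exposure regression from a scored
    cohort table (class/period indicators already appended by the scorer).

    Records with a missing diagnosis are dropped.  The adjusted design adds
    gender (female indicator), non-Italian nationality and parental
    education (single ordinal covariate).
    """
    keep = scored["diagnosis"].notna()
    d = scored.loc[keep].copy()
    X = d[EXPOSURE_PREDICTORS].astype(float)
    if adjusted:
        X["female"] = (d["gender"] == "female").astype(float)
        X["non_italian"] = (d["nationality"] == "non-Italian").astype(float)
        X["parental_education"] = d["parental_education"].astype(float)
    return d["diagnosis"].astype(str), X


def exposure_summary_table(cohort: pd.DataFrame,
                           event_map=None) -> pd.DataFrame:
    """Per-checklist-item lifetime endorsement by gender with chi-square.

    One row per event: class, male count/%, female count/%, total count/%,
    and the uncorrected chi-square for the gender contrast (NaN when a
    margin is degenerate).
    """
    from itqnet.constants import DEFAULT_EVENT_CLASSES, PERIODS, exposure_column
    from itqnet.scoring import EventClassificationMap

    classes = (event_map or EventClassificationMap()).classes
    male = cohort["gender"] == "male"
    female = cohort["gender"] == "female"
    rows = []
    for item in sorted(classes):
        cols = [exposure_column(item, p) for p in PERIODS]
        lifetime = cohort[cols].astype(bool).any(axis=1)
        k_m, n_m = int(lifetime[male].sum()), int(male.sum())
        k_f, n_f = int(lifetime[female].sum()), int(female.sum())
        try:
            stat, _, p = pearson_chi2(
                [[k_m, n_m - k_m], [k_f, n_f - k_f]]
            )
        except ValueError:
            stat, p = np.nan, np.nan
        rows.append({
            "item": item,
            "class": classes[item],
            "male_count": k_m,
            "male_pct": 100.0 * k_m / n_m if n_m else np.nan,
            "female_count": k_f,
            "female_pct": 100.0 * k_f / n_f if n_f else np.nan,
            "total_count": k_m + k_f,
            "total_pct": 100.0 * (k_m + k_f) / (n_m + n_f),
            "chi2": stat,
            "p": p,
        })
    return pd.DataFrame(rows)


class MultinomialDiagnosisRegression(BaseEstimator):
    """Multinomial logistic regression of diagnosis on exposure indicators.

    Parameters
    ----------
    adjusted : bool, default False
        Add gender, nationality and parental-education covariates.

    Attributes
    ----------
    fit_ : MultinomialFit
    odds_ratios_ : DataFrame of OR [95% CI] per predictor x outcome.
    """

    def __init__(self, adjusted: bool = False):
        self.adjusted = adjusted

    def fit(self, X: pd.DataFrame, y=None):
        """``X`` is a scored cohort table (with ``diagnosis`` and exposure
        indicators); ``y`` may override the outcome vector."""
        if y is None:
            yv, design = build_design(X, adjusted=self.adjusted)
        else:
            yv, design = pd.Series(y), pd.DataFrame(X)
        self.fit_ = fit_multinomial(yv, design)
        self.odds_ratios_ = odds_ratios(self.fit_)
        self.n_features_in_ = design.shape[1]
        return self
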