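"""Weighted-least-squares confirmatory factor analysis of the 12 ITQ items.

Four competing measurement models are compared:

* **M1** — one factor: all 12 items load on a single general factor.
* **M2** — six correlated first-order factors (two items each): Re, Av, Th,
  AD, NSC, DR.
* **M3** — six first-order factors plus a single second-order factor.
* **M4** — six first-order factors plus two correlated second-order factors
  (PTSD over Re/Av/Th; DSO over AD/NSC/DR).

Estimation minimizes the WLS discrepancy F(theta) = (s - sigma(theta))'
Gamma^-1 (s - sigma(theta)) over the q = 66 unique polychoric correlations,
where Gamma is the (n-scaled) asymptotic covariance of s — full, diagonal, or
identity (unweighted) per configuration.  chi2 = (n - 1) * F_min.  Model
selection uses BIC from the Gaussian pseudo-log-likelihood of the sample
correlation matrix under the implied structure; a BIC difference above 10 is
treated as decisive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from itqnet.constants import FACTORS, SYMPTOM_ITEMS
from itqnet.polychoric import CorrelationMatrixEstimate, polychoric_matrix, wls_weight

_N_UNIQUE = 66  # p(p-1)/2 for p = 12
_IU = np.triu_indices(12, k=1)


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FactorModelSpec:
    """Declarative structure of one candidate factor model.

    ``item_factor`` maps each of the 12 items to its first-order factor;
    ``higher_order`` is ``"none"``, ``"single"`` or ``"two"``; for ``"two"``,
    ``factor_block`` maps each first-order factor to second-order factor 0
    (PTSD) or 1 (DSO).  Identification: all factor variances fixed to 1, the
    implied correlation matrix has an enforced unit diagonal (unique
    variances absorb the remainder).
    """

    model_id: str
    items: tuple = SYMPTOM_ITEMS
    item_factor: tuple = tuple(int(i) for i in np.repeat(np.arange(6), 2))
    n_factors: int = 6
    higher_order: str = "none"
    factor_block: tuple | None = None
    correlated_factors: bool = True

    @property
    def n_free(self) -> int:
        q = 12  # first-order loadings
        if self.higher_order == "single":
            q += self.n_factors
        elif self.higher_order == "two":
            q += self.n_factors + 1
        elif self.correlated_factors and self.n_factors > 1:
            q += self.n_factors * (self.n_factors - 1) // 2
        return q

    @property
    def df(self) -> int:
        return _N_UNIQUE - self.n_free

    def validate(self):
        if len(self.item_factor) != 12:
            raise ValueError("item_factor must map all 12 items")
        covered = set(self.item_factor)
        if covered != set(range(self.n_factors)):
            raise ValueError("every first-order factor needs at least one item")
        if self.higher_order == "two" and (
            self.factor_block is None or len(self.factor_block) != self.n_factors
        ):
            raise ValueError("two-factor higher order requires factor_block")
        if self.n_free >= _N_UNIQUE:
            raise ValueError("model is not identified (q_free >= 66)")

    def to_json(self) -> dict:
        return {
            "model_id": self.model_id,
            "items": list(self.items),
            "item_factor": list(self.item_factor),
            "n_factors": self.n_factors,
            "higher_order": self.higher_order,
            "factor_block": None if self.factor_block is None else list(self.factor_block),
            "correlated_factors": self.correlated_factors,
        }


def build_standard_models() -> dict[str, FactorModelSpec]:
    """The four standard candidate models (M1 df 54, M2 df 39, M3 df 48,
    M4 df 47)."""
    m1 = FactorModelSpec(
        model_id="M1", item_factor=(0,) * 12, n_factors=1, correlated_factors=False
    )
    m2 = FactorModelSpec(model_id="M2")
    m3 = FactorModelSpec(model_id="M3", higher_order="single")
    m4 = FactorModelSpec(
        model_id="M4", higher_order="two", factor_block=(0, 0, 0, 1, 1, 1)
    )
    for m in (m1, m2, m3, m4):
        m.validate()
    return {"M1": m1, "M2": m2, "M3": m3, "M4": m4}


# ---------------------------------------------------------------------------
# Implied structure
# ---------------------------------------------------------------------------


def _unpack(params: np.ndarray, spec: FactorModelSpec):
    lam = params[:12]
    rest = params[12:]
    k = spec.n_factors
    if spec.higher_order == "single":
        gamma = rest[:k]
        phi = np.outer(gamma, gamma)
        np.fill_diagonal(phi, 1.0)
        extra = {"gamma": gamma}
    elif spec.higher_order == "two":
        gamma, r = rest[:k], rest[k]
        block = np.asarray(spec.factor_block)
        second = np.where(block[:, None] == block[None, :], 1.0, r)
        phi = np.outer(gamma, gamma) * second
        np.fill_diagonal(phi, 1.0)
        extra = {"gamma": gamma, "second_order_corr": float(r)}
    elif spec.correlated_factors and k > 1:
        phi = np.eye(k)
        phi[np.triu_indices(k, 1)] = rest
        phi = phi + phi.T - np.eye(k)
        extra = {}
    else:
        phi = np.eye(k)
        extra = {}
    return lam, phi, extra


def implied_correlations(params: np.ndarray, spec: FactorModelSpec) -> np.ndarray:
    """Model-implied 12x12 correlation matrix Sigma(theta) = Lambda Phi
    Lambda' with a unit diagonal enforced via the unique variances."""
    if len(params) != spec.n_free:
        raise ValueError(
            f"parameter vector has {len(params)} entries, spec needs {spec.n_free}"
        )
    lam, phi, _ = _unpack(np.asarray(params, float), spec)
    L = np.zeros((12, spec.n_factors))
    L[np.arange(12), np.asarray(spec.item_factor)] = lam
    sigma = L @ phi @ L.T
    np.fill_diagonal(sigma, 1.0)
    return sigma


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class CfaFit:
    """One fitted model: estimates, discrepancy, chi-square and bookkeeping."""

    model_id: str
    spec: FactorModelSpec | None
    params: np.ndarray
    loadings: np.ndarray
    factor_corr: np.ndarray
    extra: dict
    F_min: float
    chi2: float
    df: int
    n: int
    converged: bool
    weight_mode: str
    implied: np.ndarray
    residuals: np.ndarray  # s - sigma_hat over the 66 unique entries


def _metric_cholesky(est: CorrelationMatrixEstimate, weight: str) -> np.ndarray:
    """Cholesky factor of Gamma = n * Cov(s) (the weight metric); identity
    weighting uses Gamma = I."""
    n = est.n
    if weight == "identity":
        gamma = np.eye(_N_UNIQUE)
    elif weight in ("full", "diag"):
        if est.W is None:
            raise ValueError(
                f"weight='{weight}' requires a bootstrap weight matrix on the estimate"
            )
        gamma = n * (np.diag(np.diag(est.W)) if weight == "diag" else est.W)
    else:
        raise ValueError(f"unknown weight mode: {weight!r}")
    return np.linalg.cholesky(gamma)


def _start_points(spec: FactorModelSpec, n_starts: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    k = spec.n_factors
    base = [np.full(12, 0.7)]
    if spec.higher_order == "single":
        base.append(np.full(k, 0.7))
    elif spec.higher_order == "two":
        base.append(np.full(k, 0.7))
        base.append([0.5])
    elif spec.correlated_factors and k > 1:
        base.append(np.full(k * (k - 1) // 2, 0.5))
    starts = [np.concatenate([np.atleast_1d(np.asarray(b, float)) for b in base])]
    for _ in range(n_starts - 1):
        pert = starts[0] + rng.uniform(-0.25, 0.25, size=starts[0].size)
        starts.append(np.clip(pert, -0.9, 0.9))
    return starts


def fit_wls(
    est: CorrelationMatrixEstimate,
    spec: FactorModelSpec,
    weight: str = "full",
    n_starts: int = 5,
    seed: int = 0,
) -> CfaFit:
    """Fit one factor model by weighted least squares.

    Minimizes F(theta) = (s - sigma(theta))' Gamma^-1 (s - sigma(theta)) with
    bounded L-BFGS-B from ``n_starts`` start points (one structured, the rest
    seeded perturbations); chi2 = (n - 1) * F_min.
    """
    spec.validate()
    s = est.unique_correlations()
    L = _metric_cholesky(est, weight)

    def objective(theta):
        resid = s - implied_correlations(theta, spec)[_IU]
        y = solve_triangular(L, resid, lower=True)
        return float(y @ y)

    bounds = [(-0.999, 0.999)] * spec.n_free
    best = None
    any_converged = False
    for x0 in _start_points(spec, n_starts, seed):
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9},
        )
        any_converged = any_converged or res.success
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        raise RuntimeError("optimization produced no result")
    theta = best.x
    lam, phi, extra = _unpack(theta, spec)
    implied = implied_correlations(theta, spec)
    F_min = float(best.fun)
    return CfaFit(
        model_id=spec.model_id,
        spec=spec,
        params=theta,
        loadings=lam,
        factor_corr=phi,
        extra=extra,
        F_min=F_min,
        chi2=float((est.n - 1) * F_min),
        df=spec.df,
        n=est.n,
        converged=bool(any_converged),
        weight_mode=weight,
        implied=implied,
        residuals=s - implied[_IU],
    )


def fit_independence(est: CorrelationMatrixEstimate, weight: str = "full") -> CfaFit:
    """Baseline (independence) model: all correlations zero, no free
    parameters; used by the incremental fit indices."""
    s = est.unique_correlations()
    L = _metric_cholesky(est, weight)
    y = np.linalg.solve(L, s)
    F = float(y @ y)
    return CfaFit(
        model_id="baseline",
        spec=None,
        params=np.empty(0),
        loadings=np.zeros(12),
        factor_corr=np.eye(1),
        extra={},
        F_min=F,
        chi2=float((est.n - 1) * F),
        df=_N_UNIQUE,
        n=est.n,
        converged=True,
        weight_mode=weight,
        implied=np.eye(12),
        residuals=s,
    )


# ---------------------------------------------------------------------------
# Fit indices and comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitIndices:
    rmsea: float
    cfi: float
    tli: float
    srmr: float
    cd: float
    bic: float
    chi2: float
    df: int
    n: int = 0

    def as_row(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "RMSEA": self.rmsea,
            "CFI": self.cfi,
            "TLI": self.tli,
            "SRMR": self.srmr,
            "CD": self.cd,
            "BIC": self.bic,
        }


def rmsea_from_chi2(chi2: float, df: int, n: int) -> float:
    """Root-mean-square error of approximation from a chi-square statistic:
    sqrt(max(chi2 - df, 0) / (df * (n - 1)))."""
    if df <= 0:
        raise ValueError("RMSEA undefined for df <= 0")
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))


def cfi_from_chi2(chi2: float, df: int, chi2_b: float, df_b: int) -> float:
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    return 1.0 if den == 0 else float(1.0 - num / den)


def tli_from_chi2(chi2: float, df: int, chi2_b: float, df_b: int) -> float:
    ratio_b = chi2_b / df_b
    if ratio_b == 1.0:
        return 1.0
    return float((ratio_b - chi2 / df) / (ratio_b - 1.0))


def _gaussian_pseudo_loglik(R: np.ndarray, sigma: np.ndarray, n: int) -> float:
    """-(n/2) (log det Sigma + tr(Sigma^-1 R)); additive constants dropped
    (only BIC differences are meaningful)."""
    vals = np.linalg.eigvalsh(sigma)
    if vals.min() <= 1e-10:
        sigma = sigma + (1e-8 - min(vals.min(), 0.0)) * np.eye(sigma.shape[0])
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ValueError("implied matrix is not positive-definite")
    return float(-(n / 2.0) * (logdet + np.trace(np.linalg.solve(sigma, R))))


def fit_indices(fit: CfaFit, baseline: CfaFit, est: CorrelationMatrixEstimate) -> FitIndices:
    """Standard normal-theory fit indices for one fitted model.

    RMSEA/CFI/TLI from the chi-square statistics of the model and the
    independence baseline; SRMR is the root mean square of the 66 unique
    residual correlations; CD = 1 - det(unique variances)/det(implied); BIC =
    -2 * Gaussian pseudo-log-likelihood + q_free * ln n.
    """
    if baseline.df <= 0 or baseline.n != fit.n:
        raise ValueError("baseline must be the independence fit on the same data")
    rmsea = rmsea_from_chi2(fit.chi2, fit.df, fit.n)
    cfi = cfi_from_chi2(fit.chi2, fit.df, baseline.chi2, baseline.df)
    tli = tli_from_chi2(fit.chi2, fit.df, baseline.chi2, baseline.df)
    srmr = float(np.sqrt(np.mean(fit.residuals**2)))
    lam, phi = fit.loadings, fit.factor_corr
    if fit.spec is not None:
        Lmat = np.zeros((12, fit.spec.n_factors))
        Lmat[np.arange(12), np.asarray(fit.spec.item_factor)] = lam
        communality = np.clip(np.diag(Lmat @ phi @ Lmat.T), 0.0, 1.0 - 1e-10)
    else:
        communality = np.zeros(12)
    unique = 1.0 - communality
    sign, logdet_sigma = np.linalg.slogdet(fit.implied)
    cd = float(1.0 - np.exp(np.sum(np.log(unique)) - logdet_sigma))
    q_free = fit.spec.n_free if fit.spec is not None else 0
    loglik = _gaussian_pseudo_loglik(est.R, fit.implied, fit.n)
    bic = float(-2.0 * loglik + q_free * np.log(fit.n))
    return FitIndices(
        rmsea=rmsea, cfi=cfi, tli=tli, srmr=srmr, cd=cd, bic=bic,
        chi2=fit.chi2, df=fit.df, n=fit.n,
    )


@dataclass
class ModelComparison:
    table: pd.DataFrame  # one row per model, ascending BIC
    selected: str
    delta_bic: float
    decisive: bool


def compare_models(indexed_fits: dict[str, FitIndices], n: int | None = None) -> ModelComparison:
    """Rank models by BIC; the lowest-BIC model is selected and the choice is
    decisive when the gap to the runner-up exceeds 10."""
    if len(indexed_fits) < 2:
        raise ValueError("need at least two fitted models to compare")
    sizes = {fi.n for fi in indexed_fits.values() if fi.n}
    if len(sizes) > 1:
        raise ValueError(f"fits are on different sample sizes: {sorted(sizes)}")
    if n is not None and sizes and sizes != {n}:
        raise ValueError(f"fits are on n={sizes.pop()}, expected n={n}")
    rows = []
    for mid, fi in indexed_fits.items():
        row = {"model": mid}
        row.update(fi.as_row())
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("BIC", kind="mergesort").reset_index(drop=True)
    delta = float(table.loc[1, "BIC"] - table.loc[0, "BIC"])
    return ModelComparison(
        table=table,
        selected=str(table.loc[0, "model"]),
        delta_bic=delta,
        decisive=delta > 10.0,
    )


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------


class WlsCfa(BaseEstimator):
    """Ordinal confirmatory factor analysis estimator.

    Fits one of the four standard models (or a custom
    :class:`FactorModelSpec`) to an n x 12 ordinal item matrix by WLS on the
    polychoric correlation matrix.

    Parameters
    ----------
    model : str or FactorModelSpec, default "M2"
        Which measurement model to fit.
    weight : {"full", "diag", "identity"}, default "diag"
        WLS weighting: full bootstrap covariance metric, its diagonal, or
        unweighted least squares.  The full q x q metric needs a large n to
        be stable; the diagonal is the robust default.
    n_bootstrap : int, default 200
        Bootstrap resamples for the weight matrix (ignored for identity).
    n_starts : int, default 5
        Multi-start count for the optimizer.
    random_state : int, default 0

    Attributes
    ----------
    loadings_, factor_corr_, chi2_, df_, indices_, fit_, baseline_,
    correlation_estimate_
    """

    def __init__(self, model="M2", weight: str = "diag", n_bootstrap: int = 200,
                 n_starts: int = 5, random_state: int = 0):
        self.model = model
        self.weight = weight
        self.n_bootstrap = n_bootstrap
        self.n_starts = n_starts
        self.random_state = random_state

    def _spec(self) -> FactorModelSpec:
        if isinstance(self.model, FactorModelSpec):
            return self.model
        return build_standard_models()[self.model]

    def fit(self, X, y=None):
        if isinstance(X, CorrelationMatrixEstimate):
            est = X
        else:
            Xv = np.asarray(X)
            labels = list(X.columns) if isinstance(X, pd.DataFrame) else list(SYMPTOM_ITEMS)
            est = polychoric_matrix(Xv, item_labels=labels)
            if self.weight in ("full", "diag"):
                est.W, est.weight_meta = wls_weight(
                    Xv, n_bootstrap=self.n_bootstrap, seed=self.random_state
                )
        spec = self._spec()
        fit = fit_wls(est, spec, weight=self.weight, n_starts=self.n_starts,
                      seed=self.random_state)
        baseline = fit_independence(est, weight=self.weight)
        self.correlation_estimate_ = est
        self.fit_ = fit
        self.baseline_ = baseline
        self.indices_ = fit_indices(fit, baseline, est)
        self.loadings_ = fit.loadings
        self.factor_corr_ = fit.factor_corr
        self.chi2_ = fit.chi2
        self.df_ = fit.df
        self.n_features_in_ = 12
        return self
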