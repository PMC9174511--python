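"""Polychoric correlations, thresholds and the WLS weight matrix.

Ordinal questionnaire items are modelled as discretized bivariate-normal
latent responses: item category k is observed when the latent response falls
between thresholds tau_k and tau_{k+1}.  Estimation is two-step — thresholds
from the univariate margins (inverse normal CDF of cumulative proportions),
then the latent correlation rho by maximizing the bivariate-normal
orthant-probability likelihood of the observed cross-table.

The weight matrix W for weighted-least-squares factor analysis is the
covariance matrix of the vector of unique polychoric correlations, estimated
by a nonparametric bootstrap over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

#: Finite stand-in for an infinite threshold (cumulative proportion 0 or 1).
THRESHOLD_SENTINEL = 8.0

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)
_NORM_CONST = 1.0 / np.sqrt(2.0 * np.pi)


class DegenerateItemError(ValueError):
    """An item has all its mass in a single category."""


def estimate_thresholds(category_counts) -> np.ndarray:
    """Thresholds from marginal category counts (first estimation step).

    Threshold k is the standard-normal quantile of the cumulative proportion
    through category k; boundary proportions 0 / 1 map to -/+ a large finite
    sentinel so downstream quadrature stays well defined.
    """
    counts = np.asarray(category_counts, dtype=float)
    if counts.ndim != 1 or (counts < 0).any():
        raise ValueError("category_counts must be a 1-d nonnegative vector")
    total = counts.sum()
    if total <= 0:
        raise ValueError("category_counts must have positive total")
    if (counts > 0).sum() < 2:
        raise DegenerateItemError(
            "all observations fall in one category; thresholds undefined"
        )
    cum = np.cumsum(counts)[:-1] / total
    thr = np.where(
        cum <= 0.0,
        -THRESHOLD_SENTINEL,
        np.where(cum >= 1.0, THRESHOLD_SENTINEL, ndtri(np.clip(cum, 1e-12, 1 - 1e-12))),
    )
    return thr


def bivariate_cell_probs(row_thresholds, col_thresholds, rho: float) -> np.ndarray:
    """Cell probabilities of a discretized standard bivariate normal.

    Integrates phi(x) * [Phi((b_hi - rho x)/s) - Phi((b_lo - rho x)/s)] over
    each row interval with fixed Gauss-Legendre quadrature (s = sqrt(1-rho^2)),
    fully vectorized over cells.
    """
    a = np.concatenate(([-THRESHOLD_SENTINEL], np.asarray(row_thresholds, float),
                        [THRESHOLD_SENTINEL]))
    b = np.concatenate(([-THRESHOLD_SENTINEL], np.asarray(col_thresholds, float),
                        [THRESHOLD_SENTINEL]))
    a = np.clip(a, -THRESHOLD_SENTINEL, THRESHOLD_SENTINEL)
    b = np.clip(b, -THRESHOLD_SENTINEL, THRESHOLD_SENTINEL)
    lo, hi = a[:-1], a[1:]
    mid = 0.5 * (hi + lo)
    half = 0.5 * (hi - lo)
    x = mid[:, None] + half[:, None] * _GL_NODES[None, :]          # (r, m)
    w = half[:, None] * _GL_WEIGHTS[None, :]                        # (r, m)
    s = np.sqrt(max(1.0 - rho * rho, 1e-12))
    z = (b[None, None, :] - rho * x[:, :, None]) / s                # (r, m, c+1)
    inner = np.diff(ndtr(z), axis=2)                                # (r, m, c)
    dens = _NORM_CONST * np.exp(-0.5 * x * x)                       # (r, m)
    probs = np.einsum("rm,rm,rmc->rc", w, dens, inner)
    return np.clip(probs, 0.0, 1.0)


@dataclass(frozen=True)
class PolychoricResult:
    rho: float
    row_thresholds: np.ndarray
    col_thresholds: np.ndarray
    loglik: float
    converged: bool
    n: int


def polychoric_pair(table, max_abs_rho: float = 0.999) -> PolychoricResult:
    """Two-step polychoric correlation from an r x c contingency table.

    Thresholds come from the table margins; rho maximizes the multinomial
    log-likelihood of the cell counts under the discretized bivariate normal.
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (T < 0).any() or T.sum() < 1:
        raise ValueError("table must hold nonnegative counts with positive total")
    row_margin = T.sum(axis=1)
    col_margin = T.sum(axis=0)
    if (row_margin > 0).sum() < 2 or (col_margin > 0).sum() < 2:
        raise DegenerateItemError(
            "contingency table needs at least two nonempty rows and columns"
        )
    row_thr = estimate_thresholds(row_margin)
    col_thr = estimate_thresholds(col_margin)

    def neg_loglik(rho):
        probs = bivariate_cell_probs(row_thr, col_thr, rho)
        return -np.sum(T * np.log(np.clip(probs, 1e-300, None)))

    res = minimize_scalar(
        neg_loglik,
        bounds=(-max_abs_rho, max_abs_rho),
        method="bounded",
        options={"xatol": 1e-7, "maxiter": 200},
    )
    if not res.success:
        raise RuntimeError(
            f"polychoric optimization did not converge: {res.message}; "
            f"best rho={res.x:.4f}, nll={res.fun:.3f}"
        )
    return PolychoricResult(
        rho=float(res.x),
        row_thresholds=row_thr,
        col_thresholds=col_thr,
        loglik=float(-res.fun),
        converged=bool(res.success),
        n=int(T.sum()),
    )


def _crosstab(codes_i, codes_j, levels: int) -> np.ndarray:
    flat = np.bincount(codes_i * levels + codes_j, minlength=levels * levels)
    return flat.reshape(levels, levels).astype(float)


def _trim_levels(table: np.ndarray) -> np.ndarray:
    """Drop all-empty leading/trailing rows and columns (unused categories)."""
    rows = np.nonzero(table.sum(axis=1) > 0)[0]
    cols = np.nonzero(table.sum(axis=0) > 0)[0]
    return table[np.ix_(rows, cols)]


def nearest_psd_correlation(R: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Eigenvalue-clipped positive-semidefinite repair with unit diagonal."""
    vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
    vals = np.clip(vals, floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


@dataclass
class CorrelationMatrixEstimate:
    """Polychoric correlation matrix with thresholds and optional WLS weight."""

    R: np.ndarray
    thresholds: list
    n: int
    item_labels: list
    repaired: bool = False
    W: np.ndarray | None = None
    weight_meta: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.R.shape[0]

    def unique_correlations(self) -> np.ndarray:
        iu = np.triu_indices(self.p, k=1)
        return self.R[iu]


def polychoric_matrix(item_matrix, levels: int = 5, item_labels=None) -> CorrelationMatrixEstimate:
    """Pairwise polychoric correlation matrix of an n x p ordinal item matrix.

    Applies a nearest-PSD eigenvalue repair when sampling noise pushes the
    pairwise matrix indefinite (flagged on the result).
    """
    X = np.asarray(item_matrix)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("item_matrix must be n x p with p >= 2")
    n, p = X.shape
    codes = X.astype(np.int64)
    if (codes < 0).any() or (codes >= levels).any():
        raise ValueError(f"item scores must lie in 0..{levels - 1}")
    labels = list(item_labels) if item_labels is not None else [f"item{j}" for j in range(p)]

    thresholds = []
    for j in range(p):
        counts = np.bincount(codes[:, j], minlength=levels)
        if (counts > 0).sum() < 2:
            raise DegenerateItemError(f"item {labels[j]} is degenerate (single category)")
        thresholds.append(estimate_thresholds(counts))

    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            tab = _trim_levels(_crosstab(codes[:, i], codes[:, j], levels))
            R[i, j] = R[j, i] = polychoric_pair(tab).rho

    repaired = False
    if np.linalg.eigvalsh(R).min() < -1e-8:
        R = nearest_psd_correlation(R)
        repaired = True
    return CorrelationMatrixEstimate(
        R=R, thresholds=thresholds, n=n, item_labels=labels, repaired=repaired
    )


def wls_weight(
    item_matrix,
    n_bootstrap: int = 200,
    seed: int = 0,
    ridge: float = 1e-3,
    levels: int = 5,
) -> tuple[np.ndarray, dict]:
    """Bootstrap covariance matrix of the unique polychoric correlations.

    Resamples subjects with replacement ``n_bootstrap`` times, recomputes the
    full polychoric correlation matrix each time, and returns the sample
    covariance of the q = p(p-1)/2 correlation vector, ridge-stabilized as
    W + ridge * mean(diag W) * I.  Refuses fewer than 50 resamples.
    """
    if n_bootstrap < 50:
        raise ValueError("n_bootstrap < 50 gives an unstable weight matrix; refused")
    X = np.asarray(item_matrix)
    n, p = X.shape
    codes = X.astype(np.int64)
    q = p * (p - 1) // 2
    iu = np.triu_indices(p, k=1)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_bootstrap, q))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        sub = codes[idx]
        k = 0
        for i in range(p):
            for j in range(i + 1, p):
                tab = _trim_levels(_crosstab(sub[:, i], sub[:, j], levels))
                draws[b, k] = polychoric_pair(tab).rho
                k += 1
    W = np.cov(draws, rowvar=False)
    W = np.atleast_2d(W)
    scale = float(np.mean(np.diag(W)))
    W = W + ridge * scale * np.eye(q)
    meta = {"B": n_bootstrap, "seed": seed, "ridge": ridge, "n": n}
    return W, meta


class PolychoricCorrelation(BaseEstimator):
    """Polychoric correlation matrix estimator for ordinal item data.

    Parameters
    ----------
    levels : int, default 5
        Number of ordinal categories (scores 0..levels-1).
    compute_weight : bool, default False
        Also estimate the bootstrap WLS weight matrix over the unique
        correlations (needed by :class:`~itqnet.cfa.WlsCfa` full weighting).
    n_bootstrap : int, default 200
        Bootstrap resamples for the weight matrix.
    ridge : float, default 1e-3
        Relative ridge added to the weight matrix diagonal.
    random_state : int, default 0
        Bootstrap seed.

    Attributes
    ----------
    correlation_ : ndarray of shape (p, p)
        Polychoric correlation matrix (unit diagonal, PSD-repaired).
    thresholds_ : list of ndarray
        Estimated thresholds per item.
    weight_ : ndarray of shape (q, q) or None
        Bootstrap covariance of the unique correlations.
    repaired_ : bool
        Whether the PSD repair was applied.
    """

    def __init__(self, levels: int = 5, compute_weight: bool = False,
                 n_bootstrap: int = 200, ridge: float = 1e-3, random_state: int = 0):
        self.levels = levels
        self.compute_weight = compute_weight
        self.n_bootstrap = n_bootstrap
        self.ridge = ridge
        self.random_state = random_state

    def fit(self, X, y=None):
        import pandas as pd

        labels = list(X.columns) if isinstance(X, pd.DataFrame) else None
        est = polychoric_matrix(np.asarray(X), levels=self.levels, item_labels=labels)
        if self.compute_weight:
            W, meta = wls_weight(
                np.asarray(X),
                n_bootstrap=self.n_bootstrap,
                seed=self.random_state,
                ridge=self.ridge,
                levels=self.levels,
            )
            est.W = W
            est.weight_meta = meta
        self.estimate_ = est
        self.correlation_ = est.R
        self.thresholds_ = est.thresholds
        self.weight_ = est.W
        self.repaired_ = est.repaired
        self.n_features_in_ = est.p
        return self
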