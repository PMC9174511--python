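"""Regularized partial-correlation network of the 12 ITQ symptom items.

The network is a Gaussian graphical model estimated by the graphical lasso
over a path of L1 penalties, with the penalty selected by the Extended
Bayesian Information Criterion (EBIC, hyperparameter gamma, default 0.5).
Edge weights are the partial correlations implied by the selected precision
matrix K: rho_ij = -K_ij / sqrt(K_ii K_jj).

Centrality follows the psychometric-network conventions: distances are the
reciprocal absolute edge weights; betweenness uses Brandes' fractional
shortest-path counting; closeness is the reciprocal of the summed distances
to the other nodes (restricted to reachable nodes, with a disconnection
flag); strength is the sum of absolute incident weights and expected
influence its signed counterpart.  Values are reported raw and
z-standardized across nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from itqnet.constants import SYMPTOM_ITEMS
from itqnet.polychoric import nearest_psd_correlation, polychoric_matrix


@dataclass(frozen=True)
class NetworkConfig:
    """EBICglasso tuning: EBIC hyperparameter, penalty grid, input correlation."""

    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    correlation_input: str = "polychoric"

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.n_lambda < 1:
            raise ValueError("n_lambda must be positive")
        if self.correlation_input not in ("pearson", "polychoric"):
            raise ValueError("correlation_input must be 'pearson' or 'polychoric'")


def glasso_solve(S: np.ndarray, lam: float, tol: float = 1e-7) -> np.ndarray:
    """Graphical-lasso precision matrix for one penalty value.

    Maximizes log det K - tr(SK) - lam * sum_{i != j} |K_ij| over symmetric
    positive-definite K (the diagonal is unpenalized).  Ridge-repairs an
    indefinite input correlation matrix first.
    """
    S = np.asarray(S, dtype=float)
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    if np.linalg.eigvalsh(S).min() < 1e-10:
        S = nearest_psd_correlation(S, floor=1e-8)
    if lam == 0:
        return np.linalg.inv(S)
    try:
        with warnings.catch_warnings():
            # near-zero negative dual gaps trip sklearn's warning even when
            # the solution is essentially exact
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, K = graphical_lasso(S, alpha=lam, tol=tol, enet_tol=tol, max_iter=1000)
    except FloatingPointError as exc:  # pragma: no cover - solver diagnostics
        raise RuntimeError(f"graphical lasso failed to converge at lambda={lam}: {exc}")
    return (K + K.T) / 2.0


def precision_to_partial(K: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix; zero diagonal."""
    K = np.asarray(K, dtype=float)
    if np.linalg.eigvalsh(K).min() <= 0:
        raise ValueError("precision matrix must be positive-definite")
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return P


def ebic(K: np.ndarray, S: np.ndarray, n: int, gamma: float) -> float:
    """Extended BIC of a Gaussian graphical model:
    -2 * (n/2)(log det K - tr(SK)) + E ln n + 4 gamma E ln p, where E is the
    number of nonzero upper-triangle edges."""
    p = K.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return np.inf
    loglik = (n / 2.0) * (logdet - np.trace(S @ K))
    E = int(np.count_nonzero(np.triu(K, k=1)))
    return float(-2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p))


@dataclass
class GaussianNetwork:
    """Selected partial-correlation network."""

    nodes: list
    weights: np.ndarray  # symmetric, zero diagonal
    precision: np.ndarray
    lambda_selected: float
    ebic_at_selection: float
    n: int
    meta: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if w != 0:
                    rows.append({"source": self.nodes[i], "target": self.nodes[j], "weight": w})
        return pd.DataFrame(rows, columns=["source", "target", "weight"])

    def to_graph(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if w != 0:
                    G.add_edge(self.nodes[i], self.nodes[j],
                               weight=w, distance=1.0 / abs(w))
        return G


def estimate_network(
    data=None,
    correlation: np.ndarray | None = None,
    n: int | None = None,
    config: NetworkConfig | None = None,
) -> GaussianNetwork:
    """EBICglasso network estimation.

    Either raw item ``data`` (n x p) or a precomputed ``correlation`` matrix
    with its sample size ``n`` must be given.  A log-spaced grid of
    ``n_lambda`` penalties from lambda_max (the largest absolute off-diagonal
    correlation) down to lambda_max * lambda_min_ratio is solved; the
    minimum-EBIC solution is returned.
    """
    config = config or NetworkConfig()
    if correlation is None:
        if data is None:
            raise ValueError("provide item data or a correlation matrix with n")
        X = np.asarray(data)
        labels = list(data.columns) if isinstance(data, pd.DataFrame) else None
        n = X.shape[0]
        if n <= X.shape[1]:
            raise ValueError("need more observations than variables")
        if config.correlation_input == "polychoric":
            correlation = polychoric_matrix(X, item_labels=labels).R
        else:
            correlation = np.corrcoef(X, rowvar=False)
    else:
        if n is None:
            raise ValueError("a precomputed correlation matrix requires n")
        labels = None
    S = np.asarray(correlation, dtype=float)
    p = S.shape[0]
    nodes = labels if labels is not None else (
        list(SYMPTOM_ITEMS) if p == 12 else [f"node{j}" for j in range(p)]
    )
    off = np.abs(S[np.triu_indices(p, 1)])
    lam_max = float(off.max())
    if lam_max == 0:
        raise ValueError("all off-diagonal correlations are zero; nothing to estimate")
    grid = np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)
    # coarse solves along the path for EBIC ranking, then a tight re-solve
    # of the selected penalty
    best = None
    for lam in grid:
        K = glasso_solve(S, float(lam), tol=1e-5)
        crit = ebic(K, S, n, config.gamma)
        if best is None or crit < best[0]:
            best = (crit, float(lam), K)
    _, lam_sel, _ = best
    K_sel = glasso_solve(S, lam_sel)
    crit = ebic(K_sel, S, n, config.gamma)
    weights = precision_to_partial(K_sel)
    weights[np.abs(weights) < 1e-10] = 0.0
    return GaussianNetwork(
        nodes=nodes,
        weights=weights,
        precision=K_sel,
        lambda_selected=lam_sel,
        ebic_at_selection=crit,
        n=n,
        meta={
            "gamma": config.gamma,
            "n_lambda": config.n_lambda,
            "lambda_min_ratio": config.lambda_min_ratio,
            "lambda_max": lam_max,
            "correlation_input": config.correlation_input,
        },
    )


def network_sparsity(net: GaussianNetwork) -> float:
    """Share of absent edges among the p(p-1)/2 node pairs."""
    p = net.p
    total = p * (p - 1) // 2
    nonzero = int(np.count_nonzero(np.triu(net.weights, k=1)))
    return float((total - nonzero) / total)


def centrality_measures(net: GaussianNetwork) -> pd.DataFrame:
    """Raw and z-standardized centrality indices per node.

    Columns: ``betweenness``, ``closeness``, ``strength``,
    ``expected_influence`` and their ``*_z`` counterparts, plus a
    ``disconnected`` flag for nodes that cannot reach every other node.
    Distances are 1/|weight|; closeness sums distances over reachable nodes
    only.  z-standardization uses the across-node mean and (ddof=1) SD.
    """
    if net.p < 2:
        raise ValueError("centrality needs at least 2 nodes")
    G = net.to_graph()
    nodes = net.nodes
    btw = nx.betweenness_centrality(G, weight="distance", normalized=False)
    lengths = dict(nx.all_pairs_dijkstra_path_length(G, weight="distance"))
    closeness, disconnected = {}, {}
    for v in nodes:
        d = lengths.get(v, {v: 0.0})
        reach = [val for u, val in d.items() if u != v]
        disconnected[v] = len(reach) < len(nodes) - 1
        closeness[v] = 1.0 / sum(reach) if reach else 0.0
    W = net.weights
    strength = {v: float(np.abs(W[i]).sum()) for i, v in enumerate(nodes)}
    expected = {v: float(W[i].sum()) for i, v in enumerate(nodes)}

    out = pd.DataFrame(
        {
            "betweenness": [btw[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "strength": [strength[v] for v in nodes],
            "expected_influence": [expected[v] for v in nodes],
            "disconnected": [disconnected[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    for col in ("betweenness", "closeness", "strength", "expected_influence"):
        x = out[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        out[f"{col}_z"] = (x - x.mean()) / sd if sd > 0 else 0.0
    return out


class EbicGlassoNetwork(BaseEstimator):
    """Scikit-learn style EBICglasso network estimator.

    Parameters mirror :class:`NetworkConfig`; ``fit`` accepts an n x p item
    matrix (DataFrame columns become node labels).

    Attributes
    ----------
    network_ : GaussianNetwork
    weights_ : ndarray — selected partial-correlation matrix.
    precision_ : ndarray
    lambda_ : float — selected penalty.
    sparsity_ : float
    centrality_ : DataFrame
    """

    def __init__(self, gamma: float = 0.5, n_lambda: int = 100,
                 lambda_min_ratio: float = 0.01, correlation_input: str = "polychoric"):
        self.gamma = gamma
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.correlation_input = correlation_input

    def _config(self) -> NetworkConfig:
        return NetworkConfig(
            gamma=self.gamma,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            correlation_input=self.correlation_input,
        )

    def fit(self, X, y=None):
        net = estimate_network(data=X, config=self._config())
        self.network_ = net
        self.weights_ = net.weights
        self.precision_ = net.precision
        self.lambda_ = net.lambda_selected
        self.sparsity_ = network_sparsity(net)
        self.centrality_ = centrality_measures(net)
        self.n_features_in_ = net.p
        return self

    def fit_from_correlation(self, S: np.ndarray, n: int):
        net = estimate_network(correlation=S, n=n, config=self._config())
        self.network_ = net
        self.weights_ = net.weights
        self.precision_ = net.precision
        self.lambda_ = net.lambda_selected
        self.sparsity_ = network_sparsity(net)
        self.centrality_ = centrality_measures(net)
        self.n_features_in_ = net.p
        return self
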