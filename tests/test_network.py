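"""Graphical lasso, EBIC selection, partial correlations, centrality."""

import itertools

import numpy as np
import pandas as pd
import pytest

from itqnet.network import (
    EbicGlassoNetwork,
    GaussianNetwork,
    NetworkConfig,
    centrality_measures,
    ebic,
    estimate_network,
    glasso_solve,
    network_sparsity,
    precision_to_partial,
)


def _random_correlation(p, seed, n=200):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p)) + 0.5 * rng.standard_normal((n, 1))
    return np.corrcoef(X, rowvar=False)


def _net_from_weights(W, n=1000):
    p = W.shape[0]
    K = np.eye(p)  # placeholder precision; weights drive the graph methods
    return GaussianNetwork(
        nodes=[f"n{i}" for i in range(p)], weights=W, precision=K,
        lambda_selected=0.1, ebic_at_selection=0.0, n=n,
    )


# ---------------------------------------------------------------------------
# glasso solver
# ---------------------------------------------------------------------------


def test_full_shrinkage_gives_diagonal_precision():
    S = _random_correlation(6, 1)
    lam = np.abs(S - np.eye(6)).max() * 1.01
    K = glasso_solve(S, lam)
    assert np.allclose(K - np.diag(np.diag(K)), 0.0, atol=1e-7)


def test_zero_penalty_returns_inverse():
    S = _random_correlation(5, 2)
    K = glasso_solve(S, 0.0)
    assert np.allclose(K, np.linalg.inv(S), atol=1e-6)


def test_objective_matches_direct_optimizer_p3():
    """p=3: glasso objective value agrees with brute-force numerical
    maximization over symmetric PD matrices within 1e-5."""
    from scipy.optimize import minimize

    S = _random_correlation(3, 3)
    lam = 0.1
    K = glasso_solve(S, lam)

    def negobj(x):
        M = np.array([[x[0], x[3], x[4]], [x[3], x[1], x[5]], [x[4], x[5], x[2]]])
        vals = np.linalg.eigvalsh(M)
        if vals.min() <= 1e-8:
            return 1e6
        _, logdet = np.linalg.slogdet(M)
        return -(logdet - np.trace(S @ M) - lam * 2 * np.abs(x[3:]).sum())

    x0 = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    res = minimize(negobj, x0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    ours = -negobj(np.array([K[0, 0], K[1, 1], K[2, 2], K[0, 1], K[0, 2], K[1, 2]]))
    assert ours == pytest.approx(-res.fun, abs=1e-5)


def test_kkt_conditions_at_solution():
    """Subgradient optimality: |S_ij - (K^-1)_ij| <= lam for zero edges,
    = lam (sign-matched) for active edges."""
    S = _random_correlation(8, 4)
    lam = 0.08
    K = glasso_solve(S, lam, tol=1e-9)
    Sigma = np.linalg.inv(K)
    G = Sigma - S
    for i in range(8):
        for j in range(i + 1, 8):
            if K[i, j] == 0:
                assert abs(G[i, j]) <= lam + 1e-4
            else:
                assert G[i, j] * np.sign(K[i, j]) == pytest.approx(-lam, abs=1e-4) or \
                    abs(abs(G[i, j]) - lam) < 1e-4


def test_negative_penalty_rejected():
    with pytest.raises(ValueError):
        glasso_solve(np.eye(3), -0.1)


# ---------------------------------------------------------------------------
# partial correlations
# ---------------------------------------------------------------------------


def test_identity_precision_zero_partials():
    assert np.allclose(precision_to_partial(np.eye(4)), 0.0)


def test_two_by_two_closed_form():
    K = np.array([[2.0, -0.6], [-0.6, 1.5]])
    P = precision_to_partial(K)
    assert P[0, 1] == pytest.approx(0.6 / np.sqrt(2.0 * 1.5))


def test_partials_match_regression_residual_oracle():
    """p=4: partial correlation equals the correlation of the residuals of
    i and j regressed on all remaining variables."""
    rng = np.random.default_rng(5)
    A = rng.standard_normal((4, 6))
    Sigma = A @ A.T + 4 * np.eye(4)
    K = np.linalg.inv(Sigma)
    P = precision_to_partial(K)
    n = 2_000_000
    X = rng.multivariate_normal(np.zeros(4), Sigma, size=n)
    for i, j in itertools.combinations(range(4), 2):
        others = [k for k in range(4) if k not in (i, j)]
        Z = np.column_stack([np.ones(n), X[:, others]])
        beta_i, *_ = np.linalg.lstsq(Z, X[:, i], rcond=None)
        beta_j, *_ = np.linalg.lstsq(Z, X[:, j], rcond=None)
        ri = X[:, i] - Z @ beta_i
        rj = X[:, j] - Z @ beta_j
        assert np.corrcoef(ri, rj)[0, 1] == pytest.approx(P[i, j], abs=2e-3)


def test_partials_exact_population_identity():
    """Deterministic version of the residual oracle via Schur complements."""
    rng = np.random.default_rng(6)
    A = rng.standard_normal((4, 5))
    Sigma = A @ A.T + 3 * np.eye(4)
    K = np.linalg.inv(Sigma)
    P = precision_to_partial(K)
    for i, j in itertools.combinations(range(4), 2):
        others = [k for k in range(4) if k not in (i, j)]
        S11 = Sigma[np.ix_([i, j], [i, j])]
        S12 = Sigma[np.ix_([i, j], others)]
        S22 = Sigma[np.ix_(others, others)]
        cond = S11 - S12 @ np.linalg.solve(S22, S12.T)
        expected = cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])
        assert P[i, j] == pytest.approx(expected, abs=1e-9)


def test_non_pd_precision_rejected():
    with pytest.raises(ValueError):
        precision_to_partial(np.array([[1.0, 2.0], [2.0, 1.0]]))


# ---------------------------------------------------------------------------
# EBIC selection
# ---------------------------------------------------------------------------


def _sparse_precision(p, n_edges, seed, weight=0.35):
    rng = np.random.default_rng(seed)
    K = np.eye(p)
    pairs = list(itertools.combinations(range(p), 2))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    for c in chosen:
        i, j = pairs[c]
        K[i, j] = K[j, i] = weight * rng.choice([-1, 1])
    # diagonal dominance keeps K PD
    K += np.eye(p) * max(0.0, -np.linalg.eigvalsh(K).min() + 0.1)
    d = np.sqrt(np.diag(K))
    return K / np.outer(d, d)


def test_network_determinism(small_cohort):
    from itqnet.constants import SYMPTOM_ITEMS

    X = small_cohort[list(SYMPTOM_ITEMS)]
    a = EbicGlassoNetwork(n_lambda=40).fit(X)
    b = EbicGlassoNetwork(n_lambda=40).fit(X)
    assert np.array_equal(a.weights_, b.weights_)
    assert a.lambda_ == b.lambda_


def test_gamma_monotone_edge_count():
    """Larger EBIC gamma never yields more edges; a huge gamma on weak data
    gives a near-empty network."""
    rng = np.random.default_rng(7)
    K = _sparse_precision(10, 8, seed=8, weight=0.15)
    X = rng.multivariate_normal(np.zeros(10), np.linalg.inv(K), size=300)
    S = np.corrcoef(X, rowvar=False)
    edges = []
    for gamma in (0.0, 0.5, 10.0):
        net = estimate_network(correlation=S, n=300,
                               config=NetworkConfig(gamma=gamma, n_lambda=40))
        edges.append(np.count_nonzero(np.triu(net.weights, 1)))
    assert edges[0] >= edges[1] >= edges[2]
    assert edges[2] <= 3


def test_edge_count_monotone_along_lambda_path():
    S = _random_correlation(8, 9)
    lam_max = np.abs(S - np.eye(8)).max()
    counts = [
        np.count_nonzero(np.triu(glasso_solve(S, lam), 1))
        for lam in np.geomspace(lam_max, lam_max * 0.02, 25)
    ]
    assert all(a <= b + 1 for a, b in zip(counts, counts[1:]))  # tiny solver slack


def test_sparsity_definition():
    W = np.zeros((12, 12))
    assert network_sparsity(_net_from_weights(W)) == 1.0
    # 46 nonzero of 66 pairs -> sparsity 20/66 = 0.303 (prints as 0.31 like
    # the published network)
    pairs = list(itertools.combinations(range(12), 2))
    for i, j in pairs[:46]:
        W[i, j] = W[j, i] = 0.1
    assert network_sparsity(_net_from_weights(W)) == pytest.approx(20 / 66)
    for i, j in pairs:
        W[i, j] = W[j, i] = 0.1
    assert network_sparsity(_net_from_weights(W)) == 0.0


# ---------------------------------------------------------------------------
# centrality
# ---------------------------------------------------------------------------


def test_three_node_path_hand_counts():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.5
    W[1, 2] = W[2, 1] = 0.5
    c = centrality_measures(_net_from_weights(W))
    assert list(c["betweenness"]) == [0.0, 1.0, 0.0]
    assert list(c["strength"]) == [0.5, 1.0, 0.5]
    # closeness: node 0 -> distances 2, 4; node 1 -> 2, 2
    assert c["closeness"].iloc[0] == pytest.approx(1 / 6)
    assert c["closeness"].iloc[1] == pytest.approx(1 / 4)


def test_expected_influence_equals_strength_for_positive_weights():
    rng = np.random.default_rng(10)
    W = np.abs(_random_correlation(6, 11) - np.eye(6)) * 0.3
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    c = centrality_measures(_net_from_weights(W))
    assert np.allclose(c["expected_influence"], c["strength"])


def test_z_scores_standardized():
    W = np.abs(_random_correlation(12, 12) - np.eye(12)) * 0.2
    np.fill_diagonal(W, 0.0)
    c = centrality_measures(_net_from_weights(W))
    for col in ("betweenness_z", "closeness_z", "strength_z"):
        assert c[col].mean() == pytest.approx(0.0, abs=1e-12)
        assert c[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def brute_force_centrality(W):
    """Exhaustive simple-path enumeration oracle for betweenness (fractional
    counting) and closeness on a weighted graph with distances 1/|w|."""
    p = W.shape[0]
    with np.errstate(divide="ignore"):
        D = np.where(W != 0, 1.0 / np.abs(W), np.inf)
    nodes = range(p)
    best = {}
    paths = {}
    for s, t in itertools.combinations(nodes, 2):
        records = []
        inner = [v for v in nodes if v not in (s, t)]
        for r in range(len(inner) + 1):
            for mid in itertools.permutations(inner, r):
                path = (s, *mid, t)
                length = sum(D[a][b] for a, b in zip(path, path[1:]))
                if np.isfinite(length):
                    records.append((length, path))
        if not records:
            continue
        dmin = min(r[0] for r in records)
        best[(s, t)] = dmin
        paths[(s, t)] = [r[1] for r in records if r[0] <= dmin + 1e-12]
    btw = np.zeros(p)
    for (s, t), plist in paths.items():
        for path in plist:
            for v in path[1:-1]:
                btw[v] += 1.0 / len(plist)
    close = np.zeros(p)
    for v in nodes:
        tot = sum(best.get((min(v, u), max(v, u)), np.inf)
                  for u in nodes if u != v and (min(v, u), max(v, u)) in best)
        close[v] = 1.0 / tot if tot > 0 else 0.0
    return btw, close


@pytest.mark.parametrize("seed", range(10))
def test_centrality_matches_brute_force_enumeration(seed):
    """Random sparse 8-node weighted graphs: Brandes betweenness equals the
    exhaustive simple-path count exactly; closeness to 1e-9.  (A wider
    100-seed sweep runs in the acceptance suite.)"""
    rng = np.random.default_rng(seed)
    p = 8
    W = np.zeros((p, p))
    for i, j in itertools.combinations(range(p), 2):
        if rng.random() < 0.45:
            W[i, j] = W[j, i] = rng.uniform(0.1, 0.9) * rng.choice([-1, 1])
    net = _net_from_weights(W)
    c = centrality_measures(net)
    btw, close = brute_force_centrality(W)
    assert np.allclose(c["betweenness"], btw, atol=1e-9)
    assert np.allclose(c["closeness"], close, atol=1e-9)


def test_disconnected_node_flagged():
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = 0.5
    c = centrality_measures(_net_from_weights(W))
    assert c["disconnected"].all()
    assert c.loc["n3", "closeness"] == 0.0


# ---------------------------------------------------------------------------
# structural recovery
# ---------------------------------------------------------------------------


def test_two_cluster_structure_recovered():
    """Items from two correlated factor blocks: within-block mean edge
    weight exceeds between-block, mirroring the separation of core-PTSD and
    DSO symptom clusters."""
    rng = np.random.default_rng(20)
    n = 3000
    f = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=n)
    lam = 0.8
    X = np.empty((n, 12))
    for j in range(12):
        block = 0 if j < 6 else 1
        X[:, j] = lam * f[:, block] + np.sqrt(1 - lam**2) * rng.standard_normal(n)
    S = np.corrcoef(X, rowvar=False)
    net = estimate_network(correlation=S, n=n, config=NetworkConfig(n_lambda=40))
    W = net.weights
    within, between = [], []
    for i, j in itertools.combinations(range(12), 2):
        (within if (i < 6) == (j < 6) else between).append(W[i, j])
    assert np.mean(within) > np.mean(between)


def test_degenerate_input_rejected():
    X = np.ones((50, 3))
    with pytest.raises(Exception):
        estimate_network(data=X)
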