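"""Synthetic cohort generator: determinism, marginals, exposure calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from itqnet.constants import PERIODS, SYMPTOM_ITEMS, exposure_column
from itqnet.datagen import (
    SimulationConfig,
    default_config,
    generate_cohort,
    generate_exposures,
    per_item_probability,
    sample_ordinal_items,
)
from itqnet.polychoric import polychoric_pair
from itqnet.scoring import diagnose_table, classify_exposures


def _null_config(**overrides):
    """No exposures, no exposure effects: pure measurement model."""
    probs = {k: 0.0 for k in default_config().exposure_probs}
    effects = {"intentional": np.zeros(6), "unintentional": np.zeros(6)}
    return default_config(exposure_probs=probs, exposure_effects=effects, **overrides)


def test_same_seed_identical_tables():
    cfg = default_config(n_subjects=300, seed=9)
    a, b = generate_cohort(cfg), generate_cohort(default_config(n_subjects=300, seed=9))
    pd.testing.assert_frame_equal(a, b)
    assert a.to_csv() == b.to_csv()


def test_null_config_has_no_exposures_and_threshold_marginals():
    """With all exposure probabilities zero no flag is set (excluded items
    use a fixed small probability, so only non-excluded are checked), and
    symptom marginals match the normal orthant probabilities of the
    thresholds within Monte-Carlo error (4 SE familywise across the 60
    simultaneous category comparisons; ~3 SE is the single-comparison
    equivalent)."""
    cfg = _null_config(n_subjects=20_000, seed=10)
    tab = generate_cohort(cfg)
    non_excluded = [exposure_column(i, p) for i in
                    [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 14, 15, 16, 17, 18, 19, 20, 21]
                    for p in PERIODS]
    assert not tab[non_excluded].to_numpy().any()
    n = cfg.n_subjects
    for j, item in enumerate(SYMPTOM_ITEMS):
        cuts = np.concatenate(([0.0], ndtr(cfg.thresholds[j]), [1.0]))
        expected = np.diff(cuts)
        observed = np.bincount(tab[item], minlength=5) / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert (np.abs(observed - expected) <= 4 * se + 1e-12).all(), item


def test_validation_rejects_bad_factor_corr():
    phi = np.full((6, 6), 0.99)
    np.fill_diagonal(phi, 1.0)
    phi[0, 1] = phi[1, 0] = -0.99  # indefinite
    with pytest.raises(ValueError, match="factor_corr"):
        default_config(factor_corr=phi)


def test_validation_rejects_nonincreasing_thresholds():
    thr = default_config().thresholds.copy()
    thr[3, 2] = thr[3, 1]
    with pytest.raises(ValueError, match="thresholds"):
        default_config(thresholds=thr)


def test_exposure_effect_raises_diagnosis_rate_vs_monte_carlo_oracle():
    """A +1.0 intentional latent shift must raise cPTSD among the exposed;
    direction cross-checked with a direct large-n Monte-Carlo recomputation
    of the generative model, written independently of generate_cohort."""
    cfg = default_config(
        n_subjects=5000,
        seed=11,
        exposure_effects={"intentional": np.ones(6), "unintentional": np.zeros(6)},
    )
    tab = generate_cohort(cfg)
    scored = diagnose_table(tab, tab["trauma_exposed"])
    exposed = classify_exposures(tab)["intentional_lifetime"].to_numpy()
    dx = pd.Series(scored)
    rate = lambda m: (dx[m] == "cPTSD").mean()
    assert rate(exposed) > rate(~exposed)

    # independent oracle: direct simulation of the latent chain at n=100k
    rng = np.random.default_rng(1234)
    n = 100_000
    chol = np.linalg.cholesky(cfg.factor_corr)

    def cptsd_rate(shift):
        eta = rng.standard_normal((n, 6)) @ chol.T + shift
        lam = cfg.loadings
        resp = eta[:, np.repeat(np.arange(6), 2)] * lam + np.sqrt(1 - lam**2) * rng.standard_normal((n, 12))
        items = (resp[:, :, None] > cfg.thresholds[None]).sum(axis=2)
        a = cfg.impairment_composite_loading
        comp = np.empty((n, 2))
        for b, block in enumerate((slice(0, 3), slice(3, 6))):
            g = eta[:, block].mean(axis=1) / np.sqrt(cfg.factor_corr[block, block].sum() / 9)
            comp[:, b] = a * g + np.sqrt(1 - a * a) * rng.standard_normal(n)
        ilam = cfg.impairment_loadings
        iresp = comp[:, np.repeat([0, 1], 3)] * ilam + np.sqrt(1 - ilam**2) * rng.standard_normal((n, 6))
        imp = (iresp[:, :, None] > cfg.impairment_thresholds[None]).sum(axis=2)
        E = np.hstack([items, imp]) >= 2
        clusters = lambda idx: np.logical_and.reduce([E[:, i] | E[:, i + 1] for i in idx])
        ptsd = clusters([0, 2, 4]) & E[:, 12:15].any(axis=1)
        return (ptsd & clusters([6, 8, 10]) & E[:, 15:18].any(axis=1)).mean()

    assert cptsd_rate(1.0) > cptsd_rate(0.0)


def test_gender_differential_intentional_exposure_rates():
    """Default config reproduces the target any-lifetime intentional rates
    (67.47% female / 53.69% male) within 3 percentage points."""
    tab = generate_cohort(default_config(n_subjects=4000, seed=12))
    cls = classify_exposures(tab)
    rates = cls["intentional_lifetime"].groupby(tab["gender"]).mean()
    assert abs(rates["female"] - 0.6747) < 0.03
    assert abs(rates["male"] - 0.5369) < 0.03


def test_generate_exposures_degenerate_probs():
    rng = np.random.default_rng(0)
    gender = np.array(["male", "female"] * 50)
    zero = {k: 0.0 for k in default_config().exposure_probs}
    flags = generate_exposures(100, gender, zero, rng)
    non_excluded = [c for c in flags.columns if not c.startswith(("item12", "item13"))]
    assert not flags[non_excluded].to_numpy().any()

    one = dict(zero)
    one[("intentional", "childhood", "male")] = 1.0
    one[("intentional", "childhood", "female")] = 1.0
    flags = generate_exposures(100, gender, one, np.random.default_rng(0))
    assert flags[exposure_column(4, "childhood")].all()  # an intentional item


def test_generate_exposures_length_mismatch():
    with pytest.raises(ValueError, match="gender"):
        generate_exposures(10, np.array(["male"] * 9), {}, np.random.default_rng(0))


def test_zero_loading_gives_independent_item():
    rng = np.random.default_rng(3)
    latent = rng.standard_normal((10_000, 1))
    thr = np.array([[-1.0, 0.0, 1.0, 2.0]])
    items = sample_ordinal_items(latent, np.array([0.0]), thr, np.array([0]), rng)
    r = np.corrcoef(latent[:, 0], items[:, 0])[0, 1]
    assert abs(r) < 0.03


def test_known_threshold_category_proportions():
    """Thresholds (-0.6745, 0, 0.6745, 1.5) on a standard-normal response
    give proportions ~ (0.25, 0.25, 0.25, 0.1832, 0.0668)."""
    rng = np.random.default_rng(4)
    n = 200_000
    latent = rng.standard_normal((n, 1))
    thr = np.array([[-0.6745, 0.0, 0.6745, 1.5]])
    # loading ~0: response is the unique error, standard normal
    items = sample_ordinal_items(latent, np.array([1e-9]), thr, np.array([0]), rng)
    props = np.bincount(items[:, 0], minlength=5) / n
    expected = np.diff(np.concatenate(([0.0], ndtr(thr[0]), [1.0])))
    assert np.allclose(props, expected, atol=0.005)


def test_product_of_loadings_polychoric_identity():
    """Two items with loading 0.8 on the same factor: their polychoric
    correlation converges to 0.64."""
    rng = np.random.default_rng(5)
    latent = rng.standard_normal((20_000, 1))
    thr = np.tile(np.array([-0.6, 0.1, 0.9, 1.7]), (2, 1))
    items = sample_ordinal_items(
        latent, np.array([0.8, 0.8]), thr, np.array([0, 0]), rng
    )
    tab = pd.crosstab(items[:, 0], items[:, 1]).to_numpy()
    assert polychoric_pair(tab).rho == pytest.approx(0.64, abs=0.03)


def test_loading_out_of_range_rejected():
    rng = np.random.default_rng(0)
    latent = rng.standard_normal((10, 1))
    thr = np.array([[-1.0, 0.0, 1.0, 2.0]])
    with pytest.raises(ValueError, match="loading"):
        sample_ordinal_items(latent, np.array([1.2]), thr, np.array([0]), rng)


def test_lambda_phi_lambda_convergence():
    """With zero exposure effects the item polychoric correlations converge
    to the off-diagonal of Lambda Phi Lambda' (checked within +/- 0.03 on a
    spread of pairs at n=20,000)."""
    cfg = _null_config(n_subjects=20_000, seed=13)
    tab = generate_cohort(cfg)
    lam = cfg.loadings
    phi_items = cfg.factor_corr[np.repeat(np.arange(6), 2)][:, np.repeat(np.arange(6), 2)]
    target = np.outer(lam, lam) * phi_items
    items = tab[list(SYMPTOM_ITEMS)].to_numpy()
    pairs = [(0, 1), (0, 3), (2, 5), (4, 9), (6, 7), (10, 11), (1, 8), (3, 11)]
    for i, j in pairs:
        tabij = pd.crosstab(items[:, i], items[:, j]).to_numpy()
        rho = polychoric_pair(tabij).rho
        assert rho == pytest.approx(target[i, j], abs=0.03), (i, j)


def test_missingness_configurable():
    tab = generate_cohort(default_config(n_subjects=500, seed=14, missing_rate=0.1))
    frac = tab[list(SYMPTOM_ITEMS)].isna().to_numpy().mean()
    assert 0.05 < frac < 0.15
    scored = diagnose_table(tab, tab["trauma_exposed"])
    assert pd.isna(scored).any()


def test_per_item_probability_roundtrip():
    q = per_item_probability(0.6747, 13)
    assert 1 - (1 - q) ** (13 * 3) == pytest.approx(0.6747, abs=1e-12)


def test_config_json_roundtrip_records_seed():
    import json

    cfg = default_config(n_subjects=50, seed=77)
    obj = json.loads(cfg.to_json())
    assert obj["seed"] == 77
    assert obj["n_subjects"] == 50
    assert len(obj["loadings"]) == 12
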