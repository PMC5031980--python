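import warnings

import numpy as np
import pandas as pd
import pytest

from bluefinhab.gam import BinomialGAMM
from bluefinhab.surfaces import (
    LikelihoodGrid,
    choose_cutoff,
    predict_surface,
    spawning_habitat_product,
)


@pytest.fixture(scope="module")
def fitted_sst_model(small_env):
    rng = np.random.default_rng(0)
    n = 600
    sst = rng.uniform(20, 29, n)
    y = rng.uniform(size=n) < 1 / (1 + np.exp(-(sst - 24.5)))
    table = pd.DataFrame(
        {
            "sst": sst, "sst_sd": 0.5, "log_chl": 0.0, "ssha": 0.0, "ssha_sd": 4.0,
            "log_eke": -4.6, "wekman": 0.0, "uy10": -2.0, "bathy": -1000.0,
            "bathy_sd": 5.0, "moon": 0.5,
            "tag_id": np.repeat([f"f{i}" for i in range(6)], n // 6),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return BinomialGAMM(terms=("sst",)).fit(
            table, y.astype(int), groups=table["tag_id"]
        )


def test_uniform_environment_gives_uniform_surface(uniform_env, fitted_sst_model):
    grid = predict_surface(fitted_sst_model, uniform_env, "2010-04-01")
    vals = grid.values[grid.valid_mask]
    assert vals.size > 0
    np.testing.assert_allclose(vals, vals[0], atol=1e-12)


def test_surface_cell_matches_inverse_logit_of_term_sum(small_env, fitted_sst_model):
    grid = predict_surface(fitted_sst_model, small_env, "2010-05-01")
    i, j = 20, 30
    assert np.isfinite(grid.values[i, j])
    midpoint = pd.Timestamp("2010-05-01") + pd.Timedelta(days=3)
    sst = small_env.value_at("sst", small_env.lons[j], small_env.lats[i], midpoint)
    est = fitted_sst_model
    eta = est.coef_[0] + est.partial_effect("sst", [sst])[0]
    assert grid.values[i, j] == pytest.approx(1 / (1 + np.exp(-eta)), abs=1e-10)


def test_all_land_mask_gives_all_missing_grid(small_env, fitted_sst_model):
    mask = np.zeros_like(small_env.water_mask)
    grid = predict_surface(fitted_sst_model, small_env, "2010-05-01", mask=mask)
    assert not grid.valid_mask.any()


def test_ensemble_mean_surface_within_member_envelope(small_env, fitted_sst_model):
    grids = [
        predict_surface([fitted_sst_model] * 3, small_env, "2010-05-01"),
        predict_surface(fitted_sst_model, small_env, "2010-05-01"),
    ]
    mean_grid, single = grids
    ok = mean_grid.valid_mask
    np.testing.assert_allclose(mean_grid.values[ok], single.values[ok], atol=1e-12)
    assert mean_grid.sd is not None
    np.testing.assert_allclose(mean_grid.sd[ok], 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# ROC cutoffs
# ---------------------------------------------------------------------------

def test_cutoff_perfectly_separated_scores():
    scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
    y = np.array([0, 0, 0, 1, 1, 1])
    thr = choose_cutoff(scores, y, max_fpr=0.05)
    assert 0.3 < thr <= 0.7
    assert (scores[y == 0] >= thr).mean() == 0.0  # FPR 0
    assert (scores[y == 1] >= thr).mean() == 1.0  # TPR 1


def test_cutoff_hand_built_roc_case():
    # enumerating thresholds: only t = 0.8 reaches FPR 1/3 <= 0.34 with TPR 1
    scores = np.array([0.1, 0.2, 0.9, 0.8, 0.95])
    y = np.array([0, 0, 0, 1, 1])
    thr = choose_cutoff(scores, y, max_fpr=0.34)
    assert thr == pytest.approx(0.8)


def test_cutoff_all_scores_identical_warns_and_returns_max():
    with pytest.warns(UserWarning, match="no threshold"):
        thr = choose_cutoff(np.full(10, 0.4), np.array([0] * 5 + [1] * 5), 0.05)
    assert thr == pytest.approx(0.4)


def test_cutoff_monotone_in_max_fpr():
    rng = np.random.default_rng(8)
    scores = rng.uniform(size=200)
    y = (rng.uniform(size=200) < scores).astype(int)
    prev = np.inf
    for fpr in (0.01, 0.05, 0.1, 0.3, 0.6):
        thr = choose_cutoff(scores, y, max_fpr=fpr)
        assert thr <= prev + 1e-12
        prev = thr


# ---------------------------------------------------------------------------
# Habitat x spawning product
# ---------------------------------------------------------------------------

def _grid(vals, week="2010-05-01", prov="habitat"):
    vals = np.asarray(vals, dtype=float)
    ny, nx = vals.shape
    return LikelihoodGrid(
        pd.Timestamp(week),
        np.arange(nx, dtype=float),
        np.arange(ny, dtype=float),
        vals,
        provenance=prov,
    )


def test_product_multiplies_cellwise_and_thresholds():
    h = _grid([[0.8, 0.2], [np.nan, 1.0]])
    s = _grid([[0.5, 0.9], [0.3, 1.0]], prov="spawning")
    prod, binary = spawning_habitat_product(h, s, threshold=0.3)
    assert prod.values[0, 0] == pytest.approx(0.4)
    assert np.isnan(prod.values[1, 0])
    assert binary.values[0, 0] == 1.0 and binary.values[0, 1] == 0.0


def test_product_with_unit_spawning_equals_habitat():
    h = _grid([[0.8, 0.2, 0.6]])
    s = _grid([[1.0, 1.0, 1.0]], prov="spawning")
    prod, _ = spawning_habitat_product(h, s)
    np.testing.assert_allclose(prod.values, h.values)


def test_product_bounded_by_both_factors():
    rng = np.random.default_rng(2)
    h = _grid(rng.uniform(size=(4, 5)))
    s = _grid(rng.uniform(size=(4, 5)), prov="spawning")
    prod, _ = spawning_habitat_product(h, s)
    assert (prod.values <= np.minimum(h.values, s.values) + 1e-12).all()


def test_product_grid_mismatch_raises():
    h = _grid([[0.5]])
    s = _grid([[0.5, 0.5]], prov="spawning")
    with pytest.raises(ValueError, match="grids do not match"):
        spawning_habitat_product(h, s)


def test_likelihood_values_validated():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        _grid([[1.5]])
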