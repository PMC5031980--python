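import numpy as np
import pandas as pd
import pytest

from bluefinhab.spawning import (
    PROXY_NAMES,
    ProxyNaiveBayes,
    classify_days,
    compute_proxies,
    concordance,
    count_night_oscillations,
    fit_proxy_model,
)
from bluefinhab.tracks import DiveSeries
from bluefinhab import validation

from conftest import make_track


# ---------------------------------------------------------------------------
# Oscillation counting
# ---------------------------------------------------------------------------

def test_flat_night_profile_counts_zero_oscillations():
    depth = 2.0 + 0.2 * np.sin(np.linspace(0, 40, 270))  # sub-threshold ripple
    count, _ = count_night_oscillations(depth, interval_s=120)
    assert count == 0


def test_sinusoid_count_matches_cycle_budget():
    # 30-min period over a 9-h night sampled at 120 s: 18 cycles
    t = np.arange(0, 9 * 3600, 120.0)
    depth = 20.0 + 15.0 * np.sin(2 * np.pi * t / (30 * 60))
    count, period = count_night_oscillations(depth, interval_s=120)
    assert abs(count - 18) <= 1
    assert period == pytest.approx(30.0, rel=0.1)


def test_small_amplitude_oscillations_are_ignored():
    t = np.arange(0, 9 * 3600, 120.0)
    depth = 20.0 + 2.0 * np.sin(2 * np.pi * t / (30 * 60))  # < 5 m threshold
    count, _ = count_night_oscillations(depth, interval_s=120)
    assert count == 0


# ---------------------------------------------------------------------------
# Proxy computation
# ---------------------------------------------------------------------------

def _constant_dive(track, internal=27.0, external=25.0, depth=2.0):
    ts = pd.date_range(track.dates[0], periods=len(track) * 720, freq="120s")
    return DiveSeries(
        track.tag_id,
        pd.DataFrame(
            {
                "timestamp_utc": ts,
                "depth_m": depth,
                "internal_temp_c": internal,
                "external_temp_c": external,
            }
        ),
    )


def test_night_temperature_excess_proxy():
    track = make_track([-88.0] * 3, [25.0] * 3)
    proxies = compute_proxies(_constant_dive(track), track)
    assert proxies["night_temp_excess"].iloc[1] == pytest.approx(2.0)
    assert proxies["osc_cycles"].iloc[1] == 0
    assert list(proxies.columns[2:]) == list(PROXY_NAMES)


def test_no_temporal_overlap_raises():
    track = make_track([-88.0] * 3, [25.0] * 3, start="2010-04-01")
    other = make_track([-88.0] * 3, [25.0] * 3, start="2012-01-01")
    dive = _constant_dive(other)
    with pytest.raises(ValueError, match="overlap"):
        compute_proxies(dive, track)


# ---------------------------------------------------------------------------
# Naive-Bayes model
# ---------------------------------------------------------------------------

def test_perfectly_separated_proxy_recovers_training_labels():
    X = pd.DataFrame({"p": [10.0] * 6 + [0.0] * 6})
    y = np.array([1] * 6 + [0] * 6)
    model = ProxyNaiveBayes().fit(X, y)
    assert (model.predict(X) == y).all()


def test_identical_class_distributions_give_posterior_half():
    vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    X = pd.DataFrame({"p": np.concatenate([vals, vals])})
    y = np.array([1] * 5 + [0] * 5)
    model = ProxyNaiveBayes(prior=0.5).fit(X, y)
    post = model.predict_proba(X)[:, 1]
    np.testing.assert_allclose(post, 0.5, atol=1e-9)


def test_discrete_two_proxy_case_equals_bayes_rule_oracle():
    result = validation.discrete_bayes_worked_case()
    assert result["max_abs_posterior_diff"] < 1e-12


def test_all_proxies_missing_returns_prior():
    X = pd.DataFrame({"p": [0.0] * 5 + [10.0] * 5})
    y = np.array([0] * 5 + [1] * 5)
    model = ProxyNaiveBayes(prior=0.3).fit(X, y)
    post = model.predict_proba(pd.DataFrame({"p": [np.nan, np.nan]}))[:, 1]
    np.testing.assert_allclose(post, 0.3)


def test_threshold_one_labels_everything_non_spawning():
    X = pd.DataFrame({"p": [0.0] * 5 + [10.0] * 5})
    y = np.array([0] * 5 + [1] * 5)
    model = fit_proxy_model(X, y)
    out = classify_days(X, model, threshold=1.0)
    assert (out["label"][out["posterior"] < 1.0] == 0).all()


def test_class_with_too_few_examples_raises():
    X = pd.DataFrame({"p": [0.0, 1.0, 2.0, 3.0, 4.0, 10.0]})
    y = np.array([0, 0, 0, 0, 0, 1])
    with pytest.raises(ValueError, match="class 1"):
        ProxyNaiveBayes().fit(X, y)


def test_posterior_invariant_to_affine_proxy_rescaling():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(
        {"a": np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 20)]),
         "b": rng.normal(5, 2, 40)}
    )
    y = np.array([0] * 20 + [1] * 20)
    Xnew = pd.DataFrame({"a": rng.normal(1, 1.5, 15), "b": rng.normal(5, 2, 15)})
    base = ProxyNaiveBayes().fit(X, y).predict_proba(Xnew)[:, 1]
    scale, shift = 3.7, -11.0
    Xs = X.assign(a=scale * X["a"] + shift)
    Xns = Xnew.assign(a=scale * Xnew["a"] + shift)
    rescaled = ProxyNaiveBayes().fit(Xs, y).predict_proba(Xns)[:, 1]
    np.testing.assert_allclose(base, rescaled, atol=1e-9)


def test_posterior_invariant_to_proxy_column_order():
    rng = np.random.default_rng(6)
    X = pd.DataFrame(
        {"a": np.concatenate([rng.normal(0, 1, 15), rng.normal(3, 1, 15)]),
         "b": np.concatenate([rng.normal(5, 1, 15), rng.normal(4, 1, 15)])}
    )
    y = np.array([0] * 15 + [1] * 15)
    p1 = ProxyNaiveBayes().fit(X, y).predict_proba(X)[:, 1]
    p2 = ProxyNaiveBayes().fit(X[["b", "a"]], y).predict_proba(X[["b", "a"]])[:, 1]
    np.testing.assert_allclose(p1, p2, atol=1e-12)


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def test_concordance_identical_complementary_and_mismatch():
    a = np.array([0, 1, 1, 0])
    assert concordance(a, a) == 1.0
    assert concordance(a, 1 - a) == 0.0
    assert concordance(a, np.array([0, 1, 0, 0])) == 0.75
    with pytest.raises(ValueError, match="length"):
        concordance(a, a[:3])


def test_detector_end_to_end_skill_on_generator_truth():
    result = validation.spawning_detection_skill(seed=2)
    assert result["sensitivity"] >= 0.9
    assert result["specificity"] >= 0.9
    assert result["self_concordance"] == 1.0
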