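import warnings

import numpy as np
import pandas as pd
import pytest

from bluefinhab.gam import BinomialGAMM, DegenerateFitError, ModelSpec
from bluefinhab.habitat import cross_validate, select_model


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logistic_data(seed=0, n=800, beta=0.5, center=24.0):
    rng = np.random.default_rng(seed)
    sst = rng.uniform(20.0, 28.0, n)
    p = _sigmoid(beta * (sst - center))
    y = rng.uniform(size=n) < p
    tags = np.repeat([f"f{i}" for i in range(8)], n // 8)
    return pd.DataFrame({"sst": sst, "tag_id": tags, "response": y.astype(int)})


def test_monotone_logistic_signal_recovered_with_positive_slope():
    table = _logistic_data()
    est = BinomialGAMM(terms=("sst",)).fit(
        table, table["response"], groups=table["tag_id"]
    )
    xs = np.linspace(20, 28, 40)
    f = est.partial_effect("sst", xs)
    assert np.all(np.diff(f) > -1e-6)  # monotone increasing
    assert f[-1] - f[0] > 2.0

    # agreement with an unpenalized plain logistic fit (independent route)
    import statsmodels.api as sm

    X = sm.add_constant(table["sst"].to_numpy())
    ref = sm.Logit(table["response"].to_numpy(), X).fit(disp=0)
    slope_ref = ref.params[1]
    slope_fit = (f[-1] - f[0]) / (xs[-1] - xs[0])
    assert slope_fit == pytest.approx(slope_ref, rel=0.35)
    assert ref.params[1] > 0


def test_null_response_training_auc_stays_near_chance():
    aucs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n = 2000
        table = pd.DataFrame(
            {
                "sst": rng.uniform(20, 28, n),
                "ssha": rng.normal(0, 5, n),
                "tag_id": np.repeat([f"f{i}" for i in range(10)], n // 10),
                "response": rng.integers(0, 2, n),
            }
        )
        est = BinomialGAMM(terms=("sst", "ssha")).fit(
            table, table["response"], groups=table["tag_id"]
        )
        aucs.append(est.auc_)
    assert max(aucs) < 0.65


def test_single_class_response_raises():
    table = _logistic_data()
    with pytest.raises(DegenerateFitError):
        BinomialGAMM(terms=("sst",)).fit(table, np.ones(len(table)))


def test_perfect_separation_warns_but_fits():
    table = _logistic_data(n=400)
    y = (table["sst"] > 24).astype(int)
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        est = BinomialGAMM(terms=("sst",)).fit(table, y, groups=table["tag_id"])
    assert any("separation" in str(w.message) for w in rec)
    assert np.isfinite(est.aic_)
    assert est.auc_ > 0.95


def test_aic_improves_when_true_covariate_added():
    table = _logistic_data(seed=3, n=1200)
    rng = np.random.default_rng(3)
    table["junk"] = rng.normal(size=len(table))
    null_fit = BinomialGAMM(terms=("junk",)).fit(
        table, table["response"], groups=table["tag_id"]
    )
    full_fit = BinomialGAMM(terms=("junk", "sst")).fit(
        table, table["response"], groups=table["tag_id"]
    )
    assert full_fit.aic_ < null_fit.aic_ + 2.0


def test_prediction_uses_population_intercept_for_unseen_fish():
    table = _logistic_data()
    est = BinomialGAMM(terms=("sst",)).fit(
        table, table["response"], groups=table["tag_id"]
    )
    new = pd.DataFrame({"sst": [24.0], "tag_id": ["unseen"]})
    p_no_groups = est.predict_proba(new)[0, 1]
    p_unknown_group = est.predict_proba(new, groups=["unseen"])[0, 1]
    assert p_no_groups == pytest.approx(p_unknown_group, abs=1e-12)


def test_select_model_ranks_by_auc_then_aic():
    table = _logistic_data(seed=5, n=1000)
    rng = np.random.default_rng(5)
    table["junk"] = rng.normal(size=len(table))
    best, comparison = select_model(
        table,
        [
            ModelSpec("true", ("sst",)),
            ModelSpec("noise", ("junk",)),
        ],
    )
    assert best.spec.name == "true"
    aucs = comparison["auc"].to_numpy()
    assert (np.diff(aucs) <= 1e-12).all()  # sorted descending
    # within AUC ties (if any) AIC ascends
    for _, grp in comparison.groupby("auc"):
        assert grp["aic"].is_monotonic_increasing


def test_cross_validation_perfectly_separable_gives_auc_one():
    rng = np.random.default_rng(1)
    n = 400
    sst = np.concatenate([rng.uniform(20, 23, n // 2), rng.uniform(25, 28, n // 2)])
    table = pd.DataFrame(
        {
            "sst": sst,
            "tag_id": np.tile([f"f{i}" for i in range(4)], n // 4),
            "response": (sst > 24).astype(int),
            "date": pd.date_range("2010-04-01", periods=n, freq="h"),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv = cross_validate(table, ModelSpec("m", ("sst",)), k=3, seed=0)
    assert all(a == pytest.approx(1.0) for a in cv["fold_aucs"])


def test_cross_validation_shuffled_response_is_chance_level():
    rng = np.random.default_rng(2)
    n = 2000
    table = pd.DataFrame(
        {
            "sst": rng.uniform(20, 28, n),
            "tag_id": np.repeat([f"f{i}" for i in range(10)], n // 10),
            "response": rng.permutation(np.repeat([0, 1], n // 2)),
            "date": pd.date_range("2010-04-01", periods=n, freq="h"),
        }
    )
    cv = cross_validate(table, ModelSpec("m", ("sst",)), k=3, seed=1)
    assert 0.4 <= cv["mean_auc"] <= 0.6


def test_by_year_cv_requires_two_years():
    table = _logistic_data()
    table["date"] = pd.date_range("2010-04-01", periods=len(table), freq="h")
    with pytest.raises(ValueError, match="2 calendar years"):
        cross_validate(table, ModelSpec("m", ("sst",)), mode="by_year")


def test_fit_agrees_with_mgcv_oracle(tmp_path):
    """Independent cross-check: same data fitted by mgcv's binomial GAM."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    table = _logistic_data(seed=9, n=600)
    est = BinomialGAMM(terms=("sst",), random_intercept=False).fit(
        table, table["response"]
    )
    ours = est.predict_proba(table)[:, 1]
    csv = tmp_path / "d.csv"
    table[["sst", "response"]].to_csv(csv, index=False)
    out = tmp_path / "pred.csv"
    script = tmp_path / "fit.R"
    script.write_text(
        f"""
        library(mgcv)
        d <- read.csv("{csv}")
        m <- gam(response ~ s(sst, k=5), family=binomial, data=d, method="GCV.Cp")
        write.csv(data.frame(p=predict(m, type="response")), "{out}", row.names=FALSE)
        """
    )
    subprocess.run(["Rscript", "--vanilla", str(script)], check=True, capture_output=True)
    theirs = pd.read_csv(out)["p"].to_numpy()
    assert np.corrcoef(ours, theirs)[0, 1] > 0.98
    assert np.mean(np.abs(ours - theirs)) < 0.05
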