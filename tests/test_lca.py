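"""Measurement-model contracts: likelihood oracles, EM behavior, exports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lctrans as lt
from lctrans.lca import (MeasurementModel, emission_logprob, log_densities,
                         match_classes, measurement_from_probs)

from helpers import bernoulli_product_logprob, two_class_config


def _pooled(seed=0, n=2000, **cfg_kw):
    cfg = two_class_config(seed=seed, **cfg_kw)
    return cfg, lt.simulate_pooled(cfg, n)


# --------------------------------------------------------------------------
# emission_logprob
# --------------------------------------------------------------------------

def test_symmetric_emissions_give_uniform_logprob():
    meas = MeasurementModel(np.zeros((3, 8)), np.zeros(8))
    for c in range(3):
        assert emission_logprob(meas, np.ones(8, int), c) == \
            pytest.approx(-8 * np.log(2), abs=1e-12)


def test_zero_delta_makes_baseline_flag_irrelevant():
    rng = np.random.default_rng(0)
    meas = MeasurementModel(rng.normal(size=(2, 5)), np.zeros(5))
    y = rng.integers(0, 2, 5)
    assert emission_logprob(meas, y, 1, True) == \
        pytest.approx(emission_logprob(meas, y, 1, False), abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.booleans())
def test_emission_logprob_matches_bernoulli_product(seed, baseline):
    rng = np.random.default_rng(seed)
    K, J = 3, 6
    meas = MeasurementModel(rng.normal(scale=1.5, size=(K, J)),
                            np.abs(rng.normal(size=J)))
    y = rng.integers(0, 2, J)
    c = int(rng.integers(K))
    p = meas.emission_probs(baseline)[c]
    assert emission_logprob(meas, y, c, baseline) == \
        pytest.approx(bernoulli_product_logprob(p, y), rel=1e-12)


def test_emission_logprob_rejects_nonbinary():
    meas = MeasurementModel(np.zeros((1, 3)), np.zeros(3))
    with pytest.raises(lt.ValidationError):
        emission_logprob(meas, np.array([0, 2, 1]), 0)


# --------------------------------------------------------------------------
# fit_lca
# --------------------------------------------------------------------------

def test_one_class_fit_is_closed_form():
    _, data = _pooled(seed=1, n=1500)
    fit = lt.fit_lca(data, K=1, n_starts=2, start_iters=20, seed=0)
    phat = data.y.mean(axis=0)
    np.testing.assert_allclose(fit.measurement.emission_probs(False)[0],
                               phat, atol=1e-6)
    n = data.n_records
    ll = np.sum(n * (phat * np.log(phat) + (1 - phat) * np.log(1 - phat)))
    assert fit.loglik == pytest.approx(ll, abs=1e-4)
    assert fit.weights[0] == pytest.approx(1.0)
    assert fit.n_params == 1 * data.J + 0  # (K-1)=0, no delta (single flag)


def test_em_loglik_is_monotone():
    _, data = _pooled(seed=2, n=800)
    fit = lt.fit_lca(data, K=2, n_starts=4, start_iters=5, seed=3,
                     tol=1e-10)
    diffs = np.diff(fit.loglik_path)
    assert (diffs >= -1e-8).all()


def test_record_order_permutation_invariance():
    _, data = _pooled(seed=4, n=600)
    shuffled = lt.PanelDataset(
        data.df.sample(frac=1, random_state=0).reset_index(drop=True),
        data.indicators, validate=False)
    f1 = lt.fit_lca(data, 2, n_starts=4, start_iters=50, seed=5)
    f2 = lt.fit_lca(shuffled, 2, n_starts=4, start_iters=50, seed=5)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
    np.testing.assert_allclose(f1.weights, f2.weights, atol=1e-8)
    np.testing.assert_allclose(f1.measurement.beta0, f2.measurement.beta0,
                               atol=1e-6)


def test_pattern_loglik_equals_recordwise_loglik():
    _, data = _pooled(seed=6, n=500, J=5)
    fit = lt.fit_lca(data, 2, n_starts=4, start_iters=50, seed=7)
    ld = lt.class_log_densities(fit, data)
    a = ld + np.log(fit.weights)[None, :]
    m = np.logaddexp.reduce(a, axis=1)
    assert fit.loglik == pytest.approx(m.sum(), abs=1e-8)


def test_two_class_parameter_recovery():
    cfg, data = _pooled(seed=8, n=5000)
    fit = lt.fit_lca(data, 2, n_starts=8, start_iters=100, seed=9)
    perm = match_classes(fit.measurement.emission_probs(False),
                         cfg.emissions)
    w = fit.weights[perm]
    p = fit.measurement.emission_probs(False)[perm]
    assert np.abs(w - cfg.pi0).max() < 0.03
    assert np.abs(p - cfg.emissions).max() < 0.05


def test_classes_labeled_by_descending_weight():
    _, data = _pooled(seed=10, n=3000)
    fit = lt.fit_lca(data, 2, n_starts=4, start_iters=100, seed=11)
    assert fit.weights[0] >= fit.weights[1]


def test_k_exceeding_patterns_warns():
    df = pd.DataFrame({"person_id": range(6), "wave": 0,
                       "mdd": [0, 1, 0, 1, 0, 1],
                       "dys": [0, 0, 1, 1, 0, 0]})
    data = lt.PanelDataset(df, ["mdd", "dys"])
    with pytest.warns(UserWarning, match="distinct response patterns"):
        lt.fit_lca(data, K=5, n_starts=2, start_iters=10, seed=0)


def test_missing_indicator_is_hard_error():
    df = pd.DataFrame({"person_id": [0, 1], "wave": [0, 0],
                       "mdd": [1.0, np.nan], "dys": [0, 1]})
    with pytest.raises(lt.ValidationError, match="missing"):
        lt.PanelDataset(df, ["mdd", "dys"])


# --------------------------------------------------------------------------
# posteriors, log-densities, serialization
# --------------------------------------------------------------------------

def test_posteriors_match_brute_force_bayes():
    rng = np.random.default_rng(12)
    _, data = _pooled(seed=12, n=50)
    meas = MeasurementModel(rng.normal(size=(3, 6)), np.abs(rng.normal(size=6)))
    w = rng.dirichlet(np.ones(3))
    fit = lt.LCAFit(meas, w, 0.0, 0, 50, 50, True, 1, 0)
    post = lt.posterior_classes(fit, data)
    for i in range(10):
        joint = np.array([w[c] * np.exp(emission_logprob(
            meas, data.y[i], c, bool(data.is_baseline[i])))
            for c in range(3)])
        np.testing.assert_allclose(post[i], joint / joint.sum(), atol=1e-12)
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)


def test_one_class_posteriors_are_unity():
    _, data = _pooled(seed=13, n=100)
    fit = lt.fit_lca(data, 1, n_starts=1, start_iters=10, seed=0)
    assert np.all(lt.posterior_classes(fit, data) == 1.0)


def test_degenerate_emissions_classify_perfectly():
    emissions = np.array([[0.999999, 1e-6], [1e-6, 0.999999]])
    cfg = two_class_config(J=2).with_(emissions=emissions)
    data = lt.simulate_pooled(cfg, 200, seed=14)
    fit = measurement_from_probs(emissions, weights=np.array([0.5, 0.5]))
    post = lt.posterior_classes(fit, data)
    assert np.abs(post[np.arange(200), data.truth] - 1.0).max() < 1e-3


def test_class_log_densities_reproduce_posteriors():
    _, data = _pooled(seed=15, n=300)
    fit = lt.fit_lca(data, 2, n_starts=4, start_iters=50, seed=16)
    ld = lt.class_log_densities(fit, data)
    num = np.exp(ld) * fit.weights[None, :]
    np.testing.assert_allclose(num / num.sum(axis=1, keepdims=True),
                               lt.posterior_classes(fit, data), atol=1e-10)


def test_uniform_one_class_log_density_value():
    meas = MeasurementModel(np.zeros((1, 8)), np.zeros(8))
    y = np.random.default_rng(0).integers(0, 2, (4, 8))
    ld = log_densities(meas, y, np.zeros(4, bool))
    np.testing.assert_allclose(ld, -8 * np.log(2), atol=1e-12)


def test_log_density_csv_roundtrip_and_fit_serialization(tmp_path):
    _, data = _pooled(seed=17, n=200)
    fit = lt.fit_lca(data, 2, n_starts=4, start_iters=50, seed=18)
    df = lt.export_log_densities(fit, data)
    path = tmp_path / "ld.csv"
    df.to_csv(path, index=False)
    back = pd.read_csv(path)
    np.testing.assert_allclose(
        back[["ld_class1", "ld_class2"]].to_numpy(),
        lt.class_log_densities(fit, data), rtol=1e-12)
    jpath = tmp_path / "fit.json"
    fit.to_json(jpath)
    fit2 = lt.LCAFit.from_json(jpath)
    np.testing.assert_allclose(fit2.weights, fit.weights, rtol=1e-15)
    np.testing.assert_allclose(fit2.measurement.beta0,
                               fit.measurement.beta0, rtol=1e-15)
    assert fit2.loglik == fit.loglik
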