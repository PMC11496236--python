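"""Covariate machinery: class profiles and transition-logit models."""

import numpy as np
import pytest

import lctrans as lt
from lctrans.lca import measurement_from_probs
from lctrans.covariates import profile_classes, transition_logit

from helpers import three_state_chain_config, two_class_config


def _profiled_data(shift, n=4000, seed=70, missing=0.0):
    cfg = two_class_config(seed=seed).with_(
        n_individuals=n, n_waves=2,
        covariate_spec=[lt.CovariateSpec(
            "x", "binary", np.array([0.5, 0.5 + shift]),
            missing_rate=missing)])
    data = lt.simulate_panel(cfg)
    meas = measurement_from_probs(cfg.emissions, weights=cfg.pi0)
    return cfg, data, meas


def test_profile_detects_injected_class_shift():
    cfg, data, meas = _profiled_data(shift=0.35)
    prof = profile_classes(meas, data, ["x"])[0]
    assert prof.estimates[1] > prof.estimates[0] + 0.2
    assert prof.p < 1e-6
    assert prof.df == 1
    assert prof.is_proportion


def test_profile_null_type_one_error_is_nominal():
    rejections = 0
    n_reps = 200
    for r in range(n_reps):
        cfg, data, meas = _profiled_data(shift=0.0, n=400, seed=1000 + r)
        prof = profile_classes(meas, data, ["x"])[0]
        rejections += prof.p < 0.05
    rate = rejections / n_reps
    se = np.sqrt(0.05 * 0.95 / n_reps)
    assert abs(rate - 0.05) < 3 * se + 1e-12


def test_profile_excludes_missing_records_per_covariate():
    cfg, data, meas = _profiled_data(shift=0.3, missing=0.25)
    prof = profile_classes(meas, data, ["x"])[0]
    assert prof.n_used == int(data.df["x"].notna().sum())
    assert prof.n_used < data.n_records


def test_profile_constant_covariate_has_undefined_wald():
    cfg, data, meas = _profiled_data(shift=0.0)
    df = data.df.copy()
    df["x"] = 1.0
    const = lt.PanelDataset(df, data.indicators, validate=False)
    prof = profile_classes(meas, const, ["x"])[0]
    assert np.isnan(prof.wald) and np.isnan(prof.p)
    np.testing.assert_allclose(prof.estimates, 1.0, atol=1e-12)


def test_profile_single_class_gives_overall_mean_without_test():
    cfg, data, meas = _profiled_data(shift=0.2)
    meas1 = measurement_from_probs(cfg.emissions[:1], weights=np.ones(1))
    prof = profile_classes(meas1, data, ["x"])[0]
    assert prof.estimates[0] == pytest.approx(
        data.df["x"].mean(), abs=1e-12)
    assert np.isnan(prof.p)


def _chain_with_covariate(beta01=0.0, n=800, seed=80, missing=0.0,
                          class_probs=(0.5, 0.5, 0.5)):
    cfg = three_state_chain_config(seed=seed, n=n)
    eff = np.zeros((3, 3))
    eff[0, 1] = beta01
    cfg = cfg.with_(covariate_spec=[lt.CovariateSpec(
        "x", "binary", np.asarray(class_probs, float),
        missing_rate=missing, transition_effects=eff)])
    data = lt.simulate_panel(cfg)
    meas = measurement_from_probs(cfg.emissions, weights=cfg.pi0)
    return cfg, data, meas


def test_zero_slope_model_reproduces_markov_transition_matrix():
    cfg, data, meas = _chain_with_covariate(beta01=0.0, n=600)
    mfit = lt.fit_latent_markov(data, meas, compute_se=False, tol=1e-11)
    res = transition_logit(meas, data, "x", fit_slopes=False,
                           compute_se=False)
    np.testing.assert_allclose(res.implied_transition_matrix(0.0), mfit.A,
                               atol=1e-4)


def test_injected_transition_effect_recovered_with_sign():
    cfg, data, meas = _chain_with_covariate(beta01=1.0, n=4000, seed=81)
    res = transition_logit(meas, data, "x")
    row = res.table[(res.table.origin == "healthy") &
                    (res.table.destination == "depressed-worried")].iloc[0]
    assert row["estimate"] > 0.4
    assert row["p"] < 0.01
    assert row["direction"] == "unfavorable"


def test_reference_destination_is_staying():
    cfg, data, meas = _chain_with_covariate(beta01=0.0, n=300, seed=82)
    res = transition_logit(meas, data, "x", compute_se=False)
    refs = res.table[res.table.reference]
    assert (refs.origin == refs.destination).all()
    assert (refs.estimate == 0).all()
    assert np.allclose(np.diag(res.alpha), 0) and \
        np.allclose(np.diag(res.beta), 0)


def test_mean_imputation_preserves_mean_and_fit():
    cfg, data, meas = _chain_with_covariate(beta01=0.0, n=400, seed=83,
                                            missing=0.3)
    res = transition_logit(meas, data, "x", compute_se=False)
    z = data.df["x"].to_numpy()
    assert res.imputed_mean == pytest.approx(np.nanmean(z), abs=1e-12)
    assert res.n_imputed == int(np.isnan(z).sum())
    filled = data.df.copy()
    filled["x"] = np.where(np.isnan(z), np.nanmean(z), z)
    manual = lt.PanelDataset(filled, data.indicators, validate=False)
    res2 = transition_logit(meas, manual, "x", compute_se=False)
    assert res2.loglik == pytest.approx(res.loglik, abs=1e-6)
    np.testing.assert_allclose(res2.beta, res.beta, atol=1e-5)


def test_wald_invariant_under_affine_covariate_rescaling():
    cfg, data, meas = _chain_with_covariate(beta01=0.8, n=1500, seed=84)
    res1 = transition_logit(meas, data, "x")
    df = data.df.copy()
    df["x"] = 3.0 * df["x"] + 2.0
    scaled = lt.PanelDataset(df, data.indicators, validate=False)
    res2 = transition_logit(meas, scaled, "x")
    w1 = res1.table.loc[~res1.table.reference, "wald"].to_numpy()
    w2 = res2.table.loc[~res2.table.reference, "wald"].to_numpy()
    np.testing.assert_allclose(w1, w2, rtol=5e-2)


def test_constant_covariate_is_nonestimable():
    cfg, data, meas = _chain_with_covariate(beta01=0.0, n=200, seed=85)
    df = data.df.copy()
    df["x"] = 0.0
    const = lt.PanelDataset(df, data.indicators, validate=False)
    with pytest.raises(lt.NonEstimableError, match="constant"):
        transition_logit(meas, const, "x")


def test_rare_origin_class_flagged_nonestimable():
    cfg = three_state_chain_config(seed=86, n=120).with_(
        pi0=np.array([0.899, 0.1, 0.001]),
        A=np.array([[0.989, 0.01, 0.001],
                    [0.05, 0.94, 0.01],
                    [0.1, 0.1, 0.8]]),
        covariate_spec=[lt.CovariateSpec("x", "binary",
                                         np.array([0.5, 0.5, 0.5]))])
    data = lt.simulate_panel(cfg)
    meas = measurement_from_probs(cfg.emissions, weights=cfg.pi0)
    with pytest.warns(UserWarning, match="non-estimable"):
        res = transition_logit(meas, data, "x", compute_se=False)
    bad = res.table[~res.table.estimable & ~res.table.reference]
    assert len(bad) > 0
    assert bad["estimate"].isna().all()
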