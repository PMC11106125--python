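"""Phenotypic and biometric moderation models; moderation curves."""

import numpy as np
import pytest

from twinmod.ace import fit_ace
from twinmod.inference import lrt
from twinmod.moderation import (
    PhenotypicModerationModel,
    biometric_model,
    fit_biometric_moderation,
    fit_phenotypic_moderation,
    moderation_curve,
    moderation_table,
)
from twinmod.simulate import SimulationConfig, default_study_config, simulate_twins


@pytest.fixture(scope="module")
def moderated_dataset():
    """1200 pairs from the default (moderated) study conditions."""
    base = default_study_config(0)
    cfg = SimulationConfig(n_mz=600, n_dz=600, spec=base.spec,
                          prevalence=base.prevalence, seed=202)
    return simulate_twins(cfg)


# -- phenotypic moderation -------------------------------------------------

def test_model1_masked_moderation_equals_unmoderated_fit(moderated_dataset):
    m = PhenotypicModerationModel(moderated_dataset, ("CGN", "SO"), moderator="CGN")
    moderated = m.fit()
    masked = m.fit(fixed={"b_21": 0.0, "b_22": 0.0})
    assert masked.minus2ll >= moderated.minus2ll - 1e-6
    assert lrt(moderated, masked).chi2 >= 0
    # the masked model is the unmoderated phenotypic fit: refitting the same
    # mask from a different start reproduces it
    masked2 = m.fit(fixed={"b_21": 0.0, "b_22": 0.0},
                    start={"p_11": 1.1, "p_21": 0.05})
    assert masked.minus2ll == pytest.approx(masked2.minus2ll, abs=1e-6)


def test_model_name_validation(moderated_dataset):
    with pytest.raises(ValueError):
        fit_phenotypic_moderation(moderated_dataset, "model3_CGN")
    with pytest.raises(ValueError):
        fit_phenotypic_moderation(moderated_dataset, "model2_CGN")


def test_phenotypic_recovery_of_variance_moderation():
    """Simulated negative moderation of the outcome-specific path is
    recovered with the right sign at study-like magnitude."""
    base = default_study_config(0)
    cfg = SimulationConfig(n_mz=1000, n_dz=1000, spec=base.spec,
                          prevalence=base.prevalence, seed=404)
    ds = simulate_twins(cfg)
    fit = fit_phenotypic_moderation(ds, "model1_CGN",
                                    start={"b_22": -0.3, "tau_SO": 1.5})
    assert fit.converged
    # truth: E-specific slope -0.38 on the liability; phenotypically this
    # appears as negative moderation of total SO variance
    assert fit.estimates["b_22"] < 0


def test_phenotypic_twin_order_invariance(moderated_dataset):
    f1 = fit_phenotypic_moderation(moderated_dataset, "model1_CGN")
    f2 = fit_phenotypic_moderation(moderated_dataset.swap_twins(), "model1_CGN")
    assert f1.minus2ll == pytest.approx(f2.minus2ll, abs=1e-4)


# -- biometric moderation --------------------------------------------------

def test_unknown_design_rejected(moderated_dataset):
    with pytest.raises(ValueError, match="unknown design"):
        fit_biometric_moderation(moderated_dataset, "bivariate_XYZ")


def test_biometric_masked_moderation_reproduces_unmoderated(moderated_dataset):
    base = fit_ace(moderated_dataset, variables=["CGN", "SO"], include_C=False)
    model = biometric_model(moderated_dataset, "bivariate_CGN")
    zeros = {n: 0.0 for n in model.param_names if n.startswith("b")}
    masked = model.fit(fixed=zeros)
    assert masked.minus2ll == pytest.approx(base.minus2ll, abs=1e-6)
    assert masked.n_free == base.n_free
    full = model.fit(start={"bE_22": -0.38, "tau_SO": 1.5})
    test = lrt(full, masked)
    assert test.chi2 >= 0
    assert test.df == len(zeros)


def test_biometric_recovery_sign_and_magnitude(moderated_dataset):
    fit = fit_biometric_moderation(moderated_dataset, "bivariate_CGN",
                                   start={"bE_22": -0.38, "tau_SO": 1.5})
    assert fit.converged
    assert fit.estimates["bE_22"] == pytest.approx(-0.38, abs=0.25)


def test_moderation_table_shape(moderated_dataset):
    fit = fit_biometric_moderation(moderated_dataset, "bivariate_CGN",
                                   start={"bE_22": -0.38, "tau_SO": 1.5})
    tab = moderation_table(fit, "bivariate_CGN")
    assert set(tab["component"]) == {"A", "E"}
    assert set(tab["target"]) == {"CGN-SO covariance", "SO variance"}
    assert len(tab) == 4


def test_trivariate_reports_moderator_outcome_subset(study_dataset):
    model = biometric_model(study_dataset, "trivariate_ELA")
    fit = model.fit(n_starts=1)
    tab = moderation_table(fit, "trivariate_ELA")
    assert set(tab["target"]) == {"CGN variance", "CGN-SO covariance", "SO variance"}
    assert len(tab) == 6          # 3 targets x 2 components (A, E)
    full = moderation_table(fit, "trivariate_ELA", full=True)
    assert len(full) == 10        # all freed slopes


# -- moderation curves -----------------------------------------------------

def test_flat_curves_when_moderation_masked(moderated_dataset):
    model = biometric_model(moderated_dataset, "bivariate_CGN")
    zeros = {n: 0.0 for n in model.param_names if n.startswith("b")}
    fit = model.fit(fixed=zeros)
    curve = moderation_curve(model, fit, "SO", with_variable="CGN")
    for arr in (curve.varA, curve.varE, curve.total_var, curve.covA, curve.r):
        assert np.ptp(arr) < 1e-12


def test_curve_component_conservation_and_center(moderated_dataset):
    model = biometric_model(moderated_dataset, "bivariate_CGN")
    fit = model.fit(start={"bE_22": -0.38, "tau_SO": 1.5})
    curve = moderation_curve(model, fit, "SO", with_variable="CGN")
    np.testing.assert_allclose(curve.varA + curve.varC + curve.varE,
                               curve.total_var, atol=1e-12)
    np.testing.assert_allclose(curve.covA + curve.covC + curve.covE,
                               curve.total_cov, atol=1e-12)
    # at M = 0 the liability-scale identification pins total variance at 1
    mid = curve.grid.size // 2
    assert curve.grid[mid] == pytest.approx(0.0, abs=1e-12)
    assert curve.total_var[mid] == pytest.approx(1.0, abs=1e-10)


def test_e_attenuation_algebra():
    # e-path 0.76 with slope -0.38: E variance (0.76 - 0.38 M)^2 vanishes at M = 2
    e, b = 0.76, -0.38
    M = np.array([-2.0, 0.0, 2.0])
    varE = (e + b * M) ** 2
    np.testing.assert_allclose(varE, [(0.76 + 0.76) ** 2, 0.76 ** 2, 0.0])


def test_cholesky_sign_flip_leaves_curves_invariant(moderated_dataset):
    model = biometric_model(moderated_dataset, "bivariate_CGN")
    fit = model.fit(start={"bE_22": -0.38, "tau_SO": 1.5})
    flipped = dict(fit.estimates)
    # flip the sign of the first Cholesky column (paths and slopes together)
    for name in list(flipped):
        if name.endswith("_11") or name.endswith("_21"):
            flipped[name] = -flipped[name]
    import copy
    fit2 = copy.deepcopy(fit)
    fit2.estimates = flipped
    c1 = moderation_curve(model, fit, "SO", with_variable="CGN")
    c2 = moderation_curve(model, fit2, "SO", with_variable="CGN")
    np.testing.assert_allclose(c1.varA, c2.varA, atol=1e-12)
    np.testing.assert_allclose(c1.varE, c2.varE, atol=1e-12)
    np.testing.assert_allclose(c1.total_cov, c2.total_cov, atol=1e-12)


def test_unknown_curve_variable_rejected(moderated_dataset):
    model = biometric_model(moderated_dataset, "bivariate_CGN")
    fit = model.fit(start={"bE_22": -0.38, "tau_SO": 1.5})
    with pytest.raises(KeyError):
        moderation_curve(model, fit, "nope")


def test_grid_spans_requested_sd_multiple(moderated_dataset):
    model = biometric_model(moderated_dataset, "bivariate_CGN")
    fit = model.fit(start={"bE_22": -0.38, "tau_SO": 1.5})
    c3 = moderation_curve(model, fit, "SO", grid_sd=3)
    c2 = moderation_curve(model, fit, "SO", grid_sd=2)
    assert c3.grid.max() == pytest.approx(3 * model.m_sd)
    assert c2.grid.max() == pytest.approx(2 * model.m_sd)
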