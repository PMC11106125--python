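"""ACE core: expected covariances, mixed pair likelihood, fitting, closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import multivariate_normal, norm

from twinmod.ace import (
    ACEModel,
    ACEModelSpec,
    FalconerEstimates,
    ModerationCoefficients,
    PathMatrices,
    ThresholdModel,
    expected_pair_covariance,
    falconer_estimates,
    fit_ace,
    liability_threshold,
    pair_loglik,
    spec_from_yaml,
    spec_to_yaml,
    standardize_components,
)
from twinmod.io import VariableSpec
from twinmod.simulate import SimulationConfig, simulate_pairs, simulate_twins

from conftest import univariate_spec


# -- expected pair covariance ----------------------------------------------

def test_univariate_ace_identities():
    spec = univariate_spec(a2=0.36, c2=0.0, e2=0.64)
    S_mz = expected_pair_covariance(spec, "MZ")
    S_dz = expected_pair_covariance(spec, "DZ")
    assert S_mz[0, 0] == pytest.approx(1.0)
    assert S_mz[0, 1] == pytest.approx(0.36)
    assert S_dz[0, 1] == pytest.approx(0.18)


def test_moderated_cross_twin_covariance():
    # a = 0.5, bA = 0.1, M1 = 1, M2 = -1: variances 0.36/0.16, cross-A 0.012... no:
    # A parts: a(M1)^2 = 0.36, a(M2)^2 = 0.16; DZ cross = 0.5 * 0.6 * 0.4 = 0.12
    paths = PathMatrices(np.array([[0.5]]), np.zeros((1, 1)), np.zeros((1, 1)))
    mods = ModerationCoefficients(np.array([[0.1]]), np.zeros((1, 1)), np.zeros((1, 1)))
    # moderation of the moderator's own row is disallowed; build matrices directly
    a1 = paths.a + mods.beta_a * 1.0
    a2 = paths.a + mods.beta_a * (-1.0)
    assert a1[0, 0] ** 2 == pytest.approx(0.36)
    assert a2[0, 0] ** 2 == pytest.approx(0.16)
    assert 0.5 * a1[0, 0] * a2[0, 0] == pytest.approx(0.12)


def _random_spec(rng, k=3, ordinal_last=True, moderated=True):
    a = np.tril(rng.normal(0, 0.5, (k, k)))
    c = np.tril(rng.normal(0, 0.3, (k, k)))
    e = np.tril(rng.normal(0, 0.5, (k, k)))
    e[np.diag_indices(k)] = np.abs(e[np.diag_indices(k)]) + 0.3
    variables = [VariableSpec(f"V{i}", "continuous") for i in range(k)]
    if ordinal_last:
        variables[-1] = VariableSpec(f"V{k - 1}", "ordinal", n_categories=2)
        # liability scale: unit total variance at M = 0, as fitted models enforce
        row = k - 1
        tot = (a[row, :] @ a[row, :] + c[row, :] @ c[row, :] + e[row, :] @ e[row, :])
        for mat in (a, c, e):
            mat[row, :] /= np.sqrt(tot)
    mods = ModerationCoefficients.zeros(k)
    moderator = None
    if moderated:
        moderator = "V0"
        mods.beta_a[k - 1, k - 1] = rng.normal(0, 0.2)
        mods.beta_e[k - 1, 0] = rng.normal(0, 0.2)
    return ACEModelSpec(
        variables=variables, paths=PathMatrices(a, c, e), mods=mods,
        thresholds={variables[-1].name: ThresholdModel(np.array([0.8]))}
        if ordinal_last else {},
        moderator=moderator,
    )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.sampled_from(["MZ", "DZ"]),
       st.floats(-2, 2), st.floats(-2, 2))
def test_expected_covariance_always_psd(seed, zyg, m1, m2):
    spec = _random_spec(np.random.default_rng(seed))
    S = expected_pair_covariance(spec, zyg, m1, m2)
    w = np.linalg.eigvalsh(S)
    assert w.min() > -1e-10
    np.testing.assert_allclose(S, S.T, atol=1e-12)


def test_mz_cross_covariance_dominates_dz():
    rng = np.random.default_rng(5)
    for _ in range(10):
        spec = _random_spec(rng, moderated=False)
        S_mz = expected_pair_covariance(spec, "MZ")
        S_dz = expected_pair_covariance(spec, "DZ")
        k = spec.k
        assert np.all(np.diag(S_mz[:k, k:]) >= np.diag(S_dz[:k, k:]) - 1e-12)


def test_expected_covariance_matches_simulation():
    rng = np.random.default_rng(17)
    spec = _random_spec(rng, ordinal_last=False, moderated=True)
    n = 200_000
    lat = simulate_pairs(spec, "DZ", n, rng, M1=0.7, M2=-0.4)
    Y = lat.reshape(n, -1, order="F")  # not the layout we need; build manually
    Y = np.concatenate([lat[:, 0, :], lat[:, 1, :]], axis=1)
    emp = np.cov(Y.T)
    S = expected_pair_covariance(spec, "DZ", 0.7, -0.4)
    se = np.sqrt(2.0 / n) * np.abs(S).max()
    np.testing.assert_allclose(emp, S, atol=6 * se + 0.02)


# -- pair likelihood -------------------------------------------------------

def test_continuous_mz_pair_closed_form():
    spec = univariate_spec(a2=0.5, c2=0.0, e2=0.5)
    ll = pair_loglik(spec, {"X": (0.0, 0.0)}, "MZ")
    expected = multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]]).logpdf([0, 0])
    assert ll == pytest.approx(expected, abs=1e-10)
    assert ll == pytest.approx(-np.log(2 * np.pi * np.sqrt(0.75)), abs=1e-4)


def test_independent_binary_pair_log_quarter():
    # rho = 0 across twins, thresholds 0: both upper category -> log(1/4)
    paths = PathMatrices(np.zeros((1, 1)), np.zeros((1, 1)), np.eye(1))
    spec = ACEModelSpec(
        variables=[VariableSpec("B", "ordinal", n_categories=2)],
        paths=paths, thresholds={"B": ThresholdModel(np.array([0.0]))},
    )
    ll = pair_loglik(spec, {"B": (1.0, 1.0)}, "MZ")
    assert ll == pytest.approx(np.log(0.25), abs=1e-12)


def _quadrature_pair_loglik(spec, values, zygosity):
    """Brute-force oracle: 2-D quadrature of the joint normal over the
    category rectangle at the observed continuous values."""
    k = spec.k
    S = expected_pair_covariance(spec, zygosity,
                                 values[spec.moderator][0] if spec.moderator else 0.0,
                                 values[spec.moderator][1] if spec.moderator else 0.0)
    names = spec.var_names
    cont_idx, cont_vals, ord_idx, rects = [], [], [], []
    for i, name in enumerate(names):
        vs = spec.variables[i]
        for twin, slot in ((0, i), (1, k + i)):
            v = values[name][twin]
            if vs.is_ordinal:
                tau = spec.thresholds[name].tau[0]
                ord_idx.append(slot)
                rects.append((tau, np.inf) if v >= 1 else (-np.inf, tau))
            else:
                cont_idx.append(slot)
                cont_vals.append(v - spec.means[i])
    mvn = multivariate_normal(np.zeros(2 * k), S)

    def dens(z1, z2):
        point = np.zeros(2 * k)
        point[cont_idx] = cont_vals
        point[ord_idx] = [z1, z2]
        return mvn.pdf(point)

    # finite integration windows: liability means given the continuous entries
    # +/- 10 conditional SDs (keeps the adaptive grid on the mass)
    Scc = S[np.ix_(cont_idx, cont_idx)]
    Sco = S[np.ix_(cont_idx, ord_idx)]
    Soo = S[np.ix_(ord_idx, ord_idx)]
    K = Sco.T @ np.linalg.inv(Scc)
    mo = K @ np.array(cont_vals)
    sd = np.sqrt(np.diag(Soo - K @ Sco))
    (a1, b1), (a2, b2) = rects
    lo1, hi1 = max(a1, mo[0] - 10 * sd[0]), min(b1, mo[0] + 10 * sd[0])
    lo2, hi2 = max(a2, mo[1] - 10 * sd[1]), min(b2, mo[1] + 10 * sd[1])
    val, _ = integrate.dblquad(dens, lo2, hi2, lambda _: lo1, lambda _: hi1,
                               epsabs=1e-13, epsrel=1e-10)
    return np.log(val)


def _draw_mixed_pair(spec, zyg, rng):
    """One (continuous, binary) twin pair simulated from the spec itself."""
    lat = simulate_pairs(spec, zyg, 1, rng)[0]
    tau = spec.thresholds["V1"].tau[0]
    return {"V0": (lat[0, 0], lat[1, 0]),
            "V1": (float(lat[0, 1] > tau), float(lat[1, 1] > tau))}


def test_mixed_pair_likelihood_matches_quadrature():
    """FIML with a binary liability equals brute-force numerical integration."""
    rng = np.random.default_rng(23)
    for trial in range(6):
        spec = _random_spec(rng, k=2, ordinal_last=True, moderated=bool(trial % 2))
        zyg = "MZ" if trial % 2 else "DZ"
        vals = _draw_mixed_pair(spec, zyg, rng)
        ours = pair_loglik(spec, vals, zyg)
        oracle = _quadrature_pair_loglik(spec, vals, zyg)
        assert ours == pytest.approx(oracle, abs=1e-6)


def test_incomplete_pair_contributes_singleton_margin():
    spec = univariate_spec(a2=0.5, c2=0.0, e2=0.5)
    ll = pair_loglik(spec, {"X": (1.3, np.nan)}, "DZ")
    assert ll == pytest.approx(norm.logpdf(1.3), abs=1e-12)


def test_category_probabilities_integrate_to_continuous_margin():
    """Summing exp(loglik) over all category combinations of the ordinal
    variable recovers the continuous-margin density."""
    rng = np.random.default_rng(31)
    spec = _random_spec(rng, k=2, ordinal_last=True, moderated=False)
    c1, c2 = 0.4, -1.1
    total = 0.0
    for d1 in (0.0, 1.0):
        for d2 in (0.0, 1.0):
            total += np.exp(pair_loglik(spec, {"V0": (c1, c2), "V1": (d1, d2)}, "MZ"))
    margin = np.exp(pair_loglik(spec, {"V0": (c1, c2), "V1": (np.nan, np.nan)}, "MZ"))
    assert total == pytest.approx(margin, abs=1e-10)


# -- fitting ---------------------------------------------------------------

def test_univariate_ae_parameter_recovery():
    spec = univariate_spec(a2=0.5, c2=0.0, e2=0.5)
    cfg = SimulationConfig(n_mz=2000, n_dz=2000, spec=spec, seed=21)
    ds = simulate_twins(cfg)
    fit = fit_ace(ds, include_C=False)
    assert fit.converged
    est = fit.estimates
    assert est["a_11"] ** 2 == pytest.approx(0.5, abs=0.04)
    assert est["e_11"] ** 2 == pytest.approx(0.5, abs=0.04)


def test_aic_identity_on_fit(study_dataset):
    fit = fit_ace(study_dataset, include_C=False)
    assert fit.aic == pytest.approx(fit.minus2ll - 2 * fit.df, abs=1e-12)
    n_obs = np.isfinite(study_dataset.person_table(["ELA", "CGN", "SO"])).sum()
    assert fit.df == n_obs - fit.n_free


def test_twin_order_swap_invariance(study_dataset):
    fit1 = fit_ace(study_dataset, include_C=False)
    fit2 = fit_ace(study_dataset.swap_twins(), include_C=False)
    assert fit1.minus2ll == pytest.approx(fit2.minus2ll, abs=1e-4)


def test_moderation_masked_to_zero_reproduces_unmoderated_fit(study_dataset):
    base = fit_ace(study_dataset, variables=["CGN", "SO"], include_C=False)
    model = ACEModel(study_dataset, variables=["CGN", "SO"], include_C=False,
                     moderator="CGN", free_mods=["bA_21", "bA_22", "bE_21", "bE_22"])
    masked = model.fit(fixed={"bA_21": 0.0, "bA_22": 0.0, "bE_21": 0.0, "bE_22": 0.0})
    assert masked.minus2ll == pytest.approx(base.minus2ll, abs=1e-6)


def test_dropping_null_c_component_rarely_rejected():
    """Data generated with no shared environment: the ACE-vs-AE LRT stays
    below 3.84 in at least 90% of seeds (C is a boundary-null parameter, so
    the test is conservative)."""
    spec = univariate_spec(a2=0.5, c2=0.0, e2=0.5)
    below = 0
    n_seeds = 20
    for s in range(n_seeds):
        ds = simulate_twins(SimulationConfig(n_mz=300, n_dz=300, spec=spec,
                                             seed=600 + s))
        ae = fit_ace(ds, include_C=False)
        ace = fit_ace(ds, include_C=True,
                      start={**ae.estimates, "c_11": 0.1})
        # deviance improvement from freeing C (clamped: AE is nested in ACE,
        # so any negative value is optimizer noise around zero)
        chi2 = max(ae.minus2ll - ace.minus2ll, 0.0)
        if chi2 < 3.841:
            below += 1
    assert below >= 0.9 * n_seeds


# -- closed forms ----------------------------------------------------------

@pytest.mark.parametrize("rmz,rdz,expected,flag", [
    (0.63, 0.34, (0.58, 0.05, 0.37), False),   # printed adversity correlations
    (0.0, 0.0, (0.0, 0.0, 1.0), False),
    (0.56, 0.15, (0.82, -0.26, 0.44), True),   # printed orientation correlations
])
def test_falconer_closed_form(rmz, rdz, expected, flag):
    est = falconer_estimates(rmz, rdz)
    assert isinstance(est, FalconerEstimates)
    assert (est.a2, est.c2, est.e2) == pytest.approx(expected, abs=1e-12)
    assert est.negative_component == flag
    assert est.a2 + est.c2 + est.e2 == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("prev,expected,tol", [
    (0.5, 0.0, 1e-12),
    (0.068, 1.491, 5e-4),
    (0.159, 1.0, 2e-3),
])
def test_liability_threshold_quantiles(prev, expected, tol):
    assert liability_threshold(prev) == pytest.approx(expected, abs=tol)


def test_liability_threshold_rejects_boundary():
    for p in (0.0, 1.0, -0.1):
        with pytest.raises(ValueError):
            liability_threshold(p)


def test_standardize_equal_paths_thirds():
    p = PathMatrices(np.eye(2) * 0.5, np.eye(2) * 0.5, np.eye(2) * 0.5)
    sc = standardize_components(p)
    np.testing.assert_allclose(np.diag(sc.h2), [1 / 3, 1 / 3], atol=1e-12)


def test_standardize_printed_adversity_row():
    # a 0.7550, c 0.2236, e 0.6083 -> proportions (0.57, 0.05, 0.37)
    p = PathMatrices(np.array([[0.7550]]), np.array([[0.2236]]), np.array([[0.6083]]))
    sc = standardize_components(p)
    assert sc.h2[0, 0] == pytest.approx(0.57, abs=0.01)
    assert sc.c2[0, 0] == pytest.approx(0.05, abs=0.01)
    assert sc.e2[0, 0] == pytest.approx(0.37, abs=0.01)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_standardized_diagonals_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    spec = _random_spec(rng, ordinal_last=False, moderated=False)
    sc = standardize_components(spec.paths)
    np.testing.assert_allclose(np.diag(sc.h2) + np.diag(sc.c2) + np.diag(sc.e2),
                               1.0, atol=1e-12)
    assert np.all(np.diag(sc.h2) >= 0) and np.all(np.diag(sc.h2) <= 1)


def test_spec_yaml_round_trip():
    spec = _random_spec(np.random.default_rng(2))
    back = spec_from_yaml(spec_to_yaml(spec))
    np.testing.assert_allclose(back.paths.a, spec.paths.a)
    np.testing.assert_allclose(back.mods.beta_e, spec.mods.beta_e)
    assert back.moderator == spec.moderator
    assert back.var_names == spec.var_names
    np.testing.assert_allclose(back.thresholds["V2"].tau, spec.thresholds["V2"].tau)
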