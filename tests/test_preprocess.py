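"""Scale scoring, Cronbach's alpha, covariate adjustment and EM imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twinmod.io import TwinDataset, VariableSpec
from twinmod.preprocess import (
    ScoringRule,
    adjust_covariates,
    cronbach_alpha,
    em_impute,
    em_mvnorm,
    score_scales,
)

SO_RULE = ScoringRule(items=["s1", "s2", "s3", "s4"], method="mean", dichotomize_at=0.0)
CGN_RULE = ScoringRule(items=[f"c{i}" for i in range(13)], method="mean_times_k",
                       not_applicable_code=9)


@pytest.mark.parametrize("items,expected", [
    ((0, 0, 0, 0), 0.0),     # all-zero composite -> heterosexual category
    ((0, 0, 1, 0), 1.0),     # composite 0.25 -> non-heterosexual category
    ((7, 6, 7, 6), 1.0),
])
def test_orientation_composite_dichotomized(items, expected):
    t = pd.DataFrame([dict(zip(SO_RULE.items, items))])
    assert score_scales(t, SO_RULE).iloc[0] == expected


def test_gender_nonconformity_mean_times_k_with_not_applicable():
    # 12 answered items of 2, one not-applicable: mean 2 over answered x 13 = 26
    row = {f"c{i}": 2 for i in range(13)}
    row["c5"] = 9
    t = pd.DataFrame([row])
    assert score_scales(t, CGN_RULE).iloc[0] == pytest.approx(26.0)


def test_sum_rule_with_exclusions():
    items = [f"e{i}" for i in range(28)]
    rule = ScoringRule(items=items, method="sum", excluded_items=["e0", "e1", "e2"])
    t = pd.DataFrame([{c: 2 for c in items}])
    assert score_scales(t, rule).iloc[0] == 2 * 25


def test_all_missing_items_give_missing_score():
    t = pd.DataFrame([{c: 9 for c in CGN_RULE.items}])
    assert np.isnan(score_scales(t, CGN_RULE).iloc[0])


def test_out_of_range_response_rejected():
    rule = ScoringRule(items=["a", "b"], method="mean", response_range=(1, 5))
    with pytest.raises(ValueError, match="out-of-range"):
        score_scales(pd.DataFrame([{"a": 6, "b": 1}]), rule)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.permutations(list(range(4))), st.integers(0, 3))
def test_scoring_permutation_invariant_and_monotone(perm, bump_idx):
    rng = np.random.default_rng(7)
    base = rng.integers(0, 7, size=(5, 4))
    t = pd.DataFrame(base, columns=SO_RULE.items)
    shuffled = t[[SO_RULE.items[i] for i in perm]]
    shuffled.columns = SO_RULE.items
    s1 = score_scales(t, SO_RULE)
    assert s1.equals(score_scales(shuffled, SO_RULE))
    # raising any item can never flip category 1 -> 0
    t2 = t.copy()
    t2.iloc[:, bump_idx] += 1
    s2 = score_scales(t2, SO_RULE)
    assert np.all(s2 >= s1)


def test_alpha_closed_form_two_items():
    # sample variances 1, covariance 0.5 -> alpha = 2 * (1 - 2/3) = 2/3
    t = pd.DataFrame({"a": [-1.0, 0.0, 1.0], "b": [-1.0, 1.0, 0.0]})
    assert cronbach_alpha(t) == pytest.approx(2 / 3, abs=1e-12)


def test_alpha_identical_columns_is_one():
    x = np.arange(10.0)
    assert cronbach_alpha(pd.DataFrame({"a": x, "b": x, "c": x})) == pytest.approx(1.0)


def test_alpha_independent_items_near_zero():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(10000, 5))
    assert abs(cronbach_alpha(pd.DataFrame(X))) < 0.05


def test_alpha_zero_total_variance_signalled():
    t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]})
    with pytest.raises(ValueError, match="alpha undefined"):
        cronbach_alpha(t)


def _dataset_with_scores(rng, n=400, age_slope=0.0, sex_effect=0.0):
    age = rng.uniform(25, 50, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    score = np.exp(rng.normal(3.0, 0.2, size=n) + age_slope * (age - 37.0)
                   + sex_effect * sex)
    half = n // 2
    t = pd.DataFrame({
        "pair_id": [f"p{i}" for i in range(half)],
        "zygosity": ["MZ", "DZ"] * (half // 2),
        "age_t1": age[:half], "age_t2": age[:half],
        "sex_t1": sex[:half], "sex_t2": sex[half:],
        "X_t1": score[:half], "X_t2": score[half:],
    })
    return TwinDataset(t, [VariableSpec("X")])


def test_adjusted_scores_orthogonal_to_covariates():
    rng = np.random.default_rng(3)
    ds = _dataset_with_scores(rng, age_slope=0.03, sex_effect=0.4)
    out = adjust_covariates(ds)
    resid = out.person_table(["X"])[:, 0]
    age = out.person_table(["age"])[:, 0]
    sex = out.person_table(["sex"])[:, 0]
    n = resid.size
    assert abs(resid @ (age - age.mean())) / n < 1e-10
    assert abs(resid @ (sex - sex.mean())) / n < 1e-10
    assert abs(resid.mean()) < 1e-12


def test_constant_covariates_give_centered_log_scores():
    rng = np.random.default_rng(4)
    ds = _dataset_with_scores(rng)
    ds.table["age_t1"] = ds.table["age_t2"] = 40.0
    ds.table["sex_t1"] = ds.table["sex_t2"] = 1.0
    out = adjust_covariates(ds)
    logs = np.log(ds.person_table(["X"])[:, 0])
    np.testing.assert_allclose(out.person_table(["X"])[:, 0], logs - logs.mean(),
                               atol=1e-10)


def test_known_age_slope_removed():
    rng = np.random.default_rng(5)
    ds = _dataset_with_scores(rng, age_slope=0.5 / 10)   # 0.05 per year on log scale
    out = adjust_covariates(ds)
    resid = out.person_table(["X"])[:, 0]
    age = out.person_table(["age"])[:, 0]
    slope = np.polyfit(age, resid, 1)[0]
    assert abs(slope) < 1e-10


def test_nonpositive_score_at_log_step_is_an_error():
    rng = np.random.default_rng(6)
    ds = _dataset_with_scores(rng)
    ds.table.loc[3, "X_t1"] = 0.0
    with pytest.raises(ValueError, match="pair row 3"):
        adjust_covariates(ds)


def test_moderator_main_effect_removed():
    rng = np.random.default_rng(8)
    n = 300
    m = np.exp(rng.normal(3, 0.3, size=2 * n))
    y = m ** 0.8 * np.exp(rng.normal(0, 0.1, size=2 * n))
    t = pd.DataFrame({
        "pair_id": [f"p{i}" for i in range(n)], "zygosity": ["MZ"] * n,
        "age_t1": 40.0, "age_t2": 40.0, "sex_t1": 0.0, "sex_t2": 0.0,
        "M_t1": m[:n], "M_t2": m[n:], "Y_t1": y[:n], "Y_t2": y[n:],
    })
    ds = TwinDataset(t, [VariableSpec("M"), VariableSpec("Y")])
    out = adjust_covariates(ds, regress_out_moderator_mains="M")
    ym = out.person_table(["Y"])[:, 0]
    mm = out.person_table(["M"])[:, 0]
    assert abs(np.corrcoef(ym, mm)[0, 1]) < 1e-8


# -- EM imputation ---------------------------------------------------------

def test_em_no_missing_is_identity(study_dataset):
    out = em_impute(study_dataset)
    for name in study_dataset.var_names:
        np.testing.assert_array_equal(out.values(name), study_dataset.values(name))


def test_em_conditional_mean_closed_form():
    # bivariate normal, unit variances, rho 0.6: E[x2 | x1=1] = 0.6
    rng = np.random.default_rng(9)
    n = 20000
    X = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=n)
    X[0] = [1.0, np.nan]
    imp, mu, Sigma, _ = em_mvnorm(X)
    assert imp[0, 1] == pytest.approx(0.6, abs=0.03)
    observed = np.isfinite(X)
    np.testing.assert_array_equal(imp[observed], X[observed])


def test_em_recovers_moments_under_mcar():
    rng = np.random.default_rng(10)
    n = 5000
    mean = np.array([1.0, -0.5, 2.0])
    cov = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
    X = rng.multivariate_normal(mean, cov, size=n)
    X[rng.random((n, 3)) < 0.2] = np.nan
    _, mu, Sigma, n_iter = em_mvnorm(X)
    np.testing.assert_allclose(mu, mean, atol=0.05)
    np.testing.assert_allclose(Sigma, cov, atol=0.08)


def test_em_impute_never_touches_binary(study_dataset):
    ds = study_dataset.copy()
    ds.table.loc[0, "ELA_t1"] = np.nan
    ds.table.loc[1, "SO_t1"] = np.nan
    out = em_impute(ds)
    assert np.isfinite(out.values("ELA")[0, 0])          # continuous imputed
    assert np.isnan(out.values("SO")[1, 0])              # binary left missing


def test_high_missingness_individual_excluded(study_dataset):
    ds = study_dataset.copy()
    for v in ("ELA", "CGN", "SO"):
        ds.table.loc[0, f"{v}_t1"] = np.nan
    out = em_impute(ds, max_missing_fraction=0.75)
    # twin 1 of pair 0 exceeded the threshold: stays missing, twin 2 intact
    assert np.isnan(out.values("ELA")[0, 0])
    assert np.isfinite(out.values("ELA")[0, 1])
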