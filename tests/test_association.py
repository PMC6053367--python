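"""Detection core: factor estimation, OLS fits, BH, permutation machinery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

import agesplice as ag
from agesplice.association import (
    RankDeficiencyError,
    _fwl_age_tstats,
    estimate_confounders,
    estimate_hidden_factors,
)

RNG = np.random.default_rng


# ---------------------------------------------------------------- factors
def test_factor_recovers_rank_one_pattern_up_to_sign():
    rng = RNG(0)
    pattern = rng.normal(size=60)
    scale = rng.normal(size=40)
    x = np.outer(scale, pattern) + rng.normal(scale=1e-6, size=(40, 60))
    fac = estimate_hidden_factors(x, n_factors=2)
    # oracle: leading right singular vector of the row-centered matrix
    xc = x - x.mean(axis=1, keepdims=True)
    v = np.linalg.svd(xc, full_matrices=False)[2][0]
    r = abs(stats.pearsonr(fac.values.iloc[0], v).statistic)
    assert r > 0.99
    assert abs(fac.values.iloc[0].mean()) < 1e-10  # zero mean across samples


def test_duplicated_sample_columns_get_identical_factor_values():
    rng = RNG(1)
    x = rng.normal(size=(30, 20))
    x[:, 5] = x[:, 11]
    fac = estimate_hidden_factors(x, n_factors=4)
    assert np.allclose(fac.values.iloc[:, 5], fac.values.iloc[:, 11])


def test_noise_matrix_has_flat_spectrum():
    rng = RNG(2)
    x = rng.normal(size=(400, 200))
    xc = x - x.mean(axis=1, keepdims=True)
    s = np.linalg.svd(xc, compute_uv=False)
    frac = s**2 / np.sum(s**2)
    assert np.all(np.diff(frac[:20]) > -0.05)  # no factor dominates the next


def test_factor_dimension_error():
    with pytest.raises(ValueError):
        estimate_hidden_factors(np.zeros((10, 5)), n_factors=4)


def test_filter_drops_age_identical_factor_and_keeps_empty_input():
    ages = np.linspace(20, 70, 40)
    rng = RNG(3)
    vals = pd.DataFrame(
        [ages - ages.mean(), rng.normal(size=40)], index=["F1", "F2"]
    )
    fac = ag.HiddenFactors(vals)
    kept = ag.filter_age_correlated_factors(fac, ages)
    assert list(kept.values.index) == ["F2"]
    assert (kept.age_corr_pvalues >= 0.05).all()
    empty = ag.HiddenFactors(vals.iloc[:0])
    assert ag.filter_age_correlated_factors(empty, ages).n_factors == 0
    with pytest.raises(ValueError):
        ag.filter_age_correlated_factors(fac, np.full(40, 50.0))


def test_filter_type_one_rate_near_alpha():
    # a noise factor independent of age is dropped in ~5% of seeds
    ages = np.linspace(20, 70, 500)
    dropped = 0
    n_seeds = 400
    for s in range(n_seeds):
        f = pd.DataFrame([RNG(s).normal(size=500)], index=["F1"])
        kept = ag.filter_age_correlated_factors(ag.HiddenFactors(f), ages)
        dropped += kept.n_factors == 0
    rate = dropped / n_seeds
    assert 0.02 <= rate <= 0.09  # binomial(400, 0.05) 3.5-sigma band


def test_confounder_scores_keep_true_sample_pattern():
    # loadings learned on residuals, scores projected from raw data:
    # a batch factor's chance age correlation must survive in the score
    rng = RNG(11)
    n = 100
    ages = np.linspace(20, 70, n)
    gender = rng.integers(0, 2, n).astype(float)
    f = rng.normal(size=n) + 0.02 * (ages - ages.mean())  # slightly age-tilted
    lam = rng.normal(0, 1, size=300)
    x = np.outer(lam, f) + rng.normal(0, 0.3, size=(300, n))
    fac = estimate_confounders(x, ages, gender, n_factors=3)
    r = abs(stats.pearsonr(fac.values.iloc[0], f).statistic)
    assert r > 0.98


# ---------------------------------------------------------------- OLS fit
def test_exact_linear_fit_recovers_coefficient():
    ages = np.linspace(20, 70, 60)
    y = 0.5 + 0.01 * ages
    fit = ag.fit_age_model(y, ages, np.zeros(60), None, min_samples=50)
    assert fit.tested
    assert fit.beta_age == pytest.approx(0.01, abs=1e-12)
    assert fit.p_age < 1e-200 or fit.p_age == 0.0


def test_constant_response_and_small_samples_not_tested():
    ages = np.linspace(20, 70, 60)
    fit = ag.fit_age_model(np.full(60, 0.4), ages, np.zeros(60), None)
    assert not fit.tested and fit.reason == "zero_variance"
    y = np.full(60, -1.0)
    y[:20] = 0.5
    fit = ag.fit_age_model(y, ages, np.zeros(60), None, min_samples=50)
    assert not fit.tested and fit.reason == "insufficient_samples"
    assert fit.n_used == 20


def test_fit_matches_statsmodels_oracle_with_sentinels_and_factors():
    rng = RNG(4)
    n = 120
    ages = rng.uniform(20, 70, n)
    gender = rng.integers(0, 2, n).astype(float)
    fac = rng.normal(size=(3, n))
    y = 0.3 + 0.004 * ages + 0.1 * gender + fac.T @ [0.05, -0.02, 0.01] \
        + rng.normal(0, 0.1, n)
    y[rng.choice(n, 15, replace=False)] = -1.0
    fit = ag.fit_age_model(y, ages, gender, fac, min_samples=50)
    mask = (y != -1.0)
    x = sm.add_constant(np.column_stack([ages, gender, fac.T])[mask])
    res = sm.OLS(y[mask], x).fit()
    assert fit.beta_age == pytest.approx(res.params[1], rel=1e-10)
    assert fit.se_age == pytest.approx(res.bse[1], rel=1e-10)
    assert fit.p_age == pytest.approx(res.pvalues[1], rel=1e-8)
    assert fit.beta_gender == pytest.approx(res.params[2], rel=1e-10)
    assert np.allclose(fit.residuals, res.resid)


def test_collinear_design_names_offending_column():
    ages = np.linspace(20, 70, 60)
    y = 0.5 + 0.002 * ages + RNG(5).normal(0, 0.05, 60)
    with pytest.raises(RankDeficiencyError) as err:
        ag.fit_age_model(y, ages, np.zeros(60), ages[None, :], min_samples=50)
    # gender is all-zero here and age duplicates factor_1: both are flagged
    assert set(err.value.columns) & {"age", "gender", "factor_1"}


def test_ols_sampling_distribution_coverage():
    """beta_hat lands within +-2 SE of the planted 0.004 at ~95.4% frequency.

    400 seeds instead of the nominal 1000 keeps the suite fast; the binomial
    3-sigma band around 0.954 with 400 draws is [0.923, 0.985].
    """
    inside = 0
    n_seeds = 400
    for s in range(n_seeds):
        rng = RNG(1000 + s)
        ages = rng.uniform(20, 70, 150)
        y = 0.5 + 0.004 * ages + rng.normal(0, 0.05, 150)
        fit = ag.fit_age_model(y, ages, rng.integers(0, 2, 150).astype(float),
                               None, min_samples=50)
        inside += abs(fit.beta_age - 0.004) <= 2 * fit.se_age
    assert inside / n_seeds >= 0.923


# ---------------------------------------------------------------- BH
def test_bh_hand_computed_examples():
    assert np.allclose(
        ag.benjamini_hochberg([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5]
    )
    assert np.allclose(ag.benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)
    assert ag.benjamini_hochberg([0.2]) == pytest.approx([0.2])
    with pytest.raises(ValueError):
        ag.benjamini_hochberg([0.1, 1.2])


def _bh_bruteforce(p):
    """Literal step-up definition: q_i = min over j with p_j >= p_i of p_j*n/rank_j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    for pos in range(n - 1, -1, -1):
        val = p[order[pos]] * n / (pos + 1)
        if pos < n - 1:
            val = min(val, q[order[pos + 1]])
        q[order[pos]] = min(1.0, val)
    return q


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
def test_bh_matches_bruteforce_definition(pvals):
    assert np.allclose(
        ag.benjamini_hochberg(pvals), _bh_bruteforce(pvals), atol=1e-12, rtol=0
    )


# ---------------------------------------------------------------- permutations
def test_identity_permutation_reproduces_observed_fit():
    rng = RNG(6)
    n = 80
    ages = rng.uniform(20, 70, n)
    gender = rng.integers(0, 2, n).astype(float)
    y = 0.4 + 0.003 * ages + rng.normal(0, 0.1, n)
    fit = ag.fit_age_model(y, ages, gender, None, min_samples=50)
    z = np.column_stack([np.ones(n), gender])
    t, df = _fwl_age_tstats(y, ages[None, :], z)
    assert t[0] == pytest.approx(fit.t_age, rel=1e-10)
    assert df == fit.df_resid


def test_permutation_fraction_null_band_and_errors():
    rng = RNG(7)
    n = 400
    ages = rng.uniform(20, 70, n)
    gender = rng.integers(0, 2, n).astype(float)
    y = rng.uniform(0.2, 0.8, n)  # independent of everything
    frac = ag.permutation_null(y, ages, gender, None, n_perm=1000, seed=1)
    assert 0.03 <= frac <= 0.07  # binomial(1000, 0.05) concentration
    with pytest.raises(ValueError):
        ag.permutation_null(y, ages, gender, None, n_perm=0, seed=1)
    with pytest.raises(ValueError):
        ag.permutation_null(np.full(n, 0.5), ages, gender, None, n_perm=10, seed=1)


def test_permutation_fraction_near_alpha_even_for_strong_signal():
    # shuffling destroys the age link; the permuted t statistic is null
    # regardless of the response, so the fraction stays near 0.05
    ages = np.linspace(20, 70, 200)
    y = 0.2 + 0.01 * ages
    frac = ag.permutation_null(y, ages, np.zeros(200), None, n_perm=1000, seed=2)
    assert 0.02 <= frac <= 0.09


def test_call_significant_rules():
    df = pd.DataFrame(
        {
            "tested": [True, True, True, False],
            "beta_age": [0.01, -0.02, 0.005, np.nan],
            "q_value": [0.04, 0.04, 0.2, np.nan],
            "perm_pvalue": [0.02, 0.20, 0.01, np.nan],
            "perm_fraction": [0.04, 0.05, 0.05, np.nan],
        },
        index=["a", "b", "c", "d"],
    )
    out = ag.call_significant(df)
    assert out.loc["a", "significant"] and out.loc["a", "direction"] == 1
    assert not out.loc["b", "significant"]  # permutation veto
    assert not out.loc["c", "significant"]  # FDR veto
    assert not out.loc["d", "significant"] and out.loc["d", "direction"] == 0


def test_scan_results_independent_of_event_order(small_dataset):
    psi = small_dataset.psi.values.iloc[:30]
    pheno = small_dataset.cohort.table
    res1 = ag.scan_features(psi, pheno, n_factors=5, n_perm=50, seed=9)
    shuffled = psi.sample(frac=1.0, random_state=0)
    res2 = ag.scan_features(shuffled, pheno, n_factors=5, n_perm=50, seed=9)
    pd.testing.assert_frame_equal(res1.sort_index(), res2.sort_index())
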