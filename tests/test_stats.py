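"""Tertiles, adjusted OLS, mixed models, sensitivity re-fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from placentometry import stats
from placentometry.errors import ValidationError
from placentometry.synthetic_data import CohortGenSpec, generate_cohort


# --- tertiles --------------------------------------------------------------


def test_tertiles_of_one_to_nine():
    labels, cuts = stats.assign_tertiles(np.arange(1, 10, dtype=float))
    assert cuts == pytest.approx((11 / 3, 19 / 3), abs=1e-9)
    assert [int((labels == g).sum()) for g in (1, 2, 3)] == [3, 3, 3]


def test_tertile_ties_go_to_lower_group():
    v = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 4.0])
    labels, cuts = stats.assign_tertiles(v)
    # values equal to a cut point belong to the lower group
    assert (labels[v == cuts[0]] == 1).all() if (v == cuts[0]).any() else True
    assert set(labels) <= {1, 2, 3}
    assert len(labels) == len(v)


def test_constant_values_rejected():
    with pytest.raises(ValidationError):
        stats.assign_tertiles(np.full(9, 5.0))


def test_tertile_partition_balance():
    rng = np.random.default_rng(0)
    v = rng.normal(size=90)
    labels, _ = stats.assign_tertiles(v)
    sizes = sorted(int((labels == g).sum()) for g in (1, 2, 3))
    assert sizes[-1] - sizes[0] <= 1


# --- tertile comparison ----------------------------------------------------


def test_identical_groups_null_omnibus():
    vals = np.tile(np.arange(10, dtype=float), 3)
    groups = np.repeat([1, 2, 3], 10)
    res = stats.compare_tertiles(vals, groups)
    assert res.p_value > 0.99
    assert (res.posthoc.p_adj > 0.99).all()


def test_shifted_group_detected_with_correct_pairs():
    rng = np.random.default_rng(1)
    vals = np.concatenate([rng.normal(0, 0.5, 30), rng.normal(0, 0.5, 30),
                           rng.normal(1, 0.5, 30)])
    groups = np.repeat([1, 2, 3], 30)
    res = stats.compare_tertiles(vals, groups)
    assert res.p_value < 0.01
    ph = res.posthoc.set_index(["group_a", "group_b"]).p_adj
    assert ph[(1, 3)] < 0.05 and ph[(2, 3)] < 0.05
    assert ph[(1, 2)] > 0.05


def test_skewed_data_takes_nonparametric_path():
    rng = np.random.default_rng(2)
    vals = np.concatenate([rng.lognormal(0, 1.5, 40) for _ in range(3)])
    groups = np.repeat([1, 2, 3], 40)
    res = stats.compare_tertiles(vals, groups)
    assert res.test_used == "kw_bonf_mwu"


def test_anova_path_matches_independent_computation():
    """Omnibus F/p equal a from-scratch one-way ANOVA on 10 random datasets."""
    rng = np.random.default_rng(3)
    for _ in range(10):
        samples = [rng.normal(rng.normal(), 1.0, 25) for _ in range(3)]
        vals = np.concatenate(samples)
        groups = np.repeat([1, 2, 3], 25)
        res = stats.compare_tertiles(vals, groups)
        if res.test_used != "anova_tukey":
            continue
        # hand-computed F statistic
        grand = vals.mean()
        ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
        f = (ssb / 2) / (ssw / (len(vals) - 3))
        p = sps.f.sf(f, 2, len(vals) - 3)
        assert res.statistic == pytest.approx(f, rel=1e-8)
        assert res.p_value == pytest.approx(p, rel=1e-8)


def test_bonferroni_mwu_matches_direct_product():
    rng = np.random.default_rng(4)
    samples = [rng.lognormal(0, 1.5, 30) for _ in range(3)]
    vals = np.concatenate(samples)
    groups = np.repeat([1, 2, 3], 30)
    res = stats.compare_tertiles(vals, groups)
    assert res.test_used == "kw_bonf_mwu"
    for (i, j), row in zip([(0, 1), (0, 2), (1, 2)],
                           res.posthoc.itertuples()):
        raw = sps.mannwhitneyu(samples[i], samples[j],
                               alternative="two-sided").pvalue
        assert row.p_adj == pytest.approx(min(1.0, 3 * raw), rel=1e-10)


# --- adjusted OLS ----------------------------------------------------------


def small_cohort(seed=0, n=92, **kw):
    return generate_cohort(CohortGenSpec(n=n, seed=seed, **kw))


def test_noiseless_linear_recovery_is_exact():
    df = small_cohort(seed=5)
    df["y"] = 1.0 + 2.0 * df["mvpa"]
    fit = stats.fit_adjusted_model(df, "y")
    assert fit.beta("mvpa") == pytest.approx(2.0, abs=1e-10)
    lo, hi = fit.ci("mvpa")
    assert hi - lo < 1e-8


def test_standardized_beta_formula():
    df = small_cohort(seed=6)
    fit = stats.fit_adjusted_model(df, "density_villi_whole")
    p = fit.params.set_index("term")
    for term in ("mvpa", "st_pct", "age"):
        expected = p.loc[term, "beta"] * df[term].std(ddof=1) \
            / df["density_villi_whole"].std(ddof=1)
        assert p.loc[term, "sb"] == pytest.approx(expected, abs=1e-10)


def test_ols_matches_normal_equations():
    rng = np.random.default_rng(7)
    for _ in range(5):
        df = small_cohort(seed=int(rng.integers(1e6)))
        fit = stats.fit_adjusted_model(df, "density_villi_whole")
        X = np.column_stack([np.ones(len(df))]
                            + [df[t].to_numpy(dtype=float)
                               for t in ("mvpa", "st_pct", "age", "bmi",
                                         "gdm", "fetal_sex")])
        y = df["density_villi_whole"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        got = fit.params.beta.to_numpy()
        assert np.allclose(got, beta, atol=1e-8)


def test_rank_deficient_design_named():
    df = small_cohort(seed=8)
    df["bmi"] = df["age"] * 2.0
    with pytest.raises(ValidationError, match="collinear"):
        stats.fit_adjusted_model(df, "density_villi_whole")


def test_row_permutation_invariance():
    df = small_cohort(seed=9)
    fit1 = stats.fit_adjusted_model(df, "density_villi_whole")
    rng = np.random.default_rng(0)
    perm = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    fit2 = stats.fit_adjusted_model(perm, "density_villi_whole")
    assert np.allclose(fit1.params.beta, fit2.params.beta, atol=1e-10)


def test_complete_case_count_reported():
    df = small_cohort(seed=10)
    df.loc[:4, "bmi"] = np.nan
    fit = stats.fit_adjusted_model(df, "density_villi_whole")
    assert fit.n_used == len(df) - 5


def test_sex_interaction_terms_added():
    df = small_cohort(seed=11)
    fit = stats.fit_adjusted_model(df, "density_villi_whole", sex_interaction=True)
    assert "mvpa:fetal_sex" in set(fit.params.term)
    assert "st_pct:fetal_sex" in set(fit.params.term)


# --- mixed models ----------------------------------------------------------


def test_null_cluster_variance_estimated_near_zero():
    vars_ = []
    for r in range(25):
        df = small_cohort(seed=200 + r, country_random_intercept_sd=0.0,
                          residual_sd=1.0)
        vars_.append(stats.fit_mixed_model(df, "density_villi_whole")
                     .cluster_variance)
    assert np.median(vars_) <= 0.1


def test_cluster_variance_recovery():
    """Country intercept SD 2.0, 9 countries x ~10 women: the median variance
    estimate over replicates lies in a band covering the true value 4.0."""
    vars_ = []
    for r in range(40):
        df = small_cohort(seed=300 + r, n=90, country_random_intercept_sd=2.0)
        vars_.append(stats.fit_mixed_model(df, "density_villi_whole")
                     .cluster_variance)
    assert 1.0 <= np.median(vars_) <= 9.0


def test_mixed_fixed_effects_match_ols_without_clustering():
    df = small_cohort(seed=12, country_random_intercept_sd=0.0)
    ols = stats.fit_adjusted_model(df, "density_villi_whole")
    mix = stats.fit_mixed_model(df, "density_villi_whole")
    assert np.allclose(mix.params.beta, ols.params.beta, atol=1e-3)


def test_single_cluster_rejected():
    df = small_cohort(seed=13)
    df["country"] = "AT"
    with pytest.raises(ValidationError):
        stats.fit_mixed_model(df, "density_villi_whole")


# --- sensitivity -----------------------------------------------------------


def test_no_flags_identical_to_main():
    df = small_cohort(seed=14)
    df["smoking"] = 0
    df["pe_pih"] = 0
    fits = stats.sensitivity_analysis(df, "density_villi_whole")
    assert np.allclose(fits["no_smoking"].params.beta,
                       fits["main"].params.beta, atol=1e-12)
    assert np.allclose(fits["no_pe_pih"].params.beta,
                       fits["main"].params.beta, atol=1e-12)


def test_flagged_rows_reduce_n_exactly():
    df = small_cohort(seed=15)
    k = int(df["smoking"].sum())
    fits = stats.sensitivity_analysis(df, "density_villi_whole")
    assert fits["no_smoking"].n_used == fits["main"].n_used - k
    # GDM covariate dropped in the no-GDM subset
    assert "gdm" not in set(fits["no_gdm"].params.term)


def test_homogeneous_effects_give_similar_subset_betas():
    """With identical effects in all subgroups, each subset's MVPA beta stays
    within ~2 Monte-Carlo SEs of the main estimate."""
    diffs, ses = [], []
    for r in range(20):
        df = small_cohort(seed=400 + r)
        fits = stats.sensitivity_analysis(df, "density_villi_whole")
        diffs.append(fits["no_smoking"].beta("mvpa") - fits["main"].beta("mvpa"))
    assert abs(np.mean(diffs)) < 0.02
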