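"""Welch ANOVA, Kruskal-Wallis, group summaries and bootstrap fold CIs."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gardensage import (
    SimDesign,
    analyze_all,
    default_profiles,
    fold_change_ci,
    generate_count_matrix,
    group_summary,
    kruskal_wallis,
    welch_anova,
)
from gardensage.errors import (
    DegenerateVarianceError,
    DesignError,
    InsufficientReplicatesError,
    InvalidConfigError,
)
from gardensage.filtering import FilterConfig, apply_filters


def welch_oracle(groups):
    """Independent textbook transcription of Welch's heteroscedastic F."""
    k = len(groups)
    n = [len(g) for g in groups]
    m = [sum(g) / len(g) for g in groups]
    v = [sum((x - mi) ** 2 for x in g) / (ni - 1)
         for g, mi, ni in zip(groups, m, n)]
    w = [ni / vi for ni, vi in zip(n, v)]
    W = sum(w)
    grand = sum(wi * mi for wi, mi in zip(w, m)) / W
    A = sum(wi * (mi - grand) ** 2 for wi, mi in zip(w, m)) / (k - 1)
    B = sum((1 - wi / W) ** 2 / (ni - 1) for wi, ni in zip(w, n))
    F = A / (1 + 2 * (k - 2) * B / (k ** 2 - 1))
    df2 = (k ** 2 - 1) / (3 * B)
    return F, df2, sps.f.sf(F, k - 1, df2)


class TestGroupSummary:
    def test_zero_variance_interval_collapses(self):
        g = group_summary([5, 5, 5, 5])
        assert (g.mean, g.ci_low, g.ci_high) == (5.0, 5.0, 5.0)

    def test_closed_form_t_interval_with_clipping(self):
        # mean 20, sd 10, margin t_{0.975,2} * 10/sqrt(3) = 24.84: the lower
        # bound -4.84 is clipped to zero
        g = group_summary([10, 20, 30])
        assert g.mean == pytest.approx(20.0)
        assert g.ci_low == 0.0
        assert g.ci_high == pytest.approx(44.84, abs=0.01)

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            group_summary([7])


class TestWelchAnova:
    def test_identical_groups_give_null(self):
        res = welch_anova([[1, 2, 3]] * 3)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_independent_formula_exactly(self):
        groups = [[10, 12, 14], [20, 22, 24], [30, 32, 34]]
        res = welch_anova(groups)
        F, df2, p = welch_oracle(groups)
        assert res.statistic == pytest.approx(F, abs=1e-10)
        assert res.df_den == pytest.approx(df2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pingouin_on_random_data(self, seed):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        groups = [rng.normal(rng.uniform(0, 10), rng.uniform(0.5, 4), n)
                  for n in (5, 4, 7)]
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(["a", "b", "c"], [len(g) for g in groups]),
        })
        expected = pingouin.welch_anova(data=df, dv="y", between="g")
        res = welch_anova(groups)
        assert res.statistic == pytest.approx(expected["F"][0], rel=1e-9)
        p_col = "p_unc" if "p_unc" in expected else "p-unc"
        assert res.p_value == pytest.approx(expected[p_col][0], rel=1e-9)
        assert res.df_den == pytest.approx(expected["ddof2"][0], rel=1e-9)

    def test_two_groups_equal_squared_welch_t(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 3, 8)
        res = welch_anova([a, b])
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(t ** 2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_reduces_to_classic_anova_with_equal_variances(self):
        # two groups with identical within-group variances and sizes:
        # Welch F equals the classical one-way F exactly (the small-sample
        # denominator correction vanishes at k = 2)
        groups = [[1, 2, 3], [11, 12, 13]]
        res = welch_anova(groups)
        f_classic = sps.f_oneway(*groups).statistic
        assert res.statistic == pytest.approx(f_classic, abs=1e-8)
        # at k = 3 the correction is the exact factor 1 + 2(k-2)Lambda/(k^2-1)
        groups3 = [[1, 2, 3], [11, 12, 13], [24, 25, 26]]
        res3 = welch_anova(groups3)
        lam = sum((1 - 1 / 3) ** 2 / 2 for _ in range(3))
        corrected = sps.f_oneway(*groups3).statistic / (1 + 2 * 1 * lam / 8)
        assert res3.statistic == pytest.approx(corrected, abs=1e-8)

    def test_zero_variance_group_raises(self):
        with pytest.raises(DegenerateVarianceError):
            welch_anova([[5, 5, 5], [1, 2, 3]])


def kw_permutation_oracle(groups):
    """Exact p by brute force over all permutations of the pooled values
    (feasible only for tiny n); independent of the package's
    combination-based enumeration."""
    sizes = [len(g) for g in groups]
    pooled = tuple(itertools.chain.from_iterable(groups))

    def h_of(perm):
        arrays, start = [], 0
        for n in sizes:
            arrays.append(perm[start:start + n])
            start += n
        try:
            return sps.kruskal(*arrays).statistic
        except ValueError:  # all values identical
            return 0.0

    h_obs = h_of(pooled)
    perms = list(itertools.permutations(pooled))
    hits = sum(h_of(p) >= h_obs - 1e-9 for p in perms)
    return hits / len(perms)


class TestKruskalWallis:
    def test_identical_groups_are_null_not_error(self):
        res = kruskal_wallis([[3, 3], [3, 3], [3, 3]])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_asymptotic_matches_scipy(self, rng):
        groups = [rng.integers(0, 50, 5).astype(float) for _ in range(3)]
        res = kruskal_wallis(groups)
        stat, p = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.normal(i, 1, 5) for i in range(3)]
        res1 = kruskal_wallis(groups)
        res2 = kruskal_wallis([np.exp(g) for g in groups])
        assert res1.statistic == pytest.approx(res2.statistic)
        assert res1.p_value == pytest.approx(res2.p_value)

    def test_exact_p_matches_full_permutation_enumeration(self):
        groups = [[0.0, 0.0, 0.0], [1.0, 2.0], [5.0, 6.0, 7.0]]  # n = 8
        res = kruskal_wallis(groups, exact=True)
        assert res.exact
        assert res.p_value == pytest.approx(kw_permutation_oracle(groups))

    def test_exact_p_matches_monte_carlo_at_study_size(self, rng):
        # 5/4/5 exceeds feasible full-permutation enumeration; check the
        # exact enumeration against a large Monte-Carlo permutation sample
        groups = [[0, 0, 0, 0, 0], [1, 2, 3, 4], [5, 6, 7, 8, 9]]
        res = kruskal_wallis([np.asarray(g, float) for g in groups],
                             exact=True)
        pooled = np.array(list(itertools.chain.from_iterable(groups)), float)
        sizes = [len(g) for g in groups]
        n_mc = 40_000
        hits = 0
        h_obs = res.statistic
        for _ in range(n_mc):
            perm = rng.permutation(pooled)
            arrays, start = [], 0
            for n in sizes:
                arrays.append(perm[start:start + n])
                start += n
            try:
                h = sps.kruskal(*arrays).statistic
            except ValueError:
                h = 0.0
            hits += h >= h_obs - 1e-9
        mc_p = hits / n_mc
        se = math.sqrt(mc_p * (1 - mc_p) / n_mc)
        assert abs(res.p_value - mc_p) < 4 * max(se, 1e-4)


class TestFoldChange:
    def test_identical_groups_point_one_ci_covers_one(self):
        vals = [10.0, 12.0, 9.0, 11.0, 10.0]
        est = fold_change_ci(vals, vals, n_boot=2000, seed=1)
        assert est.point == pytest.approx(1.0)
        assert est.ci_low <= 1.0 <= est.ci_high

    def test_point_invariant_to_simulation_settings(self, rng):
        top = rng.poisson(50, 5).astype(float)
        bot = rng.poisson(200, 5).astype(float)
        estimates = [fold_change_ci(top, bot, n_boot=nb, seed=s)
                     for nb, s in [(500, 0), (5000, 1), (500, 2)]]
        assert len({e.point for e in estimates}) == 1
        assert estimates[0].point == pytest.approx(bot.mean() / top.mean())

    def test_zero_denominator_gives_na(self):
        est = fold_change_ci([0.0, 0.0, 0.0], [5.0, 6.0, 7.0], seed=0)
        assert est.is_na
        assert math.isnan(est.ci_low) and math.isnan(est.ci_high)

    def test_small_n_boot_rejected(self):
        with pytest.raises(InvalidConfigError):
            fold_change_ci([1.0, 2.0], [3.0, 4.0], n_boot=50, seed=0)

    def test_interval_converges_as_n_boot_doubles(self, rng):
        top = rng.poisson(100, 5).astype(float)
        bot = rng.poisson(400, 5).astype(float)
        a = fold_change_ci(top, bot, n_boot=10_000, seed=3)
        b = fold_change_ci(top, bot, n_boot=20_000, seed=4)
        half_a = (a.ci_high - a.ci_low) / 2
        half_b = (b.ci_high - b.ci_low) / 2
        assert abs(half_a - half_b) / half_a < 0.02

    def test_matches_scipy_bootstrap_oracle(self, rng):
        top = rng.poisson(80, 5).astype(float)
        bot = rng.poisson(240, 5).astype(float)
        est = fold_change_ci(top, bot, n_boot=40_000, seed=5)
        oracle = sps.bootstrap(
            (bot, top), lambda b, t, axis: b.mean(axis=axis) / t.mean(axis=axis),
            n_resamples=40_000, method="percentile", vectorized=True,
            axis=-1, random_state=np.random.default_rng(6))
        assert est.ci_low == pytest.approx(oracle.confidence_interval.low,
                                           rel=0.05)
        assert est.ci_high == pytest.approx(oracle.confidence_interval.high,
                                            rel=0.05)


@pytest.fixture(scope="module")
def analyzed():
    design = SimDesign(n_tags=60, seed=11)
    matrix, truth = generate_count_matrix(design, default_profiles(design))
    filtered, _ = apply_filters(matrix, FilterConfig())
    results = analyze_all(filtered, n_boot=500, seed=7)
    return results, truth


class TestAnalyzeAll:

    def test_zero_in_top_dispatches_to_rank_test(self, analyzed):
        results, truth = analyzed
        by_id = {r.tag_id: r for r in results}
        for tag_id, prof in truth.profiles.items():
            if prof.klass == "zero_in_top" and tag_id in by_id:
                assert by_id[tag_id].method == "kruskal_wallis"
                assert by_id[tag_id].fold is not None

    def test_results_sorted_by_p_value(self, analyzed):
        results, _ = analyzed
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)

    def test_flat_tag_is_null_under_welch(self):
        from gardensage.matrix import TagCountMatrix
        design = SimDesign(n_tags=1, seed=0)
        libs = design.libraries()
        # equal section means, nonzero variance: Welch F = 0, p = 1
        row = [9, 10, 11, 10, 10, 9, 10, 11, 10, 9, 10, 11, 10, 10]
        counts = pd.DataFrame([row], index=pd.Index([1], name="tag_id"),
                              columns=[lk.library_id for lk in libs],
                              dtype=float)
        m = TagCountMatrix(counts=counts,
                           sequences=pd.Series(["A" * 17],
                                               index=counts.index),
                           libraries=libs, state="normalized")
        (res,) = analyze_all(m, n_boot=200, seed=0)
        assert res.method == "welch"
        assert res.p_value == pytest.approx(1.0)

    def test_bh_qvalues_monotone(self, analyzed):
        design = SimDesign(n_tags=40, seed=5)
        matrix, _ = generate_count_matrix(design)
        filtered, _ = apply_filters(matrix)
        results = analyze_all(filtered, n_boot=200, seed=1, bh=True)
        qs = [r.q_value for r in results]
        assert all(q is not None for q in qs)
        assert qs == sorted(qs)
        assert all(r.q_value >= r.p_value - 1e-12 for r in results)

    def test_unassigned_section_is_design_error(self):
        design = SimDesign(n_tags=5, seed=0,
                           sections=("alpha", "beta", "gamma"))
        matrix, _ = generate_count_matrix(design)
        norm = matrix.with_counts(matrix.counts.astype(float) + 1.0,
                                  "normalized")
        with pytest.raises(DesignError):
            analyze_all(norm)  # default sections not present in this design
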