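"""Summary-statistic tests, correlation layer, and the printed-table fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sst

from glymmark import cohort_stats as cs
from glymmark import tables as tb

TABLE1 = tb.load_table("table1")
TABLE2 = tb.load_table("table2")


def _recompute(groups, kind):
    if kind == "anova":
        return cs.anova_oneway(groups).statistic
    return cs.t_test(groups[0], groups[1], variant="auto").statistic


def _attainable_range(groups, kind, input_ulp):
    """Min/max statistic over half-ulp roundings of every printed mean/sd.

    The printed summaries are rounded; a recomputed statistic matches
    the printed one if the latter is attainable from some summaries
    that round to the printed values.  Corners of the perturbation box
    bound the (monotone-per-input) statistic well in practice.
    """
    import itertools

    half = 0.5 * input_ulp
    lo, hi = np.inf, -np.inf
    for corner in itertools.product((-half, 0.0, half), repeat=2 * len(groups)):
        perturbed = [
            cs.GroupSummary(g.label, g.n, g.mean + corner[2 * i], g.sd + corner[2 * i + 1])
            for i, g in enumerate(groups)
        ]
        stat = _recompute(perturbed, kind)
        lo, hi = min(lo, stat), max(hi, stat)
    return lo, hi


# (table, variable, test kind, printed statistic, ulp of the printed inputs)
PRINTED_STATISTICS = [
    (TABLE1, "age", "anova", 2.194, 0.01),
    (TABLE1, "hama", "anova", 198.908, 0.01),
    (TABLE1, "hamd", "anova", 57.300, 0.01),
    (TABLE1, "alps_mean", "anova", 3.486, 0.001),
    (TABLE1, "alps_left", "anova", 1.771, 0.001),
    (TABLE1, "alps_right", "anova", 4.761, 0.001),
    (TABLE1, "ledd", "t", -0.005, 0.01),
    (TABLE1, "duration", "t", 2.573, 0.01),
    (TABLE1, "hy", "t", 1.918, 0.01),
    (TABLE1, "updrs3", "t", 1.442, 0.01),
    (TABLE2, "age", "anova", 2.325, 0.01),
    (TABLE2, "hama", "anova", 143.319, 0.01),
    (TABLE2, "hamd", "anova", 45.207, 0.01),
    (TABLE2, "coupling", "anova", 3.146, 0.001),
    (TABLE2, "alps_mean", "anova", 3.061, 0.001),
    (TABLE2, "alps_left", "anova", 1.124, 0.001),
    (TABLE2, "alps_right", "anova", 5.020, 0.001),
    (TABLE2, "ledd", "t", 1.057, 0.01),
    (TABLE2, "duration", "t", 2.734, 0.01),
    (TABLE2, "hy", "t", 2.767, 0.01),
    (TABLE2, "updrs3", "t", 1.465, 0.01),
]


class TestPrintedTables:
    @pytest.mark.parametrize(
        "table,var,kind,printed,input_ulp",
        PRINTED_STATISTICS,
        ids=[f"{ 't1' if t is TABLE1 else 't2'}-{v}" for t, v, *_ in PRINTED_STATISTICS],
    )
    def test_recomputed_statistic_matches_printed(self, table, var, kind, printed, input_ulp):
        groups = tb.group_summaries(table, var)
        stat = _recompute(groups, kind)
        if abs(stat - printed) <= max(0.01 * abs(printed), 5e-4):
            return
        lo, hi = _attainable_range(groups, kind, input_ulp)
        assert lo - 0.01 * abs(printed) <= printed <= hi + 0.01 * abs(printed), (
            f"{var}: recomputed {stat:.4f}, printed {printed}, "
            f"attainable [{lo:.4f}, {hi:.4f}]"
        )

    @pytest.mark.parametrize(
        "table,printed", [(TABLE1, 2.315), (TABLE2, 1.043)], ids=["t1", "t2"]
    )
    def test_sex_chi_square_matches_printed(self, table, printed):
        stat = cs.chi_square(tb.sex_contingency(table)).statistic
        assert abs(stat - printed) <= 0.01 * printed


class TestVarianceGate:
    def test_disease_duration_routes_to_welch(self):
        a, b = tb.group_summaries(TABLE1, "duration")
        assert cs.variance_gate(a, b) == "welch"

    def test_hy_routes_to_pooled(self):
        a, b = tb.group_summaries(TABLE1, "hy")
        assert cs.variance_gate(a, b) == "pooled"

    def test_equal_sds_route_to_pooled(self):
        a = cs.GroupSummary("a", 20, 0.0, 1.0)
        b = cs.GroupSummary("b", 30, 1.0, 1.0)
        assert cs.variance_gate(a, b) == "pooled"

    def test_gate_p_value_matches_monte_carlo_f_distribution(self):
        # independent oracle: simulate the variance-ratio null at (n=21, 47)
        a, b = tb.group_summaries(TABLE1, "duration")
        f_obs = a.sd**2 / b.sd**2
        rng = np.random.default_rng(0)
        reps = 20000
        va = rng.standard_normal((reps, a.n)).var(axis=1, ddof=1)
        vb = rng.standard_normal((reps, b.n)).var(axis=1, ddof=1)
        ratio = va / vb
        p_mc = 2 * min((ratio >= f_obs).mean(), (ratio <= f_obs).mean())
        p_analytic = 2 * min(
            sst.f.cdf(f_obs, a.n - 1, b.n - 1), sst.f.sf(f_obs, a.n - 1, b.n - 1)
        )
        assert p_analytic < 0.05  # drives the welch routing
        assert abs(p_mc - p_analytic) < 0.01


class TestTTestAndAnova:
    def test_identical_groups_give_null_t(self):
        g = cs.GroupSummary("g", 25, 3.0, 1.5)
        res = cs.t_test(g, g)
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_summary_and_raw_agree_to_1e10(self):
        rng = np.random.default_rng(5)
        groups_raw = [rng.normal(loc, 1.0, size=n) for loc, n in ((0, 12), (0.5, 18), (1, 9))]
        sums = [cs.summarize(g, str(i)) for i, g in enumerate(groups_raw)]
        f_raw = cs.anova_oneway(groups_raw).statistic
        f_sum = cs.anova_oneway(sums).statistic
        assert abs(f_raw - f_sum) < 1e-10
        t_raw = cs.t_test(groups_raw[0], groups_raw[1], variant="pooled").statistic
        t_sum = cs.t_test(sums[0], sums[1], variant="pooled").statistic
        assert abs(t_raw - t_sum) < 1e-10

    def test_anova_matches_scipy_on_raw_data(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(i * 0.3, 1.0, size=15) for i in range(3)]
        res = cs.anova_oneway(groups)
        ref = sst.f_oneway(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_equal_means_give_zero_f(self):
        gs = [cs.GroupSummary(str(i), 10, 5.0, 1.0 + i) for i in range(3)]
        assert cs.anova_oneway(gs).statistic == 0.0

    def test_pairwise_bonferroni_attached(self):
        groups = tb.group_summaries(TABLE1, "hama")
        res = cs.anova_oneway(groups, bonferroni_pairs=True)
        assert len(res.pairwise) == 3
        assert all(0 <= p <= 1 for p in res.pairwise.values())


class TestChiSquareAndKruskal:
    def test_expected_table_gives_zero(self):
        assert cs.chi_square([[10, 20], [20, 40]]).statistic == pytest.approx(0.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            cs.chi_square([[0, 0], [5, 5]])

    def test_kruskal_matches_hand_ranked_example(self):
        # ranks 1..9 without ties: H = 12/(9*10) * 3*((2-5)^2+(5-5)^2+(8-5)^2)
        res = cs.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2, rel=1e-12)

    def test_kruskal_identical_groups_zero_and_all_tied_error(self):
        assert cs.kruskal_wallis([[1, 2, 3]] * 3).statistic == pytest.approx(0.0)
        with pytest.raises(ValueError, match="tied"):
            cs.kruskal_wallis([[1, 1], [1, 1]])

    def test_kruskal_null_distribution_is_chi_square(self):
        rng = np.random.default_rng(7)
        pooled = rng.standard_normal(30)
        hs = []
        for _ in range(1000):
            perm = rng.permutation(pooled)
            hs.append(cs.kruskal_wallis([perm[:10], perm[10:20], perm[20:]]).statistic)
        assert sst.kstest(hs, sst.chi2(2).cdf).pvalue > 0.01


class TestBonferroni:
    def test_arithmetic_examples(self):
        assert cs.bonferroni_pairwise([0.01], m=3) == [pytest.approx(0.03)]
        assert cs.bonferroni_pairwise([0.5], m=3) == [1.0]
        assert cs.bonferroni_pairwise([0.2], m=1) == [pytest.approx(0.2)]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_monotone_and_capped(self, pvals):
        adj = cs.bonferroni_pairwise(pvals)
        assert all(0 <= a <= 1 for a in adj)
        assert all(a >= p or a == 1.0 for p, a in zip(pvals, adj))
        order = np.argsort(pvals)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-15)


class TestCorrelations:
    def test_partial_without_covariates_equals_pearson(self):
        rng = np.random.default_rng(8)
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        res = cs.partial_correlation(x, y)
        r_ref, _ = cs.pearson_correlation(x, y)
        assert res.r == pytest.approx(r_ref, rel=1e-12)

    def test_residualization_matches_recursive_formula(self):
        # 5-point worked example; textbook identity
        # r_xy.z = (r_xy - r_xz r_zy) / sqrt((1-r_xz^2)(1-r_zy^2))
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        z = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        y = x + z
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        rzy = np.corrcoef(z, y)[0, 1]
        expected = (rxy - rxz * rzy) / np.sqrt((1 - rxz**2) * (1 - rzy**2))
        res = cs.partial_correlation(x, y, covariates=z[:, None])
        assert res.r == pytest.approx(expected, abs=1e-12)
        assert res.df == 5 - 2 - 1

    def test_matches_pingouin_with_multiple_covariates(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(9)
        n = 60
        cov = rng.standard_normal((n, 3))
        x = cov @ [0.5, -0.2, 0.1] + rng.standard_normal(n)
        y = 0.4 * x + cov @ [0.3, 0.3, -0.4] + rng.standard_normal(n)
        df = pd.DataFrame(
            {"x": x, "y": y, "c0": cov[:, 0], "c1": cov[:, 1], "c2": cov[:, 2]}
        )
        ref = pg.partial_corr(df, x="x", y="y", covar=["c0", "c1", "c2"])
        res = cs.partial_correlation(x, y, cov, ["c0", "c1", "c2"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_rank_deficient_covariates_rejected(self):
        x = np.arange(10.0)
        y = np.arange(10.0)
        cov = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="rank deficient"):
            cs.partial_correlation(x, y, cov)

    def test_generator_partial_correlation_recovery(self):
        # large-n cohort; group indicator among covariates recovers the
        # within-group latent target
        from glymmark.synthetic import CohortSpec, generate_cohort

        spec = CohortSpec.from_table("table1", n_multiplier=20, seed=10,
                                     alps_hama_r=-0.28)
        df = generate_cohort(spec)
        sub = df[df["group"].isin(("PD-A", "PD-NA"))]
        covs = np.column_stack(
            [
                sub["age"],
                sub["sex_male"],
                sub["education"],
                sub["duration"],
                sub["hy"],
                (sub["group"] == "PD-A").astype(float),
            ]
        )
        res = cs.partial_correlation(sub["alps_right"], sub["hama"], covs)
        assert abs(res.r - (-0.28)) < 0.03

    def test_pearson_affine_extremes(self):
        x = np.arange(10.0)
        assert cs.pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert cs.pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_pearson_null_p_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(1000):
            x, y = rng.standard_normal(86), rng.standard_normal(86)
            ps.append(cs.pearson_correlation(x, y)[1])
        assert sst.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            cs.pearson_correlation(np.ones(10), np.arange(10.0))
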