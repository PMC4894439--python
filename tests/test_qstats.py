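"""Q statistics, decomposition rule, significance, decision rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pathq as pq
from pathq.exceptions import (
    DegreesOfFreedomError,
    InvalidParameterError,
    PerfectFitError,
)
from pathq.qstats import check_decomposition, empirical_pvalue
from pathq.reconstruction import Caps


def _qres(rss_null, rss_hom, rss_het, **dfs):
    return pq.q_statistics_from_rss(rss_null, rss_hom, rss_het, **dfs)


DFS = dict(u_c=2, v_c=10, u_d=3, v_d=8, u_t=5, v_t=8)


class TestQFromRSS:
    def test_hand_arithmetic_triple(self):
        q = _qres(16.0, 10.0, 4.0, **DFS)
        assert q.q_c == pytest.approx(3.0)
        assert q.q_d == pytest.approx(4.0)
        assert q.q_t == pytest.approx(4.8)

    def test_no_heterogeneity_improvement(self):
        q = _qres(16.0, 4.0, 4.0, **DFS)
        assert q.q_d == 0.0

    def test_no_homogeneous_signal(self):
        q = _qres(10.0, 10.0, 4.0, **DFS)
        assert q.q_c == 0.0

    def test_perfect_fit_error(self):
        with pytest.raises(PerfectFitError):
            _qres(16.0, 10.0, 0.0, **DFS)

    def test_nonpositive_v_error(self):
        bad = dict(DFS, v_d=0)
        with pytest.raises(DegreesOfFreedomError):
            _qres(16.0, 10.0, 4.0, **bad)

    def test_negative_numerator_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            q = _qres(16.0, 3.9, 4.0, **DFS)
        assert q.q_d == 0.0


class TestDecomposition:
    def test_worked_triple_identity(self):
        agg = pq.RSSAggregate(rss_hom=10.0, rss_het=4.0, rss_null=16.0,
                              m1=0, m2=0, m12=0, m0=0, n1=0, n2=0)
        q = _qres(16.0, 10.0, 4.0, **DFS)
        # 5*4.8*0.5 = 2*3*1 + 3*4*0.5 -> 12 = 6 + 6
        assert check_decomposition(q, agg) < 1e-12

    def test_zero_qd_case_exact(self):
        agg = pq.RSSAggregate(rss_hom=4.0, rss_het=4.0, rss_null=16.0,
                              m1=0, m2=0, m12=0, m0=0, n1=0, n2=0)
        q = _qres(16.0, 4.0, 4.0, **DFS)
        assert check_decomposition(q, agg) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=300)
    @given(st.floats(1e-6, 1e3), st.floats(1e-6, 1e3), st.floats(1e-6, 1e3),
           st.integers(1, 20), st.integers(1, 20),
           st.integers(1, 200), st.integers(1, 200))
    def test_identity_on_random_nested_triples(self, a, b, c, u_c, u_d, v_c, v_d):
        """RSS_het <= RSS_hom <= RSS_null by construction of the increments."""
        rss_het = a
        rss_hom = a + b
        rss_null = a + b + c
        q = pq.q_statistics_from_rss(rss_null, rss_hom, rss_het,
                                     u_c=u_c, v_c=v_c, u_d=u_d, v_d=v_d,
                                     u_t=u_c + u_d, v_t=v_d)
        agg = pq.RSSAggregate(rss_hom=rss_hom, rss_het=rss_het,
                              rss_null=rss_null, m1=0, m2=0, m12=0, m0=0,
                              n1=0, n2=0)
        assert check_decomposition(q, agg) <= 1e-9 * max(1.0, rss_null)


class TestComputeQFromAggregate:
    def test_df_derivation_from_complexities(self):
        agg = pq.RSSAggregate(rss_hom=10.0, rss_het=4.0, rss_null=16.0,
                              m1=6, m2=6, m12=6, m0=3, n1=50, n2=50)
        q = pq.compute_q(agg)
        assert (q.u_d, q.v_d) == (6, 88)
        assert (q.u_c, q.v_c) == (3, 94)
        assert (q.u_t, q.v_t) == (9, 88)

    def test_pooled_equals_null_gives_zero_qc(self):
        # all children intercept-only: m12 == m0, u_c == 0
        agg = pq.RSSAggregate(rss_hom=8.0, rss_het=6.0, rss_null=8.0,
                              m1=3, m2=3, m12=3, m0=3, n1=20, n2=20)
        q = pq.compute_q(agg)
        assert q.u_c == 0 and q.q_c == 0.0
        assert pq.asymptotic_pvalues(q).p_c == 1.0


class TestAsymptoticPvalues:
    def test_zero_statistic_upper_tail_is_one(self):
        q = _qres(16.0, 4.0, 4.0, **DFS)
        assert pq.asymptotic_pvalues(q).p_d == pytest.approx(1.0)

    def test_known_f_tail(self):
        from scipy import stats
        q = _qres(16.0, 10.0, 4.0, **DFS)
        out = pq.asymptotic_pvalues(q)
        assert out.p_d == pytest.approx(stats.f.sf(4.0, 3, 8), rel=1e-12)
        assert out.p_d == pytest.approx(0.052, abs=1e-3)

    def test_tail_monotone_in_statistic(self):
        ps = []
        for het in (8.0, 6.0, 4.0, 2.0, 1.0, 1e-6):
            q = _qres(16.0, 10.0, het, **DFS)
            ps.append(pq.asymptotic_pvalues(q).p_d)
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-8  # very large Q -> p -> 0


class TestClassify:
    @pytest.mark.parametrize("p_d,p_c,expected", [
        (0.01, 0.9, "differential"),
        (0.2, 0.01, "conserved"),
        (0.2, 0.3, "insufficient"),
        (0.04, 0.01, "differential"),  # differential regardless of homogeneity
    ])
    def test_decision_rule(self, p_d, p_c, expected):
        assert pq.classify(p_d, p_c, alpha=0.05) == expected

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            pq.classify(1.5, 0.5, 0.05)
        with pytest.raises(InvalidParameterError):
            pq.classify(0.5, 0.5, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0.001, 0.999),
           st.floats(0, 1))
    def test_monotone_in_p_d(self, p_d, p_c, alpha, p_d_smaller_frac):
        """Decreasing p_d never turns a differential call non-differential."""
        first = pq.classify(p_d, p_c, alpha)
        second = pq.classify(p_d * p_d_smaller_frac, p_c, alpha)
        if first == "differential":
            assert second == "differential"


class TestEmpiricalPvalue:
    def test_add_one_rule_extremes(self):
        null = np.arange(99, dtype=float)
        assert empirical_pvalue(1000.0, null) == pytest.approx(0.01)
        assert empirical_pvalue(-1.0, null) == pytest.approx(1.0)

    def test_ties_count_as_greater_equal(self):
        assert empirical_pvalue(5.0, [5.0, 1.0, 2.0]) == pytest.approx(2 / 4)


class TestPermutationTest:
    def test_reproducible_for_fixed_seed(self, example_noisy_pair):
        tc1, tc2, topo = example_noisy_pair
        a = pq.permutation_test(tc1, tc2, topo, topo.nodes,
                                n_permutations=30, seed=5)
        b = pq.permutation_test(tc1, tc2, topo, topo.nodes,
                                n_permutations=30, seed=5)
        assert a.p_d == b.p_d and a.p_c == b.p_c
        assert np.allclose(a.null_q_d, b.null_q_d)

    def test_unequal_grids_rejected(self, example_noisy_pair):
        tc1, tc2, topo = example_noisy_pair
        shorter = pq.TimeCourseSet("c2", tc2.times[:-1], tc2.values[:, :-1],
                                   tc2.variable_ids, tc2.derivatives[:, :-1])
        with pytest.raises(InvalidParameterError):
            pq.permutation_test(tc1, shorter, topo, topo.nodes,
                                n_permutations=5, seed=1)


class TestAsymptoticNullCalibration:
    def test_p_d_not_anticonservative_under_theory_null(self):
        """Same generating DSM, different initial states, Gaussian noise on
        the rate targets: P(p_d <= alpha) must not exceed alpha.

        Noise is placed directly on the exact rate-of-change samples so the
        check isolates the F machinery from derivative estimation (which
        has its own, permutation-calibrated error budget).
        """
        from pathq.simulate import EXAMPLE_DSM_SPEC as spec
        sysd = pq.example_additive_dsm()
        rng = np.random.default_rng(777)
        t1 = pq.make_conserved(sysd, spec, seed=1).simulate(
            spec.times(), attach_derivatives=True)
        t2 = pq.make_conserved(sysd, spec, seed=2).simulate(
            spec.times(), attach_derivatives=True)
        ps = []
        for _ in range(200):
            a = t1.with_derivatives(
                t1.derivatives + 0.1 * rng.standard_normal(t1.derivatives.shape))
            b = t2.with_derivatives(
                t2.derivatives + 0.1 * rng.standard_normal(t2.derivatives.shape))
            quartet = pq.reconstruct_pathway(a, b, sysd.topology)
            ps.append(pq.asymptotic_pvalues(
                pq.compute_q(pq.aggregate_rss(quartet))).p_d)
        ps = np.asarray(ps)
        for alpha in (0.01, 0.05, 0.1):
            # binomial 3-sigma allowance on 200 replicates
            se = np.sqrt(alpha * (1 - alpha) / ps.size)
            assert (ps <= alpha).mean() <= alpha + 3 * se


class TestNodeHeterogeneity:
    def test_identical_conditions_give_p_one(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((1, 20))
        der = rng.standard_normal((1, 20))
        tc = pq.TimeCourseSet("c", np.arange(20.0), vals, ["Z"], der)
        topo = pq.SuperPathwayTopology(["Z"])
        quartet = pq.reconstruct_pathway(tc, tc, topo)
        het = pq.node_heterogeneity(quartet)
        assert het.loc["Z", "q_d"] == pytest.approx(0.0, abs=1e-9)
        assert het.loc["Z", "p_d"] == pytest.approx(1.0)

    def test_rewired_node_stands_out_noiseless(self):
        """One rewired equation: that node's p_d is the smallest."""
        times = np.linspace(0, 8, 80)
        ids = ["A", "B", "C"]

        def build(b_coef):
            cms = {
                "A": pq.ChildModel("A", beta0=0.6, beta_linear={"A": -0.5}),
                "B": pq.ChildModel("B", beta_linear={"A": b_coef, "B": -0.6}),
                "C": pq.ChildModel("C", beta_linear={"B": 0.7, "C": -0.5}),
            }
            return pq.DSModel(cms)

        topo = pq.SuperPathwayTopology.from_edges(
            [("A", "A"), ("A", "B"), ("B", "B"), ("B", "C"), ("C", "C")])
        tc1 = pq.simulate_trajectory(build(1.0).rate_function(),
                                     [1.0, 0.2, 0.2], times, ids,
                                     condition_label="c1",
                                     attach_derivatives=True)
        tc2 = pq.simulate_trajectory(build(2.0).rate_function(),
                                     [1.1, 0.25, 0.15], times, ids,
                                     condition_label="c2",
                                     attach_derivatives=True)
        quartet = pq.reconstruct_pathway(tc1, tc2, topo,
                                         caps=Caps(families=("linear",)))
        het = pq.node_heterogeneity(quartet)
        assert het["p_d"].idxmin() == "B"
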