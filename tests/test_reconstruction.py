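"""Partial pathway reconstruction: term enumeration, fitting, selection."""

import numpy as np
import pytest

import pathq as pq
from pathq.exceptions import InfeasibleFitError, MissingVariableError
from pathq.reconstruction import Caps, f_total_from_rss

from conftest import linear_chain_pair


def _tc(values, times=None, derivs=None, ids=None, label="c"):
    values = np.atleast_2d(np.asarray(values, float))
    n = values.shape[1]
    times = np.arange(n, dtype=float) if times is None else times
    ids = ids or [f"V{i}" for i in range(values.shape[0])]
    return pq.TimeCourseSet(label, times, values, ids, derivs)


class TestCandidateTerms:
    def test_single_parent_eight_termsets(self):
        topo = pq.SuperPathwayTopology(["A", "Z"], [("A", "Z")])
        cands = pq.candidate_terms(topo, "Z", Caps(max_terms=3))
        # atoms {lin A, quad (A,A), sig A}: empty + 7 non-empty subsets
        assert len(cands) == 8
        assert cands[0].n_terms == 0

    def test_no_parents_intercept_only(self):
        topo = pq.SuperPathwayTopology(["A", "Z"], [("A", "A")])
        cands = pq.candidate_terms(topo, "Z")
        assert len(cands) == 1 and cands[0].n_terms == 0

    def test_two_parents_max_one_term(self):
        topo = pq.SuperPathwayTopology(["A", "B", "Z"], [("A", "Z"), ("B", "Z")])
        cands = pq.candidate_terms(topo, "Z", Caps(max_terms=1))
        # empty + 2 linear + 3 quadratic pairs {(A,A),(A,B),(B,B)} + 2 sigmoid
        assert len(cands) == 8
        singles = [c for c in cands if c.n_terms == 1]
        assert len(singles) == 7
        quads = {c.quadratic[0] for c in singles if c.quadratic}
        assert quads == {("A", "A"), ("A", "B"), ("B", "B")}

    def test_family_restriction(self):
        topo = pq.SuperPathwayTopology(["A", "Z"], [("A", "Z")])
        cands = pq.candidate_terms(topo, "Z", Caps(families=("linear",)))
        assert len(cands) == 2  # empty + {linear A}


class TestFitChildGivenTerms:
    def test_intercept_only_mean_and_rss(self):
        tc = _tc([[0, 0, 0]], derivs=[[1, 2, 3]], ids=["Z"])
        model, rss = pq.fit_child_given_terms(pq.TermSet("Z"), tc)
        assert model.beta0 == pytest.approx(2.0)
        assert rss == pytest.approx(2.0)

    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.5, 2.0, size=30)
        tc = _tc(np.vstack([a, np.zeros(30)]), derivs=np.vstack([a * 0, 3 * a]),
                 ids=["A", "Z"])
        model, rss = pq.fit_child_given_terms(
            pq.TermSet("Z", linear=("A",)), tc)
        assert model.beta_linear["A"] == pytest.approx(3.0, abs=1e-10)
        assert rss < 1e-10

    def test_sigmoid_h_recovered_within_grid_cell(self):
        rng = np.random.default_rng(1)
        caps = Caps()
        x = rng.uniform(0.05, 4.0, size=80)
        grid = np.quantile(x, np.linspace(0.05, 0.95, caps.h_grid_size))
        h_true = float(grid[8])
        y = 2.0 * x / (x + h_true)
        tc = _tc(np.vstack([x, np.zeros_like(x)]),
                 derivs=np.vstack([x * 0, y]), ids=["A", "Z"])
        model, rss = pq.fit_child_given_terms(
            pq.TermSet("Z", sigmoidal=("A",)), tc, caps)
        spacing = max(grid[9] - grid[8], grid[8] - grid[7])
        assert abs(model.h["A"] - h_true) <= spacing + 1e-12
        assert model.beta_sigmoid["A"] == pytest.approx(2.0, rel=1e-6)

    def test_infeasible_sample_size(self):
        tc = _tc([[1, 2, 3], [1, 1, 1.0]], derivs=np.ones((2, 3)),
                 ids=["A", "Z"])
        with pytest.raises(InfeasibleFitError):
            pq.fit_child_given_terms(
                pq.TermSet("Z", linear=("A",), sigmoidal=("A",)), tc)


class TestSelectTerms:
    def test_true_linear_parent_selected_noiseless(self):
        tc1, tc2 = linear_chain_pair()
        topo = pq.SuperPathwayTopology(["A", "B"], [("A", "B"), ("B", "B")])
        rec = pq.select_terms("B", tc1, tc2, topo)
        assert rec.terms.linear == ("A",)
        assert rec.terms.n_terms == 1

    def test_null_rss_is_pooled_time_average(self):
        d1 = _tc([[0, 0, 0, 0]], derivs=[[0, 0, 4, 4]], ids=["Z"])
        d2 = _tc([[0, 0, 0, 0]], derivs=[[0, 0, 4, 4]], ids=["Z"])
        topo = pq.SuperPathwayTopology(["Z"])
        rec = pq.select_terms("Z", d1, d2, topo)
        assert rec.models["null"].beta0 == pytest.approx(2.0)
        assert rec.rss["null"] == pytest.approx(32.0)  # 8 samples, dev 2 each

    def test_identical_conditions_het_equals_pooled(self, example_noisy_pair):
        tc1, _, topo = example_noisy_pair
        quartet = pq.reconstruct_pathway(tc1, tc1, topo)
        for rec in quartet.records.values():
            assert rec.rss_het == pytest.approx(rec.rss["pooled"], abs=1e-9)


class TestNullFDistribution:
    def test_parentless_child_f_pvalue_uniform_under_noise(self):
        """A child with no candidate parents and pure-noise rate targets:
        F_t reduces to the two-sample mean F test, so its p-value is
        Uniform(0, 1) over replicates."""
        from scipy import stats
        rng = np.random.default_rng(314)
        topo = pq.SuperPathwayTopology(["Z"])
        ps = []
        for _ in range(200):
            d1 = _tc(np.zeros((1, 15)), derivs=rng.standard_normal((1, 15)),
                     ids=["Z"], label="c1")
            d2 = _tc(np.zeros((1, 15)), derivs=rng.standard_normal((1, 15)),
                     ids=["Z"], label="c2")
            ps.append(pq.select_terms("Z", d1, d2, topo).p_total)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestReconstructPathway:
    def test_isolated_node_quartet(self):
        rng = np.random.default_rng(5)
        y1, y2 = rng.standard_normal((2, 20))
        d1 = _tc(np.zeros((1, 20)), derivs=y1[None], ids=["Z"], label="c1")
        d2 = _tc(np.zeros((1, 20)), derivs=y2[None], ids=["Z"], label="c2")
        topo = pq.SuperPathwayTopology(["Z"])
        quartet = pq.reconstruct_pathway(d1, d2, topo)
        rec = quartet.records["Z"]
        assert rec.terms.n_terms == 0
        assert rec.rss["pooled"] == pytest.approx(rec.rss["null"], abs=1e-9)
        assert rec.m["pooled"] == 1

    def test_three_node_chain_recovered(self):
        times = np.linspace(0, 6, 60)
        cms = {
            "A": pq.ChildModel("A", beta0=0.5, beta_linear={"A": -0.4}),
            "B": pq.ChildModel("B", beta0=0.0, beta_linear={"A": 1.2, "B": -0.5}),
            "C": pq.ChildModel("C", beta0=0.0, beta_linear={"B": 0.8, "C": -0.6}),
        }
        dsm = pq.DSModel(cms)
        topo = pq.SuperPathwayTopology.from_edges(
            [("A", "A"), ("A", "B"), ("B", "B"), ("A", "C"), ("B", "C"),
             ("C", "C")])

        def sim(x0, label):
            return pq.simulate_trajectory(dsm.rate_function(), x0, times,
                                          ["A", "B", "C"], condition_label=label,
                                          attach_derivatives=True)

        tc1 = sim([2.0, 0.1, 0.1], "c1")
        tc2 = sim([0.5, 1.0, 0.3], "c2")
        quartet = pq.reconstruct_pathway(tc1, tc2, topo,
                                         caps=Caps(families=("linear",)))
        assert set(quartet.records["B"].terms.linear) == {"A", "B"}
        assert set(quartet.records["C"].terms.linear) == {"B", "C"}

    def test_missing_variable_error(self):
        d1 = _tc(np.zeros((1, 10)), derivs=np.zeros((1, 10)), ids=["Z"])
        topo = pq.SuperPathwayTopology(["Z", "W"])
        with pytest.raises(MissingVariableError):
            pq.reconstruct_pathway(d1, d1, topo)

    def test_nestedness_on_random_data(self):
        rng = np.random.default_rng(99)
        topo = pq.SuperPathwayTopology.from_edges(
            [("A", "B"), ("B", "C"), ("C", "A"), ("A", "A")])
        for rep in range(5):
            vals1, vals2 = rng.standard_normal((2, 3, 25))
            der1, der2 = rng.standard_normal((2, 3, 25))
            d1 = _tc(vals1, derivs=der1, ids=["A", "B", "C"], label="c1")
            d2 = _tc(vals2, derivs=der2, ids=["A", "B", "C"], label="c2")
            quartet = pq.reconstruct_pathway(d1, d2, topo)
            for rec in quartet.records.values():
                assert rec.rss_het <= rec.rss["pooled"] + 1e-9
                assert rec.rss["pooled"] <= rec.rss["null"] + 1e-9


class TestFTotalOracle:
    def test_matches_independent_nested_ols(self):
        """F_t for linear-only TermSets equals a hand-coded nested OLS F."""
        rng = np.random.default_rng(7)
        n = 30
        for _ in range(20):
            x1, x2 = rng.standard_normal((2, n)), rng.standard_normal((2, n))
            y1 = 1.0 + 0.5 * x1[0] + rng.standard_normal(n)
            y2 = 1.0 - 0.3 * x2[0] + rng.standard_normal(n)

            def ols_rss(X, y):
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                return float(np.sum((y - X @ beta) ** 2))

            X1 = np.column_stack([np.ones(n), x1[0]])
            X2 = np.column_stack([np.ones(n), x2[0]])
            rss1 = ols_rss(X1, y1)
            rss2 = ols_rss(X2, y2)
            ypool = np.concatenate([y1, y2])
            rss0 = float(np.sum((ypool - ypool.mean()) ** 2))
            m = 2
            f, p, u, v = f_total_from_rss(rss0, rss1, rss2, m, n, n)
            # oracle: standard nested-model F with the same dfs
            f_oracle = ((rss0 - rss1 - rss2) / (2 * m - 1)) / (
                (rss1 + rss2) / (2 * n - 2 * m))
            assert f == pytest.approx(f_oracle, rel=1e-12)
            assert u == 2 * m - 1 and v == 2 * n - 2 * m
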