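"""Ground-truth generators: perturbations, noise, built-in systems."""

import numpy as np
import pytest

import pathq as pq
from pathq.exceptions import InvalidParameterError
from pathq.simulate import BUILTIN_SPECS, EXAMPLE_DSM_SPEC, dsm_to_system


SPEC = pq.PerturbationSpec(mu=2.0, sigma=0.1, L=0.001, U=0.005,
                           t_start=0.0, t_end=10.0, dt=0.1)


class TestPerturbationSpec:
    def test_grid_consistency_enforced(self):
        with pytest.raises(InvalidParameterError):
            pq.PerturbationSpec(mu=1, sigma=0, L=0, U=0,
                                t_start=0, t_end=5, dt=0.1, n_points=100)

    def test_times_grid(self):
        t = SPEC.times()
        assert t.size == 100
        assert t[0] == pytest.approx(0.1)
        assert t[-1] == pytest.approx(10.0)


class TestMakeConserved:
    def test_degenerate_bounds_keep_state(self, example_system):
        spec = pq.PerturbationSpec(mu=2, sigma=0.1, L=0.0, U=0.0,
                                   t_start=0, t_end=10, dt=0.1)
        out = pq.make_conserved(example_system, spec, seed=0)
        assert np.allclose(out.x0, example_system.x0)

    def test_parameters_never_change(self, example_system):
        out = pq.make_conserved(example_system, SPEC, seed=1)
        assert out.params == example_system.params
        assert not np.allclose(out.x0, example_system.x0)

    def test_offsets_uniform_in_bounds(self):
        sys5 = pq.example_additive_dsm()
        spec = pq.PerturbationSpec(mu=2, sigma=0.1, L=0.001, U=0.005,
                                   t_start=0, t_end=10, dt=0.1)
        offs = np.concatenate([
            pq.make_conserved(sys5, spec, seed=s).x0 - sys5.x0
            for s in range(200)])  # 1000 draws
        assert offs.min() >= spec.L and offs.max() <= spec.U
        se = (spec.U - spec.L) / np.sqrt(12 * offs.size)
        assert abs(offs.mean() - (spec.L + spec.U) / 2) < 3 * se


class TestMakeDifferential:
    def test_degenerate_multiplier_keeps_params(self, example_system):
        spec = pq.PerturbationSpec(mu=1.0, sigma=0.0, L=0, U=0.1,
                                   t_start=0, t_end=10, dt=0.1)
        out = pq.make_differential(example_system, spec, seed=0)
        for k in example_system.params:
            assert out.params[k] == pytest.approx(example_system.params[k])

    def test_initial_state_never_changes(self, example_system):
        out = pq.make_differential(example_system, SPEC, seed=3)
        assert np.allclose(out.x0, example_system.x0)
        assert out.params != example_system.params

    def test_multiplier_distribution(self, example_system):
        base = {k: v for k, v in example_system.params.items() if v != 0}
        mults = []
        for s in range(100):
            out = pq.make_differential(example_system, SPEC, seed=s)
            mults.extend(out.params[k] / v for k, v in base.items())
        mults = np.asarray(mults)
        se = SPEC.sigma / np.sqrt(mults.size)
        assert abs(mults.mean() - SPEC.mu) < 3 * se


@pytest.fixture(scope="module")
def clean(example_system):
    return example_system.simulate(EXAMPLE_DSM_SPEC.times())


class TestAddNoise:

    def test_infinite_snr_unchanged(self, clean):
        out = pq.add_noise(clean, pq.NoiseSpec())
        assert np.array_equal(out.values, clean.values)

    def test_snr0_noise_power_matches_signal_power(self, clean):
        out = pq.add_noise(clean, pq.NoiseSpec(0, seed=8))
        ratio = (out.values - clean.values).var(axis=1) / clean.values.var(axis=1)
        assert np.all(ratio > 0.6) and np.all(ratio < 1.5)

    def test_snr20_ratio_near_one_percent(self, clean):
        out = pq.add_noise(clean, pq.NoiseSpec(20, seed=8))
        ratio = (out.values - clean.values).var(axis=1) / clean.values.var(axis=1)
        assert np.all(ratio > 0.004) and np.all(ratio < 0.025)

    def test_seed_reproducible_and_independent(self, clean):
        a = pq.add_noise(clean, pq.NoiseSpec(10, seed=5))
        b = pq.add_noise(clean, pq.NoiseSpec(10, seed=5))
        c = pq.add_noise(clean, pq.NoiseSpec(10, seed=6))
        assert np.array_equal(a.values, b.values)
        na, nc = (a.values - clean.values).ravel(), (c.values - clean.values).ravel()
        assert abs(np.corrcoef(na, nc)[0, 1]) < 0.1

    def test_derivatives_cleared(self, example_system):
        tc = example_system.simulate(EXAMPLE_DSM_SPEC.times(),
                                     attach_derivatives=True)
        assert not pq.add_noise(tc, pq.NoiseSpec(20, seed=1)).has_derivatives

    def test_constant_variable_warns(self):
        tc = pq.TimeCourseSet("c", [0, 1, 2.0], [[1.0, 1.0, 1.0]], ["A"])
        with pytest.warns(UserWarning, match="constant"):
            out = pq.add_noise(tc, pq.NoiseSpec(20, seed=1))
        assert np.allclose(out.values, 1.0)


class TestLV3:
    def test_zero_rates_constant(self):
        params = pq.LVParams(r=(0, 0, 0), a=((0,) * 3,) * 3, x0=(1, 2, 3))
        tc = pq.lv3(params).simulate(np.linspace(1, 10, 10))
        assert np.allclose(tc.values, [[1], [2], [3]] * np.ones((1, 10)))

    def test_zero_initial_state_invariant_axis(self):
        params = pq.LVParams(x0=(0.0, 1.5, 1.5))
        tc = pq.lv3(params).simulate(np.linspace(0.3, 30, 100))
        assert np.allclose(tc.series("x1"), 0.0, atol=1e-12)

    def test_conserved_initial_state_diverges_macroscopically(self):
        spec = BUILTIN_SPECS["lv3"]
        a = pq.lv3().simulate(spec.times())
        b = pq.lv3(pq.LVParams(x0=pq.LVParams.X0_CONSERVED)).simulate(spec.times())
        d = np.linalg.norm(a.values - b.values, axis=0)
        # same parameters, tiny initial offset: late-horizon distance reaches
        # the scale of the trajectories themselves
        assert d[:10].max() < 0.2
        assert d.max() > 1.0


class TestRandomAdditiveDSM:
    def test_reproducible_for_seed(self):
        d1, t1 = pq.random_additive_dsm(5, seed=42)
        d2, t2 = pq.random_additive_dsm(5, seed=42)
        assert t1.edges == t2.edges
        for v in d1.variable_ids:
            assert d1.child_models[v].beta0 == d2.child_models[v].beta0

    def test_single_node_no_edges(self):
        dsm, topo = pq.random_additive_dsm(1, edges_per_node=0.0, seed=1)
        assert topo.nodes == ["X1"]
        cm = dsm.child_models["X1"]
        assert set(cm.beta_linear) <= {"X1"}

    def test_generated_trajectories_bounded(self):
        dsm, topo = pq.random_additive_dsm(4, seed=7)
        tc = pq.simulate_trajectory(dsm.rate_function(), dsm._x0,
                                    np.linspace(0, 10, 50),
                                    dsm.variable_ids)
        assert np.abs(tc.values).max() <= 100.0


class TestBuiltinSystems:
    def test_cell_cycle_oscillates(self):
        sysd = pq.cell_division_cycle()
        tc = sysd.simulate(BUILTIN_SPECS["cell-division-cycle"].times())
        m = tc.series("M")
        assert (m[50:].max() - m[50:].min()) > 0.05  # sustained oscillation

    def test_glycolysis_oscillates(self):
        sysd = pq.glycolytic_oscillator()
        tc = sysd.simulate(BUILTIN_SPECS["glycolytic-oscillator"].times())
        x = tc.series("x")
        assert (x[50:].max() - x[50:].min()) > 0.5

    def test_example_dsm_rates_hand_computed(self, example_system):
        """OdeSystem vector field matches the written-out child equations."""
        rhs = example_system.rhs()
        got = rhs(0.0, np.array([1.0, 0.8, 1.2, 0.9, 1.1]))
        expected = [
            0.8 - 0.5 * 1.0,                                   # X1
            0.4 + 1.2 * (1.0 / 2.0) - 0.6 * 0.8,               # X2
            0.2 + 0.9 * 0.8 - 0.7 * 1.2,                       # X3
            0.3 + 0.45 * 1.2 ** 2 - 0.6 * 0.9,                 # X4
            0.25 + 1.0 * (0.9 / (0.9 + 1.2)) - 0.5 * 1.1,      # X5
        ]
        assert np.allclose(got, expected)
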