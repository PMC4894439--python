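import numpy as np
import pytest

import pathq as pq
from pathq.simulate import EXAMPLE_DSM_SPEC


@pytest.fixture(scope="session")
def example_system():
    """Bundled 5-node additive DSM with its topology and perturbation spec."""
    return pq.example_additive_dsm()


@pytest.fixture(scope="session")
def example_noisy_pair(example_system):
    """A conserved pair of the bundled DSM at SNR 20 dB, derivatives estimated."""
    spec = EXAMPLE_DSM_SPEC
    conserved = pq.make_conserved(example_system, spec, seed=11)
    tc1 = pq.add_noise(example_system.simulate(spec.times()),
                       pq.NoiseSpec(20, seed=1))
    tc2 = pq.add_noise(conserved.simulate(spec.times()),
                       pq.NoiseSpec(20, seed=2))
    return (pq.estimate_derivatives(tc1), pq.estimate_derivatives(tc2),
            example_system.topology)


def linear_chain_pair(slope=2.0, n=40, seed=None, noise_sd=0.0):
    """Noiseless (or noisy) data from dx_B/dt = slope * x_A, dx_A/dt = -0.3 x_A.

    Returns two independent-initial-condition realisations with exact
    derivatives attached — handy for selection-consistency tests.
    """
    rng = np.random.default_rng(seed)

    def make(x0a, label):
        times = np.linspace(0.0, 5.0, n)
        cmA = pq.ChildModel("A", beta0=0.0, beta_linear={"A": -0.3})
        cmB = pq.ChildModel("B", beta0=0.0, beta_linear={"A": slope})
        dsm = pq.DSModel({"A": cmA, "B": cmB})
        tc = pq.simulate_trajectory(dsm.rate_function(), [x0a, 0.1], times,
                                    ["A", "B"], condition_label=label,
                                    attach_derivatives=True)
        if noise_sd:
            vals = tc.values + noise_sd * rng.standard_normal(tc.values.shape)
            tc = pq.TimeCourseSet(label, times, vals, ["A", "B"])
            tc = pq.estimate_derivatives(tc)
        return tc

    return make(2.0, "c1"), make(1.0, "c2")
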