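"""Ground-truth generators for the rewiring benchmark.

The benchmark compares *conserved* and *differential* (rewired) variants of a
base ODE model:

* conserved — identical parameters, each initial value offset by an
  independent Uniform(L, U) draw (a changed input, not a changed mechanism);
* differential — every parameter multiplied by an independent
  Normal(mu, sigma) draw, initial state untouched (a mechanistic rewiring).

Time courses are sampled on a uniform grid of ``n_points`` (default 100)
model-dependent time steps, then Gaussian noise is added per variable at a
prescribed signal-to-noise ratio, snr_db = 10*log10(Var_signal/Var_noise)
(0 dB means noise power equals signal power).

Built-in base systems: a cdc2–cyclin cell-division-cycle oscillator, the
Sel'kov glycolytic oscillator, a chaotic 3-species generalized Lotka–
Volterra predator–prey model, a compact 5-node additive DSM used for
calibration studies, and random additive DSMs drawn from the same model
family the reconstruction step fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .dsm import ChildModel, DSModel, simulate_trajectory
from .exceptions import (
    GenerationError,
    IntegrationError,
    InvalidParameterError,
)
from .timecourse import SuperPathwayTopology, TimeCourseSet

__all__ = [
    "PerturbationSpec",
    "NoiseSpec",
    "LVParams",
    "OdeSystem",
    "make_conserved",
    "make_differential",
    "add_noise",
    "lv3",
    "cell_division_cycle",
    "glycolytic_oscillator",
    "example_additive_dsm",
    "random_additive_dsm",
    "dsm_to_system",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """Benchmark perturbation setup for one base model.

    ``mu``/``sigma`` parameterise the Normal multipliers of the differential
    variant; ``L``/``U`` bound the Uniform initial-state offsets of the
    conserved variant; the sampling grid runs from ``t_start`` in
    ``n_points`` steps of ``dt`` up to ``t_end``.
    """

    mu: float
    sigma: float
    L: float
    U: float
    t_start: float
    t_end: float
    dt: float
    n_points: int = 100

    def __post_init__(self):
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")
        if self.L > self.U:
            raise InvalidParameterError("need L <= U")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        span = self.t_start + self.n_points * self.dt
        if not math.isclose(span, self.t_end, rel_tol=1e-9, abs_tol=1e-9):
            raise InvalidParameterError(
                f"t_start + n_points*dt = {span} inconsistent with t_end = {self.t_end}"
            )

    def times(self) -> np.ndarray:
        """The uniform sampling grid t_1 ... t_{n_points} (excludes t_start)."""
        return self.t_start + self.dt * np.arange(1, self.n_points + 1)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise level on the decibel power scale."""

    snr_db: float = math.inf
    seed: int | None = None

    def __post_init__(self):
        if math.isnan(self.snr_db):
            raise InvalidParameterError("snr_db must be finite or +inf")


@dataclass
class OdeSystem:
    """A parameterised ODE model: named parameters, initial state, vector field.

    ``rhs_factory(params)`` returns the vector field ``f(t, x)``; keeping the
    factory form lets variant generators swap parameter sets without touching
    the dynamics code.
    """

    name: str
    variable_ids: list[str]
    params: dict[str, float]
    x0: np.ndarray
    rhs_factory: Callable[[dict[str, float]], Callable]
    topology: SuperPathwayTopology
    # per-system integration error control; atol=0 forces pure relative
    # control, needed when trajectories dip many orders of magnitude
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.x0.size != len(self.variable_ids):
            raise InvalidParameterError("x0 length must match variable count")

    def rhs(self) -> Callable:
        return self.rhs_factory(dict(self.params))

    def with_params(self, params: dict[str, float]) -> "OdeSystem":
        return replace(self, params=dict(params), x0=self.x0.copy())

    def with_x0(self, x0) -> "OdeSystem":
        return replace(self, params=dict(self.params), x0=np.asarray(x0, float))

    def simulate(self, times, *, condition_label=None, rtol=None, atol=None,
                 attach_derivatives=False, bound=1e6) -> TimeCourseSet:
        return simulate_trajectory(
            self.rhs(), self.x0, times, self.variable_ids,
            condition_label=condition_label or self.name,
            rtol=self.rtol if rtol is None else rtol,
            atol=self.atol if atol is None else atol,
            attach_derivatives=attach_derivatives,
            bound=bound,
        )


def make_conserved(base: OdeSystem, spec: PerturbationSpec,
                   seed: int | None = None) -> OdeSystem:
    """Conserved variant: same parameters, initial state offset by U(L, U)."""
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(spec.L, spec.U, size=base.x0.size)
    sys = base.with_x0(base.x0 + offsets)
    sys.name = f"{base.name}-conserved"
    return sys


def make_differential(base: OdeSystem, spec: PerturbationSpec,
                      seed: int | None = None) -> OdeSystem:
    """Differential variant: every parameter scaled by an N(mu, sigma) draw."""
    rng = np.random.default_rng(seed)
    mult = rng.normal(spec.mu, spec.sigma, size=len(base.params))
    new = {k: v * m for (k, v), m in zip(base.params.items(), mult)}
    sys = base.with_params(new)
    sys.name = f"{base.name}-differential"
    return sys


def add_noise(tc: TimeCourseSet, noise: NoiseSpec) -> TimeCourseSet:
    """Add zero-mean Gaussian noise per variable at the prescribed SNR.

    Noise variance is Var(signal_i) * 10^(-snr_db/10); a constant variable
    gets zero noise with a warning. Negative post-noise abundances are kept.
    The derivatives field is cleared — it must be re-estimated from the noisy
    series.
    """
    if math.isinf(noise.snr_db):
        return tc.without_derivatives()
    rng = np.random.default_rng(noise.seed)
    sig_var = tc.values.var(axis=1)
    if np.any(sig_var == 0):
        flat = [v for v, s in zip(tc.variable_ids, sig_var) if s == 0]
        warnings.warn(
            f"constant series get zero noise: {', '.join(flat)}", stacklevel=2)
    sd = np.sqrt(sig_var * 10 ** (-noise.snr_db / 10))
    noisy = tc.values + sd[:, None] * rng.standard_normal(tc.values.shape)
    return TimeCourseSet(tc.condition_label, tc.times.copy(), noisy,
                         list(tc.variable_ids), None)


# ---------------------------------------------------------------------------
# built-in systems
# ---------------------------------------------------------------------------

# Chaotic one-prey/two-predator generalized Lotka-Volterra setting:
# Gilpin's classic "spiral chaos" food-web parameterization (prey consumed
# by two competing predators), with state divided by 200 and time sped up 50-fold
# so abundances are unit-order, the oscillation period is a few model time
# units, and nearby initial states diverge macroscopically around t ~ 10-15.
# The affine rescaling leaves the generalized-LV form intact. Largest
# Lyapunov exponent ~ 0.5 per time unit (Benettin estimate, docs/methods.md).
_LV_R = (50.0, 50.0, -50.0)
_LV_A = (
    (-10.0, -10.0, -100.0),
    (-15.0, -10.0, -10.0),
    (50.0, 5.0, 0.0),
)


@dataclass(frozen=True)
class LVParams:
    """3-species generalized Lotka-Volterra parameters dx_i/dt = x_i (r_i + sum_j a_ij x_j)."""

    r: tuple[float, float, float] = _LV_R
    a: tuple[tuple[float, float, float], ...] = _LV_A
    x0: tuple[float, float, float] = (1.5, 1.5, 1.5)

    # initial state of the conserved variant shown in phase-plane examples
    X0_CONSERVED = (1.504, 1.510, 1.509)


def lv3(params: LVParams = LVParams()) -> OdeSystem:
    """3-variable Lotka-Volterra predator-prey system (chaotic by default)."""
    ids = ["x1", "x2", "x3"]
    pdict = {f"r{i+1}": params.r[i] for i in range(3)}
    pdict.update({f"a{i+1}{j+1}": params.a[i][j]
                  for i in range(3) for j in range(3)})

    def factory(p):
        r = np.array([p["r1"], p["r2"], p["r3"]])
        A = np.array([[p[f"a{i+1}{j+1}"] for j in range(3)] for i in range(3)])

        def rhs(t, x):
            return x * (r + A @ x)

        return rhs

    edges = [(ids[j], ids[i]) for i in range(3) for j in range(3)]
    # near-zero atol: the predator dips span many decades, so error control
    # must stay relative all the way down (yet nonzero, or an exactly-zero
    # invariant axis defeats LSODA's error weights)
    return OdeSystem("lv3", ids, pdict, np.array(params.x0), factory,
                     SuperPathwayTopology(ids, edges),
                     rtol=1e-8, atol=1e-150)


def cell_division_cycle() -> OdeSystem:
    """cdc2-cyclin cell-division-cycle oscillator (Tyson 1991).

    Six species: free cdc2 (C2), phosphorylated cdc2 (CP), the inactive
    cyclin~cdc2-P complex preMPF (pM), active MPF (M), free cyclin (Y) and
    phosphorylated cyclin (YP). MPF activates its own formation through
    F(M) = k4' + k4 (M/CT)^2 with CT the total cdc2 pool, which drives the
    system between an excitable and an oscillatory regime.
    """
    ids = ["C2", "CP", "pM", "M", "Y", "YP"]
    params = {
        "k1": 0.015, "k2": 0.0, "k3": 200.0, "k4": 180.0, "k4p": 0.018,
        "k5": 0.0, "k6": 1.0, "k7": 0.6, "k8": 1e6, "k9": 1e3,
    }

    def factory(p):
        def rhs(t, x):
            C2, CP, pM, M, Y, YP = x
            CT = C2 + CP + pM + M
            F = p["k4p"] + p["k4"] * (M / CT) ** 2 if CT > 0 else p["k4p"]
            return np.array([
                p["k6"] * M - p["k8"] * C2 + p["k9"] * CP,
                p["k8"] * C2 - p["k9"] * CP - p["k3"] * CP * Y,
                p["k3"] * CP * Y - pM * F + p["k5"] * M,
                pM * F - p["k5"] * M - p["k6"] * M,
                p["k1"] - p["k2"] * Y - p["k3"] * CP * Y,
                p["k6"] * M - p["k7"] * YP,
            ])

        return rhs

    x0 = np.array([0.0, 0.75, 0.25, 0.0, 0.0, 0.0])
    # parent j -> child i whenever x_j enters dx_i/dt
    edges = [
        ("M", "C2"), ("C2", "C2"), ("CP", "C2"),
        ("C2", "CP"), ("CP", "CP"), ("Y", "CP"),
        ("CP", "pM"), ("Y", "pM"), ("pM", "pM"), ("M", "pM"),
        ("C2", "M"), ("CP", "M"), ("pM", "M"), ("M", "M"),
        ("Y", "Y"), ("CP", "Y"),
        ("M", "YP"), ("YP", "YP"),
    ]
    return OdeSystem("cell-division-cycle", ids, params, x0, factory,
                     SuperPathwayTopology(ids, edges))


def glycolytic_oscillator() -> OdeSystem:
    """Sel'kov glycolytic oscillator (ADP x, F6P y) on its limit cycle."""
    ids = ["x", "y"]
    params = {"a": 0.08, "b": 0.6}

    def factory(p):
        def rhs(t, s):
            x, y = s
            return np.array([
                -x + p["a"] * y + x * x * y,
                p["b"] - p["a"] * y - x * x * y,
            ])

        return rhs

    edges = [("x", "x"), ("y", "x"), ("x", "y"), ("y", "y")]
    return OdeSystem("glycolytic-oscillator", ids, params,
                     np.array([0.6, 1.2]), factory,
                     SuperPathwayTopology(ids, edges))


# benchmark perturbation setups for the built-in systems; the cell-cycle row
# follows the published cdc2-cyclin benchmark setup (mu 3, sigma 0.1,
# offsets in [0.001, 0.005], 100 unit steps), the glycolysis row mirrors the
# published glycolysis-oscillation setup, and the chaotic LV row uses
# near-unity multipliers (a chaotic system is maximally parameter-sensitive)
# with initial offsets matching the conserved state (1.504, 1.510, 1.509).
BUILTIN_SPECS: dict[str, PerturbationSpec] = {
    "cell-division-cycle": PerturbationSpec(
        mu=3.0, sigma=0.1, L=0.001, U=0.005, t_start=0.0, t_end=100.0, dt=1.0),
    "glycolytic-oscillator": PerturbationSpec(
        mu=1.8, sigma=0.1, L=0.03, U=0.05, t_start=0.0, t_end=100.0, dt=1.0),
    "lv3": PerturbationSpec(
        mu=1.1, sigma=0.01, L=0.004, U=0.010, t_start=0.0, t_end=30.0, dt=0.3),
}


# ---------------------------------------------------------------------------
# additive DSM generators (the model family the reconstruction step fits)
# ---------------------------------------------------------------------------

def dsm_to_system(dsm: DSModel, x0, topology: SuperPathwayTopology,
                  name: str = "additive-dsm") -> OdeSystem:
    """Wrap a DSModel as an OdeSystem (parameters named per coefficient)."""
    ids = dsm.variable_ids
    params: dict[str, float] = {}
    for vid in ids:
        cm = dsm.child_models[vid]
        params[f"{vid}.beta0"] = cm.beta0
        for p, b in cm.beta_linear.items():
            params[f"{vid}.lin.{p}"] = b
        for (a, b_), bb in cm.beta_quadratic.items():
            params[f"{vid}.quad.{a}*{b_}"] = bb
        for p, b in cm.beta_sigmoid.items():
            params[f"{vid}.sig.{p}"] = b
            params[f"{vid}.h.{p}"] = cm.h[p]

    def factory(p):
        models = []
        for vid in ids:
            cm = dsm.child_models[vid]
            models.append(ChildModel(
                vid,
                beta0=p[f"{vid}.beta0"],
                beta_linear={q: p[f"{vid}.lin.{q}"] for q in cm.beta_linear},
                beta_quadratic={pr: p[f"{vid}.quad.{pr[0]}*{pr[1]}"]
                                for pr in cm.beta_quadratic},
                beta_sigmoid={q: p[f"{vid}.sig.{q}"] for q in cm.beta_sigmoid},
                h={q: abs(p[f"{vid}.h.{q}"]) or 1e-6 for q in cm.h},
            ))

        def rhs(t, x):
            state = dict(zip(ids, x))
            return np.array([m.eval_rate(state) for m in models])

        return rhs

    return OdeSystem(name, ids, params, np.asarray(x0, float), factory, topology)


def example_additive_dsm() -> OdeSystem:
    """The bundled 5-node additive DSM used for calibration studies.

    A stable cascade X1 -> X2 -> X3 -> X4 -> X5 mixing the three term
    families (sigmoidal activation, linear activation, quadratic activation)
    with first-order decay, so a perturbed initial state produces a visible
    transient before settling.
    """
    ids = [f"X{i}" for i in range(1, 6)]
    cms = {
        "X1": ChildModel("X1", beta0=0.8, beta_linear={"X1": -0.5}),
        "X2": ChildModel("X2", beta0=0.4, beta_linear={"X2": -0.6},
                         beta_sigmoid={"X1": 1.2}, h={"X1": 1.0}),
        "X3": ChildModel("X3", beta0=0.2,
                         beta_linear={"X2": 0.9, "X3": -0.7}),
        "X4": ChildModel("X4", beta0=0.3, beta_linear={"X4": -0.6},
                         beta_quadratic={("X3", "X3"): 0.45}),
        "X5": ChildModel("X5", beta0=0.25, beta_linear={"X5": -0.5},
                         beta_sigmoid={"X4": 1.0}, h={"X4": 1.2}),
    }
    dsm = DSModel(cms, label="cond1")
    edges = set()
    for vid, cm in cms.items():
        for p in cm.parents:
            edges.add((p, vid))
    topo = SuperPathwayTopology(ids, sorted(edges))
    x0 = np.array([1.0, 0.8, 1.2, 0.9, 1.1])
    return dsm_to_system(dsm, x0, topo, name="example-additive-dsm")


# perturbation setup of the bundled calibration DSM: offsets large enough to
# excite a visible transient; multipliers in the mid range of the published
# benchmark rows
EXAMPLE_DSM_SPEC = PerturbationSpec(
    mu=2.0, sigma=0.1, L=0.1, U=0.5, t_start=0.0, t_end=10.0, dt=0.1)


def random_additive_dsm(
    p: int,
    edges_per_node: float = 1.0,
    term_weights: tuple[float, float, float] = (0.5, 0.25, 0.25),
    seed: int | None = None,
    extra_edges: int = 0,
    horizon: tuple[float, float, int] = (0.0, 10.0, 50),
    max_tries: int = 200,
) -> tuple[DSModel, SuperPathwayTopology]:
    """Random sparse additive DSM plus its (superset) topology.

    Every child gets basal production, first-order self-decay and, per drawn
    parent, one term whose family is sampled from ``term_weights``
    (linear, quadratic, sigmoidal). Candidate models are rejection-sampled
    for bounded trajectories over ``horizon``; ``extra_edges`` inactive
    distractor edges can be added to the returned topology to exercise term
    selection.
    """
    if p < 1:
        raise InvalidParameterError("need p >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"X{i}" for i in range(1, p + 1)]
    weights = np.asarray(term_weights, float)
    weights = weights / weights.sum()

    for _ in range(max_tries):
        cms = {}
        edges = set()
        for vid in ids:
            others = [v for v in ids if v != vid]
            n_par = min(len(others), rng.poisson(edges_per_node))
            parents = list(rng.choice(others, size=n_par, replace=False)) if n_par else []
            cm = ChildModel(
                vid,
                beta0=float(rng.uniform(0.1, 0.8)),
                beta_linear={vid: -float(rng.uniform(0.3, 1.0))},
            )
            for par in parents:
                kind = rng.choice(3, p=weights)
                mag = float(rng.uniform(0.3, 1.2)) * float(rng.choice([-1.0, 1.0]))
                if kind == 0:
                    cm.beta_linear[par] = mag
                elif kind == 1:
                    cm.beta_quadratic[tuple(sorted((par, par)))] = 0.5 * mag
                else:
                    cm.beta_sigmoid[par] = mag
                    cm.h[par] = float(rng.uniform(0.5, 2.0))
            cm = ChildModel(vid, cm.beta0, cm.beta_linear, cm.beta_quadratic,
                            cm.beta_sigmoid, cm.h)
            cms[vid] = cm
            for par in cm.parents:
                edges.add((par, vid))
        dsm = DSModel(cms, label="cond1")
        for _ in range(extra_edges):
            a, b = rng.choice(ids, size=2, replace=True)
            edges.add((str(a), str(b)))
        topo = SuperPathwayTopology(ids, sorted(edges))
        x0 = rng.uniform(0.5, 2.0, size=p)
        t0, t1, n = horizon
        try:
            tc = simulate_trajectory(dsm.rate_function(), x0,
                                     np.linspace(t0, t1, n), ids, bound=100.0)
        except IntegrationError:
            continue
        if np.abs(tc.values).max() <= 100.0 and tc.values.min() > -10.0:
            dsm._x0 = x0  # convenience for callers wrapping it as a system
            return dsm, topo
    raise GenerationError(
        f"no bounded random DSM found in {max_tries} tries (p={p})")
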