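"""Additive nonlinear dynamical-system models (DSMs).

Each pathway node ``i`` is modelled by an ODE for its rate of change,

    dx_i/dt = beta0 + sum_l beta_l x_l + sum_(q1,q2) beta_q x_q1 x_q2
              + sum_s beta_s * x_s / (x_s + h_s) + noise,

a linear combination of linear, quadratic and sigmoidal terms in the
topology-parents of ``i``. The sigmoidal term is the Michaelis-Menten form
``x/(x+h)``: basal activation, near-linear response around ``h`` (the
half-occupation constant, where the term equals exactly 0.5), and saturation
towards 1 — a one-parameter approximation of transcription-activation
kinetics.

Model complexity counts every fitted quantity: the intercept, one per linear
or quadratic coefficient, and two per sigmoidal term (coefficient plus the
estimated ``h``). The latter convention is configurable via
:meth:`TermSet.complexity`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import (
    IntegrationError,
    InvalidParameterError,
    MissingVariableError,
)
from .timecourse import TimeCourseSet

__all__ = [
    "TermSet",
    "ChildModel",
    "DSModel",
    "eval_sigmoid_term",
    "model_complexity",
    "simulate_trajectory",
]


def eval_sigmoid_term(x, h):
    """Sigmoidal (half-occupation) term ``x / (x + h)``.

    Strictly increasing in ``x``, strictly decreasing in ``h``, bounded in
    ``[0, 1)``, and equal to 0.5 exactly at ``x = h``.

    Parameters
    ----------
    x : float or ndarray
        Non-negative regulator abundance.
    h : float
        Strictly positive half-occupation constant.
    """
    h = float(h)
    if not h > 0:
        raise InvalidParameterError(f"half-occupation constant must be > 0, got {h}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise InvalidParameterError("sigmoid input must be non-negative")
    out = x / (x + h)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TermSet:
    """Active term structure for one child variable.

    ``linear`` and ``sigmoidal`` are parent ids; ``quadratic`` holds unordered
    parent pairs (stored sorted; self-pairs ``(A, A)`` are allowed and encode
    ``x_A^2``).
    """

    child: str
    linear: tuple[str, ...] = ()
    quadratic: tuple[tuple[str, str], ...] = ()
    sigmoidal: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "linear", tuple(sorted(self.linear)))
        object.__setattr__(
            self, "quadratic",
            tuple(sorted(tuple(sorted(p)) for p in self.quadratic)),
        )
        object.__setattr__(self, "sigmoidal", tuple(sorted(self.sigmoidal)))

    @property
    def n_terms(self) -> int:
        return len(self.linear) + len(self.quadratic) + len(self.sigmoidal)

    @property
    def parents(self) -> tuple[str, ...]:
        seen = set(self.linear) | set(self.sigmoidal)
        for a, b in self.quadratic:
            seen.update((a, b))
        return tuple(sorted(seen))

    def complexity(self, count_h: bool = True) -> int:
        """Number of fitted parameters: 1 (intercept) + terms (+h's)."""
        per_sig = 2 if count_h else 1
        return 1 + len(self.linear) + len(self.quadratic) + per_sig * len(self.sigmoidal)

    def validate_against(self, parents: Sequence[str]) -> None:
        allowed = set(parents)
        bad = [p for p in self.parents if p not in allowed]
        if bad:
            raise MissingVariableError(bad, f"term set of child '{self.child}'")


@dataclass
class ChildModel:
    """Fitted additive ODE right-hand side for one child variable."""

    child: str
    beta0: float = 0.0
    beta_linear: dict[str, float] = field(default_factory=dict)
    beta_quadratic: dict[tuple[str, str], float] = field(default_factory=dict)
    beta_sigmoid: dict[str, float] = field(default_factory=dict)
    h: dict[str, float] = field(default_factory=dict)
    terms: TermSet | None = None
    count_h: bool = True

    def __post_init__(self):
        self.beta_quadratic = {
            tuple(sorted(k)): float(v) for k, v in self.beta_quadratic.items()
        }
        if set(self.h) != set(self.beta_sigmoid):
            raise InvalidParameterError(
                "each sigmoidal term needs exactly one half-occupation constant"
            )
        for parent, hv in self.h.items():
            if not float(hv) > 0:
                raise InvalidParameterError(
                    f"h for parent '{parent}' must be > 0, got {hv}"
                )
        if self.terms is None:
            self.terms = TermSet(
                self.child,
                linear=tuple(self.beta_linear),
                quadratic=tuple(self.beta_quadratic),
                sigmoidal=tuple(self.beta_sigmoid),
            )

    @property
    def complexity_m(self) -> int:
        return self.terms.complexity(count_h=self.count_h)

    @property
    def parents(self) -> tuple[str, ...]:
        return self.terms.parents

    def eval_rate(self, state: Mapping[str, float]) -> float:
        """Evaluate the modelled rate of change at a state vector.

        Negative abundances (possible after additive noise) contribute 0
        occupancy to sigmoidal terms.
        """
        missing = [p for p in self.parents if p not in state]
        if missing:
            raise MissingVariableError(missing, f"state for child '{self.child}'")
        rate = self.beta0
        for parent, beta in self.beta_linear.items():
            rate += beta * state[parent]
        for (a, b), beta in self.beta_quadratic.items():
            rate += beta * state[a] * state[b]
        for parent, beta in self.beta_sigmoid.items():
            x = max(state[parent], 0.0)
            rate += beta * eval_sigmoid_term(x, self.h[parent])
        return float(rate)


def model_complexity(model: ChildModel) -> int:
    """Number of fitted parameters m(i); the constant null model returns 1."""
    return model.complexity_m


@dataclass
class DSModel:
    """A pathway DSM: one ChildModel per variable.

    ``label`` identifies its role in the comparative quartet:
    ``cond1``/``cond2`` (heterogeneous), ``pooled`` (homogeneous) or ``null``.
    """

    child_models: dict[str, ChildModel]
    label: str = "cond1"

    LABELS = ("cond1", "cond2", "pooled", "null")

    def __post_init__(self):
        if self.label not in self.LABELS:
            raise InvalidParameterError(
                f"label must be one of {self.LABELS}, got '{self.label}'"
            )
        for vid, cm in self.child_models.items():
            if cm.child != vid:
                raise InvalidParameterError(
                    f"child model for '{vid}' is labelled '{cm.child}'"
                )

    @property
    def variable_ids(self) -> list[str]:
        return sorted(self.child_models)

    @property
    def complexity_m(self) -> int:
        return sum(cm.complexity_m for cm in self.child_models.values())

    def rate_function(self) -> Callable[[float, np.ndarray], np.ndarray]:
        """Vector field f(t, x) over variables in sorted-id order."""
        ids = self.variable_ids
        models = [self.child_models[v] for v in ids]

        def rhs(t, x):
            state = dict(zip(ids, x))
            return np.array([m.eval_rate(state) for m in models])

        return rhs


def simulate_trajectory(
    system: Callable[[float, np.ndarray], np.ndarray],
    x0: Sequence[float],
    times: Sequence[float],
    variable_ids: Sequence[str] | None = None,
    *,
    condition_label: str = "simulated",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    attach_derivatives: bool = False,
    bound: float = 1e6,
) -> TimeCourseSet:
    """Integrate an ODE system and report states at the requested times.

    Uses adaptive step-size error control (``rtol``/``atol``). When
    ``attach_derivatives`` is true the exact right-hand side at the sample
    times is stored on the returned :class:`TimeCourseSet` — handy as ground
    truth for derivative-estimation tests.

    Raises
    ------
    IntegrationError
        On solver failure or states exceeding ``bound``; carries
        ``last_valid_time``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 3:
        raise InvalidParameterError("need at least 3 strictly increasing times")
    if not np.all(np.diff(times) > 0):
        raise InvalidParameterError("times must be strictly increasing")
    x0 = np.asarray(x0, dtype=float)
    if variable_ids is None:
        variable_ids = [f"x{i+1}" for i in range(x0.size)]

    t0, t1 = float(times[0]), float(times[-1])

    def _blowup(t, x):  # terminal guard: stop instead of chasing a singularity
        return bound - np.max(np.abs(x))

    _blowup.terminal = True

    sol = solve_ivp(
        system, (t0, t1), x0, t_eval=times, method=method, rtol=rtol, atol=atol,
        events=_blowup,
    )
    if sol.status != 0 or sol.y.shape[1] != times.size:
        last = float(sol.t[-1]) if sol.t.size else t0
        raise IntegrationError(
            f"ODE integration failed at t={last:g}: {sol.message}",
            last_valid_time=last,
        )
    if not np.all(np.isfinite(sol.y)) or np.max(np.abs(sol.y)) > bound:
        finite = np.all(np.isfinite(sol.y), axis=0) & (np.max(np.abs(sol.y), axis=0) <= bound)
        last = float(times[finite.nonzero()[0][-1]]) if finite.any() else t0
        raise IntegrationError(
            f"trajectory blew up beyond |x| = {bound:g}", last_valid_time=last,
        )

    derivs = None
    if attach_derivatives:
        derivs = np.column_stack([system(t, sol.y[:, k]) for k, t in enumerate(times)])
    return TimeCourseSet(condition_label, times, sol.y, list(variable_ids), derivs)
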