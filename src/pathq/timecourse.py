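"""Observed time courses and super-pathway topologies.

A :class:`TimeCourseSet` holds one condition's trajectories: the observed
abundances ``x_i(t_k)`` of ``p`` molecular variables at ``n`` (possibly
non-uniform) time stamps, plus — once estimated — the rates of change
``yhat_i(t_k)`` used as regression targets by the reconstruction step.

A :class:`SuperPathwayTopology` is a directed parent->child graph that is a
superset of all interactions possibly active; partial pathway reconstruction
selects a subset of it. Self-edges are allowed (self-regulation/degradation)
and the graph may be disconnected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .exceptions import InvalidParameterError, MissingVariableError

__all__ = ["TimeCourseSet", "SuperPathwayTopology"]


@dataclass
class TimeCourseSet:
    """One condition's observed trajectories, indexed by variable id.

    Parameters
    ----------
    condition_label : str
        Free-text label ("wildtype", "condition-2", ...).
    times : array-like of float, shape (n,)
        Strictly increasing sampling times in model time units.
    values : array-like, shape (p, n)
        Abundances, row ``i`` holds variable ``variable_ids[i]``.
    variable_ids : sequence of str
        Unique variable identifiers; all matrices are addressed by id.
    derivatives : array-like, shape (p, n), optional
        Estimated (or, for simulated data, exact) rates of change.
    """

    condition_label: str
    times: np.ndarray
    values: np.ndarray
    variable_ids: list[str]
    derivatives: np.ndarray | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.variable_ids = [str(v) for v in self.variable_ids]
        if self.times.ndim != 1:
            raise InvalidParameterError("times must be one-dimensional")
        if self.times.size < 3:
            raise InvalidParameterError("need at least 3 time points")
        if not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        if self.values.shape != (len(self.variable_ids), self.times.size):
            raise InvalidParameterError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.variable_ids)} variables, {self.times.size} times)"
            )
        if len(set(self.variable_ids)) != len(self.variable_ids):
            raise InvalidParameterError("variable ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("values contain non-finite entries")
        if self.derivatives is not None:
            self.derivatives = np.asarray(self.derivatives, dtype=float)
            if self.derivatives.shape != self.values.shape:
                raise InvalidParameterError(
                    "derivatives shape must match values shape"
                )
            if not np.all(np.isfinite(self.derivatives)):
                raise InvalidParameterError("derivatives contain non-finite entries")
        self._index = {v: i for i, v in enumerate(self.variable_ids)}

    # -- basic geometry -------------------------------------------------
    @property
    def n_times(self) -> int:
        return int(self.times.size)

    @property
    def n_variables(self) -> int:
        return len(self.variable_ids)

    @property
    def has_derivatives(self) -> bool:
        return self.derivatives is not None

    # -- access by id ---------------------------------------------------
    def row(self, variable: str) -> int:
        try:
            return self._index[variable]
        except KeyError:
            raise MissingVariableError(variable, f"time course '{self.condition_label}'")

    def series(self, variable: str) -> np.ndarray:
        """Observed abundance series of one variable."""
        return self.values[self.row(variable)]

    def derivative_series(self, variable: str) -> np.ndarray:
        if self.derivatives is None:
            raise InvalidParameterError(
                "derivatives not estimated; call estimate_derivatives first"
            )
        return self.derivatives[self.row(variable)]

    def state_at(self, k: int) -> dict[str, float]:
        """State vector (all variables) at time index ``k``."""
        return {v: float(self.values[i, k]) for v, i in self._index.items()}

    # -- derived sets ---------------------------------------------------
    def with_derivatives(self, derivatives: np.ndarray) -> "TimeCourseSet":
        return TimeCourseSet(
            self.condition_label, self.times.copy(), self.values.copy(),
            list(self.variable_ids), np.asarray(derivatives, dtype=float),
        )

    def without_derivatives(self) -> "TimeCourseSet":
        return TimeCourseSet(
            self.condition_label, self.times.copy(), self.values.copy(),
            list(self.variable_ids), None,
        )

    def subset(self, variables: Sequence[str]) -> "TimeCourseSet":
        rows = [self.row(v) for v in variables]
        return TimeCourseSet(
            self.condition_label, self.times.copy(), self.values[rows].copy(),
            list(variables),
            None if self.derivatives is None else self.derivatives[rows].copy(),
        )

    def swap_series(self, other: "TimeCourseSet", variables: Iterable[str]
                    ) -> tuple["TimeCourseSet", "TimeCourseSet"]:
        """Exchange the listed variables' series (and derivatives) with ``other``.

        Used by the permutation test to swap a node's condition assignment.
        """
        a_vals, b_vals = self.values.copy(), other.values.copy()
        a_der = None if self.derivatives is None else self.derivatives.copy()
        b_der = None if other.derivatives is None else other.derivatives.copy()
        for v in variables:
            ia, ib = self.row(v), other.row(v)
            a_vals[ia], b_vals[ib] = other.values[ib].copy(), self.values[ia].copy()
            if a_der is not None and b_der is not None:
                a_der[ia], b_der[ib] = other.derivatives[ib].copy(), self.derivatives[ia].copy()
        a = TimeCourseSet(self.condition_label, self.times.copy(), a_vals,
                          list(self.variable_ids), a_der)
        b = TimeCourseSet(other.condition_label, other.times.copy(), b_vals,
                          list(other.variable_ids), b_der)
        return a, b


class SuperPathwayTopology:
    """Directed parent->child graph constraining all candidate interactions."""

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        self._g = nx.DiGraph()
        self._g.add_nodes_from(str(n) for n in nodes)
        for parent, child in edges:
            parent, child = str(parent), str(child)
            for end in (parent, child):
                if end not in self._g:
                    raise InvalidParameterError(
                        f"edge endpoint '{end}' is not a declared node"
                    )
            self._g.add_edge(parent, child)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "SuperPathwayTopology":
        edges = [(str(a), str(b)) for a, b in edges]
        nodes = sorted({n for e in edges for n in e})
        return cls(nodes, edges)

    @property
    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._g.edges)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def parents(self, child: str) -> list[str]:
        """Sorted parent ids of ``child`` (may include ``child`` itself)."""
        if child not in self._g:
            raise MissingVariableError(child, "topology")
        return sorted(self._g.predecessors(child))

    def induced(self, nodes: Sequence[str]) -> "SuperPathwayTopology":
        """Sub-topology induced by a node subset (permutation pseudo-pathways)."""
        missing = [n for n in nodes if n not in self._g]
        if missing:
            raise MissingVariableError(missing, "topology")
        sub = self._g.subgraph(nodes)
        return SuperPathwayTopology(list(nodes), list(sub.edges))

    def to_networkx(self) -> nx.DiGraph:
        return self._g.copy()

    def __eq__(self, other):
        return (isinstance(other, SuperPathwayTopology)
                and set(self._g.nodes) == set(other._g.nodes)
                and self.edges == other.edges)

    def __repr__(self):
        return (f"SuperPathwayTopology({self._g.number_of_nodes()} nodes, "
                f"{self._g.number_of_edges()} edges)")
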