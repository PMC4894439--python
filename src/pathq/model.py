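"""Model/Results interface for pathway-rewiring analysis.

`PathwayRewiringModel` bundles the two conditions' time courses and the
super-pathway topology; `fit()` runs derivative smoothing, partial pathway
reconstruction, the Q statistics and significance, and returns a
`PathwayRewiringResults` carrying estimates, p-values, the rewiring decision
and per-node heterogeneity, with a printable `summary()`.

    >>> model = PathwayRewiringModel(tc1, tc2, topology)
    >>> res = model.fit(alpha=0.05)
    >>> print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .qstats import (
    QResult,
    aggregate_rss,
    asymptotic_pvalues,
    classify,
    compute_q,
    check_decomposition,
    node_heterogeneity,
    permutation_test,
)
from .reconstruction import Caps, ModelQuartet, reconstruct_pathway
from .smoothing import estimate_derivatives
from .timecourse import SuperPathwayTopology, TimeCourseSet
from .exceptions import InvalidParameterError


class PathwayRewiringModel:
    """Comparative dynamical-system model of one pathway under two conditions.

    Parameters
    ----------
    data1, data2 : TimeCourseSet
        Observed time courses per condition. Derivatives are estimated by
        penalized smoothing splines on construction if absent.
    topology : SuperPathwayTopology
        Super-pathway topology (a superset of candidate interactions).
    pathway_nodes : sequence of str, optional
        Restrict the tested pathway to these nodes (default: all topology
        nodes); the full system is still available to the permutation test.
    caps : Caps
        Term-search configuration.
    smoothing_penalty : "auto" or float
        Spline penalty policy, per variable ("auto" = GCV).
    """

    def __init__(
        self,
        data1: TimeCourseSet,
        data2: TimeCourseSet,
        topology: SuperPathwayTopology,
        pathway_nodes: Sequence[str] | None = None,
        caps: Caps = Caps(),
        smoothing_penalty="auto",
    ):
        if not data1.has_derivatives:
            data1 = estimate_derivatives(data1, penalty=smoothing_penalty)
        if not data2.has_derivatives:
            data2 = estimate_derivatives(data2, penalty=smoothing_penalty)
        self.data1 = data1
        self.data2 = data2
        self.topology = topology
        self.pathway_nodes = list(pathway_nodes) if pathway_nodes else topology.nodes
        self.caps = caps

    @classmethod
    def from_files(cls, path1, path2, topology_path, **kwargs):
        """Build from two time-course TSVs and a SIF topology file."""
        from .io import read_timecourse, read_topology
        return cls(read_timecourse(path1, condition_label="condition-1"),
                   read_timecourse(path2, condition_label="condition-2"),
                   read_topology(topology_path), **kwargs)

    def fit(
        self,
        alpha: float = 0.05,
        pvalue_method: str = "asymptotic",
        n_permutations: int = 1000,
        seed: int | None = None,
    ) -> "PathwayRewiringResults":
        """Reconstruct the model quartet and test for pathway rewiring.

        ``pvalue_method`` is "asymptotic" (F distributions) or "permutation"
        (pseudo-pathways resampled from the whole system; ``seed`` required).
        """
        if pvalue_method not in ("asymptotic", "permutation"):
            raise InvalidParameterError(
                f"unknown pvalue_method '{pvalue_method}'")
        if pvalue_method == "permutation" and seed is None:
            raise InvalidParameterError(
                "a seed is mandatory for the permutation test")
        quartet = reconstruct_pathway(
            self.data1, self.data2, self.topology, caps=self.caps,
            nodes=self.pathway_nodes)
        agg = aggregate_rss(quartet)
        q = asymptotic_pvalues(compute_q(agg))
        perm = None
        if pvalue_method == "permutation":
            perm = permutation_test(
                self.data1, self.data2, self.topology, self.pathway_nodes,
                n_permutations=n_permutations, seed=seed, caps=self.caps,
                observed=q)
            q.p_d, q.p_c = perm.p_d, perm.p_c
            q.p_source = "permutation"
        q.alpha = alpha
        q.decision = classify(q.p_d, q.p_c, alpha)
        return PathwayRewiringResults(
            model=self, quartet=quartet, rss=agg, qresult=q,
            permutation=perm)


@dataclass
class PathwayRewiringResults:
    """Fitted quartet, Q statistics, significance and decision."""

    model: PathwayRewiringModel
    quartet: ModelQuartet
    rss: object
    qresult: QResult
    permutation: object | None = None
    _node_het: pd.DataFrame | None = field(default=None, repr=False)

    # -- convenience accessors ------------------------------------------
    @property
    def q_d(self): return self.qresult.q_d

    @property
    def q_c(self): return self.qresult.q_c

    @property
    def q_t(self): return self.qresult.q_t

    @property
    def p_d(self): return self.qresult.p_d

    @property
    def p_c(self): return self.qresult.p_c

    @property
    def p_t(self): return self.qresult.p_t

    @property
    def decision(self): return self.qresult.decision

    def node_heterogeneity(self) -> pd.DataFrame:
        """Per-node Q_d p-values (molecule + immediate parents)."""
        if self._node_het is None:
            self._node_het = node_heterogeneity(self.quartet)
        return self._node_het

    def decomposition_residual(self) -> float:
        return check_decomposition(self.qresult, self.rss)

    def summary(self) -> str:
        q = self.qresult
        a = self.rss
        lines = [
            "Pathway Rewiring Analysis (Q-method)",
            "=" * 60,
            f"nodes: {len(self.quartet.nodes)}   "
            f"n1: {a.n1}   n2: {a.n2}   p-values: {q.p_source}",
            f"RSS  null: {a.rss_null:.6g}   hom: {a.rss_hom:.6g}   "
            f"het: {a.rss_het:.6g}",
            f"complexity  m1: {a.m1}  m2: {a.m2}  m12: {a.m12}  m0: {a.m0}",
            "-" * 60,
            f"{'':<14}{'stat':>12}{'df':>12}{'p-value':>12}",
            f"{'Q_d (het.)':<14}{q.q_d:>12.4f}{f'({q.u_d},{q.v_d})':>12}"
            f"{q.p_d:>12.4g}",
            f"{'Q_c (hom.)':<14}{q.q_c:>12.4f}{f'({q.u_c},{q.v_c})':>12}"
            f"{q.p_c:>12.4g}",
            f"{'Q_t (total)':<14}{q.q_t:>12.4f}{f'({q.u_t},{q.v_t})':>12}"
            f"{q.p_t:>12.4g}",
            "-" * 60,
            f"decision at alpha={q.alpha}: {q.decision.upper()}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "qresult": self.qresult.to_dict(),
            "rss": {
                "rss_null": self.rss.rss_null,
                "rss_hom": self.rss.rss_hom,
                "rss_het": self.rss.rss_het,
            },
            "complexity": {"m1": self.rss.m1, "m2": self.rss.m2,
                           "m12": self.rss.m12, "m0": self.rss.m0},
            "n1": self.rss.n1, "n2": self.rss.n2,
            "nodes": list(self.quartet.nodes),
            "node_heterogeneity":
                self.node_heterogeneity().reset_index().to_dict("records"),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
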