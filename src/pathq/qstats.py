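"""Pathway-level Q statistics, significance, and the rewiring decision.

Per-child residuals from the reconstruction quartet are summed into

    RSS_hom  = sum_i RSS^(1,2)(i)      (homogeneous / pooled model)
    RSS_het  = sum_i RSS^(1)(i) + RSS^(2)(i)   (heterogeneous pair)
    RSS_null = sum_i RSS^0(i)          (pooled constant model)

and compared, normalised by degrees of freedom as in an F test:

    Q_d = [(RSS_hom  - RSS_het)/u_d] / [RSS_het/v_d]   heterogeneity
    Q_c = [(RSS_null - RSS_hom)/u_c] / [RSS_hom/v_c]   homogeneity
    Q_t = [(RSS_null - RSS_het)/u_t] / [RSS_het/v_t]   total strength

with u_d = m1+m2-m12, u_c = m12-m0, u_t = m1+m2-m0 and
v_d = v_t = n1+n2-(m1+m2), v_c = n1+n2-m12. The three statistics obey the
pathway interaction decomposition rule

    u_t Q_t RSS_het/v_t = u_c Q_c RSS_hom/v_c + u_d Q_d RSS_het/v_d,

i.e. total interaction strength splits exactly into homogeneity plus
heterogeneity. Significance comes either from asymptotic F distributions or
from a permutation test that resamples pseudo-pathways from the whole system
and randomly swaps each sampled node's condition assignment.

Decision rule: *differential* if p_d <= alpha (regardless of homogeneity);
otherwise *conserved* if p_c <= alpha; otherwise *insufficient* evidence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegreesOfFreedomError,
    InvalidParameterError,
    PerfectFitError,
)
from .reconstruction import Caps, ModelQuartet, reconstruct_pathway
from .timecourse import SuperPathwayTopology, TimeCourseSet

logger = logging.getLogger("pathq.qstats")

__all__ = [
    "RSSAggregate",
    "QResult",
    "PermutationResult",
    "aggregate_rss",
    "q_statistics_from_rss",
    "compute_q",
    "check_decomposition",
    "asymptotic_pvalues",
    "empirical_pvalue",
    "permutation_test",
    "classify",
    "node_heterogeneity",
]


@dataclass(frozen=True)
class RSSAggregate:
    """Pathway-summed residuals and complexities of the model quartet."""

    rss_hom: float
    rss_het: float
    rss_null: float
    m1: int
    m2: int
    m12: int
    m0: int
    n1: int
    n2: int


@dataclass
class QResult:
    """Q statistics with degrees of freedom, p-values, and the decision."""

    q_c: float
    q_d: float
    q_t: float
    u_c: int
    v_c: int
    u_d: int
    v_d: int
    u_t: int
    v_t: int
    p_c: float | None = None
    p_d: float | None = None
    p_t: float | None = None
    p_source: str | None = None      # "asymptotic" or "permutation"
    decision: str | None = None      # "differential", "conserved", "insufficient"
    alpha: float | None = None
    # natural-log tail probabilities; keep resolution when p underflows,
    # e.g. for ranking nearly-noiseless benchmark pairs
    log_p_c: float | None = None
    log_p_d: float | None = None
    log_p_t: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "q_c", "q_d", "q_t", "u_c", "v_c", "u_d", "v_d", "u_t", "v_t",
            "p_c", "p_d", "p_t", "p_source", "decision", "alpha")}


def aggregate_rss(quartet: ModelQuartet) -> RSSAggregate:
    """Sum per-child RSS and complexities over the pathway."""
    return RSSAggregate(
        rss_hom=quartet.total_rss("pooled"),
        rss_het=quartet.total_rss("cond1") + quartet.total_rss("cond2"),
        rss_null=quartet.total_rss("null"),
        m1=quartet.complexity("cond1"),
        m2=quartet.complexity("cond2"),
        m12=quartet.complexity("pooled"),
        m0=quartet.complexity("null"),
        n1=quartet.n1,
        n2=quartet.n2,
    )


def q_statistics_from_rss(
    rss_null: float, rss_hom: float, rss_het: float,
    u_c: int, v_c: int, u_d: int, v_d: int, u_t: int, v_t: int,
) -> QResult:
    """Q statistics from aggregated residuals with explicit dfs.

    Negative numerators (possible only as a numerical artifact, the model
    quartet is nested by construction) are clamped to zero with a warning.
    """
    for name, v in (("v_c", v_c), ("v_d", v_d), ("v_t", v_t)):
        if v <= 0:
            raise DegreesOfFreedomError(f"{name} = {v} must be positive")
    if rss_het <= 0.0:
        raise PerfectFitError(
            "heterogeneous RSS is zero; the F-type statistics are undefined "
            "(data fitted perfectly)"
        )
    diffs = {
        "Q_d": rss_hom - rss_het,
        "Q_c": rss_null - rss_hom,
        "Q_t": rss_null - rss_het,
    }
    for name, d in diffs.items():
        if d < 0:
            warnings.warn(
                f"{name} numerator {d:.3e} < 0 clamped to 0 (numerical artifact)",
                stacklevel=2,
            )
            diffs[name] = 0.0
    q_d = (diffs["Q_d"] / u_d) / (rss_het / v_d) if u_d > 0 else 0.0
    q_c = (diffs["Q_c"] / u_c) / (rss_hom / v_c) if u_c > 0 and rss_hom > 0 else 0.0
    q_t = (diffs["Q_t"] / u_t) / (rss_het / v_t) if u_t > 0 else 0.0
    return QResult(q_c=q_c, q_d=q_d, q_t=q_t,
                   u_c=u_c, v_c=v_c, u_d=u_d, v_d=v_d, u_t=u_t, v_t=v_t)


def compute_q(agg: RSSAggregate) -> QResult:
    """Q statistics for a pathway aggregate; p-values left unset."""
    u_d = agg.m1 + agg.m2 - agg.m12
    v_d = agg.n1 + agg.n2 - (agg.m1 + agg.m2)
    u_c = agg.m12 - agg.m0
    v_c = agg.n1 + agg.n2 - agg.m12
    u_t = agg.m1 + agg.m2 - agg.m0
    v_t = v_d
    return q_statistics_from_rss(
        agg.rss_null, agg.rss_hom, agg.rss_het,
        u_c, v_c, u_d, v_d, u_t, v_t,
    )


def check_decomposition(q: QResult, agg: RSSAggregate) -> float:
    """Absolute residual of the pathway interaction decomposition rule.

    Verifies u_t*Q_t*RSS_het/v_t = u_c*Q_c*RSS_hom/v_c + u_d*Q_d*RSS_het/v_d
    (the df-weighted restatement of RSS_null - RSS_het =
    (RSS_null - RSS_hom) + (RSS_hom - RSS_het)).
    """
    lhs = q.u_t * q.q_t * agg.rss_het / q.v_t
    rhs = (q.u_c * q.q_c * agg.rss_hom / q.v_c
           + q.u_d * q.q_d * agg.rss_het / q.v_d)
    return abs(lhs - rhs)


def asymptotic_pvalues(q: QResult) -> QResult:
    """Upper-tail F probabilities for Q_c, Q_d, Q_t.

    A zero numerator df (a pathway whose pooled model is the null model, so
    homogeneity beyond the constant is untestable) yields p = 1.
    """
    def tail(stat, u, v):
        if u <= 0:
            return 1.0, 0.0
        with np.errstate(divide="ignore"):
            return float(stats.f.sf(stat, u, v)), float(stats.f.logsf(stat, u, v))

    out = replace(q)
    out.p_c, out.log_p_c = tail(q.q_c, q.u_c, q.v_c)
    out.p_d, out.log_p_d = tail(q.q_d, q.u_d, q.v_d)
    out.p_t, out.log_p_t = tail(q.q_t, q.u_t, q.v_t)
    out.p_source = "asymptotic"
    return out


def empirical_pvalue(observed: float, null_values: Sequence[float]) -> float:
    """Permutation p with the add-one rule: (1 + #{null >= obs}) / (B + 1)."""
    null_values = np.asarray(null_values, float)
    return float((1 + np.sum(null_values >= observed)) / (null_values.size + 1))


def classify(p_d: float, p_c: float, alpha: float) -> str:
    """Rewiring decision: differential > conserved > insufficient."""
    for name, p in (("p_d", p_d), ("p_c", p_c)):
        if not 0.0 <= p <= 1.0:
            raise InvalidParameterError(f"{name} = {p} outside [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha = {alpha} outside (0, 1)")
    if p_d <= alpha:
        return "differential"
    if p_c <= alpha:
        return "conserved"
    return "insufficient"


@dataclass
class PermutationResult:
    """Empirical significance of Q_d and Q_c from pseudo-pathway permutations."""

    p_d: float
    p_c: float
    observed: QResult
    null_q_d: np.ndarray
    null_q_c: np.ndarray
    n_permutations: int
    seed: int | None


def _quartet_q(tc1, tc2, topology, nodes, caps) -> QResult:
    quartet = reconstruct_pathway(tc1, tc2, topology, caps=caps, nodes=nodes)
    return compute_q(aggregate_rss(quartet))


class _ChildFitCache:
    """Memoises per-child fits across permutations.

    A permutation only changes which nodes form the pseudo-pathway and which
    nodes' condition series are swapped; a child's fit depends on nothing but
    (child, its induced parents, the swap pattern of child and parents), so
    across hundreds of permutations only a handful of distinct fits occur.
    Requires both conditions to share one time grid (otherwise per-node
    condition swapping would misalign regression samples).
    """

    def __init__(self, tc1, tc2, topology, caps):
        if tc1.n_times != tc2.n_times or not np.allclose(tc1.times, tc2.times):
            raise InvalidParameterError(
                "permutation test requires both conditions sampled on the "
                "same time grid")
        self.tc1, self.tc2, self.topology, self.caps = tc1, tc2, topology, caps
        self._store: dict = {}

    def record(self, child, parents, swapped: frozenset):
        from .reconstruction import select_terms  # local import, no cycle
        from .timecourse import SuperPathwayTopology, TimeCourseSet

        relevant = sorted({child, *parents})
        key = (child, tuple(parents),
               tuple(v in swapped for v in relevant))
        rec = self._store.get(key)
        if rec is not None:
            return rec
        rows1, rows2, d1, d2 = [], [], [], []
        for v in relevant:
            a, b = (self.tc2, self.tc1) if v in swapped else (self.tc1, self.tc2)
            rows1.append(a.series(v)); d1.append(a.derivative_series(v))
            rows2.append(b.series(v)); d2.append(b.derivative_series(v))
        t1 = TimeCourseSet("perm-c1", self.tc1.times, np.array(rows1),
                           relevant, np.array(d1))
        t2 = TimeCourseSet("perm-c2", self.tc2.times, np.array(rows2),
                           relevant, np.array(d2))
        topo = SuperPathwayTopology(relevant, [(p, child) for p in parents])
        rec = select_terms(child, t1, t2, topo, self.caps)
        self._store[key] = rec
        return rec

    def pathway_q(self, nodes, swapped: frozenset) -> QResult:
        node_set = set(nodes)
        recs = []
        for child in nodes:
            parents = [p for p in self.topology.parents(child)
                       if p in node_set]
            recs.append(self.record(child, tuple(parents), swapped))
        agg = RSSAggregate(
            rss_hom=sum(r.rss["pooled"] for r in recs),
            rss_het=sum(r.rss_het for r in recs),
            rss_null=sum(r.rss["null"] for r in recs),
            m1=sum(r.m["cond1"] for r in recs),
            m2=sum(r.m["cond2"] for r in recs),
            m12=sum(r.m["pooled"] for r in recs),
            m0=len(recs),
            n1=self.tc1.n_times, n2=self.tc2.n_times,
        )
        return compute_q(agg)


def permutation_test(
    tc1: TimeCourseSet,
    tc2: TimeCourseSet,
    topology: SuperPathwayTopology,
    pathway_nodes: Sequence[str],
    n_permutations: int = 1000,
    seed: int | None = None,
    caps: Caps = Caps(),
    observed: QResult | None = None,
) -> PermutationResult:
    """Permutation significance of Q_d and Q_c for one pathway.

    Each permutation draws ``len(pathway_nodes)`` nodes uniformly without
    replacement from the entire system (``topology`` covers the system; the
    pseudo-pathway inherits its induced sub-topology), independently swaps
    each sampled node's condition-1/condition-2 series with probability 0.5,
    reconstructs, and records Q*_d and Q*_c. Empirical p-values use the
    add-one rule, so the smallest attainable p is 1/(B+1). Draws that would
    reproduce the observed comparison verbatim (the tested node set with
    none or all nodes swapped — a concern only when the system is not much
    larger than the pathway) are redrawn, since the identity is already
    accounted for by the add-one rule.

    ``tc1``/``tc2`` must cover the whole system and carry derivative
    estimates (smoothing is per condition, so swapped series keep their own
    derivative estimates).
    """
    if n_permutations < 1:
        raise InvalidParameterError("need at least 1 permutation")
    if n_permutations > 100_000:
        logger.warning("B = %d permutations exceeds any practical budget",
                       n_permutations)
    pathway_nodes = list(pathway_nodes)
    system_nodes = topology.nodes
    if len(system_nodes) < len(pathway_nodes):
        raise InvalidParameterError(
            "system has fewer nodes than the pathway to permute")

    if observed is None:
        observed = _quartet_q(tc1, tc2, topology, pathway_nodes, caps)

    rng = np.random.default_rng(seed)
    cache = _ChildFitCache(tc1, tc2, topology, caps)
    null_q_d = np.empty(n_permutations)
    null_q_c = np.empty(n_permutations)
    pathway_set = frozenset(pathway_nodes)
    for b in range(n_permutations):
        # draw a pseudo-pathway + swap pattern; patterns that reproduce the
        # observed comparison exactly (the tested node set with no node, or
        # every node, swapped) carry no null information -- the add-one rule
        # already accounts for the identity -- so they are redrawn
        for _ in range(1000):
            sampled = list(rng.choice(system_nodes, size=len(pathway_nodes),
                                      replace=False))
            swap_mask = rng.random(len(sampled)) < 0.5
            swapped = frozenset(v for v, s in zip(sampled, swap_mask) if s)
            noop = (frozenset(sampled) == pathway_set
                    and swapped in (frozenset(), frozenset(sampled)))
            if not noop:
                break
        try:
            qb = cache.pathway_q(sampled, swapped)
            null_q_d[b] = qb.q_d
            null_q_c[b] = qb.q_c
        except (PerfectFitError, DegreesOfFreedomError) as exc:
            logger.info("permutation %d degenerate (%s); Q* set to 0", b, exc)
            null_q_d[b] = 0.0
            null_q_c[b] = 0.0

    return PermutationResult(
        p_d=empirical_pvalue(observed.q_d, null_q_d),
        p_c=empirical_pvalue(observed.q_c, null_q_c),
        observed=observed,
        null_q_d=null_q_d,
        null_q_c=null_q_c,
        n_permutations=n_permutations,
        seed=seed,
    )


def node_heterogeneity(quartet: ModelQuartet) -> pd.DataFrame:
    """Per-node interaction heterogeneity: Q_d restricted to one child.

    For each molecule the sub-pathway consists of the molecule and its
    immediate parents, so the statistic uses that child's fit record alone:
    u_d(i) = m(i), v_d(i) = n1 + n2 - 2 m(i). Returns a DataFrame indexed by
    node with columns ``q_d`` and ``p_d``.
    """
    rows = []
    n = quartet.n1 + quartet.n2
    for child in quartet.nodes:
        rec = quartet.records[child]
        m = rec.m["cond1"]
        u, v = m, n - 2 * m
        num = max(rec.rss["pooled"] - rec.rss_het, 0.0)
        if v <= 0:
            rows.append((child, np.nan, np.nan))
            continue
        if rec.rss_het <= 0.0:
            q_d = np.inf if num > 0 else 0.0
        else:
            q_d = (num / u) / (rec.rss_het / v)
        rows.append((child, q_d, float(stats.f.sf(q_d, u, v))))
    return pd.DataFrame(rows, columns=["node", "q_d", "p_d"]).set_index("node")
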