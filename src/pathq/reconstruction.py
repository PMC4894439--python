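"""Partial pathway reconstruction.

For every child variable a shared active-term structure (TermSet) is selected
from the super-pathway topology, and four models are fitted:

* two *heterogeneous* models — the same TermSet fitted separately to each
  condition's (state, derivative-estimate) samples;
* one *homogeneous* model — the TermSet fitted to the two conditions'
  samples pooled;
* the *null* model — a constant equal to the time-averaged derivative over
  the pooled sample.

Coefficients are ordinary least squares of the estimated derivative on the
term design matrix; each sigmoidal half-occupation constant ``h`` is profiled
over a fixed grid of quantiles of the parent's observed values, refitting the
linear coefficients per grid point and keeping the global RSS minimiser.

The TermSet is chosen, per child, to minimise the p-value of the total
interaction-strength F statistic

    F_t(i) = [(RSS0 - RSS1 - RSS2) / u] / [(RSS1 + RSS2) / v],
    u = m1(i) + m2(i) - 1,   v = n1 + n2 - (m1(i) + m2(i)),

over all candidate TermSets drawn from the child's topology-parents
(exhaustively up to ``Caps.max_terms`` terms; greedy forward selection when
the candidate count exceeds ``Caps.max_candidates``).

Implementation note: the search evaluates thousands of tiny OLS problems per
child. All candidate columns (intercept, linear, quadratic, sigmoid at every
grid value of h) are materialised once per (child, data set); their Gram
matrix is precomputed so that each candidate's normal equations are solved by
indexing into it, batched across candidates. A small ridge (``Caps.ridge`` on
unit-normalised columns) keeps near-collinear candidates finite during the
search; the finally selected structure is refitted by ``lstsq`` on the raw
columns, so reported RSS values carry no ridge bias.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats

from .dsm import ChildModel, DSModel, TermSet
from .exceptions import (
    InfeasibleFitError,
    InvalidParameterError,
    MissingVariableError,
)
from .timecourse import SuperPathwayTopology, TimeCourseSet

logger = logging.getLogger("pathq.reconstruction")

__all__ = [
    "Caps",
    "ChildFitRecord",
    "ModelQuartet",
    "candidate_terms",
    "fit_child_given_terms",
    "select_terms",
    "reconstruct_pathway",
    "f_total_from_rss",
]

_FAMILIES = ("linear", "quadratic", "sigmoidal")


@dataclass(frozen=True)
class Caps:
    """Search-space and fitting configuration.

    max_terms : largest number of terms per child TermSet.
    max_candidates : above this candidate count, greedy forward selection
        replaces exhaustive enumeration.
    h_grid_size : number of quantile grid points profiled for each h.
    h_quantiles : quantile range of the parent's positive observed values
        spanned by the h grid.
    count_h : whether each sigmoidal term contributes 2 to model complexity
        (coefficient + fitted h) rather than 1.
    families : term families admitted as candidates.
    ridge : diagonal jitter on the unit-normalised Gram matrix used during
        the candidate search only.
    """

    max_terms: int = 3
    max_candidates: int = 5000
    h_grid_size: int = 17
    h_quantiles: tuple[float, float] = (0.05, 0.95)
    count_h: bool = True
    families: tuple[str, ...] = _FAMILIES

    ridge: float = 1e-8

    def __post_init__(self):
        if self.max_terms < 0 or self.max_candidates < 1:
            raise InvalidParameterError("max_terms >= 0 and max_candidates >= 1 required")
        bad = set(self.families) - set(_FAMILIES)
        if bad:
            raise InvalidParameterError(f"unknown term families: {sorted(bad)}")


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def _atoms(parents: Sequence[str], families: Sequence[str],
           sigmoid_ok=None) -> list[tuple]:
    """Ordered atomic terms for a child: linear, quadratic pairs, sigmoidal."""
    atoms: list[tuple] = []
    if "linear" in families:
        atoms += [("linear", p) for p in sorted(parents)]
    if "quadratic" in families:
        pairs = itertools.combinations_with_replacement(sorted(parents), 2)
        atoms += [("quadratic", pair) for pair in pairs]
    if "sigmoidal" in families:
        for p in sorted(parents):
            if sigmoid_ok is None or sigmoid_ok(p):
                atoms.append(("sigmoidal", p))
    return atoms


def _termset(child: str, chosen: Sequence[tuple]) -> TermSet:
    return TermSet(
        child,
        linear=tuple(a[1] for a in chosen if a[0] == "linear"),
        quadratic=tuple(a[1] for a in chosen if a[0] == "quadratic"),
        sigmoidal=tuple(a[1] for a in chosen if a[0] == "sigmoidal"),
    )


def candidate_terms(topology: SuperPathwayTopology, child: str,
                    caps: Caps = Caps()) -> list[TermSet]:
    """All candidate TermSets for ``child`` with at most ``caps.max_terms`` terms.

    Deterministic order: subsets by size, atoms ordered linear < quadratic <
    sigmoidal, each sorted by parent id. A child with no topology-parents
    yields only the intercept-only (empty) TermSet.
    """
    atoms = _atoms(topology.parents(child), caps.families)
    out = []
    for size in range(min(caps.max_terms, len(atoms)) + 1):
        for chosen in itertools.combinations(atoms, size):
            out.append(_termset(child, chosen))
    return out


def _n_subsets(n_atoms: int, max_terms: int) -> int:
    return sum(comb(n_atoms, s) for s in range(min(max_terms, n_atoms) + 1))


# ---------------------------------------------------------------------------
# column pools: batched OLS over precomputed Gram matrices
# ---------------------------------------------------------------------------

def _h_grid(values: np.ndarray, caps: Caps) -> np.ndarray:
    """Quantile grid of positive observed parent values for profiling h."""
    pos = values[values > 0]
    if pos.size < 3:
        return np.empty(0)
    lo, hi = caps.h_quantiles
    grid = np.quantile(pos, np.linspace(lo, hi, caps.h_grid_size))
    return np.unique(grid[grid > 0])


class _ColumnPool:
    """All candidate design columns for one (child, data set) pair."""

    def __init__(self, y, parent_values, atoms, h_grids, ridge):
        self.y = np.asarray(y, float)
        self.n = self.y.size
        self.ridge = ridge
        cols = [np.ones(self.n)]
        self.atom_cols: dict[tuple, np.ndarray] = {}
        for atom in atoms:
            kind, ref = atom
            if kind == "linear":
                cols.append(parent_values[ref])
                idx = [len(cols) - 1]
            elif kind == "quadratic":
                a, b = ref
                cols.append(parent_values[a] * parent_values[b])
                idx = [len(cols) - 1]
            else:  # sigmoidal: one column per grid value of h
                grid = h_grids[ref]
                xp = np.clip(parent_values[ref], 0.0, None)
                idx = []
                for h in grid:
                    cols.append(xp / (xp + h))
                    idx.append(len(cols) - 1)
            self.atom_cols[atom] = np.asarray(idx)
        self.h_grids = h_grids
        self.C_raw = np.column_stack(cols)
        scale = np.linalg.norm(self.C_raw, axis=0)
        scale[scale == 0] = 1.0
        self.scale = scale
        C = self.C_raw / scale
        self.G = C.T @ C
        self.g = C.T @ self.y
        self.yy = float(self.y @ self.y)
        self.null_rss = float(np.sum((self.y - self.y.mean()) ** 2))

    # -- combo helpers ---------------------------------------------------
    def _combos(self, terms: TermSet) -> np.ndarray:
        """Index rows (combos, k) into the pool for every h-grid assignment."""
        atoms = ([("linear", p) for p in terms.linear]
                 + [("quadratic", q) for q in terms.quadratic]
                 + [("sigmoidal", p) for p in terms.sigmoidal])
        return self.combos_for_atoms(tuple(atoms))

    def combos_for_atoms(self, atom_set: tuple) -> np.ndarray:
        """Index rows for an atom tuple (column layout is pool-independent
        across pools built from the same atoms and grids)."""
        fixed = [0]
        sig_choices = []
        for atom in atom_set:
            cols = self.atom_cols[atom]
            if atom[0] == "sigmoidal":
                sig_choices.append(cols)
            else:
                fixed.append(int(cols[0]))
        if not sig_choices:
            return np.array([fixed])
        rows = [fixed + list(combo) for combo in itertools.product(*sig_choices)]
        return np.asarray(rows)

    def _batch_rss(self, idx: np.ndarray) -> np.ndarray:
        """RSS for each index row, via ridge-stabilised normal equations."""
        k = idx.shape[1]
        Gs = self.G[idx[:, :, None], idx[:, None, :]] + self.ridge * np.eye(k)
        gs = self.g[idx]
        try:
            b = np.linalg.solve(Gs, gs[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:  # pragma: no cover - ridge makes this rare
            b = np.einsum("mij,mj->mi", np.linalg.pinv(Gs), gs)
        rss = self.yy - np.einsum("mi,mi->m", b, gs)
        return np.maximum(rss, 0.0)

    def search_rss(self, termsets: Sequence[TermSet]) -> np.ndarray:
        """Minimum profile RSS per TermSet (over its h-grid combinations)."""
        return self.search_rss_rows([self._combos(ts) for ts in termsets])

    def search_rss_rows(self, rows_per_cand: Sequence[np.ndarray]) -> np.ndarray:
        """Minimum RSS per candidate given precomputed combo index rows."""
        out = np.full(len(rows_per_cand), np.inf)
        by_k: dict[int, list[int]] = {}
        for i, rows in enumerate(rows_per_cand):
            by_k.setdefault(rows.shape[1], []).append(i)
        for k, members in by_k.items():
            stacked = np.concatenate([rows_per_cand[i] for i in members])
            rss = self._batch_rss(stacked)
            pos = 0
            for i in members:
                m = rows_per_cand[i].shape[0]
                out[i] = rss[pos:pos + m].min()
                pos += m
        return out

    def best_combo(self, terms: TermSet) -> np.ndarray:
        rows = self._combos(terms)
        rss = self._batch_rss(rows)
        return rows[int(np.argmin(rss))]

    def lstsq_at(self, idx: np.ndarray) -> tuple[np.ndarray, float]:
        """Exact least-squares fit on the raw columns of one index row."""
        X = self.C_raw[:, idx]
        beta, _, rank, _ = np.linalg.lstsq(X, self.y, rcond=None)
        if rank < idx.size:
            warnings.warn(
                "rank-deficient design; minimum-norm (pseudoinverse) solution used",
                stacklevel=3,
            )
        rss = float(np.sum((self.y - X @ beta) ** 2))
        return beta, rss

    def h_of_row(self, terms: TermSet, idx: np.ndarray) -> dict[str, float]:
        """Map each sigmoidal parent to the h encoded by an index row."""
        n_fixed = 1 + len(terms.linear) + len(terms.quadratic)
        out = {}
        for j, p in enumerate(terms.sigmoidal):
            col = idx[n_fixed + j]
            grid_cols = self.atom_cols[("sigmoidal", p)]
            out[p] = float(self.h_grids[p][int(np.where(grid_cols == col)[0][0])])
        return out


def _dataset_from_tc(tc: TimeCourseSet, child: str, parents: Sequence[str]):
    if not tc.has_derivatives:
        raise InvalidParameterError(
            f"time course '{tc.condition_label}' has no derivative estimates; "
            "run estimate_derivatives first"
        )
    y = tc.derivative_series(child)
    pv = {p: tc.series(p) for p in parents}
    return y, pv


def _child_model_from_fit(child, terms: TermSet, beta, h_map, count_h) -> ChildModel:
    pos = 1
    b_lin = {}
    for p in terms.linear:
        b_lin[p] = float(beta[pos]); pos += 1
    b_quad = {}
    for pair in terms.quadratic:
        b_quad[pair] = float(beta[pos]); pos += 1
    b_sig = {}
    for p in terms.sigmoidal:
        b_sig[p] = float(beta[pos]); pos += 1
    return ChildModel(
        child, beta0=float(beta[0]), beta_linear=b_lin, beta_quadratic=b_quad,
        beta_sigmoid=b_sig, h=dict(h_map), terms=terms, count_h=count_h,
    )


# ---------------------------------------------------------------------------
# public fitting operations
# ---------------------------------------------------------------------------

def fit_child_given_terms(
    terms: TermSet,
    tc: TimeCourseSet,
    caps: Caps = Caps(),
    h_grids: dict[str, np.ndarray] | None = None,
) -> tuple[ChildModel, float]:
    """OLS fit of one TermSet to one data set; returns (model, RSS).

    ``h`` for each sigmoidal term is profiled over ``h_grids`` (default: the
    quantile grid of this data set's parent values), refitting the linear
    coefficients per grid point and keeping the global RSS minimiser.
    """
    y, pv = _dataset_from_tc(tc, terms.child, terms.parents)
    m = terms.complexity(count_h=caps.count_h)
    if y.size <= m:
        raise InfeasibleFitError(
            f"child '{terms.child}': sample size {y.size} must exceed "
            f"model complexity {m}"
        )
    if h_grids is None:
        h_grids = {p: _h_grid(pv[p], caps) for p in terms.sigmoidal}
    for p in terms.sigmoidal:
        if h_grids.get(p) is None or len(h_grids[p]) == 0:
            raise InfeasibleFitError(
                f"child '{terms.child}': parent '{p}' has no positive values "
                "to place a sigmoid half-occupation grid on"
            )
    atoms = ([("linear", p) for p in terms.linear]
             + [("quadratic", q) for q in terms.quadratic]
             + [("sigmoidal", p) for p in terms.sigmoidal])
    pool = _ColumnPool(y, pv, atoms, h_grids, caps.ridge)
    rows = pool._combos(terms)
    # exact (lstsq) profiling over the full grid for the final fit
    best = None
    for row in rows:
        beta, rss = pool.lstsq_at(row)
        if best is None or rss < best[1]:
            best = (beta, rss, row)
    beta, rss, row = best
    model = _child_model_from_fit(terms.child, terms, beta,
                                  pool.h_of_row(terms, row), caps.count_h)
    return model, rss


@dataclass
class ChildFitRecord:
    """Fit of the four models for one child under a shared TermSet."""

    child: str
    terms: TermSet
    models: dict[str, ChildModel]          # keys: cond1, cond2, pooled, null
    rss: dict[str, float]                  # same keys
    m: dict[str, int]                      # same keys (null -> 1)
    f_total: float
    p_total: float
    u_total: int
    v_total: int
    n1: int
    n2: int

    @property
    def rss_het(self) -> float:
        return self.rss["cond1"] + self.rss["cond2"]

    def to_dict(self) -> dict:
        def cm_dict(cm: ChildModel):
            return {
                "beta0": cm.beta0,
                "beta_linear": dict(cm.beta_linear),
                "beta_quadratic": {f"{a}*{b}": v for (a, b), v in cm.beta_quadratic.items()},
                "beta_sigmoid": dict(cm.beta_sigmoid),
                "h": dict(cm.h),
                "complexity_m": cm.complexity_m,
            }
        return {
            "child": self.child,
            "terms": {
                "linear": list(self.terms.linear),
                "quadratic": [list(q) for q in self.terms.quadratic],
                "sigmoidal": list(self.terms.sigmoidal),
            },
            "rss": dict(self.rss),
            "complexity": dict(self.m),
            "f_total": self.f_total,
            "p_total": self.p_total,
            "u_total": self.u_total,
            "v_total": self.v_total,
            "models": {label: cm_dict(cm) for label, cm in self.models.items()},
        }


@dataclass
class ModelQuartet:
    """The four partially reconstructed pathway DSMs with per-child RSS."""

    nodes: list[str]
    records: dict[str, ChildFitRecord]
    n1: int
    n2: int

    def model(self, label: str) -> DSModel:
        return DSModel(
            {c: r.models[label] for c, r in self.records.items()}, label=label
        )

    def complexity(self, label: str) -> int:
        return sum(r.m[label] for r in self.records.values())

    def total_rss(self, label: str) -> float:
        return sum(r.rss[label] for r in self.records.values())

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "n1": self.n1,
            "n2": self.n2,
            "complexity": {lab: self.complexity(lab)
                           for lab in ("cond1", "cond2", "pooled", "null")},
            "children": {c: r.to_dict() for c, r in self.records.items()},
        }


def f_total_from_rss(rss0: float, rss1: float, rss2: float, m: int,
                     n1: int, n2: int) -> tuple[float, float, int, int]:
    """Total-strength F statistic and p-value for one child.

    ``m`` is the (shared) complexity of the per-condition models. Returns
    ``(F, p, u, v)``; caller guarantees ``v > 0``.
    """
    u = 2 * m - 1
    v = n1 + n2 - 2 * m
    het = rss1 + rss2
    num = max(rss0 - het, 0.0) / u
    if het <= 0.0:
        f = np.inf if num > 0 else 0.0
    else:
        f = num / (het / v)
    p = float(stats.f.sf(f, u, v))
    return float(f), p, u, v


def _atom_complexity(atom_set, count_h: bool) -> int:
    per_sig = 2 if count_h else 1
    return 1 + sum(per_sig if a[0] == "sigmoidal" else 1 for a in atom_set)


def _evaluate_candidates(atom_sets, pool1, pool2, rss0, n1, n2, count_h):
    """p-value and complexity arrays for candidate atom tuples.

    Infeasible candidates (non-positive denominator df, or complexity not
    below the smaller sample size) get p = +inf. The F tail probabilities
    are evaluated vectorised per complexity group.
    """
    ms = np.array([_atom_complexity(a, count_h) for a in atom_sets])
    vs = n1 + n2 - 2 * ms
    feasible = (vs > 0) & (ms < min(n1, n2))
    idx = np.flatnonzero(feasible)
    rows = [pool1.combos_for_atoms(atom_sets[i]) for i in idx]
    rss1 = pool1.search_rss_rows(rows)
    rss2 = pool2.search_rss_rows(rows)
    # log-scale tail probabilities: at low noise the F statistics are huge
    # and plain survival probabilities underflow to exactly 0, which would
    # reduce "minimize the p-value" to a complexity tie-break
    ps = np.full(len(atom_sets), np.inf)
    het = rss1 + rss2
    m_live = ms[idx]
    u = 2 * m_live - 1
    v = n1 + n2 - 2 * m_live
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = np.where(
            het > 0,
            (np.maximum(rss0 - het, 0.0) / u) / (het / np.maximum(v, 1)),
            np.where(np.maximum(rss0 - het, 0.0) > 0, np.inf, 0.0),
        )
        logp_live = np.empty(idx.size)
        for m_val in np.unique(m_live):
            sel = m_live == m_val
            logp_live[sel] = stats.f.logsf(fstat[sel], 2 * m_val - 1,
                                           n1 + n2 - 2 * m_val)
    ps[idx] = logp_live
    return ps, ms


def _pick_best(ps, ms):
    """Smallest p; ties by smaller complexity, then enumeration order."""
    order = sorted(range(len(ps)), key=lambda i: (ps[i], ms[i], i))
    return order[0]


def select_terms(
    child: str,
    tc1: TimeCourseSet,
    tc2: TimeCourseSet,
    topology: SuperPathwayTopology,
    caps: Caps = Caps(),
) -> ChildFitRecord:
    """Select the shared TermSet for one child and fit the model quartet.

    Both conditions are fitted with the same candidate TermSet; the candidate
    minimising the upper-tail p-value of ``F_t(i)`` wins (ties: smaller
    complexity, then enumeration order). Candidates whose denominator df is
    non-positive are skipped. The pooled model refits the selected TermSet on
    the concatenated samples; the null model is the pooled time-average of
    the derivative estimates.

    The h-profiling grid for every fit is computed from the pooled sample, so
    the heterogeneous pair can always realise the pooled model's h — this
    makes the nestedness RSS1+RSS2 <= RSS12 <= RSS0 exact.
    """
    parents = topology.parents(child)
    y1, pv1 = _dataset_from_tc(tc1, child, parents)
    y2, pv2 = _dataset_from_tc(tc2, child, parents)
    n1, n2 = y1.size, y2.size
    y_pool = np.concatenate([y1, y2])
    pv_pool = {p: np.concatenate([pv1[p], pv2[p]]) for p in parents}

    h_grids = {p: _h_grid(pv_pool[p], caps) for p in parents}
    atoms = _atoms(parents, caps.families, sigmoid_ok=lambda p: h_grids[p].size > 0)

    pool1 = _ColumnPool(y1, pv1, atoms, h_grids, caps.ridge)
    pool2 = _ColumnPool(y2, pv2, atoms, h_grids, caps.ridge)
    pool12 = _ColumnPool(y_pool, pv_pool, atoms, h_grids, caps.ridge)

    rss0 = pool12.null_rss

    if _n_subsets(len(atoms), caps.max_terms) <= caps.max_candidates:
        atom_sets = []
        for size in range(min(caps.max_terms, len(atoms)) + 1):
            atom_sets.extend(itertools.combinations(atoms, size))
        ps, ms = _evaluate_candidates(
            atom_sets, pool1, pool2, rss0, n1, n2, caps.count_h)
        best = _pick_best(ps, ms)
        selected = _termset(child, atom_sets[best])
        if ps[best] == np.inf:  # no feasible candidate at all
            warnings.warn(
                f"child '{child}': no feasible candidate TermSet; "
                "falling back to intercept-only", stacklevel=2)
            selected = _termset(child, ())
    else:
        logger.info(
            "child %s: %d candidates exceed cap %d; greedy forward selection",
            child, _n_subsets(len(atoms), caps.max_terms), caps.max_candidates)
        selected = _greedy_select(child, atoms, pool1, pool2, rss0,
                                  n1, n2, caps)

    return _fit_record(child, selected, pool1, pool2, pool12, rss0,
                       n1, n2, caps)


def _greedy_select(child, atoms, pool1, pool2, rss0, n1, n2, caps):
    current: list[tuple] = []
    remaining = list(atoms)
    ps, _ = _evaluate_candidates([tuple(current)], pool1, pool2, rss0,
                                 n1, n2, caps.count_h)
    best_p = ps[0]
    while len(current) < caps.max_terms and remaining:
        cands = [tuple(current + [a]) for a in remaining]
        ps, ms = _evaluate_candidates(cands, pool1, pool2, rss0, n1, n2,
                                      caps.count_h)
        j = _pick_best(ps, ms)
        if ps[j] == np.inf or ps[j] >= best_p:
            break
        best_p = ps[j]
        current.append(remaining.pop(j))
    return _termset(child, current)


def _fit_record(child, terms, pool1, pool2, pool12, rss0, n1, n2, caps):
    # pooled model first: its h assignment must be available to both
    # condition fits so nestedness holds exactly
    row12 = pool12.best_combo(terms)
    beta12, rss12 = pool12.lstsq_at(row12)
    h12 = pool12.h_of_row(terms, row12)

    def cond_fit(pool):
        row = pool.best_combo(terms)
        beta, rss = pool.lstsq_at(row)
        if not np.array_equal(row, row12):
            beta_b, rss_b = pool.lstsq_at(row12)
            if rss_b < rss:
                beta, rss, row = beta_b, rss_b, row12
        return beta, rss, pool.h_of_row(terms, row)

    beta1, rss1, h1 = cond_fit(pool1)
    beta2, rss2, h2 = cond_fit(pool2)

    m = terms.complexity(count_h=caps.count_h)
    f, p, u, v = f_total_from_rss(rss0, rss1, rss2, m, n1, n2)

    y_pool_mean = float(pool12.y.mean())
    null_model = ChildModel(child, beta0=y_pool_mean, count_h=caps.count_h)

    models = {
        "cond1": _child_model_from_fit(child, terms, beta1, h1, caps.count_h),
        "cond2": _child_model_from_fit(child, terms, beta2, h2, caps.count_h),
        "pooled": _child_model_from_fit(child, terms, beta12, h12, caps.count_h),
        "null": null_model,
    }
    return ChildFitRecord(
        child=child, terms=terms, models=models,
        rss={"cond1": rss1, "cond2": rss2, "pooled": rss12, "null": rss0},
        m={"cond1": m, "cond2": m, "pooled": m, "null": 1},
        f_total=f, p_total=p, u_total=u, v_total=v, n1=n1, n2=n2,
    )


def reconstruct_pathway(
    tc1: TimeCourseSet,
    tc2: TimeCourseSet,
    topology: SuperPathwayTopology,
    caps: Caps = Caps(),
    nodes: Sequence[str] | None = None,
) -> ModelQuartet:
    """Partial pathway reconstruction: the four fitted DSMs per pathway.

    ``nodes`` restricts the pathway to a node subset (default: all topology
    nodes); parents are still drawn from the full topology restricted to
    those nodes. Both time courses must carry derivative estimates.
    """
    if nodes is None:
        nodes = topology.nodes
    nodes = list(nodes)
    for tc in (tc1, tc2):
        missing = [v for v in nodes if v not in tc.variable_ids]
        if missing:
            raise MissingVariableError(missing,
                                       f"time course '{tc.condition_label}'")
    sub = topology.induced(nodes) if set(nodes) != set(topology.nodes) else topology
    records = {}
    for child in nodes:
        records[child] = select_terms(child, tc1, tc2, sub, caps)
    n1 = tc1.n_times
    n2 = tc2.n_times
    return ModelQuartet(nodes=nodes, records=records, n1=n1, n2=n2)
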