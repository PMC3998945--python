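"""Exact alignment solvers with certified optimality bounds.

The global pairwise network alignment problem is a generalization of the
quadratic assignment problem: choose a partial injective query → target
mapping, restricted to E-value-admissible candidate pairs, maximizing the
total score (conserved-interaction fraction plus the subordinate sequence
term).  We solve a standard linearization exactly:

* binary pair variables x(u, v) for every candidate pair, with row/column
  injectivity constraints;
* conservation variables y(uv, pq), one per (query edge, target edge) pair
  that some orientation of candidate choices can realize, linked by
  ``y <= sum of x on the u side`` and ``y <= sum of x on the v side``.
  Under injectivity, y = 1 exactly when the query edge uv maps onto the
  target edge pq, so y may be left continuous in [0, 1];
* objective (sum y) / min|E| + coefficient * sum b(u, v) x(u, v).

The mixed-integer program is handed to HiGHS through
:func:`scipy.optimize.milp` with a zero relative-gap target; the engine's
best dual bound is reported as a certified upper bound on the optimal
score, and the gap between bound and incumbent is the optimality gap.  On
query-scale instances the gap closes and the alignment is provably optimal.

``align_sequence_only`` ignores topology: it is a maximum-weight bipartite
assignment under the normalized bit scores, solved exactly with the
Hungarian algorithm.  ``brute_force_align`` enumerates every feasible
partial injective map and serves as an independent oracle on small
instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import LinearConstraint, linear_sum_assignment, milp
from scipy.sparse import csr_matrix

from netquery.errors import NetQueryError
from netquery.score import Alignment, SCORE_TOL, bit_sum, sequence_coefficient, total_score
from netquery.similarity import CandidateSet

#: gap at or below which a solution is declared optimal
GAP_TOL = 1e-6

#: cap on the number of feasible mappings brute force will enumerate
BRUTE_FORCE_GUARD = 10_000_000


@dataclass
class AlignmentResult:
    """An alignment together with its certificate and run metadata."""

    alignment: Alignment
    score: float
    upper_bound: float
    gap: float
    optimal: bool
    mode: str  # "topology" | "sequence_only"
    e_max: float | None = None
    solver_status: str = ""
    wall_time: float = 0.0


def _empty_result(mode: str, status: str) -> AlignmentResult:
    return AlignmentResult(
        alignment=Alignment({}), score=0.0, upper_bound=0.0, gap=0.0,
        optimal=True, mode=mode, solver_status=status,
    )


def _finalize(mapping: dict[str, str], upper_bound: float, mode: str, status: str,
              query: nx.Graph | None, target: nx.Graph | None,
              cand: CandidateSet) -> AlignmentResult:
    """Recompute the score independently from the mapping and attach the bound."""
    align = Alignment(dict(mapping))
    if mode == "topology":
        score = total_score(align, query, target, cand)
    else:
        score = bit_sum(align, cand)
    upper_bound = max(upper_bound, score)
    gap = max(0.0, upper_bound - score)
    return AlignmentResult(
        alignment=align, score=score, upper_bound=upper_bound, gap=gap,
        optimal=gap <= GAP_TOL, mode=mode, e_max=cand.e_max, solver_status=status,
    )


def align_topology(query: nx.Graph, target: nx.Graph, cand: CandidateSet,
                   time_limit: float = 300.0) -> AlignmentResult:
    """Maximize the total score over alignments consistent with ``cand``.

    Both networks must already be confidence-filtered and have at least one
    edge.  Returns the best alignment found plus a certified upper bound;
    if the time limit expires the incumbent and the best proven bound are
    returned with ``optimal=False``.  An empty candidate set yields the
    empty alignment with a warning status rather than an error.
    """
    if cand.is_empty():
        res = _empty_result("topology", "no_candidates")
        res.e_max = cand.e_max
        return res
    if min(query.number_of_edges(), target.number_of_edges()) == 0:
        raise NetQueryError("alignment score undefined: a filtered network has no edges")

    pairs = [p for p in cand.pairs() if p[0] in query.nodes and p[1] in target.nodes]
    if not pairs:
        res = _empty_result("topology", "no_candidates_in_networks")
        res.e_max = cand.e_max
        return res
    x_index = {p: i for i, p in enumerate(pairs)}
    n_x = len(pairs)

    m_min = min(query.number_of_edges(), target.number_of_edges())
    seq_coef = sequence_coefficient(query, target)

    q_edges = sorted(tuple(sorted(e)) for e in query.edges)
    t_edges = sorted(tuple(sorted(e)) for e in target.edges)

    # y variables: one per (query edge, target edge) pair realizable by
    # either orientation of candidate choices
    y_defs = []  # (u-side x indices, v-side x indices)
    for u, v in q_edges:
        au = cand.allowed.get(u, frozenset())
        av = cand.allowed.get(v, frozenset())
        if not au or not av:
            continue
        for p, q in t_edges:
            u_side, v_side = [], []
            if p in au and q in av:  # orientation u->p, v->q
                u_side.append(x_index[(u, p)])
                v_side.append(x_index[(v, q)])
            if q in au and p in av:  # orientation u->q, v->p
                u_side.append(x_index[(u, q)])
                v_side.append(x_index[(v, p)])
            if u_side:
                y_defs.append((u_side, v_side))
    n_y = len(y_defs)
    n_var = n_x + n_y

    # objective: maximize -> negate for milp
    c = np.zeros(n_var)
    for p, i in x_index.items():
        c[i] = -seq_coef * cand.b[p]
    c[n_x:] = -1.0 / m_min

    rows, cols, vals, lo, hi = [], [], [], [], []
    row = 0

    def add_row(coef: dict[int, float], lb: float, ub: float):
        nonlocal row
        for j, a in coef.items():
            rows.append(row)
            cols.append(j)
            vals.append(a)
        lo.append(lb)
        hi.append(ub)
        row += 1

    by_query: dict[str, list[int]] = {}
    by_target: dict[str, list[int]] = {}
    for (u, v), i in x_index.items():
        by_query.setdefault(u, []).append(i)
        by_target.setdefault(v, []).append(i)
    for idxs in by_query.values():
        add_row({i: 1.0 for i in idxs}, 0.0, 1.0)
    for idxs in by_target.values():
        add_row({i: 1.0 for i in idxs}, 0.0, 1.0)
    for k, (u_side, v_side) in enumerate(y_defs):
        coef = {n_x + k: 1.0}
        for i in u_side:
            coef[i] = coef.get(i, 0.0) - 1.0
        add_row(coef, -math.inf, 0.0)
        coef = {n_x + k: 1.0}
        for i in v_side:
            coef[i] = coef.get(i, 0.0) - 1.0
        add_row(coef, -math.inf, 0.0)

    A = csr_matrix((vals, (rows, cols)), shape=(row, n_var))
    constraints = LinearConstraint(A, np.array(lo), np.array(hi))
    integrality = np.concatenate([np.ones(n_x), np.zeros(n_y)])

    res = milp(
        c=c,
        constraints=constraints,
        integrality=integrality,
        bounds=(0.0, 1.0),
        options={"time_limit": float(time_limit), "mip_rel_gap": 0.0, "disp": False},
    )

    status_map = {0: "optimal", 1: "iteration_or_time_limit", 2: "infeasible",
                  3: "unbounded", 4: "numerical_error"}
    status = status_map.get(res.status, f"status_{res.status}")
    upper = -res.mip_dual_bound if res.mip_dual_bound is not None else math.inf

    mapping: dict[str, str] = {}
    if res.x is not None:
        for p, i in x_index.items():
            if res.x[i] > 0.5:
                mapping[p[0]] = p[1]
    return _finalize(mapping, upper, "topology", status, query, target, cand)


def align_sequence_only(cand: CandidateSet) -> AlignmentResult:
    """Maximum-weight injective assignment under normalized bit scores.

    Topology is ignored entirely.  Solved exactly via the Hungarian
    algorithm on the candidate weight matrix (forbidden pairs carry zero
    weight and are stripped afterwards, which is lossless because bit
    scores are non-negative), so the result is always provably optimal.
    """
    if cand.is_empty():
        return _empty_result("sequence_only", "no_candidates")
    qnodes = sorted(cand.allowed)
    tnodes = sorted({t for ts in cand.allowed.values() for t in ts})
    W = np.zeros((len(qnodes), len(tnodes)))
    for i, u in enumerate(qnodes):
        for j, v in enumerate(tnodes):
            if v in cand.allowed[u]:
                W[i, j] = cand.b[(u, v)]
    transpose = len(qnodes) > len(tnodes)
    rows, cols = linear_sum_assignment(W.T if transpose else W, maximize=True)
    if transpose:
        rows, cols = cols, rows
    mapping = {
        qnodes[i]: tnodes[j]
        for i, j in zip(rows, cols)
        if tnodes[j] in cand.allowed[qnodes[i]]
    }
    align = Alignment(mapping)
    score = bit_sum(align, cand)
    return AlignmentResult(
        alignment=align, score=score, upper_bound=score, gap=0.0, optimal=True,
        mode="sequence_only", e_max=cand.e_max, solver_status="optimal",
    )


def _count_feasible(cand_lists: list[list[str]]) -> float:
    count = 1.0
    for options in cand_lists:
        count *= len(options) + 1
        if count > 10 * BRUTE_FORCE_GUARD:
            break
    return count


def brute_force_align(query: nx.Graph, target: nx.Graph, cand: CandidateSet,
                      mode: str = "topology") -> AlignmentResult:
    """Exhaustive enumeration of all partial injective maps (test oracle).

    Guards against instances with more than ``BRUTE_FORCE_GUARD`` feasible
    mappings.  Ties within 1e-12 in score are broken toward the
    lexicographically smallest mapped-pair list, so the result is
    deterministic.
    """
    if mode not in ("topology", "sequence_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if cand.is_empty():
        return _empty_result(mode, "no_candidates")
    if mode == "topology" and min(query.number_of_edges(), target.number_of_edges()) == 0:
        raise NetQueryError("alignment score undefined: a network has no edges")

    qnodes = sorted(cand.allowed)
    cand_lists = [sorted(cand.allowed[u]) for u in qnodes]
    if _count_feasible(cand_lists) > BRUTE_FORCE_GUARD:
        raise NetQueryError(
            "too many feasible mappings for brute force; use align_topology"
        )

    def score_of(mapping: dict[str, str]) -> float:
        align = Alignment(dict(mapping))
        if mode == "topology":
            return total_score(align, query, target, cand)
        return bit_sum(align, cand)

    best_score = -math.inf
    best_mapping: dict[str, str] = {}
    current: dict[str, str] = {}
    used: set[str] = set()

    def recurse(k: int):
        nonlocal best_score, best_mapping
        if k == len(qnodes):
            s = score_of(current)
            if s > best_score + SCORE_TOL:
                best_score = s
                best_mapping = dict(current)
            elif abs(s - best_score) <= SCORE_TOL:
                if sorted(current.items()) < sorted(best_mapping.items()):
                    best_mapping = dict(current)
            return
        u = qnodes[k]
        recurse(k + 1)  # leave u unmapped
        for v in cand_lists[k]:
            if v in used:
                continue
            current[u] = v
            used.add(v)
            recurse(k + 1)
            used.discard(v)
            del current[u]

    recurse(0)
    align = Alignment(best_mapping)
    score = score_of(best_mapping)
    return AlignmentResult(
        alignment=align, score=score, upper_bound=score, gap=0.0, optimal=True,
        mode=mode, e_max=cand.e_max, solver_status="exhaustive",
    )
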