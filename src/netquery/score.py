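"""Alignment scoring: edge correctness and the topology-first total score.

A network alignment is a partial injective map ``a`` from query nodes to
target nodes.  Its topology score is the *edge correctness*

    t(a) = (1 / min{|E1|, |E2|}) * sum over query edges uv of w(u,a(u),v,a(v))

where the conservation indicator w is 1 exactly when both endpoints are
mapped and their images interact in the target.  The total score adds a
sequence term scaled so that it can never outweigh a single conserved edge:

    s(a) = t(a) + sum_u b(u, a(u)) / ((1 + min{|E1|, |E2|}) * min{|V1|, |V2|})

with b the normalized bit score in [0, 1].  Because the sum of b over mapped
nodes is at most min{|V1|, |V2|}, the sequence term is strictly below
1 / min{|E1|, |E2|}: maximizing s is equivalent to maximizing edge
correctness first and total bit score second.

All counts refer to the confidence-filtered networks.  Score equality is
judged at an absolute tolerance of 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from netquery.similarity import CandidateSet

#: absolute tolerance for "same score" comparisons
SCORE_TOL = 1e-12


@dataclass(frozen=True)
class Alignment:
    """A partial injective query → target node mapping."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        values = list(self.mapping.values())
        if len(values) != len(set(values)):
            raise ValueError("alignment is not injective")

    def conserved_edges(self, query: nx.Graph, target: nx.Graph) -> list[tuple[str, str]]:
        """Query edges uv with (a(u), a(v)) an edge of the target, sorted."""
        out = []
        for u, v in query.edges:
            au, av = self.mapping.get(u), self.mapping.get(v)
            if au is not None and av is not None and target.has_edge(au, av):
                out.append((u, v) if u <= v else (v, u))
        return sorted(out)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self.mapping.items())

    def __len__(self) -> int:
        return len(self.mapping)


def conservation_indicator(align: Alignment, u: str, v: str,
                           query: nx.Graph, target: nx.Graph) -> int:
    """w(u, a(u), v, a(v)): 1 iff the query edge uv maps onto a target edge."""
    if not query.has_edge(u, v):
        raise ValueError(f"({u!r}, {v!r}) is not a query edge")
    au, av = align.mapping.get(u), align.mapping.get(v)
    if au is None or av is None:
        return 0
    return 1 if target.has_edge(au, av) else 0


def _min_edges(query: nx.Graph, target: nx.Graph) -> int:
    m = min(query.number_of_edges(), target.number_of_edges())
    if m == 0:
        raise ValueError("edge correctness undefined: a network has no edges")
    return m


def edge_correctness(align: Alignment, query: nx.Graph, target: nx.Graph) -> float:
    """t(a): fraction of conserved edges relative to the smaller edge set."""
    conserved = sum(
        conservation_indicator(align, u, v, query, target) for u, v in query.edges
    )
    return conserved / _min_edges(query, target)


def sequence_coefficient(query: nx.Graph, target: nx.Graph) -> float:
    """Scale factor of the sequence term: 1 / ((1 + min|E|) * min|V|)."""
    m_min = _min_edges(query, target)
    n_min = min(query.number_of_nodes(), target.number_of_nodes())
    return 1.0 / ((1.0 + m_min) * n_min)


def bit_sum(align: Alignment, cand: CandidateSet) -> float:
    """Sum of normalized bit scores over the mapped pairs."""
    total = 0.0
    for u, v in sorted(align.mapping.items()):
        if (u, v) not in cand.b:
            raise ValueError(f"mapped pair ({u!r}, {v!r}) has no bit score in the candidate set")
        total += cand.b[(u, v)]
    return total


def total_score(align: Alignment, query: nx.Graph, target: nx.Graph,
                cand: CandidateSet) -> float:
    """s(a) = t(a) + sequence_coefficient * sum of b over mapped pairs."""
    return edge_correctness(align, query, target) + sequence_coefficient(
        query, target
    ) * bit_sum(align, cand)
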