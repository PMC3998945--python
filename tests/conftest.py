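import itertools

import networkx as nx
import numpy as np
import pytest

from netquery.netio import SimilarityTable
from netquery.score import Alignment
from netquery.similarity import build_candidates, normalize_bits
from netquery.synthetic import wnt_fixture


def make_network(edges, nodes=()):
    """Build a confidence-weighted graph from (u, v, conf) or (u, v) tuples."""
    net = nx.Graph()
    net.add_nodes_from(nodes)
    for e in edges:
        u, v, conf = e if len(e) == 3 else (*e, 1.0)
        net.add_edge(u, v, confidence=conf)
    return net


def random_instance(seed, n1_range=(4, 8), n2_range=(5, 10), max_cand=4,
                    p1=0.5, p2=0.4):
    """A random query/target pair with a random candidate table.

    Both networks are guaranteed at least one edge; every query node gets
    1..max_cand candidate targets with bit scores uniform in (10, 200) and
    E-values monotone in the bit score.
    """
    rng = np.random.default_rng(seed)
    n1 = int(rng.integers(*n1_range))
    n2 = int(rng.integers(*n2_range))
    while True:
        q = nx.gnp_random_graph(n1, p1, seed=int(rng.integers(2**31)))
        t = nx.gnp_random_graph(n2, p2, seed=int(rng.integers(2**31)))
        if q.number_of_edges() > 0 and t.number_of_edges() > 0:
            break
    q = nx.relabel_nodes(q, {i: f"q{i}" for i in q.nodes})
    t = nx.relabel_nodes(t, {i: f"t{i}" for i in t.nodes})
    nx.set_edge_attributes(q, 1.0, "confidence")
    nx.set_edge_attributes(t, 1.0, "confidence")
    table = SimilarityTable()
    for u in sorted(q.nodes):
        k = int(rng.integers(1, max_cand + 1))
        for j in rng.choice(n2, size=min(k, n2), replace=False):
            bits = float(rng.uniform(10, 200))
            table.entries[(u, f"t{j}")] = (10 ** (-bits / 5), bits)
    return q, t, normalize_bits(table)


def enumerate_alignments(cand):
    """Yield every partial injective mapping consistent with a candidate set.

    Independent of the solver module: plain itertools enumeration over
    per-node option lists (including 'unmapped'), filtered for injectivity.
    """
    qnodes = sorted(cand.allowed)
    options = [[None] + sorted(cand.allowed[u]) for u in qnodes]
    for choice in itertools.product(*options):
        chosen = [c for c in choice if c is not None]
        if len(chosen) != len(set(chosen)):
            continue
        yield Alignment({u: v for u, v in zip(qnodes, choice) if v is not None})


@pytest.fixture(scope="session")
def wnt():
    net, table = wnt_fixture()
    return net, normalize_bits(table)


@pytest.fixture
def wnt_candidates(wnt):
    _, table = wnt
    return build_candidates(table, 0.0)
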