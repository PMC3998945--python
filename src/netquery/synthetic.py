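"""Synthetic benchmark instances with planted ground truth, plus the Wnt fixture.

``generate_planted`` builds a correlated query/target network pair: the
query is an Erdős–Rényi random graph embedded into a larger target under a
known injective mapping, with a fraction of the embedded edges deleted
(rewired away) and random background edges added among the remaining
target node pairs.  A matched similarity table gives every true pair the
top bit score (optionally perturbed by Gaussian noise) and a configurable
number of lower-scoring decoy candidates per query node, so both the
candidate restriction and the tiebreaking machinery are exercised.

E-values are derived from bit scores by the fixed monotone map
``E = 10 ** (-bits / 5)``.  The map is arbitrary — real E-values depend on
database size and alignment statistics — but it is order-consistent with
bit score and spreads synthetic pairs across the default cutoff ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np

from netquery.netio import SimilarityTable, read_network

#: base raw bit score assigned to a true planted pair before noise
TRUE_PAIR_BITS = 100.0


@dataclass(frozen=True)
class PlantedParams:
    """Generator settings for a planted-alignment instance.

    n_query, n_target
        node counts; the query is embedded into the target (n_query <= n_target).
    edge_prob
        Erdős–Rényi edge probability, used for both the query graph and the
        background edges of the target.
    rewire_rate
        probability that an embedded copy of a query edge is deleted from
        the target, i.e. the fraction of interactions lost between species.
    decoys_per_node
        number of random lower-scoring candidate targets per query node.
    bit_noise
        relative Gaussian noise on true-pair bit scores.
    inflated_decoy_rate
        probability that a decoy outscores the true pair, emulating a
        sequence-wise closer but topologically wrong homolog.
    """

    n_query: int = 8
    n_target: int = 20
    edge_prob: float = 0.3
    rewire_rate: float = 0.1
    decoys_per_node: int = 3
    bit_noise: float = 0.1
    inflated_decoy_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.n_query <= self.n_target:
            raise ValueError("need 1 <= n_query <= n_target")
        for name in ("edge_prob", "rewire_rate", "inflated_decoy_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.decoys_per_node < 0 or self.bit_noise < 0:
            raise ValueError("decoys_per_node and bit_noise must be non-negative")


@dataclass
class PlantedInstance:
    """A generated query/target pair with known ground-truth alignment."""

    query: nx.Graph
    target: nx.Graph
    truth: dict[str, str]
    similarity: SimilarityTable
    params: PlantedParams = field(default_factory=PlantedParams)


def _evalue(bits: float) -> float:
    return 10.0 ** (-bits / 5.0)


def generate_planted(params: PlantedParams) -> PlantedInstance:
    """Generate a reproducible planted-alignment instance.

    With ``rewire_rate=0``, ``bit_noise=0`` and no decoys the planted
    mapping is the unique optimum at every cutoff; increasing any of the
    three degrades the signal in a controlled way.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    width = max(2, len(str(params.n_target - 1)))
    qnames = [f"q{i:0{width}d}" for i in range(params.n_query)]
    tnames = [f"t{i:0{width}d}" for i in range(params.n_target)]

    # query: ER random graph, regenerated until it has at least one edge
    query = nx.Graph()
    query.add_nodes_from(qnames)
    while query.number_of_edges() == 0:
        for i in range(params.n_query):
            for j in range(i + 1, params.n_query):
                if rng.random() < params.edge_prob:
                    query.add_edge(qnames[i], qnames[j], confidence=1.0)

    # embed under a random injection; delete embedded edges at rewire_rate
    image = rng.choice(params.n_target, size=params.n_query, replace=False)
    truth = {qnames[i]: tnames[image[i]] for i in range(params.n_query)}
    image_set = set(truth.values())
    target = nx.Graph()
    target.add_nodes_from(tnames)
    for u, v in sorted(tuple(sorted(e)) for e in query.edges):
        if rng.random() >= params.rewire_rate:
            target.add_edge(truth[u], truth[v], confidence=round(rng.uniform(0.5, 1.0), 3))

    # background edges among pairs not both truth-images
    for i in range(params.n_target):
        for j in range(i + 1, params.n_target):
            a, b = tnames[i], tnames[j]
            if a in image_set and b in image_set:
                continue
            if rng.random() < params.edge_prob:
                target.add_edge(a, b, confidence=round(rng.uniform(0.5, 1.0), 3))

    # similarity: true pair on top, decoys below (or above when inflated)
    table = SimilarityTable()
    for u in qnames:
        bits = TRUE_PAIR_BITS * max(0.01, 1.0 + params.bit_noise * rng.standard_normal())
        table.entries[(u, truth[u])] = (_evalue(bits), round(bits, 3))
        others = [t for t in tnames if t != truth[u]]
        k = min(params.decoys_per_node, len(others))
        decoys = rng.choice(len(others), size=k, replace=False)
        for d in decoys:
            if rng.random() < params.inflated_decoy_rate:
                dbits = TRUE_PAIR_BITS * rng.uniform(1.3, 1.6)
            else:
                dbits = TRUE_PAIR_BITS * rng.uniform(0.2, 0.7)
            table.entries[(u, others[d])] = (_evalue(dbits), round(dbits, 3))
    return PlantedInstance(query=query, target=target, truth=truth,
                           similarity=table, params=params)


def wnt_fixture() -> tuple[nx.Graph, SimilarityTable]:
    """The packaged Wnt-pathway query network and an identity similarity table.

    Returns the 11-protein, 17-interaction Wnt signaling query network
    (WNT1, A2MR, FZD1, DVL1, AXIN1, GSK3B, CTNNB1, APC, TCF7, TLE1, MYC)
    together with a similarity table pairing each protein with itself at
    E-value 0 and raw bit score 100, for self-alignment sanity checks.

    The 11 proteins and the 17-edge count are fixed by the pathway
    description; the specific edge list is a reconstruction of the
    described interactions (see the packaged data file), so downstream
    analyses should rely on the counts and member set, not on individual
    reconstructed edges.
    """
    ref = resources.files("netquery.data").joinpath("wnt_query.txt")
    with resources.as_file(ref) as path:
        net = read_network(path, format="edgelist")
    table = SimilarityTable(
        entries={(p, p): (0.0, TRUE_PAIR_BITS) for p in net.nodes}
    )
    return net, table
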