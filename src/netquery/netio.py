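"""Reading and writing of PPI network and similarity file formats.

Networks are represented as :class:`networkx.Graph` objects: undirected and
simple, with a ``confidence`` attribute in [0, 1] on every edge and an
optional ``description`` attribute on nodes.  Four text formats are
supported, with structural autodetection:

``edgelist``
    2-3 whitespace-separated columns; the optional third column is a
    confidence value.  Lines starting with ``#`` are comments.  A line with
    a single token declares an isolated node.
``sif``
    Cytoscape's simple interaction format: ``node type node [node ...]``.
    Carries no confidence; edges default to 1.0.
``mitab``
    IntAct's PSI-MI tab format, >= 15 tab-separated columns.  Columns 1-2
    are interactor identifiers (database prefix stripped); column 15 is
    scanned for a ``score:x`` confidence.
``string``
    STRING's protein-links text format: a header line plus rows of two
    identifiers and an integer combined score in 0-999, normalized to
    [0, 1] by division by 1000.

Node identifiers are case-sensitive exact strings; no cross-referencing to
external databases is performed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import networkx as nx

from netquery.errors import FormatError

logger = logging.getLogger(__name__)

FORMATS = ("edgelist", "sif", "mitab", "string")

#: header column names that identify STRING protein-links files
_STRING_HEADER_TOKENS = {"combined_score", "protein1", "protein2"}


@dataclass
class SimilarityTable:
    """Sparse table of pairwise sequence-alignment statistics.

    ``entries`` maps an ordered (query id, target id) pair to its
    ``(evalue, bits_raw)``; ``bits_norm`` holds normalized bit scores in
    [0, 1] once :func:`netquery.similarity.normalize_bits` has run.
    """

    entries: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    bits_norm: dict[tuple[str, str], float] | None = None

    def evalue(self, u: str, v: str) -> float:
        return self.entries[(u, v)][0]

    def bits_raw(self, u: str, v: str) -> float:
        return self.entries[(u, v)][1]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.entries


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _is_integer(token: str) -> bool:
    try:
        int(token)
    except ValueError:
        return False
    return True


def _content_lines(path):
    """Yield (1-based line number, stripped line) skipping blanks and # comments."""
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield i, line


def detect_format(path) -> str:
    """Detect the network file format from structure, not the extension.

    Returns one of ``edgelist``, ``sif``, ``mitab``, ``string``.  Raises
    :class:`FormatError` naming the first unclassifiable line.
    """
    lines = []
    for i, line in _content_lines(path):
        lines.append((i, line))
        if len(lines) >= 50:
            break
    if not lines:
        raise FormatError("empty file (no content lines)", path=path)

    first_no, first = lines[0]
    # MITAB: >= 15 tab-separated columns on every sampled line
    if all(len(line.split("\t")) >= 15 for _, line in lines):
        return "mitab"
    # STRING: recognizable header line
    header_tokens = set(first.replace("\t", " ").split())
    if header_tokens & _STRING_HEADER_TOKENS:
        return "string"

    data = lines[1:] if not _is_number(first.split()[-1]) and len(lines) > 1 else lines
    ncols = [len(line.split()) for _, line in data]
    if all(n >= 3 for n in ncols):
        cols = [line.split() for _, line in data]
        # SIF: "node type node [node ...]" — interaction type and trailing
        # node(s) are non-numeric, unlike a confidence or score column
        if all(not _is_number(c[1]) and not _is_number(c[-1]) for c in cols):
            return "sif"
        if all(len(c) == 3 and _is_integer(c[2]) for c in cols):
            return "string"  # integer combined scores, headerless
        if all(len(c) == 3 and _is_number(c[2]) for c in cols):
            return "edgelist"
    if all(1 <= n <= 3 for n in ncols):
        if all(len(line.split()) != 3 or _is_number(line.split()[2]) for _, line in data):
            return "edgelist"
    bad_no, bad = next(
        ((i, l) for i, l in lines if len(l.split()) not in (1, 2, 3)), lines[0]
    )
    raise FormatError(f"unknown format, offending line: {bad!r}", path=path, line=bad_no)


def _add_edge(net: nx.Graph, u: str, v: str, conf: float, path, line: int) -> None:
    if not 0.0 <= conf <= 1.0:
        raise FormatError(f"confidence {conf} outside [0, 1]", path=path, line=line)
    if u == v:
        logger.warning("%s:%d: dropping self-loop on %r", path, line, u)
        net.add_node(u)
        return
    if net.has_edge(u, v):
        # duplicate edges keep the maximum confidence
        conf = max(conf, net.edges[u, v]["confidence"])
    net.add_edge(u, v, confidence=conf)


def _read_edgelist(path) -> nx.Graph:
    net = nx.Graph()
    for i, line in _content_lines(path):
        cols = line.split()
        if len(cols) == 1:
            net.add_node(cols[0])
        elif len(cols) == 2:
            _add_edge(net, cols[0], cols[1], 1.0, path, i)
        elif len(cols) == 3:
            try:
                conf = float(cols[2])
            except ValueError:
                raise FormatError(
                    f"third column {cols[2]!r} is not a confidence", path=path, line=i
                ) from None
            _add_edge(net, cols[0], cols[1], conf, path, i)
        else:
            raise FormatError(f"expected 1-3 columns, got {len(cols)}", path=path, line=i)
    return net


def _read_sif(path) -> nx.Graph:
    net = nx.Graph()
    for i, line in _content_lines(path):
        cols = line.split()
        if len(cols) == 1:
            net.add_node(cols[0])
        elif len(cols) >= 3:
            # "source type target [target ...]" — one edge per trailing target
            for v in cols[2:]:
                _add_edge(net, cols[0], v, 1.0, path, i)
        else:
            raise FormatError("SIF line needs 1 or >= 3 columns", path=path, line=i)
    return net


def _strip_db_prefix(ident: str) -> str:
    return ident.split(":", 1)[1] if ":" in ident else ident


def _read_mitab(path) -> nx.Graph:
    net = nx.Graph()
    for i, line in _content_lines(path):
        cols = line.split("\t")
        if len(cols) < 15:
            raise FormatError(f"MITAB line has {len(cols)} < 15 columns", path=path, line=i)
        u, v = _strip_db_prefix(cols[0]), _strip_db_prefix(cols[1])
        conf = 1.0
        for item in cols[14].split("|"):
            tail = item.rsplit(":", 1)[-1].strip('"')
            if _is_number(tail):
                conf = float(tail)
                break
        _add_edge(net, u, v, conf, path, i)
    return net


def _read_string(path) -> nx.Graph:
    net = nx.Graph()
    for i, line in _content_lines(path):
        cols = line.replace("\t", " ").split()
        if len(cols) != 3:
            raise FormatError(f"expected 3 columns, got {len(cols)}", path=path, line=i)
        if not _is_number(cols[2]):
            if i <= 1 or net.number_of_nodes() == 0:
                continue  # header line
            raise FormatError(f"score {cols[2]!r} is not numeric", path=path, line=i)
        _add_edge(net, cols[0], cols[1], float(cols[2]) / 1000.0, path, i)
    return net


_READERS = {
    "edgelist": _read_edgelist,
    "sif": _read_sif,
    "mitab": _read_mitab,
    "string": _read_string,
}


def read_network(path, format: str | None = None) -> nx.Graph:
    """Parse a PPI network file into a graph.

    Duplicate edges are merged keeping the maximum confidence; self-loops
    are dropped with a warning; edges without a stated confidence get 1.0.
    Raises :class:`FormatError` on malformed input or an empty graph.
    """
    fmt = format if format is not None else detect_format(path)
    if fmt not in FORMATS:
        raise FormatError(f"unknown format tag {fmt!r}", path=path)
    net = _READERS[fmt](path)
    if net.number_of_nodes() == 0:
        raise FormatError("no nodes parsed", path=path)
    return net


def filter_confidence(net: nx.Graph, c_min: float) -> nx.Graph:
    """Return a copy keeping only edges with confidence strictly above ``c_min``.

    Isolated nodes are retained; the input graph is not modified.
    """
    if not 0.0 <= c_min <= 1.0:
        raise ValueError(f"c_min must be in [0, 1], got {c_min}")
    out = nx.Graph()
    out.add_nodes_from(net.nodes(data=True))
    out.add_edges_from(
        (u, v, d) for u, v, d in net.edges(data=True) if d["confidence"] > c_min
    )
    return out


# ---------------------------------------------------------------------------
# writers

def _conf_str(c: float) -> str:
    return format(c, ".9g") if c != int(c) else f"{c:.1f}"


def _write_edgelist(net: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u in sorted(nx.isolates(net)):
            fh.write(f"{u}\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{u}\t{v}\t{_conf_str(net.edges[u, v]['confidence'])}\n")


def _write_sif(net: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u in sorted(nx.isolates(net)):
            fh.write(f"{u}\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{u} pp {v}\n")


def _write_mitab(net: nx.Graph, path) -> None:
    filler = ["-"] * 12
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges):
            conf = net.edges[u, v]["confidence"]
            cols = [f"uniprotkb:{u}", f"uniprotkb:{v}", *filler, f"score:{_conf_str(conf)}"]
            fh.write("\t".join(cols) + "\n")


def _write_string(net: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.edges):
            score = round(net.edges[u, v]["confidence"] * 1000.0)
            fh.write(f"{u} {v} {score}\n")


_WRITERS = {
    "edgelist": _write_edgelist,
    "sif": _write_sif,
    "mitab": _write_mitab,
    "string": _write_string,
}


def write_network(net: nx.Graph, path, format: str = "edgelist") -> None:
    """Write a network in one of the supported formats.

    SIF carries no confidence values; MITAB and STRING cannot represent
    isolated nodes.  Round-trips are exact for formats that can express the
    information present.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format tag {format!r}")
    _WRITERS[format](net, path)


# ---------------------------------------------------------------------------
# similarity tables

def read_similarity(path) -> SimilarityTable:
    """Read a tab-separated (query id, target id, E-value, bit score) table.

    Duplicate pairs keep the entry with the larger bit score.  E-values may
    be exactly 0 (BLAST reports 0.0 below its floating-point floor).
    """
    table = SimilarityTable()
    for i, line in _content_lines(path):
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) != 4:
            raise FormatError(f"expected 4 columns, got {len(cols)}", path=path, line=i)
        q, t = cols[0], cols[1]
        try:
            evalue, bits = float(cols[2]), float(cols[3])
        except ValueError:
            raise FormatError(f"non-numeric E-value or bit score: {line!r}", path=path, line=i) from None
        if evalue < 0:
            raise FormatError(f"negative E-value {evalue}", path=path, line=i)
        if bits < 0:
            raise FormatError(f"negative bit score {bits}", path=path, line=i)
        prev = table.entries.get((q, t))
        if prev is None or bits > prev[1]:
            table.entries[(q, t)] = (evalue, bits)
    if not table.entries:
        raise FormatError("no similarity entries parsed", path=path)
    return table


def write_similarity(table: SimilarityTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (q, t), (evalue, bits) in sorted(table.entries.items()):
            fh.write(f"{q}\t{t}\t{evalue:.6g}\t{bits:.6g}\n")


# ---------------------------------------------------------------------------
# alignment output tables

def _sorted_edge(u, v):
    return (u, v) if u <= v else (v, u)


def write_alignment_tables(result, query: nx.Graph, target: nx.Graph,
                           similarity: SimilarityTable, out_dir) -> dict[str, str]:
    """Emit the four alignment tables as TSV files in ``out_dir``.

    * ``aligned_nodes.tsv`` — query id, target id, bit score, E-value
    * ``conserved_edges.tsv`` — query edges whose endpoint images interact
    * ``unaligned_query_edges.tsv`` — the remaining query edges
    * ``unaligned_target_edges.tsv`` — target edges between aligned nodes
      whose pre-images are non-adjacent (the predicted interactions)

    Rows are sorted lexicographically; returns a name → path map.
    """
    os.makedirs(out_dir, exist_ok=True)
    mapping = result.alignment.mapping
    paths = {}

    def emit(name, header, rows):
        p = os.path.join(out_dir, name + ".tsv")
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("\t".join(header) + "\n")
            for row in sorted(rows):
                fh.write("\t".join(str(c) for c in row) + "\n")
        paths[name] = p

    emit(
        "aligned_nodes",
        ("query_id", "target_id", "bit_score", "e_value"),
        [
            (u, v, format(similarity.bits_raw(u, v), ".6g"), format(similarity.evalue(u, v), ".6g"))
            if (u, v) in similarity else (u, v, "NA", "NA")
            for u, v in mapping.items()
        ],
    )

    conserved, unaligned_q = [], []
    for u, v in query.edges:
        u, v = _sorted_edge(u, v)
        qc = _conf_str(query.edges[u, v]["confidence"])
        au, av = mapping.get(u), mapping.get(v)
        if au is not None and av is not None and target.has_edge(au, av):
            tc = _conf_str(target.edges[au, av]["confidence"])
            conserved.append((u, v, au, av, qc, tc))
        else:
            unaligned_q.append((u, v, qc))
    emit(
        "conserved_edges",
        ("query_u", "query_v", "target_u", "target_v", "query_confidence", "target_confidence"),
        conserved,
    )
    emit("unaligned_query_edges", ("query_u", "query_v", "confidence"), unaligned_q)

    inv = {v: u for u, v in mapping.items()}
    unaligned_t = []
    for x, y in target.edges:
        x, y = _sorted_edge(x, y)
        qu, qv = inv.get(x), inv.get(y)
        if qu is not None and qv is not None and not query.has_edge(qu, qv):
            unaligned_t.append((x, y, qu, qv, _conf_str(target.edges[x, y]["confidence"])))
    emit(
        "unaligned_target_edges",
        ("target_u", "target_v", "query_u", "query_v", "target_confidence"),
        unaligned_t,
    )
    return paths


def write_cytoscape(result, query: nx.Graph, target: nx.Graph, out_dir) -> dict[str, str]:
    """Emit Cytoscape-compatible files for the alignment union graph.

    The union graph lives on query node identifiers: all query edges, plus
    pre-images of matched target edges.  Edge origins are ``both`` for
    conserved interactions, ``query`` for unmatched query edges, and
    ``target`` for target interactions between aligned nodes with no query
    counterpart.  Node attributes carry the aligned target identifier.
    """
    os.makedirs(out_dir, exist_ok=True)
    mapping = result.alignment.mapping
    inv = {v: u for u, v in mapping.items()}

    edge_origin: dict[tuple[str, str], str] = {}
    for u, v in query.edges:
        u, v = _sorted_edge(u, v)
        au, av = mapping.get(u), mapping.get(v)
        conserved = au is not None and av is not None and target.has_edge(au, av)
        edge_origin[(u, v)] = "both" if conserved else "query"
    for x, y in target.edges:
        qu, qv = inv.get(x), inv.get(y)
        if qu is not None and qv is not None and not query.has_edge(qu, qv):
            edge_origin[_sorted_edge(qu, qv)] = "target"

    sif_path = os.path.join(out_dir, "alignment.sif")
    with open(sif_path, "w", encoding="utf-8") as fh:
        for u in sorted(n for n in query.nodes if query.degree(n) == 0):
            fh.write(f"{u}\n")
        for u, v in sorted(edge_origin):
            fh.write(f"{u} pp {v}\n")

    node_path = os.path.join(out_dir, "node_attributes.tsv")
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("node\taligned\ttarget_id\n")
        for u in sorted(query.nodes):
            v = mapping.get(u)
            fh.write(f"{u}\t{'yes' if v is not None else 'no'}\t{v if v is not None else 'NA'}\n")

    edge_path = os.path.join(out_dir, "edge_attributes.tsv")
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("node_u\tnode_v\torigin\n")
        for (u, v), origin in sorted(edge_origin.items()):
            fh.write(f"{u}\t{v}\t{origin}\n")

    return {"sif": sif_path, "node_attributes": node_path, "edge_attributes": edge_path}
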