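"""End-to-end query pipeline: parse, filter, normalize, sweep cutoffs, solve.

``run_pipeline`` is the offline counterpart of a two-step wrapper around an
all-against-all sequence comparison and the network aligner: the sequence
step is replaced by a required precomputed similarity table, and the
aligner is run once per E-value cutoff on the candidate pairings that
cutoff admits.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from netquery.errors import NetQueryError, PipelineError
from netquery.netio import SimilarityTable, filter_confidence, read_network, read_similarity
from netquery.score import bit_sum, edge_correctness, total_score
from netquery.similarity import build_candidates, default_cutoffs, normalize_bits
from netquery.solver import AlignmentResult, align_sequence_only, align_topology

logger = logging.getLogger(__name__)


@dataclass
class PipelineReport:
    """All per-cutoff alignment results plus input statistics and settings."""

    runs: list[AlignmentResult]
    query: nx.Graph  # confidence-filtered
    target: nx.Graph  # confidence-filtered
    similarity: SimilarityTable  # with normalized bit scores
    query_stats: dict = field(default_factory=dict)
    target_stats: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)


def _stats(before: nx.Graph, after: nx.Graph) -> dict:
    return {
        "nodes": before.number_of_nodes(),
        "edges": before.number_of_edges(),
        "nodes_filtered": after.number_of_nodes(),
        "edges_filtered": after.number_of_edges(),
    }


def run_pipeline(query_path, target_path, similarity_path, c_min: float = 0.1,
                 mode: str = "topology", cutoffs=None, time_limit: float = 300.0,
                 query_format: str | None = None, target_format: str | None = None,
                 seed: int = 0) -> PipelineReport:
    """Align a query network to a target across a ladder of E-value cutoffs.

    Edges with confidence at or below ``c_min`` are discarded first (default
    0.1); bit scores are normalized once; then one solver run per cutoff in
    ascending order.  A cutoff admitting no candidate pair produces an
    empty-alignment run, not an abort.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    if mode not in ("topology", "sequence_only"):
        raise PipelineError("settings", ValueError(f"unknown mode {mode!r}"))
    cutoffs = tuple(sorted(default_cutoffs() if cutoffs is None else cutoffs))

    try:
        query_raw = read_network(query_path, query_format)
        target_raw = read_network(target_path, target_format)
    except Exception as exc:
        raise PipelineError("parse_networks", exc) from exc
    try:
        table = read_similarity(similarity_path)
    except Exception as exc:
        raise PipelineError("parse_similarity", exc) from exc

    try:
        query = filter_confidence(query_raw, c_min)
        target = filter_confidence(target_raw, c_min)
        if mode == "topology" and min(query.number_of_edges(), target.number_of_edges()) == 0:
            raise NetQueryError(
                f"no edges left after filtering at c_min={c_min}"
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("filter_confidence", exc) from exc

    try:
        table = normalize_bits(table)
    except Exception as exc:
        raise PipelineError("normalize_bits", exc) from exc

    runs: list[AlignmentResult] = []
    for e_max in cutoffs:
        try:
            t0 = time.perf_counter()
            cand = build_candidates(table, e_max)
            if mode == "topology":
                res = align_topology(query, target, cand, time_limit=time_limit)
            else:
                res = align_sequence_only(cand)
            res.wall_time = time.perf_counter() - t0
            res.e_max = e_max
        except Exception as exc:
            raise PipelineError(f"align[e_max={e_max:g}]", exc) from exc
        logger.info(
            "e_max=%g: %d mapped pairs, score %.6f, gap %.2g (%s)",
            e_max, len(res.alignment), res.score, res.gap, res.solver_status,
        )
        runs.append(res)

    return PipelineReport(
        runs=runs, query=query, target=target, similarity=table,
        query_stats=_stats(query_raw, query),
        target_stats=_stats(target_raw, target),
        settings={
            "c_min": c_min, "mode": mode, "cutoffs": cutoffs,
            "time_limit": time_limit, "seed": seed,
        },
    )


def predicted_interactions(result: AlignmentResult, query: nx.Graph,
                           target: nx.Graph) -> pd.DataFrame:
    """Target edges between images of aligned nodes with no query counterpart.

    These are the candidate missing interactions of the query species: the
    target organism supports an interaction between the aligned partners
    that the query network does not contain.  Rows carry the target edge
    confidence and the query pre-images, sorted lexicographically.
    """
    inv = {v: u for u, v in result.alignment.mapping.items()}
    rows = []
    for x, y in target.edges:
        x, y = (x, y) if x <= y else (y, x)
        qu, qv = inv.get(x), inv.get(y)
        if qu is not None and qv is not None and not query.has_edge(qu, qv):
            rows.append((x, y, qu, qv, target.edges[x, y]["confidence"]))
    rows.sort()
    return pd.DataFrame(
        rows, columns=["target_u", "target_v", "query_u", "query_v", "confidence"]
    )


def run_summary(report: PipelineReport) -> pd.DataFrame:
    """One overview row per cutoff, recomputed from the stored alignments."""
    rows = []
    for res in report.runs:
        cand = build_candidates(report.similarity, res.e_max)
        align = res.alignment
        n_conserved = len(align.conserved_edges(report.query, report.target))
        has_edges = min(report.query.number_of_edges(), report.target.number_of_edges()) > 0
        ec = edge_correctness(align, report.query, report.target) if has_edges else float("nan")
        bsum = bit_sum(align, cand) if align.mapping else 0.0
        tscore = (
            total_score(align, report.query, report.target, cand) if has_edges else float("nan")
        )
        rows.append({
            "e_max": res.e_max,
            "mapped_nodes": len(align),
            "conserved_edges": n_conserved,
            "edge_correctness": ec,
            "bit_sum": bsum,
            "total_score": tscore,
            "score": res.score,
            "upper_bound": res.upper_bound,
            "gap": res.gap,
            "optimal": res.optimal,
            "status": res.solver_status,
            "wall_time_s": res.wall_time,
        })
    return pd.DataFrame(rows)
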