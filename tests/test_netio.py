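import networkx as nx
import pytest

from conftest import make_network
from netquery.errors import FormatError
from netquery.netio import (
    FORMATS,
    SimilarityTable,
    detect_format,
    filter_confidence,
    read_network,
    read_similarity,
    write_network,
    write_similarity,
)
from netquery.similarity import build_candidates, normalize_bits
from netquery.netio import write_alignment_tables, write_cytoscape
from netquery.score import Alignment
from netquery.solver import AlignmentResult


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestDetectFormat:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("A B\nB C\n", "edgelist"),
            ("A B 0.5\nB C 0.25\n", "edgelist"),
            ("A pp B\n", "sif"),
            ("A pp B\nB pd C D\n", "sif"),
            ("protein1 protein2 combined_score\np1 p2 172\n", "string"),
            ("p1 p2 172\np2 p3 900\n", "string"),
        ],
    )
    def test_structural_cues(self, tmp_path, text, expected):
        assert detect_format(_write(tmp_path, "net.txt", text)) == expected

    def test_mitab_column_count(self, tmp_path):
        line = "\t".join(["uniprotkb:P1", "uniprotkb:P2"] + ["-"] * 12 + ["score:0.7"])
        assert detect_format(_write(tmp_path, "net.txt", line + "\n")) == "mitab"

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(FormatError, match="empty"):
            detect_format(_write(tmp_path, "net.txt", "# only a comment\n"))

    def test_unknown_format_names_line(self, tmp_path):
        path = _write(tmp_path, "net.txt", "a 1 b 2\n")
        with pytest.raises(FormatError, match="unknown format"):
            detect_format(path)

    @pytest.mark.parametrize("fmt", FORMATS)
    def test_roundtrip_tag_identity(self, tmp_path, fmt):
        """detect_format composed with each writer is the identity on tags."""
        net = make_network([("A", "B", 0.5), ("B", "C", 0.9), ("C", "D", 0.25)])
        path = tmp_path / "out.txt"
        write_network(net, path, fmt)
        assert detect_format(path) == fmt


class TestReadNetwork:
    def test_duplicate_edges_keep_max_confidence(self, tmp_path):
        net = read_network(_write(tmp_path, "n.txt", "A B 0.5\nB A 0.9\n"))
        assert net.number_of_nodes() == 2
        assert net.number_of_edges() == 1
        assert net.edges["A", "B"]["confidence"] == 0.9

    def test_string_combined_score_normalized(self, tmp_path):
        net = read_network(_write(tmp_path, "n.txt", "p1 p2 172\n"), format="string")
        assert net.edges["p1", "p2"]["confidence"] == pytest.approx(0.172)

    def test_missing_confidence_defaults_to_one(self, tmp_path):
        net = read_network(_write(tmp_path, "n.txt", "A B\n"))
        assert net.edges["A", "B"]["confidence"] == 1.0

    def test_self_loop_dropped_with_warning(self, tmp_path, caplog):
        net = read_network(_write(tmp_path, "n.txt", "A A 0.5\nA B 0.5\n"))
        assert not net.has_edge("A", "A")
        assert net.has_edge("A", "B")
        assert any("self-loop" in r.message for r in caplog.records)

    def test_malformed_line_reports_number(self, tmp_path):
        path = _write(tmp_path, "n.txt", "A B 0.5\nA C x\n")
        with pytest.raises(FormatError, match="n.txt:2"):
            read_network(path, format="edgelist")

    def test_mitab_prefix_stripped_and_score_parsed(self, tmp_path):
        line = "\t".join(
            ["uniprotkb:P1", "uniprotkb:P2"] + ["-"] * 12 + ["intact-miscore:0.56"]
        )
        net = read_network(_write(tmp_path, "n.txt", line + "\n"), format="mitab")
        assert net.edges["P1", "P2"]["confidence"] == pytest.approx(0.56)

    @pytest.mark.parametrize("fmt", ["edgelist", "mitab", "string"])
    def test_roundtrip_preserves_network(self, tmp_path, fmt):
        """Write-then-read reproduces nodes, edges and confidences."""
        net = make_network(
            [("A", "B", 0.512), ("B", "C", 0.9), ("C", "D", 0.001), ("A", "D", 1.0)]
        )
        path = tmp_path / "rt.txt"
        write_network(net, path, fmt)
        back = read_network(path, format=fmt)
        assert set(back.nodes) == set(net.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in net.edges}
        for u, v in net.edges:
            assert back.edges[u, v]["confidence"] == pytest.approx(
                net.edges[u, v]["confidence"], abs=1e-9
            )

    def test_sif_roundtrip_topology_and_isolates(self, tmp_path):
        net = make_network([("A", "B"), ("B", "C")], nodes=["Z"])
        path = tmp_path / "rt.sif"
        write_network(net, path, "sif")
        back = read_network(path, format="sif")
        assert set(back.nodes) == {"A", "B", "C", "Z"}
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in net.edges}
        assert all(d["confidence"] == 1.0 for _, _, d in back.edges(data=True))


class TestFilterConfidence:
    def test_threshold_is_strict(self):
        net = make_network([("A", "B", 0.1), ("B", "C", 0.5)])
        out = filter_confidence(net, 0.1)
        assert out.number_of_edges() == 1
        assert out.has_edge("B", "C")

    def test_zero_threshold_keeps_positive_confidences(self):
        net = make_network([("A", "B", 0.1), ("B", "C", 0.5)])
        assert filter_confidence(net, 0.0).number_of_edges() == 2

    def test_isolated_nodes_retained_and_input_unmodified(self):
        net = make_network([("A", "B", 0.05)])
        out = filter_confidence(net, 0.1)
        assert set(out.nodes) == {"A", "B"}
        assert out.number_of_edges() == 0
        assert net.number_of_edges() == 1

    def test_idempotent(self):
        net = make_network([("A", "B", 0.3), ("B", "C", 0.7), ("C", "D", 0.05)])
        once = filter_confidence(net, 0.3)
        twice = filter_confidence(once, 0.3)
        assert nx.utils.graphs_equal(once, twice)

    def test_matches_independent_recount(self):
        import numpy as np

        rng = np.random.default_rng(7)
        edges = [(f"n{i}", f"n{j}", round(float(rng.uniform()), 3))
                 for i, j in zip(rng.integers(0, 30, 50), rng.integers(30, 60, 50))]
        net = make_network(edges)
        confs = [d["confidence"] for _, _, d in net.edges(data=True)]
        c_min = float(np.median(confs))
        expected = sum(c > c_min for c in confs)
        assert filter_confidence(net, c_min).number_of_edges() == expected

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_invalid_threshold(self, bad):
        with pytest.raises(ValueError):
            filter_confidence(make_network([("A", "B", 0.5)]), bad)


class TestSimilarityIO:
    def test_single_row(self, tmp_path):
        table = read_similarity(_write(tmp_path, "s.tsv", "q1\tt1\t1e-50\t200\n"))
        assert table.entries == {("q1", "t1"): (1e-50, 200.0)}

    def test_duplicates_keep_larger_bits(self, tmp_path):
        table = read_similarity(
            _write(tmp_path, "s.tsv", "q1\tt1\t1e-5\t100\nq1\tt1\t1e-9\t150\n")
        )
        assert table.bits_raw("q1", "t1") == 150.0

    @pytest.mark.parametrize("row", ["q\tt\t-1\t100", "q\tt\t1e-5\t-3"])
    def test_negative_values_rejected_with_line(self, tmp_path, row):
        path = _write(tmp_path, "s.tsv", "a\tb\t0\t10\n" + row + "\n")
        with pytest.raises(FormatError, match="s.tsv:2"):
            read_similarity(path)

    def test_write_read_roundtrip(self, tmp_path):
        table = SimilarityTable(
            entries={("q1", "t1"): (0.0, 519.0), ("q1", "t2"): (6e-38, 150.0),
                     ("q2", "t1"): (1.5, 22.5)}
        )
        path = tmp_path / "rt.tsv"
        write_similarity(table, path)
        back = read_similarity(path)
        assert back.entries == table.entries


def _self_result(net, table, e_max=0.0):
    cand = build_candidates(table, e_max)
    align = Alignment({u: u for u in net.nodes})
    return AlignmentResult(
        alignment=align, score=0.0, upper_bound=0.0, gap=0.0, optimal=True,
        mode="topology", e_max=e_max,
    ), cand


class TestAlignmentTables:
    def test_wnt_self_alignment_tables(self, tmp_path, wnt):
        net, table = wnt
        result, _ = _self_result(net, table)
        paths = write_alignment_tables(result, net, net, table, tmp_path)
        conserved = (tmp_path / "conserved_edges.tsv").read_text().splitlines()
        unaligned = (tmp_path / "unaligned_query_edges.tsv").read_text().splitlines()
        assert len(conserved) - 1 == 17
        assert len(unaligned) - 1 == 0
        assert set(paths) == {
            "aligned_nodes", "conserved_edges", "unaligned_query_edges",
            "unaligned_target_edges",
        }

    def test_empty_alignment_lists_every_query_edge(self, tmp_path, wnt):
        net, table = wnt
        result = AlignmentResult(
            alignment=Alignment({}), score=0.0, upper_bound=0.0, gap=0.0,
            optimal=True, mode="topology",
        )
        write_alignment_tables(result, net, net, table, tmp_path)
        aligned = (tmp_path / "aligned_nodes.tsv").read_text().splitlines()
        unaligned = (tmp_path / "unaligned_query_edges.tsv").read_text().splitlines()
        assert len(aligned) - 1 == 0
        assert len(unaligned) - 1 == 17

    def test_edge_tables_partition_query_edges(self, tmp_path):
        """conserved + unaligned_query tile the query edge set exactly."""
        from conftest import random_instance
        from netquery.solver import align_topology

        q, t, table = random_instance(11)
        cand = build_candidates(table, 100.0)
        res = align_topology(q, t, cand)
        write_alignment_tables(res, q, t, table, tmp_path)

        def rows(name, k):
            lines = (tmp_path / f"{name}.tsv").read_text().splitlines()[1:]
            return {tuple(sorted(l.split("\t")[:k])) for l in lines}

        conserved = rows("conserved_edges", 2)
        unaligned = rows("unaligned_query_edges", 2)
        all_edges = {tuple(sorted(e)) for e in q.edges}
        assert conserved | unaligned == all_edges
        assert conserved & unaligned == set()
        # brute-force reclassification of every query edge
        m = res.alignment.mapping
        expect_conserved = {
            tuple(sorted((u, v))) for u, v in q.edges
            if u in m and v in m and t.has_edge(m[u], m[v])
        }
        assert conserved == expect_conserved


class TestCytoscape:
    def test_self_alignment_all_edges_both(self, tmp_path, wnt):
        net, table = wnt
        result, _ = _self_result(net, table)
        write_cytoscape(result, net, net, tmp_path)
        lines = (tmp_path / "edge_attributes.tsv").read_text().splitlines()[1:]
        assert lines and all(l.split("\t")[2] == "both" for l in lines)

    def test_no_conserved_edges_no_both(self, tmp_path, wnt):
        net, table = wnt
        result = AlignmentResult(
            alignment=Alignment({}), score=0.0, upper_bound=0.0, gap=0.0,
            optimal=True, mode="topology",
        )
        write_cytoscape(result, net, net, tmp_path)
        lines = (tmp_path / "edge_attributes.tsv").read_text().splitlines()[1:]
        assert all(l.split("\t")[2] != "both" for l in lines)

    def test_sif_reread_reproduces_union(self, tmp_path):
        from conftest import random_instance
        from netquery.solver import align_topology

        q, t, table = random_instance(5)
        cand = build_candidates(table, 100.0)
        res = align_topology(q, t, cand)
        write_cytoscape(res, q, t, tmp_path)
        back = read_network(tmp_path / "alignment.sif", format="sif")
        m = res.alignment.mapping
        inv = {v: u for u, v in m.items()}
        union = {tuple(sorted(e)) for e in q.edges}
        for x, y in t.edges:
            if x in inv and y in inv and not q.has_edge(inv[x], inv[y]):
                union.add(tuple(sorted((inv[x], inv[y]))))
        assert {tuple(sorted(e)) for e in back.edges} == union
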