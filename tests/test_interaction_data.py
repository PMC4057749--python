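"""Parsing, normalization and round-trip behavior of interaction records."""

import logging

import networkx as nx
import pytest

from hetnet import (
    EdgeTableFormatError,
    Family,
    HetNetGraph,
    ReceptorProtomer,
    family_summary,
    normalize_graph,
    parse_family,
    read_edge_table,
    read_graph,
    read_node_attrs,
    write_graph,
)
from hetnet.interaction_data import RawEdgeRecord


class TestReadEdgeTable:
    def test_tsv_rows_echoed_in_order(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("DRD2\tAA2AR\nDRD2\tDRD2\nAA2AR\tDRD2\n")
        records = read_edge_table(path)
        assert [(r.a, r.b) for r in records] == [
            ("DRD2", "AA2AR"), ("DRD2", "DRD2"), ("AA2AR", "DRD2")]

    def test_header_attribute_columns_captured_by_name(self, tmp_path):
        path = tmp_path / "edges.csv"
        path.write_text(
            "protomer_a,protomer_b,methods,n_publications,controversial\n"
            "DRD2,AA2AR,BRET;coIP,3,false\n")
        (rec,) = read_edge_table(path)
        assert rec.attributes == {"methods": "BRET;coIP",
                                  "n_publications": "3",
                                  "controversial": "false"}

    def test_sif_multi_target_row_expands(self, tmp_path):
        path = tmp_path / "net.sif"
        path.write_text("DRD2 pp AA2AR NTR1\n")
        records = read_edge_table(path)
        assert [(r.a, r.b) for r in records] == [("DRD2", "AA2AR"), ("DRD2", "NTR1")]

    def test_sif_single_token_is_isolated_node(self, tmp_path):
        path = tmp_path / "net.sif"
        path.write_text("TSHR\n")
        (rec,) = read_edge_table(path)
        assert rec.a == "TSHR" and rec.b is None

    def test_sif_missing_target_names_line(self, tmp_path):
        path = tmp_path / "net.sif"
        path.write_text("DRD2 pp AA2AR\nDRD2 pp\n")
        with pytest.raises(EdgeTableFormatError, match=":2"):
            read_edge_table(path)

    def test_short_row_names_line(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("protomer_a\tprotomer_b\nDRD2\t\n")
        with pytest.raises(EdgeTableFormatError, match=":2"):
            read_edge_table(path)

    def test_empty_file_warns_and_returns_nothing(self, tmp_path, caplog):
        path = tmp_path / "edges.tsv"
        path.write_text("")
        with caplog.at_level(logging.WARNING, logger="hetnet"):
            assert read_edge_table(path) == []
        assert "no records" in caplog.text

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_edge_table(tmp_path / "nope.tsv")


class TestNormalizeGraph:
    def test_dedup_and_self_loop_removal(self):
        records = [RawEdgeRecord("A", "B"), RawEdgeRecord("B", "A"),
                   RawEdgeRecord("A", "A")]
        g = normalize_graph(records)
        assert set(g.nx.nodes) == {"A", "B"}
        assert g.n_edges == 1
        assert g.normalization.n_self_loops_dropped == 1
        assert g.normalization.n_duplicates_merged == 1

    def test_duplicate_merge_unions_methods_keeps_max_publications(self):
        records = [
            RawEdgeRecord("A", "B", {"methods": "BRET", "n_publications": "2"}),
            RawEdgeRecord("B", "A", {"methods": "coIP;FRET",
                                     "n_publications": "1",
                                     "controversial": "true"}),
        ]
        g = normalize_graph(records)
        (edge,) = g.heteromer_edges()
        assert edge.methods == frozenset({"BRET", "coIP", "FRET"})
        assert edge.n_publications == 2  # max, never summed
        assert edge.controversial is True

    def test_self_loop_only_id_kept_as_isolated_node(self):
        # a homodimer-only record contributes its protomer, not an edge
        g = normalize_graph([RawEdgeRecord("C", "C")])
        assert set(g.nx.nodes) == {"C"}
        assert g.n_edges == 0

    def test_ids_uppercased(self):
        g = normalize_graph([RawEdgeRecord("mGluR5", "drd2")])
        assert set(g.nx.nodes) == {"MGLUR5", "DRD2"}

    def test_attribute_only_ids_become_isolated_nodes(self):
        attrs = {f"X{i}": ReceptorProtomer(f"X{i}", Family.F1) for i in range(23)}
        g = normalize_graph([RawEdgeRecord("A", "B")], node_attrs=attrs)
        assert g.n_nodes == 25
        assert sum(1 for n in g.nx.nodes if g.nx.degree(n) == 0) == 23

    def test_idempotent(self):
        records = [RawEdgeRecord("A", "B"), RawEdgeRecord("B", "C"),
                   RawEdgeRecord("A", "B")]
        g1 = normalize_graph(records)
        g2 = normalize_graph([RawEdgeRecord(e.a, e.b) for e in g1.heteromer_edges()])
        assert nx.utils.graphs_equal(
            nx.Graph(g1.nx.edges), nx.Graph(g2.nx.edges))

    def test_edge_count_bounded_by_records_node_count_exact(self):
        records = [RawEdgeRecord("A", "B"), RawEdgeRecord("B", "A"),
                   RawEdgeRecord("C", "C"), RawEdgeRecord("B", "C")]
        attrs = {"Z": ReceptorProtomer("Z")}
        g = normalize_graph(records, node_attrs=attrs)
        assert g.n_edges <= len(records)
        assert g.n_nodes == 4  # A, B, C plus attribute-only Z


class TestFamilySummary:
    def test_single_family_triangle(self):
        g = HetNetGraph.from_edges([("A", "B"), ("B", "C"), ("A", "C")],
                                   families={"A": "F1", "B": "F1", "C": "F1"})
        summary = family_summary(g)
        assert summary.edge_counts["F1"] == 3
        assert summary.edge_counts["interfamily"] == 0

    def test_bipartite_star_is_all_interfamily(self):
        g = HetNetGraph.from_edges([("H", "L1"), ("H", "L2"), ("H", "L3")],
                                   families={"H": "F1", "L1": "F2",
                                             "L2": "F2", "L3": "F2"})
        summary = family_summary(g)
        assert summary.edge_counts["interfamily"] == 3

    def test_partitions_sum_to_n_and_e(self, hetnet_like_graph):
        summary = family_summary(hetnet_like_graph)
        assert summary.total_nodes == hetnet_like_graph.n_nodes
        assert summary.total_edges == hetnet_like_graph.n_edges

    def test_class_aliases_map_to_families(self):
        assert parse_family("A") is Family.F1
        assert parse_family("f2") is Family.F2
        assert parse_family("3") is Family.F3
        assert parse_family(None) is Family.UNKNOWN
        with pytest.raises(ValueError):
            parse_family("F9")


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["json", "tsv", "sif"])
    def test_triangle_round_trip(self, tmp_path, dialect):
        g = HetNetGraph.from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        path = tmp_path / f"g.{dialect}"
        write_graph(g, path, dialect=dialect)
        back = read_graph(path, dialect=dialect)
        assert set(back.nx.nodes) == set(g.nx.nodes)
        assert set(map(frozenset, back.nx.edges)) == set(map(frozenset, g.nx.edges))

    def test_json_round_trip_preserves_attributes(self, tmp_path):
        records = [RawEdgeRecord("A", "B", {"methods": "BRET;PLA",
                                            "n_publications": "4",
                                            "controversial": "true"})]
        attrs = {"A": ReceptorProtomer("A", Family.F1, "dopamine D2"),
                 "B": ReceptorProtomer("B", Family.F3),
                 "C": ReceptorProtomer("C", Family.F2)}
        g = normalize_graph(records, node_attrs=attrs)
        path = tmp_path / "g.json"
        write_graph(g, path, dialect="json")
        back = read_graph(path)
        assert back.heteromer_edges() == g.heteromer_edges()
        assert back.protomer("A").family is Family.F1
        assert back.protomer("A").display_name == "dopamine D2"
        assert back.protomer("C").family is Family.F2  # isolated node kept

    def test_tsv_round_trip_with_attr_table(self, tmp_path):
        g = normalize_graph(
            [RawEdgeRecord("A", "B")],
            node_attrs={"A": ReceptorProtomer("A", Family.F1),
                        "Z": ReceptorProtomer("Z", Family.F2)})
        epath, apath = tmp_path / "e.tsv", tmp_path / "a.tsv"
        write_graph(g, epath, dialect="tsv", attrs_path=apath)
        back = read_graph(epath, attrs_path=apath)
        assert set(back.nx.nodes) == {"A", "B", "Z"}
        assert back.protomer("Z").family is Family.F2

    def test_sif_keeps_isolated_nodes(self, tmp_path):
        g = HetNetGraph.from_edges([("A", "B")], nodes=["LONER"])
        path = tmp_path / "g.sif"
        write_graph(g, path, dialect="sif")
        back = read_graph(path)
        assert "LONER" in back.nx

    def test_empty_graph_writes_header_only_tsv(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_graph(HetNetGraph(), path, dialect="tsv")
        assert path.read_text().startswith("protomer_a\tprotomer_b")
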