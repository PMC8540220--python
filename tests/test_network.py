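import numpy as np
import pandas as pd
import pytest

import gi_refine as gr
from gi_refine.exceptions import ConfigurationError, FormatError
from gi_refine.network import from_edges

import oracles


def chain(*names, directed=False):
    return from_edges(zip(names, names[1:]), directed=directed)


class TestLoadNetwork:
    def test_undirected_canonicalizes_reversed_duplicates(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nB\tA\n")
        net = gr.load_network(p, directed=False)
        assert net.n_edges() == 1

    def test_directed_keeps_both_orientations(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nB\tA\n")
        net = gr.load_network(p, directed=True)
        assert net.n_edges() == 2

    def test_self_loop_dropped(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tA\nA\tB\n")
        net = gr.load_network(p, directed=False)
        assert net.n_edges() == 1
        assert "A" in net.nodes

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nJUSTONE\n")
        with pytest.raises(FormatError, match=":2"):
            gr.load_network(p, directed=False)

    def test_header_line_skipped(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("source\ttarget\nA\tB\n")
        net = gr.load_network(p, directed=False)
        assert net.n_edges() == 1


class TestWithinDistance:
    def test_chain_true_at_two_false_at_one(self):
        net = chain("A", "x", "C")
        assert gr.within_distance(net, "A", {"C"}, 2)
        assert not gr.within_distance(net, "A", {"C"}, 1)

    def test_directed_either_vs_forward(self):
        net = from_edges([("A", "B")], directed=True)
        assert gr.within_distance(net, "B", {"A"}, 1, "either")
        assert not gr.within_distance(net, "B", {"A"}, 1, "forward")
        assert gr.within_distance(net, "B", {"A"}, 1, "ignore")

    def test_self_target_excluded(self):
        net = chain("A", "B")
        assert not gr.within_distance(net, "A", {"A"}, 2)

    def test_missing_source_is_false(self):
        net = chain("A", "B")
        assert not gr.within_distance(net, "ZZ", {"A"}, 1)

    def test_ignore_mode_allows_mixed_orientation_paths(self):
        # A -> w <- C : no consistent directed path, but an undirected one
        net = from_edges([("A", "w"), ("C", "w")], directed=True)
        assert gr.within_distance(net, "A", {"C"}, 2, "ignore")
        assert not gr.within_distance(net, "A", {"C"}, 2, "either")

    @pytest.mark.parametrize("directed", [False, True])
    @pytest.mark.parametrize("mode", ["ignore", "either", "forward"])
    def test_agrees_with_adjacency_power_oracle(self, directed, mode):
        rng = np.random.default_rng(42)
        for _ in range(15):
            nodes, edges = oracles.random_graph(rng, directed=directed)
            net = from_edges(edges, directed=directed, nodes=nodes)
            for k in (1, 2):
                reach, idx = oracles.reach_within(nodes, edges, directed, k, mode)
                for _ in range(10):
                    s, t = rng.choice(nodes, size=2, replace=False)
                    got = gr.within_distance(net, s, {t}, k, mode)
                    assert got == bool(reach[idx[s], idx[t]]), (s, t, k, mode, edges)


class TestRefine:
    def test_isolated_sp_removed_connected_kept(self):
        net = from_edges([("A", "B")], nodes=["A", "B", "C"])
        res = gr.refine({"A", "B", "C"}, net, 1)
        assert res.retained_sps == {"A", "B"}
        assert res.removed_sps == {"C"}

    def test_mutually_distant_sps_all_removed(self):
        net = from_edges([("A", "x1"), ("x1", "x2"), ("x2", "B"), ("C", "y")])
        res = gr.refine({"A", "B", "C"}, net, 2)
        assert res.retained_sps == frozenset()

    def test_clique_fully_retained_at_both_distances(self):
        sps = {"A", "B", "C", "D"}
        edges = [(u, v) for u in sps for v in sps if u < v]
        net = from_edges(edges)
        for k in (1, 2):
            assert gr.refine(sps, net, k).retained_sps == sps

    def test_single_sp_skipped(self):
        net = chain("A", "B")
        res = gr.refine({"A"}, net, 1)
        assert res.skipped

    def test_input_order_invariance(self):
        rng = np.random.default_rng(9)
        nodes, edges = oracles.random_graph(rng, n_nodes=20)
        net = from_edges(edges, nodes=nodes)
        sps = list(rng.choice(nodes, 8, replace=False))
        a = gr.refine(sps, net, 2)
        b = gr.refine(sps[::-1], net, 2)
        assert a.retained_sps == b.retained_sps

    def test_single_pass_evaluates_against_initial_set(self):
        # Directed A -> B in forward mode: A sees B, B sees nobody.  The
        # single pass keeps A (B was in the *initial* set); iterating to a
        # fixed point removes A too once B is gone.
        net = from_edges([("A", "B")], directed=True)
        single = gr.refine({"A", "B"}, net, 1, direction_mode="forward")
        assert single.retained_sps == {"A"}
        iterated = gr.refine({"A", "B"}, net, 1, direction_mode="forward", fixed_point=True)
        assert iterated.retained_sps == frozenset()

    def test_single_pass_and_fixed_point_agree_on_undirected(self):
        # Undirected within-k is symmetric, so removal never cascades.
        rng = np.random.default_rng(13)
        for _ in range(10):
            nodes, edges = oracles.random_graph(rng)
            net = from_edges(edges, nodes=nodes)
            sps = set(rng.choice(nodes, min(6, len(nodes)), replace=False))
            for k in (1, 2):
                a = gr.refine(sps, net, k)
                b = gr.refine(sps, net, k, fixed_point=True)
                assert a.retained_sps == b.retained_sps

    def test_nesting_rp1_within_rp2_within_initial(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            directed = bool(rng.integers(2))
            nodes, edges = oracles.random_graph(rng, directed=directed)
            net = from_edges(edges, directed=directed, nodes=nodes)
            n_sp = int(rng.integers(2, min(8, len(nodes)) + 1))
            sps = set(rng.choice(nodes, n_sp, replace=False))
            r1 = gr.refine(sps, net, 1).retained_sps
            r2 = gr.refine(sps, net, 2).retained_sps
            assert r1 <= r2 <= frozenset(sps)


class TestMapSPs:
    def test_restriction_to_network_nodes(self, small_gi, small_screen):
        mapped = gr.map_sps(small_gi, small_screen.network)
        nodes = small_screen.network.nodes
        for q, m in mapped.items():
            assert m["initial"] <= nodes

    def test_single_mapped_sp_flagged_skipped(self):
        from gi_refine.screen import GITable
        from gi_refine.io import GI_TABLE_COLUMNS

        rec = pd.DataFrame(
            [
                ["Q", "K1", "sensitive", -3.0, 0.001, 0.01, 5, 50, 0, 0],
                ["Q", "KOFF", "sensitive", -3.0, 0.001, 0.01, 5, 50, 0, 0],
            ],
            columns=GI_TABLE_COLUMNS,
        )
        table = GITable(records=rec, m_tests=2)
        net = chain("K1", "K2")
        mapped = gr.map_sps(table, net)
        assert mapped["Q"]["initial"] == {"K1"}
        assert mapped["Q"]["skipped"]
        assert mapped["Q"]["n_unmapped"] == 1

    def test_self_gi_participates_unless_excluded(self):
        from gi_refine.screen import GITable
        from gi_refine.io import GI_TABLE_COLUMNS

        rec = pd.DataFrame(
            [
                ["Q", "Q", "sensitive", -3.0, 0.001, 0.01, 5, 50, 0, 0],
                ["Q", "K1", "sensitive", -3.0, 0.001, 0.01, 5, 50, 0, 0],
            ],
            columns=GI_TABLE_COLUMNS,
        )
        table = GITable(records=rec, m_tests=2)
        net = chain("Q", "K1")
        assert gr.map_sps(table, net)["Q"]["initial"] == {"Q", "K1"}
        assert gr.map_sps(table, net, exclude_self=True)["Q"]["initial"] == {"K1"}


class TestSPN:
    def _table(self, rows):
        from gi_refine.screen import GITable
        from gi_refine.io import GI_TABLE_COLUMNS

        rec = pd.DataFrame(rows, columns=GI_TABLE_COLUMNS)
        return GITable(records=rec, m_tests=len(rows))

    def test_distance_two_connector(self):
        net = chain("A", "x", "C")
        res = gr.refine({"A", "C"}, net, 2)
        spn = gr.build_spn(res, net)
        assert set(spn.sp_nodes) == {"A", "C"}
        assert spn.connector_nodes == {"x"}
        assert set(spn.edges) == {("A", "x"), ("C", "x")}

    def test_distance_one_has_no_connectors(self):
        net = from_edges([("A", "B")])
        res = gr.refine({"A", "B"}, net, 1)
        spn = gr.build_spn(res, net)
        assert spn.connector_nodes == frozenset()
        assert set(spn.edges) == {("A", "B")}

    def test_empty_retained_set_gives_empty_spn(self):
        net = from_edges([("A", "x")], nodes=["A", "B"])
        res = gr.refine({"A", "B"}, net, 1)
        spn = gr.build_spn(res, net)
        assert spn.is_empty() and spn.nodes == set()

    def test_annotations_come_from_gi_table(self):
        table = self._table(
            [
                ["Q", "A", "sensitive", -3.0, 0.001, 0.01, 5, 50, 0, 0],
                ["Q", "B", "resistant", 3.0, 0.001, 0.02, 5, 50, 0, 0],
            ]
        )
        net = from_edges([("A", "B")])
        res = gr.refine({"A", "B"}, net, 1, mutated_gene="Q")
        spn = gr.build_spn(res, net, gi_table=table)
        assert spn.sp_nodes["A"]["direction"] == "sensitive"
        assert spn.sp_nodes["B"]["fdr"] == pytest.approx(0.02)

    def test_every_sp_has_a_neighbor_within_k(self, small_gi, small_screen):
        mapped = gr.map_sps(small_gi, small_screen.network)
        for q, m in mapped.items():
            if m["skipped"]:
                continue
            for k in (1, 2):
                res = gr.refine(m["initial"], small_screen.network, k, mutated_gene=q)
                spn = gr.build_spn(res, small_screen.network, gi_table=small_gi)
                for s in spn.sp_nodes:
                    assert gr.within_distance(
                        small_screen.network, s, set(spn.sp_nodes) - {s}, k
                    )

    def test_directed_two_path_semantics(self):
        # A -> w -> C is a consistent directed path; A -> w <- C is not
        net = from_edges([("A", "w"), ("w", "C"), ("B", "u"), ("D", "u")], directed=True)
        res = gr.refine({"A", "C"}, net, 2, direction_mode="either")
        spn = gr.build_spn(res, net)
        assert spn.connector_nodes == {"w"}
        res2 = gr.refine({"B", "D"}, net, 2, direction_mode="ignore")
        spn2 = gr.build_spn(res2, net)
        assert spn2.connector_nodes == {"u"}

    def test_sif_export_line_count(self, tmp_path):
        net = chain("A", "x", "C")
        spn = gr.build_spn(gr.refine({"A", "C"}, net, 2), net)
        path = tmp_path / "spn.sif"
        gr.export_spn(spn, path, format="sif")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2 and all("interacts" in ln for ln in lines)

    def test_tsv_round_trip_preserves_roles(self, tmp_path):
        table = self._table([["Q", "A", "sensitive", -3.0, 0.001, 0.01, 5, 50, 0, 0],
                             ["Q", "C", "resistant", 3.0, 0.001, 0.05, 5, 50, 0, 0]])
        net = chain("A", "x", "C")
        spn = gr.build_spn(gr.refine({"A", "C"}, net, 2, mutated_gene="Q"), net, gi_table=table)
        path = tmp_path / "spn.tsv"
        gr.export_spn(spn, path, format="tsv")
        back = gr.read_spn_tsv(path)
        assert back.mutated_gene == "Q" and back.k == 2
        assert back.sp_nodes == spn.sp_nodes
        assert back.connector_nodes == spn.connector_nodes
        assert set(back.edges) == set(spn.edges)

    def test_empty_spn_exports_valid_file(self, tmp_path):
        spn = gr.SPN(mutated_gene="Q", k=1)
        path = tmp_path / "empty.tsv"
        gr.export_spn(spn, path, format="tsv")
        back = gr.read_spn_tsv(path)
        assert back.is_empty()

    def test_graphml_export_is_readable(self, tmp_path):
        import networkx as nx

        net = chain("A", "x", "C")
        spn = gr.build_spn(gr.refine({"A", "C"}, net, 2), net)
        path = tmp_path / "spn.graphml"
        gr.export_spn(spn, path, format="graphml")
        g = nx.read_graphml(path)
        assert set(g.nodes) == {"A", "x", "C"}
        assert g.nodes["x"]["role"] == "connector"

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ConfigurationError):
            gr.export_spn(gr.SPN(mutated_gene="Q", k=1), tmp_path / "x", format="dot")
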