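import numpy as np
import pytest

from volnet import (
    BrainGraph,
    Hemisphere,
    LobeGroup,
    VolitionalProcess,
    build_roster,
    bundled_roster,
    edge_count,
    load_graph,
    load_roster,
    validate,
    write_graph,
)
from volnet.network_model import GraphFormatError, RosterError, normalize_label
from volnet.table1 import TABLE1_RECORDS

from conftest import graph_from_edges


class TestRoster:
    def test_full_table_yields_82_unique_nodes(self):
        roster = build_roster(TABLE1_RECORDS)
        assert len(roster) == 82
        assert len(set(roster.labels)) == 82

    def test_every_process_represented(self):
        roster = build_roster(TABLE1_RECORDS)
        for process in VolitionalProcess:
            assert roster.nodes_for_process(process), process

    def test_bundled_fixture_matches_rebuild(self):
        assert bundled_roster() == build_roster(TABLE1_RECORDS)

    def test_bilateral_expansion_of_single_record(self):
        roster = build_roster(
            [{"area_name": "M1", "sub_area_labels": ["A4hf"],
              "brodmann_label": "BA4", "lobe_group": "FRO",
              "processes": ["EXECUTION"]}]
        )
        assert roster.labels == ["A4hf_l", "A4hf_r"]
        assert all(n.processes == {VolitionalProcess.EXECUTION} for n in roster)

    def test_multi_process_stems_merge_with_union(self):
        roster = bundled_roster()
        for hemi in ("_l", "_r"):
            assert roster["A6m" + hemi].processes == {
                VolitionalProcess.PLANNING,
                VolitionalProcess.TIMING,
            }
            assert roster["A9m" + hemi].processes == {
                VolitionalProcess.PLANNING,
                VolitionalProcess.DECISION,
            }
            assert roster["G" + hemi].processes == {
                VolitionalProcess.MOTIVATION,
                VolitionalProcess.AGENCY,
            }

    def test_decision_seed_nodes_are_a9m_pair(self, roster82):
        labels = {n.label for n in roster82.nodes_for_process(VolitionalProcess.DECISION)}
        assert labels == {"A9m_l", "A9m_r"}

    def test_idempotent_deterministic_order(self):
        assert build_roster(TABLE1_RECORDS).labels == build_roster(TABLE1_RECORDS).labels

    def test_hemisphere_agrees_with_suffix(self, roster82):
        for node in roster82:
            expected = Hemisphere.LEFT if node.label.endswith("_l") else Hemisphere.RIGHT
            assert node.hemisphere is expected

    def test_conflicting_lobe_group_rejected(self):
        records = [
            {"area_name": "x", "sub_area_labels": ["A1"], "brodmann_label": "BA1",
             "lobe_group": "FRO", "processes": ["TIMING"]},
            {"area_name": "y", "sub_area_labels": ["A1"], "brodmann_label": "BA1",
             "lobe_group": "PAR", "processes": ["PLANNING"]},
        ]
        with pytest.raises(RosterError, match="lobe group"):
            build_roster(records)

    def test_empty_process_list_rejected(self):
        with pytest.raises(RosterError):
            build_roster(
                [{"area_name": "x", "sub_area_labels": ["A1"],
                  "brodmann_label": "BA1", "lobe_group": "FRO", "processes": []}]
            )


class TestBrainGraph:
    def test_duplicate_and_reversed_edges_collapse(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("a_l\tb_l\nb_l\ta_l\nb_l\tc_l\n")
        g = load_graph(p)
        assert sorted(g.edges()) == [("a_l", "b_l"), ("b_l", "c_l")]

    def test_matrix_csv_triangle(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text(",a_l,b_l,c_l\na_l,0,1,1\nb_l,1,0,1\nc_l,1,1,0\n")
        g = load_graph(p)
        assert edge_count(g) == 3

    def test_asymmetric_matrix_rejected_without_symmetrize(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text(",a_l,b_l,c_l\na_l,0,1,0\nb_l,1,0,1\nc_l,0,0,0\n")
        with pytest.raises(GraphFormatError, match="asymmetric"):
            load_graph(p)
        with pytest.warns(UserWarning, match="symmetrizing"):
            g = load_graph(p, symmetrize=True)
        assert edge_count(g) == 2

    def test_non_binary_matrix_rejected_with_context(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text(",a_l,b_l\na_l,0,2\nb_l,2,0\n")
        with pytest.raises(GraphFormatError, match="row 2"):
            load_graph(p)

    def test_self_loops_dropped_with_warning(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("a_l\ta_l\na_l\tb_l\n")
        with pytest.warns(UserWarning, match="self-loop"):
            g = load_graph(p)
        assert edge_count(g) == 1

    def test_asymmetric_adjacency_rejected_at_construction(self):
        adj = np.zeros((3, 3), dtype=np.uint8)
        adj[1, 2] = 1
        with pytest.raises(GraphFormatError, match="symmetric"):
            BrainGraph(labels=("a_l", "b_l", "c_l"), adjacency=adj)

    @pytest.mark.parametrize("format", ["edge_list_tsv", "matrix_csv"])
    def test_write_load_round_trip(self, format, tmp_path, two_cliques_bridge):
        p = tmp_path / ("g.csv" if format == "matrix_csv" else "g.tsv")
        write_graph(two_cliques_bridge, p, format=format)
        assert load_graph(p, format=format) == two_cliques_bridge

    def test_label_normalization_case_insensitive(self):
        assert normalize_label("A9m_L") == "A9m_l"
        assert normalize_label("NAC_R") == "NAC_r"


class TestEdgeCount:
    @pytest.mark.parametrize(
        "edges,unordered",
        [([(0, 1), (1, 2), (0, 2)], 3), ([(0, 1)], 1)],
    )
    def test_conventions(self, edges, unordered):
        g = graph_from_edges(max(max(e) for e in edges) + 1, edges)
        assert edge_count(g, "unordered") == unordered
        assert edge_count(g, "ordered") == 2 * unordered

    def test_ordered_2330_means_unordered_1165(self):
        # By definition ordered = 2 x unordered, so the study's 2330
        # matrix entries correspond to 1165 undirected edges.
        assert 2330 // 2 == 1165


class TestValidate:
    def test_matching_connected_graph_passes(self, roster82):
        rng = np.random.default_rng(0)
        from volnet import generate_volitional_like

        g = generate_volitional_like(3).graph
        rep = validate(g, roster82)
        assert rep.passed and rep.components == 1

    def test_missing_label_named(self, roster82, triangle):
        rep = validate(triangle, roster82)
        assert not rep.passed
        assert "A9m_l" in rep.missing_from_graph

    def test_disconnected_graph_warns_not_fails(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        roster = build_roster(
            [{"area_name": "x", "sub_area_labels": [f"v{i}" for i in range(4)],
              "brodmann_label": "BA1", "lobe_group": "FRO",
              "processes": ["TIMING"]}]
        )
        # roster has _l and _r homologues; restrict graph labels to match
        g = BrainGraph.from_edges(roster.labels, [
            ("v0_l", "v1_l"), ("v2_l", "v3_l"), ("v0_r", "v1_r"), ("v2_r", "v3_r"),
        ])
        rep = validate(g, roster)
        assert rep.passed
        assert rep.components == 4
        assert rep.warnings
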