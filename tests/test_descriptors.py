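"""Guanidine anchors, topological distances and the indicator variables."""

import numpy as np
import pandas as pd
import pytest

import triazopep as tp
from triazopep.descriptors import DescriptorError


def _bfs_all_pairs(graph):
    """Independent brute-force shortest-path oracle (no networkx)."""
    adj = {n: set() for n in graph.g.nodes}
    for a, b in graph.g.edges:
        adj[a].add(b)
        adj[b].add(a)
    dist = {}
    for src in adj:
        d = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in d:
                        d[v] = d[u] + 1
                        nxt.append(v)
            frontier = nxt
        dist[src] = d
    return dist


def test_shortest_distances_match_brute_force_oracle(panel_graphs):
    for cid, g in panel_graphs.items():
        oracle = _bfs_all_pairs(g)
        a, b = tp.guanidine_anchors(g)
        assert tp.topological_distance(g, a, b, ring_side="shortest",
                                       count="bonds") == oracle[a][b]
        assert tp.topological_distance(g, a, b, ring_side="shortest") == \
            oracle[a][b] - 1


def test_distance_symmetric_and_zero_on_self(panel_graphs):
    g = panel_graphs["3"]
    a, b = tp.guanidine_anchors(g)
    assert tp.topological_distance(g, a, a) == 0
    assert tp.topological_distance(g, a, b) == \
        tp.topological_distance(g, b, a)


def test_anchor_identification(panel_graphs):
    g = panel_graphs["3"]
    n_side, c_side = tp.guanidine_anchors(g)
    # the C-terminal anchor belongs to the arginine, the last main-chain block
    assert g.g.nodes[c_side]["block"] == "Arg"
    assert g.g.nodes[n_side]["block"] == "Har"


def test_single_guanidine_is_an_error():
    g = tp.assemble_graph(tp.parse_sequence("Arg"))
    with pytest.raises(DescriptorError):
        tp.guanidine_anchors(g)


def test_fmoc_capping_leaves_anchors_unchanged(panel_graphs):
    # compounds 3 and 14 differ only by the cap
    for cid in ("3", "14"):
        g = panel_graphs[cid]
        blocks = sorted(g.g.nodes[a]["block"] for a in tp.guanidine_anchors(g))
        assert blocks == ["Arg", "Har"]
    assert tp.guanidine_distance(panel_graphs["3"]) == \
        tp.guanidine_distance(panel_graphs["14"])


def test_triazole_insertion_lengthens_the_path(panel_graphs):
    """One extra glycyl-triazole unit adds 4 path atoms on the shortest
    route (CH2, C4, C5, N1) and 5 on the nitrogen-side route."""
    d1s = tp.guanidine_distance(panel_graphs["1"], ring_side="shortest")
    d3s = tp.guanidine_distance(panel_graphs["3"], ring_side="shortest")
    assert d3s == d1s + 4
    d1n = tp.guanidine_distance(panel_graphs["1"], ring_side="nitrogen")
    d3n = tp.guanidine_distance(panel_graphs["3"], ring_side="nitrogen")
    assert d3n == d1n + 5
    assert d3s == 28


def test_counting_convention_is_affine_after_normalization(panel_sequences):
    """Atoms-between vs bond counting shifts the raw column by one
    panel-wide, so the min-max normalized column is identical."""
    items = list(panel_sequences.items())
    excl = tp.build_descriptor_matrix(items, count="atoms_between")
    bonds = tp.build_descriptor_matrix(items, count="bonds")
    assert ((bonds["dis_N-C"] - excl["dis_N-C"]) == 1).all()
    assert np.allclose(bonds["dis_N-C,norm"], excl["dis_N-C,norm"])


def test_ring_side_convention_is_not_affine(panel_sequences):
    """The ring-traversal side scales with the number of rings on the
    path, so it survives normalization — the one convention choice that
    matters for the regression models."""
    items = list(panel_sequences.items())
    nit = tp.build_descriptor_matrix(items, ring_side="nitrogen")
    sho = tp.build_descriptor_matrix(items, ring_side="shortest")
    assert not np.allclose(nit["dis_N-C,norm"], sho["dis_N-C,norm"])


def test_trl2_indicator_definition():
    assert tp.indicator_trl2_cn(
        tp.parse_sequence("Lys(Har)-GlyΨ[Trl]GlyΨ[Trl]Arg")) == 1
    assert tp.indicator_trl2_cn(
        tp.parse_sequence("Lys(Har)-GlyΨ[Trl]Arg")) == 0
    # pure peptide: no triazole anywhere
    assert tp.indicator_trl2_cn(tp.parse_sequence("Lys(Har)-Gly-Gly-Arg")) == 0
    with pytest.raises(DescriptorError):
        tp.indicator_trl2_cn(tp.parse_sequence("Har-Arg"))


def test_am2n_indicator_definition():
    # free Lys alpha-amine flanks linkage 2 counted from the arm
    assert tp.indicator_am2n(
        tp.parse_sequence("Lys(Har)-GlyΨ[Trl]GlyΨ[Trl]Arg")) == 1
    # 6Ahx has no alpha-amine
    assert tp.indicator_am2n(
        tp.parse_sequence("Har-6Ahx-GlyΨ[Trl]GlyΨ[Trl]Arg")) == 0
    # Fmoc on the arm masks the Har amine but the Lys alpha-amine stays free
    assert tp.indicator_am2n(
        tp.parse_sequence("Lys(Fmoc-Har)-GlyΨ[Trl]GlyΨ[Trl]Arg")) == 1
    # backbone lysine: its alpha-amine is acylated, the side-chain
    # epsilon-amine does not count
    assert tp.indicator_am2n(
        tp.parse_sequence("Har-Lys-GlyΨ[Trl]GlyΨ[Trl]Arg")) == 0


def test_panel_indicator_columns(panel_descriptors):
    trl2 = panel_descriptors["2Trl_C-N"]
    am = panel_descriptors["am_2N"]
    assert set(trl2.unique()) <= {0, 1} and set(am.unique()) <= {0, 1}
    expected_trl2 = [0, 0, 1, 1, 1, 0, 0, 0, 0, 1, 1,
                     0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
    expected_am = [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1,
                   0, 0, 1, 1, 0, 1, 1, 0, 0, 0, 0, 0]
    assert trl2.tolist() == expected_trl2
    assert am.tolist() == expected_am


def test_normalized_column_attains_zero_and_one(panel_descriptors):
    norm = panel_descriptors["dis_N-C,norm"]
    assert norm.min() == 0.0 and norm.max() == 1.0
    assert ((norm >= 0) & (norm <= 1)).all()


def test_matrix_values_invariant_to_compound_order(panel_sequences):
    items = list(panel_sequences.items())
    fwd = tp.build_descriptor_matrix(items)
    rev = tp.build_descriptor_matrix(items[::-1])
    pd.testing.assert_frame_equal(fwd.sort_index(), rev.sort_index())


def test_single_compound_panel_degenerate_normalization():
    seq = tp.parse_sequence("Lys(Har)-GlyΨ[Trl]Arg")
    df = tp.build_descriptor_matrix([("only", seq)])
    assert df.loc["only", "dis_N-C,norm"] == 0.0
    assert df.attrs.get("degenerate_norm") is True


def test_descriptor_failure_names_the_compound():
    with pytest.raises(DescriptorError, match="bad"):
        tp.build_descriptor_matrix([("bad", tp.parse_sequence("Ala-Arg"))])


def test_am2n_override_column():
    seq = tp.parse_sequence("Lys(Har)-GlyΨ[Trl]GlyΨ[Trl]Arg")
    df = tp.build_descriptor_matrix([("x", seq)], am2n_override={"x": 0})
    assert df.loc["x", "am_2N"] == 0
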