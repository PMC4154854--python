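"""Median, sign, and gap cuts, and strict/overlap fragment extraction."""

import numpy as np
import pytest

import ragcut as rc
from ragcut.partition import extract_fragments, shared_vertex


def unordered(cut):
    return {frozenset(p) for p in cut.parts}


class TestThresholdSplit:
    def test_six_two_at_minus_point_one(self, paper_graphs):
        g = paper_graphs["6_2"]
        # splitting value applies to the caller's orientation: here the
        # published one, with the three-way branch on the negative side
        mu2 = -rc.spectrum(g).mu2
        cut = rc.threshold_split(g, mu2, -0.10)
        assert cut.part_a == frozenset({1, 2, 3})
        assert cut.part_b == frozenset({4, 5, 6})
        assert cut.cut_edges == ((2, 4),)

    def test_s_below_minimum_is_empty_part(self, paper_graphs):
        g = paper_graphs["6_1"]
        mu2 = rc.spectrum(g).mu2
        with pytest.raises(rc.EmptyPartError):
            rc.threshold_split(g, mu2, float(mu2.min()) - 1.0)

    def test_path_four_antisymmetry_at_zero(self):
        g = rc.build_graph([(1, 2), (2, 3), (3, 4)], 4)
        mu2 = rc.spectrum(g).mu2
        cut = rc.threshold_split(g, -mu2, 0.0)
        assert unordered(cut) == {frozenset({1, 2}), frozenset({3, 4})}

    def test_membership_rule(self, paper_graphs):
        for g in paper_graphs.values():
            mu2 = rc.spectrum(g).mu2
            for method in ("median", "sign", "gap"):
                cut = rc.cut(g, method)
                expected = frozenset(
                    v for v, x in zip(g.vertices, mu2) if x <= cut.s
                )
                assert cut.part_a == expected


class TestMedianCut:
    def test_linear_six(self, paper_graphs):
        cut = rc.median_cut(paper_graphs["6_1"])
        assert unordered(cut) == {frozenset({1, 2, 3}), frozenset({4, 5, 6})}

    def test_six_five_two_three_vertex_parts(self, paper_graphs):
        cut = rc.median_cut(paper_graphs["6_5"])
        assert unordered(cut) == {frozenset({2, 4, 5}), frozenset({1, 3, 6})}

    def test_single_edge(self, paper_graphs):
        cut = rc.median_cut(paper_graphs["2_1"])
        assert unordered(cut) == {frozenset({1}), frozenset({2})}

    def test_odd_n_median_component_in_part_a(self, paper_graphs):
        g = paper_graphs["5_2"]
        mu2 = rc.spectrum(g).mu2
        cut = rc.median_cut(g)
        median_vertex = g.vertices[int(np.argsort(mu2)[g.n // 2])]
        assert cut.s == pytest.approx(float(np.median(mu2)))
        assert median_vertex in cut.part_a


class TestSignCut:
    def test_six_five(self, paper_graphs):
        cut = rc.sign_cut(paper_graphs["6_5"])
        assert unordered(cut) == {frozenset({4, 5}), frozenset({1, 2, 3, 6})}

    def test_six_two_same_as_median(self, paper_graphs):
        g = paper_graphs["6_2"]
        assert unordered(rc.sign_cut(g)) == unordered(rc.median_cut(g))
        assert unordered(rc.sign_cut(g)) == {frozenset({1, 2, 3}), frozenset({4, 5, 6})}

    def test_path_three_zero_component_joins_part_a(self, paper_graphs):
        # mu2(P3) = (1, 0, -1)/sqrt(2) under the first-nonzero-positive
        # orientation; the zero-valued center falls on the nu <= 0 side
        cut = rc.sign_cut(paper_graphs["3_1"])
        assert cut.part_a == frozenset({2, 3})
        assert unordered(cut) == {frozenset({1}), frozenset({2, 3})}


class TestGapCut:
    def test_six_five(self, paper_graphs):
        cut = rc.gap_cut(paper_graphs["6_5"])
        assert unordered(cut) == {frozenset({4, 5}), frozenset({1, 2, 3, 6})}
        # largest gap lies between the sorted components -0.38 and 0.16
        assert cut.gap_width == pytest.approx(0.1620 + 0.3759, abs=1e-3)

    def test_linear_six_agrees_with_median_and_sign(self, paper_graphs):
        g = paper_graphs["6_1"]
        assert (
            unordered(rc.gap_cut(g))
            == unordered(rc.median_cut(g))
            == unordered(rc.sign_cut(g))
            == {frozenset({1, 2, 3}), frozenset({4, 5, 6})}
        )

    def test_six_two_strict_largest_gap(self, paper_graphs):
        # Documented behaviour: the strict largest-gap rule picks the
        # 0.3644 gap (split {1,2,3}/{4,5,6}) over the 0.3380 gap that
        # would separate the junction from its two-vertex tail.
        g = paper_graphs["6_2"]
        cut = rc.gap_cut(g)
        assert unordered(cut) == {frozenset({1, 2, 3}), frozenset({4, 5, 6})}
        assert cut.gap_width == pytest.approx(0.3644, abs=1e-3)
        gaps = np.sort(np.diff(np.sort(rc.spectrum(g).mu2)))
        runner_up = float(gaps[-2])
        assert cut.gap_width > runner_up == pytest.approx(0.3380, abs=1e-3)

    def test_gap_tie_breaks_toward_smaller_values(self):
        g = rc.build_graph([(1, 2), (2, 3), (3, 4)], 4)
        # P4's sorted components have two equal flanking gaps; the
        # central gap is strictly largest, so construct an explicit tie
        mu2 = np.array([-0.6, -0.1, 0.1, 0.6])
        cut = rc.gap_cut(g, mu2)
        assert cut.s == pytest.approx(-0.35)


class TestOrientationInvariance:
    @pytest.mark.parametrize("method", ["median", "sign", "gap"])
    def test_flip_on_seeded_random_trees(self, method):
        for seed in range(200):
            g = rc.random_tree(4 + seed % 13, seed)
            mu2 = rc.spectrum(g).mu2
            assert unordered(rc.cut(g, method, mu2)) == unordered(
                rc.cut(g, method, -mu2)
            )


class TestExtractFragments:
    def test_strict_six_two(self, paper_graphs):
        g = paper_graphs["6_2"]
        cut = extract_fragments(g, rc.gap_cut(g), "strict")
        fa, fb = cut.fragments
        assert {fa.vertices, fb.vertices} == {(1, 2, 3), (4, 5, 6)}
        assert all(len(f.edges) == 2 for f in (fa, fb))  # both are P3
        assert (2, 4) not in fa.edges | fb.edges  # cut edge dropped

    def test_overlap_star_plus_pendant(self):
        # three-way junction with internal loop: cutting off the pendant
        # leaf keeps the cut edge with the leaf side (it has no edge)
        g = rc.build_graph([(1, 2), (2, 3), (2, 5), (3, 4)], 5)
        cut = rc.CutResult("replay", float("nan"), frozenset({1, 2, 3, 5}),
                           frozenset({4}), ((3, 4),))
        cut = extract_fragments(g, cut, "overlap")
        fa, fb = cut.fragments
        assert fa.vertices == (1, 2, 3, 5) and set(fa.edges) == {(1, 2), (2, 3), (2, 5)}
        assert fb.vertices == (3, 4) and set(fb.edges) == {(3, 4)}
        assert shared_vertex(cut) == 3

    def test_overlap_junction_takes_the_cut_helix(self):
        # both sides have edges: the side whose cut endpoint has the
        # higher degree (the junction, vertex 7) is augmented
        g = rc.RAGTreeGraph((1, 6, 7, 8, 9), frozenset({(1, 7), (6, 7), (7, 8), (8, 9)}))
        cut = rc.CutResult("replay", float("nan"), frozenset({1, 6, 7}),
                           frozenset({8, 9}), ((7, 8),))
        cut = extract_fragments(g, cut, "overlap")
        fa, fb = cut.fragments
        assert fa.vertices == (1, 6, 7, 8)
        assert fb.vertices == (8, 9)
        assert shared_vertex(cut) == 8

    def test_overlap_edge_sets_partition_parent(self, paper_graphs):
        for seed in range(50):
            g = rc.random_tree(5 + seed % 8, seed + 1000)
            cut = rc.gap_cut(g)
            if len(cut.cut_edges) != 1:
                continue
            cut = extract_fragments(g, cut, "overlap")
            fa, fb = cut.fragments
            assert fa.edges.isdisjoint(fb.edges)
            assert fa.edges | fb.edges == g.edges
            assert len(set(fa.vertices) & set(fb.vertices)) == 1

    def test_strict_multi_cut_returns_components_with_warning(self, paper_graphs):
        g = paper_graphs["6_5"]
        cut = rc.median_cut(g)  # breaks the 4-way junction: 3 cut edges
        assert len(cut.cut_edges) == 3
        cut = extract_fragments(g, cut, "strict")
        assert any("connected components" in w for w in cut.warnings)
        sides = {frozenset(p) for p in cut.parts}
        assert frozenset({1, 3, 6}) in sides  # edgeless side -> 3 lone vertices
        multi = next(f for f in cut.fragments if isinstance(f, tuple))
        assert sorted(c.vertices for c in multi) == [(1,), (3,), (6,)]

    def test_overlap_multi_cut_refused(self, paper_graphs):
        g = paper_graphs["6_5"]
        with pytest.raises(rc.MultiCutError):
            extract_fragments(g, rc.median_cut(g), "overlap")

    def test_single_edge_cut_on_fixtures(self, paper_graphs):
        for g in paper_graphs.values():
            for method in ("sign", "gap"):
                cut = extract_fragments(g, rc.cut(g, method), "strict")
                assert len(cut.cut_edges) == 1
                for frag in cut.fragments:
                    assert isinstance(frag, rc.RAGTreeGraph)  # connected

    def test_degenerate_warning_propagates(self):
        star = rc.build_graph([(1, 2), (2, 3), (2, 4)], 4)
        cut = rc.gap_cut(star)
        assert cut.degenerate_warning
        assert any("degenerate" in w for w in cut.warnings)
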