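"""Segment labeling rules: LCx selection, tree partitioning, side branches."""

import numpy as np
import pytest

from corolabel.geometry import Centerline, PointCloud, arc_length, count_within, distance_profile
from corolabel.labeler import (
    SEGMENT_LABELS,
    LabeledTree,
    LabelerConfig,
    LcxCandidate,
    enumerate_lcx_candidates,
    label_left_tree,
    label_tree,
    select_lcx,
    split_left_right,
)
from corolabel.phantom import generate_case, ground_truth_tree, rasterize
from corolabel.pipeline import graph_from_centerlines, graph_from_mask
from corolabel.skeleton import VesselGraph


def make_candidate(score_la, score_lv, length, endpoint=(0, 0, 0)):
    n = max(score_la, score_lv, 2)
    pts = np.linspace([0, 0, 0], endpoint if any(endpoint) else [length, 0, 0], max(n, 2))
    return LcxCandidate(
        path=Centerline(pts + np.arange(len(pts))[:, None] * 1e-6),
        node_path=[0, 1],
        attribute_la=score_la,
        attribute_lv=score_lv,
        length=length,
    )


class TestSelectLcx:
    def test_single_candidate_returned(self):
        c = make_candidate(10, 10, 50.0)
        assert select_lcx([c]) is c

    def test_strict_score_dominance_ignores_length(self):
        hi = make_candidate(60, 60, 10.0)
        lo = make_candidate(40, 40, 500.0)
        assert select_lcx([lo, hi]) is hi

    def test_equal_scores_longer_wins(self):
        a = make_candidate(50, 50, 84.0)
        b = make_candidate(50, 50, 61.0)
        assert select_lcx([b, a]) is a

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            select_lcx([])

    def test_agrees_with_brute_force_rule(self, rng):
        """Randomized trials against an exhaustive evaluator of the
        score-then-length selection rule."""
        for _ in range(200):
            n = rng.integers(2, 8)
            cands = [
                make_candidate(
                    int(rng.integers(0, 60)),
                    int(rng.integers(0, 60)),
                    float(np.round(rng.uniform(10, 120), 1)),
                    endpoint=tuple(rng.integers(1, 50, 3)),
                )
                for _ in range(n)
            ]
            if rng.random() < 0.5:  # force score ties
                cands[1].attribute_la = cands[0].attribute_la
                cands[1].attribute_lv = cands[0].attribute_lv
            chosen = select_lcx(cands)
            best = sorted(
                cands,
                key=lambda c: (c.score, c.length, tuple(-c.path.points[-1])),
            )[-1]
            assert chosen.score == best.score and chosen.length == best.length

    def test_length_among_top_score_mode(self):
        a = make_candidate(50, 50, 30.0)
        b = make_candidate(50, 50, 90.0)
        c = make_candidate(49, 52, 200.0)  # score 101, longer, higher score
        assert select_lcx([a, b, c], rule="length_among_top_score") is c
        # with a strictly top-scoring pair, the longest of that pair wins
        d = make_candidate(51, 50, 10.0)
        e = make_candidate(51, 50, 40.0)
        assert select_lcx([d, e, a], rule="length_among_top_score") is e


def small_bifurcation_graph():
    """Stem (0,0,0)->(0,0,10) splitting into posterior and anterior arms."""
    g = VesselGraph()
    g.add_node(0, [0, 0, 0])
    g.add_node(1, [0, 0, 10])
    g.add_node(2, [5, -20, 15])  # posterior arm end
    g.add_node(3, [2, 20, 15])  # anterior arm end
    stem = np.array([[0, 0, 0], [0, 0, 5], [0, 0, 10]], float)
    post = np.array([[0, 0, 10], [2, -10, 12], [5, -20, 15]], float)
    ant = np.array([[0, 0, 10], [1, 10, 12], [2, 20, 15]], float)
    g.add_edge(0, 1, stem, 1)
    g.add_edge(1, 2, post, 1)
    g.add_edge(1, 3, ant, 1)
    return g


class TestEnumerateCandidates:
    def setup_method(self):
        self.g = small_bifurcation_graph()
        self.la = PointCloud([[0, -30, 10]], role="LA")
        self.lv = PointCloud([[0, 0, 40]], role="LV")

    def test_two_paths_share_start(self):
        cfg = LabelerConfig(lcx_direction_filter="off")
        cands = enumerate_lcx_candidates(self.g, 1, self.la, self.lv, cfg, exclude_endpoints={0})
        assert len(cands) == 2
        starts = {tuple(c.path.points[0]) for c in cands}
        assert starts == {(0.0, 0.0, 10.0)}

    def test_filter_off_counts_all_downstream_endpoints(self):
        cfg = LabelerConfig(lcx_direction_filter="off")
        cands = enumerate_lcx_candidates(self.g, 1, self.la, self.lv, cfg, exclude_endpoints={0})
        assert len(cands) == 2

    def test_anatomical_filter_drops_anterior_path(self):
        cfg = LabelerConfig(lcx_direction_filter="anatomical")
        cands = enumerate_lcx_candidates(self.g, 1, self.la, self.lv, cfg, exclude_endpoints={0})
        assert len(cands) == 1
        assert cands[0].path.points[-1][1] < 0

    def test_attributes_match_brute_force_recount(self):
        cfg = LabelerConfig(lcx_direction_filter="off")
        cands = enumerate_lcx_candidates(self.g, 1, self.la, self.lv, cfg, exclude_endpoints={0})
        for c in cands:
            prof = distance_profile(c.path, self.la, self.lv)
            assert c.attribute_la == count_within(prof.d_min_la, cfg.la_threshold_mm)
            assert c.attribute_lv == count_within(prof.d_min_lv, cfg.lv_threshold_mm)
            assert c.score == c.attribute_la + c.attribute_lv


class TestSplitLeftRight:
    def test_phantom_partition(self, default_case, default_graph):
        left, right, lroot, rroot = split_left_right(
            default_graph, default_case.ostia, tol=8.0
        )
        assert left is not None and right is not None
        assert not set(left.g.nodes) & set(right.g.nodes)

    def test_single_seed_gives_one_tree(self, default_case, default_graph):
        left, right, lroot, rroot = split_left_right(
            default_graph, {"left": default_case.ostia["left"], "right": None}, tol=8.0
        )
        assert left is not None and right is None and rroot is None

    def test_same_component_rejected(self):
        g = small_bifurcation_graph()
        with pytest.raises(ValueError, match="same connected component"):
            split_left_right(g, {"left": [0, 0, 0], "right": [5, -20, 15]}, tol=3.0)


class TestLabelTreeOnPhantoms:
    def test_full_phantom_recovers_every_label(self, default_case, default_graph):
        tree = label_tree(
            default_graph, default_case.la_cloud, default_case.lv_cloud, default_case.ostia
        )
        truth = ground_truth_tree(default_case)
        assert tree.labels_present() == truth.labels_present()

    def test_determinism(self, default_case, default_graph):
        kw = dict(la=default_case.la_cloud, lv=default_case.lv_cloud, ostia=default_case.ostia)
        t1 = label_tree(default_graph, **kw)
        t2 = label_tree(default_graph, **kw)
        assert [f.label for f in t1.fragments] == [f.label for f in t2.fragments]
        for a, b in zip(t1.fragments, t2.fragments):
            np.testing.assert_array_equal(a.points, b.points)

    def test_vocabulary_closure(self, default_case, default_graph):
        tree = label_tree(
            default_graph, default_case.la_cloud, default_case.lv_cloud, default_case.ostia
        )
        assert tree.labels_present() <= set(SEGMENT_LABELS)

    def test_left_only_input_yields_left_labels(self, default_case, default_graph):
        tree = label_tree(
            default_graph,
            default_case.la_cloud,
            default_case.lv_cloud,
            {"left": default_case.ostia["left"], "right": None},
        )
        right_labels = {"pRCA", "mRCA", "dRCA", "R-PDA", "R-PLB"}
        assert not tree.labels_present() & right_labels

    def test_selected_lcx_closer_to_la_than_lad(self, default_case, default_graph):
        """The anatomical premise: the circumflex hugs the LA, the LAD does not."""
        left, _, lroot, _ = split_left_right(default_graph, default_case.ostia, tol=8.0)
        tree = label_left_tree(
            left, lroot, default_case.la_cloud, default_case.lv_cloud, LabelerConfig()
        )
        lcx_pts = np.vstack([tree.get("pCx").points, tree.get("LCx").points])
        lad_pts = np.vstack(
            [tree.get("pLAD").points, tree.get("mLAD").points, tree.get("dLAD").points]
        )
        d_lcx = distance_profile(
            Centerline(lcx_pts), default_case.la_cloud, default_case.lv_cloud
        ).d_min_la.mean()
        d_lad = distance_profile(
            Centerline(lad_pts), default_case.la_cloud, default_case.lv_cloud
        ).d_min_la.mean()
        assert d_lcx < d_lad

    def test_selected_score_recomputes_from_raw_distances(self, default_case, default_graph):
        tree = label_tree(
            default_graph, default_case.la_cloud, default_case.lv_cloud, default_case.ostia
        )
        sel = tree.provenance["lcx_selected"]
        assert sel["score"] == sel["attribute_la"] + sel["attribute_lv"]
        best = max(c["score"] for c in tree.provenance["lcx_candidates"])
        assert sel["score"] == best

    def test_phantom_without_optional_branches(self):
        """Absent branches yield absent labels, main vessels still split."""
        # find a seed with no diagonals generated under defaults
        for s in range(200):
            case = generate_case(s)
            if case.descriptor["n_diagonals"] == 0:
                break
        else:
            pytest.skip("no diagonal-free case in seed range")
        g = graph_from_mask(rasterize(case))
        tree = label_tree(g, case.la_cloud, case.lv_cloud, case.ostia)
        assert "D1" not in tree.labels_present()
        assert {"pLAD", "mLAD", "dLAD"} <= tree.labels_present()


class TestMarginalCap:
    def test_three_marginals_third_flagged(self, default_case):
        """A third marginal exceeds the OM1/OM2 vocabulary and is flagged."""
        case = default_case
        extra = case.branches["OM2"].points.copy()
        shift = np.array([1.0, -6.0, 9.0])
        lcx = case.branches["LCX"]
        # attach a third marginal farther along the circumflex
        origin = lcx.points[min(60, len(lcx) - 2)]
        extra = origin + (extra - extra[0]) * 0.8 + shift * 0.0
        branches = dict(case.branches)
        branches["OM3"] = Centerline(extra)
        lines = [branches[k] for k in sorted(branches)]
        g = graph_from_centerlines(lines)
        tree = label_tree(g, case.la_cloud, case.lv_cloud, case.ostia)
        assert {"OM1", "OM2"} <= tree.labels_present()
        assert any("marginal" in w for w in tree.warnings)
        assert tree.labels_present() <= set(SEGMENT_LABELS)


class TestConfigValidation:
    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            LabelerConfig(subdivision_fractions=(0.5, 0.5, 0.5))

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            LabelerConfig(la_threshold_mm=0)

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError):
            LabelerConfig(lcx_direction_filter="sideways")


def test_duplicate_labels_rejected():
    from corolabel.labeler import LabeledFragment

    f1 = LabeledFragment("LM", "LM", np.zeros((2, 3)), 0, 1)
    f2 = LabeledFragment("LM", "LM", np.ones((2, 3)), 0, 1)
    with pytest.raises(ValueError, match="duplicate"):
        LabeledTree([f1, f2])
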