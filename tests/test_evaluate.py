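"""Presence, overlap, confusion and agreement metrics."""

import numpy as np
import pandas as pd
import pytest

from corolabel.evaluate import (
    REFERENCE_PRESENCE_COUNTS,
    ConfusionCounts,
    classification_metrics,
    confusion_matrix,
    display_round,
    metrics_table,
    modification_rate,
    overlap_accuracy,
    presence_confusion,
    rater_agreement,
    segment_recovery,
)
from corolabel.labeler import SEGMENT_LABELS, LabeledFragment, LabeledTree


def line_tree(spec):
    """Tree of straight fragments along x; spec: [(label, x0, x1), ...]."""
    frags = []
    for label, x0, x1 in spec:
        xs = np.arange(x0, x1)
        pts = np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)]).astype(float)
        frags.append(LabeledFragment(label, label, pts, float(x0), float(x1 - 1)))
    return LabeledTree(frags)


class TestPresenceConfusion:
    def test_identical_sets_no_errors(self):
        sets = [{"LM", "pLAD"}, {"LM"}, set()] * 3 + [{"RI"}]
        counts = presence_confusion(sets, sets)
        for lab, c in counts.items():
            assert c.fp == 0 and c.fn == 0
            assert c.total == 10

    def test_empty_predictions_all_fn(self):
        ref = [{"LM", "LCx"}, {"LM"}, set()]
        counts = presence_confusion([set()] * 3, ref)
        assert counts["LM"].fn == 2 and counts["LM"].fp == 0
        assert counts["LCx"].fn == 1
        assert counts["RI"].tn == 3

    def test_matches_direct_tally(self, rng):
        labs = list(SEGMENT_LABELS)
        pred = [set(rng.choice(labs, rng.integers(0, 10), replace=False)) for _ in range(100)]
        ref = [set(rng.choice(labs, rng.integers(0, 10), replace=False)) for _ in range(100)]
        counts = presence_confusion(pred, ref)
        for lab in labs:
            tp = sum(1 for p, r in zip(pred, ref) if lab in p and lab in r)
            fn = sum(1 for p, r in zip(pred, ref) if lab not in p and lab in r)
            fp = sum(1 for p, r in zip(pred, ref) if lab in p and lab not in r)
            tn = sum(1 for p, r in zip(pred, ref) if lab not in p and lab not in r)
            c = counts[lab]
            assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            presence_confusion([{"LIMA"}], [set()])


# printed percentages of the published 157-patient presence table; the D1
# F1 value follows from its own counts: 2*152/(2*152+0+2) = 99.3%
EXPECTED_METRICS = {
    "pRCA": (100.0, 100.0, 100.0, 100.0),
    "mRCA": (100.0, 100.0, 100.0, 100.0),
    "dRCA": (100.0, 100.0, 100.0, 100.0),
    "R-PDA": (99.3, 99.3, 98.7, 99.3),
    "R-PLB": (100.0, 74.0, 79.0, 85.1),
    "LM": (100.0, 100.0, 100.0, 100.0),
    "pLAD": (100.0, 100.0, 100.0, 100.0),
    "mLAD": (100.0, 100.0, 100.0, 100.0),
    "dLAD": (99.4, 100.0, 99.4, 99.7),
    "D1": (100.0, 98.7, 98.7, 99.3),
    "D2": (90.2, 94.8, 88.5, 92.4),
    "pCx": (100.0, 99.4, 99.4, 99.7),
    "LCx": (100.0, 96.2, 96.2, 98.1),
    "OM1": (99.2, 93.4, 93.6, 96.2),
    "OM2": (92.6, 94.9, 93.6, 93.8),
    "RI": (80.7, 78.0, 84.7, 79.3),
    "In total": (98.5, 96.6, 95.7, 97.6),
}


class TestClassificationMetrics:
    @pytest.mark.parametrize("segment", list(REFERENCE_PRESENCE_COUNTS))
    def test_reference_table_rows(self, segment):
        c = ConfusionCounts(*REFERENCE_PRESENCE_COUNTS[segment])
        m = classification_metrics(c)
        got = tuple(display_round(m[k]) for k in ("precision", "recall", "accuracy", "f1"))
        assert got == EXPECTED_METRICS[segment]

    def test_pooled_total_row(self):
        counts = {k: ConfusionCounts(*v) for k, v in REFERENCE_PRESENCE_COUNTS.items()}
        table = metrics_table(counts)
        total = table[table.Segment == "In total"].iloc[0]
        assert (total.TP, total.TN, total.FP, total.FN) == (2148, 257, 32, 75)
        assert (total.Precision, total.Recall, total.Accuracy, total.F1) == EXPECTED_METRICS["In total"]

    def test_perfect_detector(self):
        m = classification_metrics(ConfusionCounts(10, 5, 0, 0))
        assert all(v == 100.0 for v in m.values())

    def test_zero_denominators_undefined(self):
        m = classification_metrics(ConfusionCounts(0, 5, 0, 0))
        assert np.isnan(m["precision"]) and np.isnan(m["recall"]) and np.isnan(m["f1"])
        assert m["accuracy"] == 100.0
        m = classification_metrics(ConfusionCounts())
        assert all(np.isnan(v) for v in m.values())

    def test_half_up_display_rounding(self):
        # the OM2 F1 is exactly 93.75: half-up gives 93.8
        assert display_round(93.75) == 93.8
        assert display_round(99.34) == 99.3


class TestOverlap:
    def test_identical_labelings_full_overlap(self):
        t = line_tree([("LM", 0, 10), ("pLAD", 10, 30)])
        assert overlap_accuracy(t, t, "LM") == 100.0
        assert overlap_accuracy(t, t, "pLAD") == 100.0

    def test_half_shifted_boundary(self):
        ref = line_tree([("pLAD", 0, 20), ("mLAD", 20, 40)])
        pred = line_tree([("pLAD", 0, 10), ("mLAD", 10, 40)])
        assert overlap_accuracy(pred, ref, "pLAD") == pytest.approx(50.0)

    def test_matches_point_count_oracle(self, rng):
        cut_ref, cut_pred = rng.integers(10, 30, 2)
        ref = line_tree([("pCx", 0, cut_ref), ("LCx", cut_ref, 40)])
        pred = line_tree([("pCx", 0, cut_pred), ("LCx", cut_pred, 40)])
        expected = 100.0 * min(cut_ref, cut_pred) / cut_ref
        assert overlap_accuracy(pred, ref, "pCx") == pytest.approx(expected)

    def test_dice_mode_symmetric(self):
        ref = line_tree([("LM", 0, 20)])
        pred = line_tree([("LM", 0, 10), ("pLAD", 10, 20)])
        assert overlap_accuracy(pred, ref, "LM", mode="dice") == pytest.approx(
            100.0 * 2 * 10 / 30
        )

    def test_absent_segment_undefined(self):
        t = line_tree([("LM", 0, 10)])
        assert np.isnan(overlap_accuracy(t, t, "RI"))

    def test_disjoint_labelings_rejected(self):
        ref = line_tree([("LM", 0, 20)])
        pred_far = LabeledTree(
            [LabeledFragment("LM", "LM", np.full((20, 3), 500.0) + np.arange(20)[:, None], 0, 19)]
        )
        with pytest.raises(ValueError, match="not comparable"):
            overlap_accuracy(pred_far, ref, "LM")


class TestConfusionMatrix:
    def test_identity_for_identical_labelings(self):
        t = line_tree([("LM", 0, 10), ("pLAD", 10, 25), ("mLAD", 25, 40)])
        m = confusion_matrix(t, t)
        for lab in ("LM", "pLAD", "mLAD"):
            assert m.loc[lab, lab] == 1.0
        assert np.allclose(m.loc["LM"].sum(), 1.0)

    def test_constructed_om1_lcx_confusion(self):
        ref = line_tree([("pCx", 0, 10), ("OM1", 10, 30)])
        pred = line_tree([("pCx", 0, 10), ("LCx", 10, 30)])
        m = confusion_matrix(pred, ref)
        assert m.loc["OM1", "LCx"] == 1.0

    def test_rows_sum_to_one_over_present_labels(self, rng):
        ref = line_tree([("pCx", 0, 15), ("LCx", 15, 40), ("OM1", 40, 55)])
        cut = int(rng.integers(5, 35))
        pred = line_tree([("pCx", 0, cut), ("LCx", cut, 55)])
        m = confusion_matrix(pred, ref)
        for lab in ("pCx", "LCx", "OM1"):
            assert m.loc[lab].sum() == pytest.approx(1.0, abs=1e-9)


class TestRaterAgreement:
    def test_identical_raters(self):
        sets = [{"LM", "OM1"}, {"LM"}] * 10
        rep = rater_agreement(sets, sets)
        assert all(v == 100.0 for v in rep.per_segment.values())
        assert rep.unresolved == []

    def test_one_in_twenty_disagreement(self):
        r1 = [{"OM1"}] * 20
        r2 = [{"OM1"}] * 19 + [set()]
        rep = rater_agreement(r1, r2)
        assert rep.per_segment["OM1"] == pytest.approx(95.0)

    def test_adjudicator_resolves_disagreements_only(self, rng):
        labs = list(SEGMENT_LABELS)
        r1 = [set(rng.choice(labs, 5, replace=False)) for _ in range(30)]
        r2 = [set(rng.choice(labs, 5, replace=False)) for _ in range(30)]
        adj = [set(rng.choice(labs, 5, replace=False)) for _ in range(30)]
        rep = rater_agreement(r1, r2, adjudicator=adj)
        for i, cons in enumerate(rep.consensus):
            for lab in labs:
                if (lab in r1[i]) == (lab in r2[i]):
                    assert (lab in cons) == (lab in r1[i])
                else:
                    assert (lab in cons) == (lab in adj[i])

    def test_mismatched_case_lists_rejected(self):
        with pytest.raises(ValueError):
            rater_agreement([set()], [set(), set()])


class TestModificationRate:
    def test_published_review_arithmetic(self):
        assert display_round(modification_rate(117, 2180)) == 5.4

    def test_zero_modified(self):
        assert modification_rate(0, 50) == 0.0

    def test_matches_direct_division(self, rng):
        for _ in range(20):
            total = int(rng.integers(1, 5000))
            mod = int(rng.integers(0, total + 1))
            assert modification_rate(mod, total) == pytest.approx(100 * mod / total)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            modification_rate(0, 0)


def test_segment_recovery_threshold():
    ref = line_tree([("pLAD", 0, 20), ("mLAD", 20, 40)])
    good = line_tree([("pLAD", 0, 19), ("mLAD", 19, 40)])
    bad = line_tree([("pLAD", 0, 5), ("mLAD", 5, 40)])
    assert segment_recovery(good, ref) == {"pLAD": True, "mLAD": True}
    assert segment_recovery(bad, ref)["pLAD"] is False
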