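"""Evaluation of coronary segment labelings.

Per-segment presence is scored across cases as a binary detection task
(TP: labeled by both prediction and reference; FN: reference only; FP:
prediction only; TN: neither), from which precision, sensitivity
(recall), accuracy and F1 are derived. Labeled extent is scored by
point-wise overlap against the reference, misassignment patterns by a
row-normalized confusion matrix, and inter-rater reliability by
per-segment agreement percentage with optional third-rater adjudication.

Metric conventions: percentages are kept at full precision internally
and rounded half-up to one decimal only for display; zero-denominator
metrics are reported as undefined (NaN), never coerced to 0 or 100;
pooled totals are computed by summing counts, not averaging percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .labeler import SEGMENT_LABELS, LabeledTree

__all__ = [
    "ConfusionCounts",
    "presence_confusion",
    "classification_metrics",
    "overlap_accuracy",
    "segment_overlaps",
    "confusion_matrix",
    "rater_agreement",
    "modification_rate",
    "segment_recovery",
    "display_round",
    "metrics_table",
    "REFERENCE_PRESENCE_COUNTS",
]


#: Per-segment presence confusion counts (TP, TN, FP, FN) from a published
#: 157-patient CCTA reader study of this labeling approach; used as worked
#: examples for the metric formulas and by the reproduction checks.
REFERENCE_PRESENCE_COUNTS = {
    "pRCA": (157, 0, 0, 0),
    "mRCA": (157, 0, 0, 0),
    "dRCA": (156, 1, 0, 0),
    "R-PDA": (139, 16, 1, 1),
    "R-PLB": (94, 30, 0, 33),
    "LM": (157, 0, 0, 0),
    "pLAD": (157, 0, 0, 0),
    "mLAD": (157, 0, 0, 0),
    "dLAD": (156, 0, 1, 0),
    "D1": (152, 3, 0, 2),
    "D2": (110, 29, 12, 6),
    "pCx": (156, 0, 0, 1),
    "LCx": (151, 0, 0, 6),
    "OM1": (128, 19, 1, 9),
    "OM2": (75, 72, 6, 4),
    "RI": (46, 87, 11, 13),
}


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def display_round(value: float, decimals: int = 1) -> float:
    """Half-up rounding for display (matches one-decimal report tables)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return float("nan")
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def presence_confusion(pred_sets, ref_sets, vocabulary=SEGMENT_LABELS) -> dict:
    """Per-label presence confusion over paired per-case label sets."""
    if len(pred_sets) != len(ref_sets):
        raise ValueError("prediction and reference case lists differ in length")
    vocab = set(vocabulary)
    for s in list(pred_sets) + list(ref_sets):
        unknown = set(s) - vocab
        if unknown:
            raise ValueError(f"labels outside the vocabulary: {sorted(unknown)}")
    out = {lab: ConfusionCounts() for lab in vocabulary}
    for pred, ref in zip(pred_sets, ref_sets):
        for lab in vocabulary:
            p, r = lab in pred, lab in ref
            c = out[lab]
            if p and r:
                c.tp += 1
            elif r:
                c.fn += 1
            elif p:
                c.fp += 1
            else:
                c.tn += 1
    return out


def classification_metrics(c: ConfusionCounts) -> dict:
    """Precision, recall, accuracy and F1 as percentages (NaN if undefined)."""
    def ratio(num, den):
        return float("nan") if den == 0 else 100.0 * num / den

    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    accuracy = ratio(c.tp + c.tn, c.total)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "accuracy": accuracy, "f1": f1}


def metrics_table(counts: dict, vocabulary=SEGMENT_LABELS) -> pd.DataFrame:
    """Per-segment metrics plus a pooled total row, display-rounded."""
    rows = []
    total = ConfusionCounts()
    for lab in vocabulary:
        c = counts[lab]
        total = total + c
        m = classification_metrics(c)
        rows.append(
            dict(Segment=lab, TP=c.tp, TN=c.tn, FP=c.fp, FN=c.fn,
                 **{k.capitalize(): display_round(v) for k, v in m.items()})
        )
    m = classification_metrics(total)
    rows.append(
        dict(Segment="In total", TP=total.tp, TN=total.tn, FP=total.fp, FN=total.fn,
             **{k.capitalize(): display_round(v) for k, v in m.items()})
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# point-wise comparisons
# ---------------------------------------------------------------------------

def _match_labels(pred: LabeledTree, ref: LabeledTree, tol: float, strict: bool = True):
    """Predicted label of the nearest predicted point, per reference point.

    Reference points with no predicted point within ``tol`` mm get label
    ``None``. When ``strict``, errors out if more than 5% of reference
    points are unmatched — the labelings then do not describe the same
    centerlines. Non-strict matching treats unmatched points as unlabeled
    (used when scoring predictions that may omit whole branches).
    """
    ref_pts, ref_lab = ref.points_and_labels()
    pred_pts, pred_lab = pred.points_and_labels()
    if len(ref_pts) == 0:
        raise ValueError("reference labeling has no points")
    matched = np.full(len(ref_pts), None, dtype=object)
    if len(pred_pts):
        d, i = cKDTree(pred_pts).query(ref_pts)
        ok = d <= tol
        matched[ok] = pred_lab[i[ok]]
    frac_unmatched = float(np.mean(matched == None))  # noqa: E711
    if strict and frac_unmatched > 0.05 and len(pred_pts):
        raise ValueError(
            f"{frac_unmatched:.0%} of reference points have no predicted point "
            f"within {tol} mm; labelings are not comparable"
        )
    return ref_lab, matched


def overlap_accuracy(pred: LabeledTree, ref: LabeledTree, segment: str,
                     tol: float = 1.0, mode: str = "recall", strict: bool = True) -> float:
    """Percentage of reference ``segment`` points labeled ``segment`` in pred.

    ``mode="recall"`` (default): |both| / |ref|. ``mode="dice"``:
    2·|both| / (|ref| + |pred|), a symmetric alternative for sensitivity
    analysis. NaN when the reference contains no such points.
    """
    if segment not in SEGMENT_LABELS:
        raise ValueError(f"unknown segment {segment!r}")
    ref_lab, matched = _match_labels(pred, ref, tol, strict=strict)
    ref_mask = ref_lab == segment
    n_ref = int(ref_mask.sum())
    if n_ref == 0:
        return float("nan")
    n_both = int(np.sum(matched[ref_mask] == segment))
    if mode == "recall":
        return 100.0 * n_both / n_ref
    if mode == "dice":
        _, pred_lab = pred.points_and_labels()
        n_pred = int(np.sum(pred_lab == segment))
        if n_ref + n_pred == 0:
            return float("nan")
        return 100.0 * 2 * n_both / (n_ref + n_pred)
    raise ValueError(f"unknown overlap mode {mode!r}")


def segment_overlaps(pred: LabeledTree, ref: LabeledTree, tol: float = 1.0,
                     mode: str = "recall", strict: bool = True) -> dict:
    """Overlap percentage for every segment present in the reference."""
    return {
        lab: overlap_accuracy(pred, ref, lab, tol=tol, mode=mode, strict=strict)
        for lab in SEGMENT_LABELS
        if lab in ref.labels_present()
    }


def confusion_matrix(pred: LabeledTree, ref: LabeledTree, tol: float = 1.0) -> pd.DataFrame:
    """Row-normalized point-wise confusion matrix over the 16 labels.

    Entry (i, j): fraction of reference-label-i points whose nearest
    predicted point carries label j; an extra ``unlabeled`` column
    absorbs reference points with no match. Rows sum to 1.
    """
    ref_lab, matched = _match_labels(pred, ref, tol)
    cols = list(SEGMENT_LABELS) + ["unlabeled"]
    mat = pd.DataFrame(0.0, index=list(SEGMENT_LABELS), columns=cols)
    for lab in SEGMENT_LABELS:
        mask = ref_lab == lab
        n = int(mask.sum())
        if n == 0:
            continue
        got = matched[mask]
        for col in SEGMENT_LABELS:
            mat.loc[lab, col] = np.sum(got == col) / n
        mat.loc[lab, "unlabeled"] = np.sum(got == None) / n  # noqa: E711
    return mat


def segment_recovery(pred: LabeledTree, ref: LabeledTree, tol: float = 2.0,
                     min_overlap: float = 50.0) -> dict:
    """Per present reference segment: was it recovered by the prediction?

    A segment counts as recovered when the prediction emits the label and
    at least ``min_overlap`` percent of the reference points of that
    segment map to predicted points carrying it.
    """
    out = {}
    for lab in sorted(ref.labels_present()):
        if lab not in pred.labels_present():
            out[lab] = False
            continue
        ov = overlap_accuracy(pred, ref, lab, tol=tol, strict=False)
        out[lab] = bool(not np.isnan(ov) and ov >= min_overlap)
    return out


# ---------------------------------------------------------------------------
# raters
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    per_segment: dict  # label -> agreement percentage
    consensus: list  # per-case consensus label sets
    unresolved: list  # (case index, label) pairs with no adjudicator


def rater_agreement(r1, r2, adjudicator=None, vocabulary=SEGMENT_LABELS) -> AgreementReport:
    """Two-rater per-segment agreement with optional third-rater adjudication.

    ``r1``/``r2`` are per-case label sets. Agreement per segment is the
    percentage of cases where both raters make the same presence call.
    Disagreements take the adjudicator's call when given, else the case is
    flagged unresolved (rater 1's call is carried into the consensus).
    """
    if len(r1) != len(r2) or (adjudicator is not None and len(adjudicator) != len(r1)):
        raise ValueError("rater case lists differ in length")
    n = len(r1)
    if n == 0:
        raise ValueError("no cases to compare")
    agree = {lab: 0 for lab in vocabulary}
    consensus = []
    unresolved = []
    for i, (a, b) in enumerate(zip(r1, r2)):
        cons = set()
        for lab in vocabulary:
            pa, pb = lab in a, lab in b
            if pa == pb:
                agree[lab] += 1
                if pa:
                    cons.add(lab)
            elif adjudicator is not None:
                if lab in adjudicator[i]:
                    cons.add(lab)
            else:
                unresolved.append((i, lab))
                if pa:
                    cons.add(lab)
        consensus.append(cons)
    per_segment = {lab: 100.0 * c / n for lab, c in agree.items()}
    return AgreementReport(per_segment, consensus, unresolved)


def modification_rate(modified: int, total: int) -> float:
    """Percentage of labels the reviewers had to modify or eliminate."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= modified <= total:
        raise ValueError("modified must lie in [0, total]")
    return 100.0 * modified / total
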