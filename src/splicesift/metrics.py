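"""Intron- and transcript-level agreement metrics and ranking summaries.

Junction-level classification uses the junction score = min(donor score,
acceptor score) throughout.  Intron matching is strand-aware, except that
unstranded observed junctions (strand '.') match a reference intron on
either strand, since alignment-derived junctions may lack strand evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PRPoint",
    "MatchCounts",
    "intron_precision_recall",
    "transcript_match_stats",
    "threshold_sweep",
    "roc_pr_auc",
    "score_difference_summary",
]


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fp: int
    fn: int


def _junction_keys(junctions):
    keys = set()
    for j in junctions:
        keys.add(j.key if hasattr(j, "key") else tuple(j))
    return keys


def intron_precision_recall(observed, reference):
    """(precision, recall, MatchCounts) of observed vs reference intron sets.

    Sets are keyed by (chrom, start, end, strand); an observed intron with
    strand '.' counts as a match if the reference holds either orientation.
    Empty denominators yield NaN.
    """
    obs = _junction_keys(observed)
    ref = _junction_keys(reference)

    def matches(key):
        if key in ref:
            return True
        c, s, e, strand = key
        return strand == "." and ((c, s, e, "+") in ref or (c, s, e, "-") in ref)

    tp_keys = {k for k in obs if matches(k)}
    tp = len(tp_keys)
    fp = len(obs) - tp
    matched_ref = set()
    for c, s, e, strand in tp_keys:
        if (c, s, e, strand) in ref:
            matched_ref.add((c, s, e, strand))
        else:
            matched_ref.update(k for k in ((c, s, e, "+"), (c, s, e, "-")) if k in ref)
    fn = len(ref) - len(matched_ref)
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return precision, recall, MatchCounts(tp, fp, fn)


def transcript_match_stats(assembled_chains, reference_chains):
    """(n_matching, precision) under strict intron-chain equality.

    A transcript is an intron chain: (chrom, strand, ((s1, e1), (s2, e2), ...)).
    Single-exon transcripts are compared by their exon interval instead:
    (chrom, strand, ((start, end),)) with an empty intron chain represented
    by the exon interval itself.
    """
    assembled = list(assembled_chains)
    ref = set(reference_chains)
    n_match = sum(1 for chain in assembled if chain in ref)
    precision = n_match / len(assembled) if assembled else float("nan")
    return n_match, precision


def threshold_sweep(scores, labels, grid):
    """Precision/recall/F1 at each threshold; returns (points, best_threshold).

    Predictions are positive iff score >= threshold.  The best threshold
    maximizes F1, ties broken toward the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("threshold sweep needs both classes present")
    points = []
    for t in grid:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        points.append(PRPoint(float(t), precision, recall, f1))
    best = max(points, key=lambda p: (p.f1, -p.threshold))
    return points, best.threshold


def roc_pr_auc(scores, labels):
    """(AUROC, AUPR).

    AUROC is the Mann-Whitney rank statistic (ties counted half), equal to
    trapezoidal integration of the ROC curve.  AUPR is the step integration
    of the precision-recall curve (average precision).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC/AUPR need both classes present")
    ranks = rankdata(scores)
    auroc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_labels)
    n = np.arange(1, len(labels) + 1)
    precision = tp / n
    recall = tp / n_pos
    # collapse tied scores to the last (most permissive) point of each block
    block_end = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    precision, recall = precision[block_end], recall[block_end]
    drecall = np.diff(np.r_[0.0, recall])
    aupr = float(np.sum(precision * drecall))
    return float(auroc), aupr


def score_difference_summary(scored, exclusion_band: tuple[float, float] | None = None):
    """Signed (donor - acceptor) score differences with quantiles.

    ``exclusion_band=(lo, hi)`` drops differences inside the open interval
    (lo, hi) to focus on junctions whose two scores diverge.
    Returns (differences, {quantile: value}).
    """
    diffs = np.array([s.donor - s.acceptor for s in scored], dtype=float)
    if exclusion_band is not None:
        lo, hi = exclusion_band
        diffs = diffs[(diffs <= lo) | (diffs >= hi)]
    qs = (0.0, 0.25, 0.5, 0.75, 1.0)
    quantiles = (
        {q: float(v) for q, v in zip(qs, np.quantile(diffs, qs))}
        if diffs.size
        else {q: float("nan") for q in qs}
    )
    return diffs, quantiles
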