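"""Ranking evaluation metrics for per-drug target predictions.

Eight metrics in three families: overall ranking quality (AuROC, AuPRC),
early recognition (BEDROC with decay 20, precision and recall of the top-20
predictions) and binary classification at the best threshold (maximum MCC,
F1 and balanced accuracy over all score thresholds).

Targets disconnected from the training network can never be predicted and
are masked out before any metric is computed.  Metrics that are undefined
for a ranking (e.g. AuROC without both a positive and a negative) are
returned as NaN and counted as skipped by the validation harnesses.

Top-k retrieval only counts targets with a strictly positive score: a zero
resource score means the method made no prediction for that target (the
query-target pair is outside the diffusion's reach), so it is not treated
as retrieved even when the target panel is smaller than k.  The P@k
denominator remains k regardless of panel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

METRIC_NAMES = (
    "auroc", "auprc", "bedroc", "p_at_k", "r_at_k", "max_mcc", "max_f1", "max_bacc",
)

#: Exponential decay of the early-recognition weight in BEDROC.
BEDROC_ALPHA = 20.0
#: Ranking cut for precision/recall at k.
TOP_K = 20


@dataclass(frozen=True)
class LabeledRanking:
    """Scores and binary labels over a target panel, with an evaluable mask."""

    target_ids: tuple[str, ...]
    scores: np.ndarray
    labels: np.ndarray
    mask: np.ndarray = field(default=None)  # True = evaluable

    def __post_init__(self) -> None:
        n = len(self.target_ids)
        if self.scores.shape != (n,) or self.labels.shape != (n,):
            raise ValueError("scores/labels length mismatch")
        if self.mask is None:
            object.__setattr__(self, "mask", np.ones(n, dtype=bool))
        if self.mask.shape != (n,):
            raise ValueError("mask length mismatch")

    def evaluable(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(ids, scores, labels) restricted to unmasked targets."""
        ids = np.array(self.target_ids)[self.mask]
        return ids, self.scores[self.mask], self.labels[self.mask].astype(bool)


def _ranked_order(ids: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Deterministic ranking order: score descending, target ID ascending."""
    return np.lexsort((ids, -scores))


def auroc(r: LabeledRanking) -> float:
    """Probability that a random positive outscores a random negative.

    Computed from average ranks (ties count one half), the Mann-Whitney
    formulation.  NaN if either class is empty.
    """
    _, scores, labels = r.evaluable()
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # average ranks, ascending
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def auprc(r: LabeledRanking) -> float:
    """Area under the precision-recall curve as average precision.

    Step-wise (average-precision) interpolation, which never over-credits
    the region between operating points.  NaN without a positive.
    """
    _, scores, labels = r.evaluable()
    if labels.sum() == 0:
        return float("nan")
    if (~labels).sum() == 0:
        return 1.0
    return float(average_precision_score(labels, scores))


def bedroc(r: LabeledRanking, alpha: float = BEDROC_ALPHA) -> float:
    """Boltzmann-enhanced discrimination of ROC (early-recognition weight).

    Exponentially down-weights positions deep in the ranked list with decay
    ``alpha`` and normalises the resulting enrichment onto [0, 1] so that 1
    means all positives lead the ranking and 0 means they trail it.
    """
    ids, scores, labels = r.evaluable()
    n = int(labels.sum())
    N = len(labels)
    if n == 0 or n == N:
        return float("nan")
    order = _ranked_order(ids, scores)
    pos_ranks = np.nonzero(labels[order])[0] + 1  # 1-based ranks
    ra = n / N
    s = np.exp(-alpha * pos_ranks / N).sum()
    rie = s / (ra * (1 - np.exp(-alpha)) / (np.exp(alpha / N) - 1))
    factor = ra * np.sinh(alpha / 2) / (np.cosh(alpha / 2) - np.cosh(alpha / 2 - alpha * ra))
    return float(rie * factor + 1 / (1 - np.exp(alpha * (1 - ra))))


def precision_recall_at_k(r: LabeledRanking, k: int = TOP_K) -> tuple[float, float]:
    """(P@k, R@k) of the top-k strictly positive-scoring predictions.

    P@k keeps denominator k even when fewer than k targets exist or carry a
    prediction; R@k is NaN when the ranking holds no positive at all.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ids, scores, labels = r.evaluable()
    n_pos = int(labels.sum())
    order = _ranked_order(ids, scores)
    predicted = order[scores[order] > 0][:k]
    hits = int(labels[predicted].sum())
    p_at_k = hits / k
    r_at_k = hits / n_pos if n_pos else float("nan")
    return p_at_k, r_at_k


def max_threshold_metrics(r: LabeledRanking) -> tuple[float, float, float]:
    """(max MCC, max F1, max bACC) over all observed score thresholds.

    Every distinct score is used as an inclusive threshold (predict positive
    when score >= threshold); each metric's maximum is taken independently.
    Degenerate denominators contribute 0, the conventional MCC/F1 fallback.
    """
    ids, scores, labels = r.evaluable()
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return (float("nan"),) * 3
    order = _ranked_order(ids, scores)
    s_sorted = scores[order]
    l_sorted = labels[order].astype(int)
    tp_cum = np.cumsum(l_sorted)
    fp_cum = np.cumsum(1 - l_sorted)
    # thresholds at the last index of each distinct score (inclusive cut)
    cut = np.nonzero(np.diff(s_sorted, append=-np.inf) != 0)[0]
    tp = tp_cum[cut].astype(float)
    fp = fp_cum[cut].astype(float)
    fn = n_pos - tp
    tn = n_neg - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = np.where(mcc_den > 0, (tp * tn - fp * fn) / mcc_den, 0.0)
        f1_den = 2 * tp + fp + fn
        f1 = np.where(f1_den > 0, 2 * tp / f1_den, 0.0)
        bacc = 0.5 * (tp / n_pos + tn / n_neg)
    return float(mcc.max()), float(f1.max()), float(bacc.max())


def score_ranking(r: LabeledRanking, k: int = TOP_K, bedroc_alpha: float = BEDROC_ALPHA) -> dict[str, float]:
    """All eight metrics for one ranking, NaN where undefined."""
    p_at_k, r_at_k = precision_recall_at_k(r, k)
    mcc, f1, bacc = max_threshold_metrics(r)
    return {
        "auroc": auroc(r),
        "auprc": auprc(r),
        "bedroc": bedroc(r, bedroc_alpha),
        "p_at_k": p_at_k,
        "r_at_k": r_at_k,
        "max_mcc": mcc,
        "max_f1": f1,
        "max_bacc": bacc,
    }
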