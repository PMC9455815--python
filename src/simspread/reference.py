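"""Slow, per-node reference implementations used to verify the vectorised core.

Everything here is written as explicit loops over nodes, pairs or
thresholds, mirroring the procedural description of each algorithm, and is
deliberately independent of the matrix-product code paths in
:mod:`simspread.network`, :mod:`simspread.baselines` and
:mod:`simspread.metrics`.  The test suite asserts agreement between the two
routes on randomised instances; these functions are never used for
production predictions.
"""

from __future__ import annotations

import math

import numpy as np

from .metrics import LabeledRanking
from .network import TripartiteNetwork


def traversal_spread(
    net: TripartiteNetwork, query_features: np.ndarray, propagation: str = "weighted"
) -> dict[str, np.ndarray]:
    """Two-round diffusion done edge by edge with dictionaries of resources."""
    nF, nD, nT = len(net.feature_ids), len(net.drug_ids), len(net.target_ids)
    q = np.asarray(query_features, dtype=float)
    rF = {i: q[i] for i in range(nF)}
    rD = {j: 0.0 for j in range(nD)}
    rT = {k: 0.0 for k in range(nT)}

    def weight(w: float) -> float:
        return 1.0 if propagation == "binary" and w > 0 else (w if w > 0 else 0.0)

    # round 1: F -> D
    for i in range(nF):
        degree = sum(weight(net.FD[i, j]) for j in range(nD))
        if degree == 0 or rF[i] == 0:
            continue
        share = rF[i] / degree
        for j in range(nD):
            if net.FD[i, j] > 0:
                rD[j] += share * weight(net.FD[i, j])
        rF[i] = 0.0
    # round 2: D -> F and D -> T jointly
    rF2 = {i: 0.0 for i in range(nF)}
    for j in range(nD):
        degree = sum(weight(net.FD[i, j]) for i in range(nF)) + sum(
            1.0 for k in range(nT) if net.DT[j, k] > 0
        )
        if degree == 0 or rD[j] == 0:
            continue
        share = rD[j] / degree
        for i in range(nF):
            if net.FD[i, j] > 0:
                rF2[i] += share * weight(net.FD[i, j])
        for k in range(nT):
            if net.DT[j, k] > 0:
                rT[k] += share
        rD[j] = 0.0
    return {
        "F2": np.array([rF2[i] for i in range(nF)]),
        "D2": np.array([rD[j] for j in range(nD)]),
        "T2": np.array([rT[k] for k in range(nT)]),
    }


def traversal_nbi(DT: np.ndarray, drug_index: int) -> np.ndarray:
    """Bipartite two-round spreading done node by node."""
    nD, nT = DT.shape
    rT = {k: float(DT[drug_index, k]) for k in range(nT)}
    rD = {j: 0.0 for j in range(nD)}
    for k in range(nT):
        ligands = [j for j in range(nD) if DT[j, k] > 0]
        if not ligands or rT[k] == 0:
            continue
        share = rT[k] / len(ligands)
        for j in ligands:
            rD[j] += share
        rT[k] = 0.0
    out = {k: 0.0 for k in range(nT)}
    for j in range(nD):
        targets = [k for k in range(nT) if DT[j, k] > 0]
        if not targets or rD[j] == 0:
            continue
        share = rD[j] / len(targets)
        for k in targets:
            out[k] += share
    return np.array([out[k] for k in range(nT)])


def pairwise_auroc(r: LabeledRanking) -> float:
    """AuROC as the fraction of concordant positive-negative pairs (ties 1/2)."""
    _, scores, labels = r.evaluable()
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def direct_bedroc(r: LabeledRanking, alpha: float = 20.0) -> float:
    """BEDROC via literal summation of the exponential enrichment terms."""
    ids, scores, labels = r.evaluable()
    N = len(labels)
    n = int(labels.sum())
    if n == 0 or n == N:
        return float("nan")
    ranked = sorted(range(N), key=lambda i: (-scores[i], ids[i]))
    rie_num = sum(
        math.exp(-alpha * (pos + 1) / N)
        for pos, i in enumerate(ranked)
        if labels[i]
    )
    rie_den = (n / N) * (1 - math.exp(-alpha)) / (math.exp(alpha / N) - 1)
    rie = rie_num / rie_den
    ra = n / N
    scale = ra * math.sinh(alpha / 2) / (math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra))
    return rie * scale + 1 / (1 - math.exp(alpha * (1 - ra)))


def brute_force_threshold_metrics(r: LabeledRanking) -> tuple[float, float, float]:
    """Max MCC/F1/bACC by explicitly classifying at every observed score."""
    _, scores, labels = r.evaluable()
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return (float("nan"),) * 3
    best = [-math.inf, -math.inf, -math.inf]
    for threshold in sorted(set(scores)):
        pred = scores >= threshold
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        fn = n_pos - tp
        tn = n_neg - fp
        den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = (tp * tn - fp * fn) / den if den > 0 else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        bacc = 0.5 * (tp / n_pos + tn / n_neg)
        best = [max(best[0], mcc), max(best[1], f1), max(best[2], bacc)]
    return tuple(best)  # type: ignore[return-value]
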