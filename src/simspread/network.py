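"""De novo network-based inference on a compound-feature-drug-target graph.

The graph has four node layers: query compounds C, features F, drugs D and
targets T.  Resources start on the feature layer (one vector per query,
given by the query-feature block), then spread in two rounds:

* round 1 — every feature node divides its resource by its (weighted or
  unweighted) degree towards D and hands a share to each linked drug;
* round 2 — every drug node divides its resource by its joint degree over
  F and T and hands shares back to F and forward to T.

The final resources on T are the prediction scores.  Because every node
passes on exactly what it holds, total resource is conserved whenever no
resource sits on a degree-zero node.  A drug-drug-target instantiation
(features are the training drugs themselves, linked by thresholded chemical
similarity) yields the SimSpread method; a substructure-drug-target
instantiation yields SDTNBI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import DescriptorMatrix, build_feature_matrix, pairwise_similarity
from .datasets import InteractionDataset

logger = logging.getLogger(__name__)


class NetworkError(ValueError):
    """Raised on inconsistent network blocks or query vectors."""


@dataclass(frozen=True)
class TripartiteNetwork:
    """Weighted biadjacency blocks of the F-D-T spreading subgraph.

    ``FD`` links features to drugs (non-negative weights), ``DT`` is the
    binary drug-target adjacency.  For SimSpread the feature IDs equal the
    drug IDs; for SDTNBI they are fingerprint bit positions.
    """

    feature_ids: tuple[str, ...]
    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    FD: np.ndarray  # (n_features, n_drugs), weights >= 0
    DT: np.ndarray  # (n_drugs, n_targets), binary

    def __post_init__(self) -> None:
        if self.FD.shape != (len(self.feature_ids), len(self.drug_ids)):
            raise NetworkError("FD block shape mismatch")
        if self.DT.shape != (len(self.drug_ids), len(self.target_ids)):
            raise NetworkError("DT block shape mismatch")
        if (self.FD < 0).any():
            raise NetworkError("FD weights must be non-negative")
        if not np.isin(self.DT, (0, 1)).all():
            raise NetworkError("DT adjacency must be binary")

    @property
    def isolated_drugs(self) -> tuple[str, ...]:
        deg = self.DT.sum(axis=1) + (self.FD > 0).sum(axis=0)
        return tuple(d for d, k in zip(self.drug_ids, deg) if k == 0)


@dataclass(frozen=True)
class PredictionScores:
    """Per-target scores for one query, with deterministic ranking."""

    query: str
    target_ids: tuple[str, ...]
    scores: np.ndarray
    in_domain: bool = True

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.target_ids):
            raise NetworkError("score vector length mismatch")
        if (self.scores < 0).any() or not np.isfinite(self.scores).all():
            raise NetworkError("scores must be finite and non-negative")

    def ranking(self) -> list[str]:
        """Targets ordered by (score desc, target ID asc) — a stable total order."""
        return sorted(self.target_ids, key=lambda t: (-self.scores[self.target_ids.index(t)], t))

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.target_ids), name=self.query)

    def to_frame(self) -> pd.DataFrame:
        order = np.lexsort((np.array(self.target_ids), -self.scores))
        return pd.DataFrame(
            {
                "query": self.query,
                "target": np.array(self.target_ids)[order],
                "score": self.scores[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )


def _spread_operators(net: TripartiteNetwork, propagation: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-stochastic-where-possible operators for the two spreading rounds.

    Returns (W1, W2F, W2T): feature->drug, drug->feature and drug->target
    transfer matrices.  Rows of degree-zero nodes are all-zero (the node
    keeps nothing and passes nothing).
    """
    if propagation == "binary":
        fd = (net.FD > 0).astype(float)
        dt = net.DT.astype(float)
    elif propagation == "weighted":
        fd = net.FD.astype(float)
        dt = net.DT.astype(float)  # DT is binary; weight 1 per annotation
    else:
        raise NetworkError(f"unknown propagation mode {propagation!r}")
    deg_f = fd.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        W1 = np.where(deg_f[:, None] > 0, fd / deg_f[:, None], 0.0)
    joint = fd.sum(axis=0) + dt.sum(axis=1)  # drug degree over F and T jointly
    with np.errstate(invalid="ignore", divide="ignore"):
        W2F = np.where(joint[None, :] > 0, fd / joint[None, :], 0.0).T
        W2T = np.where(joint[:, None] > 0, dt / joint[:, None], 0.0)
    return W1, W2F, W2T


def spread_rounds(
    net: TripartiteNetwork, query_features: np.ndarray, propagation: str = "weighted"
) -> dict[str, np.ndarray]:
    """Run the two spreading rounds, returning the resource state per layer.

    Keys: ``F0`` (initial feature resources), ``D1`` (drug resources after
    round 1), ``F2``/``T2`` (feature and target resources after round 2).
    """
    q = np.asarray(query_features, dtype=float)
    if q.shape != (len(net.feature_ids),):
        raise NetworkError(
            f"query feature vector has length {q.shape}, expected {len(net.feature_ids)}"
        )
    if (q < 0).any():
        raise NetworkError("query features must be non-negative")
    W1, W2F, W2T = _spread_operators(net, propagation)
    d1 = q @ W1
    return {"F0": q, "D1": d1, "F2": d1 @ W2F, "T2": d1 @ W2T}


def denovo_spread(
    net: TripartiteNetwork,
    query_features: np.ndarray,
    propagation: str = "weighted",
    query: str = "query",
) -> PredictionScores:
    """Two-round resource diffusion; scores are the final target resources.

    An all-zero query vector means the query is outside the application
    domain: all scores are zero and the result is flagged, not an error.
    """
    state = spread_rounds(net, query_features, propagation)
    in_domain = bool(np.any(np.asarray(query_features) > 0))
    if not in_domain:
        logger.info("query %r is outside the application domain (no feature links)", query)
    return PredictionScores(query, net.target_ids, state["T2"], in_domain=in_domain)


def build_simspread_network(
    train: InteractionDataset,
    drug_features: DescriptorMatrix,
    alpha: float = 0.2,
    scheme: str = "similarity",
    metric: str = "tanimoto",
) -> TripartiteNetwork:
    """Assemble the drug-drug-target network for SimSpread.

    The feature layer is a copy of the training drugs; the FD block is the
    thresholded drug-drug similarity matrix S'.  Self-similarity is 1, so
    the diagonal always survives the cutoff and every drug keeps a path to
    its own targets.
    """
    train_fp = drug_features.subset(train.drugs)
    S_dd = pairwise_similarity(train_fp, train_fp, metric=metric)
    Sp_dd = build_feature_matrix(S_dd, alpha, scheme)
    DT = np.zeros((train.n_drugs, train.n_targets))
    t_index = {t: j for j, t in enumerate(train.targets)}
    d_index = {d: i for i, d in enumerate(train.drugs)}
    for d, t in train.edges:
        DT[d_index[d], t_index[t]] = 1.0
    return TripartiteNetwork(
        feature_ids=train.drugs,
        drug_ids=train.drugs,
        target_ids=train.targets,
        FD=Sp_dd.values,
        DT=DT,
    )


def simspread_predict(
    train: InteractionDataset,
    drug_features: DescriptorMatrix,
    queries: DescriptorMatrix,
    alpha: float = 0.2,
    scheme: str = "similarity",
    propagation: str = "weighted",
    metric: str = "tanimoto",
) -> list[PredictionScores]:
    """Predict targets for each query compound via similarity-guided spreading.

    Builds S'(query vs training drugs) and S'(drugs vs drugs) at cutoff
    ``alpha``, then runs the two-round diffusion with each query's S' row as
    its initial feature resources.  Queries whose S' row is all zero fall
    outside the application domain and receive all-zero, flagged scores.
    """
    net = build_simspread_network(train, drug_features, alpha, scheme, metric)
    train_fp = drug_features.subset(train.drugs)
    S_qd = pairwise_similarity(queries, train_fp, metric=metric)
    Sp_qd = build_feature_matrix(S_qd, alpha, scheme)
    return [
        denovo_spread(net, Sp_qd.values[i], propagation, query=qid)
        for i, qid in enumerate(queries.ids)
    ]


def write_predictions(predictions: list[PredictionScores], path) -> None:
    """Serialise rankings as TSV (query, target, score, rank)."""
    pd.concat([p.to_frame() for p in predictions], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
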