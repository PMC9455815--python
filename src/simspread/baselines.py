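"""Comparison methods: bipartite NBI, substructure-based SDTNBI, and k-NN.

NBI is the classical two-round recommender diffusion on the bipartite
drug-target graph and can only score drugs already in the network.  SDTNBI
replaces the drug layer of the de novo spreading core with fingerprint
substructure bits, which lets it score unseen compounds.  k-NN scores each
target by the similarity of the query to the target's most similar
annotated ligand (k = 1 by default; for k > 1 the top-k similarities are
averaged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import DescriptorMatrix, SimilarityMatrix
from .datasets import InteractionDataset
from .network import NetworkError, PredictionScores, TripartiteNetwork, denovo_spread


@dataclass(frozen=True)
class BipartiteNetwork:
    """Binary drug-target adjacency with ordered ID lists."""

    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    DT: np.ndarray

    def __post_init__(self) -> None:
        if self.DT.shape != (len(self.drug_ids), len(self.target_ids)):
            raise NetworkError("DT shape mismatch")
        if not np.isin(self.DT, (0, 1)).all():
            raise NetworkError("DT adjacency must be binary")

    @classmethod
    def from_dataset(cls, ds: InteractionDataset) -> "BipartiteNetwork":
        DT = np.zeros((ds.n_drugs, ds.n_targets))
        di = {d: i for i, d in enumerate(ds.drugs)}
        ti = {t: j for j, t in enumerate(ds.targets)}
        for d, t in ds.edges:
            DT[di[d], ti[t]] = 1.0
        return cls(ds.drugs, ds.targets, DT)


def nbi_predict(net: BipartiteNetwork, drug: str) -> PredictionScores:
    """Two-round degree-normalised spreading from one network drug.

    One unit of resource is placed on each of the drug's annotated targets;
    targets split their unit equally over their ligands, and ligands split
    what they received equally over their targets.  The returned scores are
    the final target resources; their total equals the number of annotated
    targets of the query (conservation).  An isolated drug yields all-zero
    scores.
    """
    if drug not in net.drug_ids:
        raise NetworkError(f"drug {drug!r} is not part of the network")
    A = net.DT
    r_t0 = A[net.drug_ids.index(drug)].astype(float)  # unit per annotated target
    deg_t = A.sum(axis=0)
    deg_d = A.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        # target -> drug: column-normalised; drug -> target: row-normalised
        T2D = np.where(deg_t[None, :] > 0, A / deg_t[None, :], 0.0)  # (d, t) entries
        D2T = np.where(deg_d[:, None] > 0, A / deg_d[:, None], 0.0)
    r_d = T2D @ r_t0
    r_t = r_d @ D2T
    return PredictionScores(drug, net.target_ids, r_t, in_domain=bool(r_t0.any()))


def sdtnbi_network(train: InteractionDataset, substructures: DescriptorMatrix) -> TripartiteNetwork:
    """Assemble the substructure-drug-target network for SDTNBI."""
    if substructures.kind != "binary":
        raise NetworkError("SDTNBI requires binary substructure fingerprints")
    fp = substructures.subset(train.drugs)
    n_bits = fp.values.shape[1]
    DT = BipartiteNetwork.from_dataset(train).DT
    return TripartiteNetwork(
        feature_ids=tuple(f"bit{i}" for i in range(n_bits)),
        drug_ids=train.drugs,
        target_ids=train.targets,
        FD=fp.values.T.astype(float),
        DT=DT,
    )


def sdtnbi_predict(
    train: InteractionDataset,
    substructures: DescriptorMatrix,
    query_bits: np.ndarray,
    query: str = "query",
) -> PredictionScores:
    """De novo spreading with fingerprint bits as the feature layer.

    Delegates to the shared spreading core with binary propagation; a query
    sharing no bit with the training substructure vocabulary receives
    all-zero scores.
    """
    net = sdtnbi_network(train, substructures)
    return denovo_spread(net, np.asarray(query_bits, dtype=float), "binary", query=query)


def knn_predict(
    train: InteractionDataset,
    similarities: SimilarityMatrix,
    query: str,
    k: int = 1,
) -> PredictionScores:
    """Similarity-to-nearest-ligand scoring.

    score(query, t) is the mean of the k highest similarities between the
    query and t's annotated ligands (k = 1: the plain maximum).  Targets
    without annotated ligands score 0.  Duplicated ligand entries cannot
    change the score because edges are a set.
    """
    if k < 1:
        raise NetworkError("k must be >= 1")
    sims = similarities.values[similarities.row_ids.index(query)]
    col = {d: j for j, d in enumerate(similarities.col_ids)}
    scores = np.zeros(train.n_targets)
    for j, t in enumerate(train.targets):
        ligands = train.drugs_of(t)
        if not ligands:
            continue
        vals = np.sort([sims[col[d]] for d in ligands])[::-1]
        scores[j] = float(vals[: min(k, len(vals))].mean())
    return PredictionScores(query, train.targets, scores)
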