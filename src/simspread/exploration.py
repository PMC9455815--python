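"""Chemical and biological space exploration of high-scoring predictions.

Given the pooled prediction list of a validation run, this module measures
how diverse the top-L predicted interactions are: how many distinct Murcko
scaffolds their ligands span (split into scaffolds already seen in training
vs. novel ones — the scaffold-hopping signal) and how many distinct targets
they cover (the target-hopping signal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import InteractionDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScaffoldRecord:
    compound: str
    scaffold: str  # canonical SMILES; "" for acyclic molecules
    novelty: str  # "known" | "novel"


@dataclass(frozen=True)
class TargetAnnotation:
    """Binary GO-term presence vector for one target over a shared vocabulary."""

    target: str
    terms: frozenset[str]

    def vector(self, vocabulary: tuple[str, ...]) -> np.ndarray:
        return np.array([term in self.terms for term in vocabulary], dtype=np.uint8)


def murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko framework (rings + linkers, side chains removed).

    Acyclic molecules have no framework; the empty string is returned and a
    warning logged.
    """
    from rdkit import Chem
    from rdkit.Chem.Scaffolds import MurckoScaffold

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r}")
    scaffold = MurckoScaffold.MurckoScaffoldSmiles(mol=mol)
    if not scaffold:
        logger.warning("molecule %r is acyclic: empty scaffold", smiles)
    return scaffold


def scaffold_table(
    structures: dict[str, str], train_structures: dict[str, str]
) -> list[ScaffoldRecord]:
    """Classify each compound's scaffold as known (seen in training) or novel."""
    train_scaffolds = {murcko_scaffold(s) for s in train_structures.values()}
    out = []
    for cid, smi in structures.items():
        scaf = murcko_scaffold(smi)
        out.append(ScaffoldRecord(cid, scaf, "known" if scaf in train_scaffolds else "novel"))
    return out


def read_annotations(path) -> list[TargetAnnotation]:
    """Read a TSV of (target, GO term) rows into per-target term sets."""
    frame = pd.read_csv(path, sep="\t", names=["target", "term"], header=None, skiprows=_sniff_header(path))
    grouped = frame.groupby("target")["term"].apply(frozenset)
    return [TargetAnnotation(str(t), terms) for t, terms in grouped.items()]


def _sniff_header(path) -> int:
    with open(path) as fh:
        first = fh.readline()
    return 1 if first.lower().startswith("target") else 0


def annotation_matrix(annotations: list[TargetAnnotation]) -> pd.DataFrame:
    """Binary target x GO-term matrix over the union vocabulary."""
    vocabulary = tuple(sorted(set().union(*(a.terms for a in annotations)) if annotations else ()))
    return pd.DataFrame(
        [a.vector(vocabulary) for a in annotations],
        index=[a.target for a in annotations],
        columns=list(vocabulary),
    )


def pool_predictions(predictions: pd.DataFrame) -> pd.DataFrame:
    """Sort pooled (query, target, score) rows by score with deterministic ties."""
    required = {"query", "target", "score"}
    if not required <= set(predictions.columns):
        raise ValueError(f"prediction table needs columns {sorted(required)}")
    return predictions.sort_values(
        ["score", "query", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)


def diversity_curves(
    predictions: pd.DataFrame,
    train: InteractionDataset,
    test_structures: dict[str, str],
    train_structures: dict[str, str],
    L_grid=None,
) -> pd.DataFrame:
    """Unique-scaffold and unique-target counts among the top-L predictions.

    ``predictions`` is the pooled (query, target, score) table of a run;
    pooling and ranking are global over all query-target pairs.  For each L
    in the grid (default 10..1000 step 10) the top-L rows are cut and the
    number of distinct known scaffolds, novel scaffolds and targets counted.
    An L beyond the available predictions is truncated with a warning.
    """
    if L_grid is None:
        L_grid = range(10, 1001, 10)
    pooled = pool_predictions(predictions)
    records = {r.compound: r for r in scaffold_table(test_structures, train_structures)}
    rows = []
    for L in L_grid:
        if L > len(pooled):
            logger.warning("top-L=%d exceeds %d available predictions; truncating", L, len(pooled))
        top = pooled.head(L)
        scafs = {records[q].scaffold: records[q].novelty for q in top["query"] if q in records}
        rows.append({
            "L": int(L),
            "n_known_scaffolds": sum(1 for v in scafs.values() if v == "known"),
            "n_novel_scaffolds": sum(1 for v in scafs.values() if v == "novel"),
            "n_unique_targets": top["target"].nunique(),
        })
    return pd.DataFrame(rows)


def embed_2d(vectors: np.ndarray, seed: int = 0) -> np.ndarray:
    """2D UMAP embedding of binary vectors, for plotting only.

    Deterministic for a fixed seed.  Requires the optional ``umap-learn``
    dependency; never feeds any metric.
    """
    vectors = np.asarray(vectors)
    if vectors.shape[0] < 3:
        raise ValueError("need at least 3 rows to embed")
    import umap

    reducer = umap.UMAP(
        n_components=2, random_state=seed,
        n_neighbors=min(15, vectors.shape[0] - 1), metric="jaccard",
    )
    return np.asarray(reducer.fit_transform(vectors), dtype=float)
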