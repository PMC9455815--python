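"""Molecular descriptors, pairwise similarity, and the thresholded feature matrix.

Compounds are described either by binary fingerprints (ECFP4/FCFP4/MACCS or a
Daylight-style path fingerprint) computed with RDKit, or by any precomputed
real-valued descriptor matrix imported from TSV.  Similarities are Tanimoto
(binary or continuous form) or the asymmetric Tversky index.  The feature
matrix S' applies a similarity cutoff alpha and one of two weighting schemes:

    S'_ij = w(i, j)  if S_ij >= alpha,   0 otherwise,

with w(i, j) = 1 under the binary scheme and w(i, j) = S_ij under the
similarity scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUPPORTED_DESCRIPTORS = ("ecfp4", "fcfp4", "maccs", "fp2")

#: Fold length for hashed fingerprints.
DEFAULT_N_BITS = 4096


class ChemError(ValueError):
    """Raised on invalid structures, descriptors or similarity arguments."""


@dataclass(frozen=True)
class DescriptorMatrix:
    """Per-compound descriptor vectors (binary fingerprints or continuous).

    Continuous matrices are column-normalised to [0, 1] with
    :func:`normalize_columns` before continuous-Tanimoto use; constant
    columns normalise to 0 so that similarities stay finite.
    """

    ids: tuple[str, ...]
    values: np.ndarray  # shape (n_compounds, n_features)
    kind: str = "binary"  # "binary" | "continuous"

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or len(self.ids) != self.values.shape[0]:
            raise ChemError("descriptor matrix shape does not match ID list")
        if self.kind not in ("binary", "continuous"):
            raise ChemError(f"unknown descriptor kind {self.kind!r}")
        if self.kind == "binary" and not np.isin(self.values, (0, 1)).all():
            raise ChemError("binary descriptor matrix contains values outside {0,1}")

    def row(self, cid: str) -> np.ndarray:
        try:
            return self.values[self.ids.index(cid)]
        except ValueError as exc:
            raise ChemError(f"no descriptor row for compound {cid!r}") from exc

    def subset(self, ids) -> "DescriptorMatrix":
        idx = [self.ids.index(c) for c in ids]
        return DescriptorMatrix(tuple(ids), self.values[idx], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise similarities between a row set and a column set of compounds."""

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ChemError("similarity matrix shape mismatch")
        if np.nanmin(self.values) < -1e-12 or np.nanmax(self.values) > 1 + 1e-12:
            raise ChemError("similarity values outside [0, 1]")


@dataclass(frozen=True)
class FeatureMatrix:
    """Thresholded, weighted similarity matrix S' (the query/feature links)."""

    similarity: SimilarityMatrix
    alpha: float
    scheme: str  # "binary" | "similarity"
    values: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ChemError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.scheme not in ("binary", "similarity"):
            raise ChemError(f"unknown weighting scheme {self.scheme!r}")
        keep = self.similarity.values >= self.alpha
        if self.scheme == "binary":
            vals = keep.astype(float)
        else:
            vals = np.where(keep, self.similarity.values, 0.0)
        object.__setattr__(self, "values", vals)

    @property
    def row_ids(self) -> tuple[str, ...]:
        return self.similarity.row_ids

    @property
    def col_ids(self) -> tuple[str, ...]:
        return self.similarity.col_ids


def _mol_from_smiles(smi: str, cid: str):
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise ChemError(f"could not parse SMILES for compound {cid!r}: {smi!r}")
    return mol


def compute_fingerprints(
    smiles: dict[str, str], descriptor: str = "ecfp4", n_bits: int = DEFAULT_N_BITS
) -> DescriptorMatrix:
    """Compute binary fingerprints for a set of SMILES.

    Supported descriptors: ``ecfp4`` (Morgan radius 2), ``fcfp4`` (Morgan
    radius 2 with pharmacophoric invariants), ``maccs`` (166 keys), ``fp2``
    (Daylight-style path fingerprint up to length 7, the closest RDKit
    analog of OpenBabel's FP2).  Hashed fingerprints are folded to ``n_bits``.
    """
    from rdkit.Chem import MACCSkeys, RDKFingerprint
    from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator, GetMorganFeatureAtomInvGen

    name = descriptor.lower()
    if name not in SUPPORTED_DESCRIPTORS:
        raise ChemError(
            f"unsupported descriptor {descriptor!r}; supported: {', '.join(SUPPORTED_DESCRIPTORS)}"
        )
    rows = []
    ids = tuple(smiles)
    for cid in ids:
        mol = _mol_from_smiles(smiles[cid], cid)
        if name in ("ecfp4", "fcfp4"):
            gen = GetMorganGenerator(
                radius=2,
                fpSize=n_bits,
                atomInvariantsGenerator=GetMorganFeatureAtomInvGen() if name == "fcfp4" else None,
            )
            fp = gen.GetFingerprint(mol)
        elif name == "maccs":
            fp = MACCSkeys.GenMACCSKeys(mol)
        else:  # fp2
            fp = RDKFingerprint(mol, maxPath=7, fpSize=n_bits)
        arr = np.zeros(fp.GetNumBits(), dtype=np.uint8)
        for bit in fp.GetOnBits():
            arr[bit] = 1
        rows.append(arr)
    return DescriptorMatrix(ids, np.asarray(rows), kind="binary")


def normalize_columns(values: np.ndarray) -> np.ndarray:
    """Min-max normalise each column to [0, 1]; constant columns map to 0."""
    values = np.asarray(values, dtype=float)
    lo = values.min(axis=0)
    span = values.max(axis=0) - lo
    out = np.zeros_like(values)
    ok = span > 0
    out[:, ok] = (values[:, ok] - lo[ok]) / span[ok]
    return out


def tanimoto(a: np.ndarray, b: np.ndarray, kind: str = "binary") -> float:
    """Tanimoto similarity of two descriptor vectors.

    Binary form |a & b| / |a | b|; continuous form
    sum(ab) / (sum(a^2) + sum(b^2) - sum(ab)).  The empty/empty case (0/0)
    is defined as 0: an empty fingerprint should not link compounds.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ChemError("descriptor vectors differ in length")
    ab = float(a @ b)
    denom = float(a @ a) + float(b @ b) - ab
    return ab / denom if denom > 0 else 0.0


def tversky(a: np.ndarray, b: np.ndarray, alpha: float = 0.0, beta: float = 1.0) -> float:
    """Tversky index |a&b| / (|a&b| + alpha*|a\\b| + beta*|b\\a|) for bit vectors."""
    if alpha < 0 or beta < 0:
        raise ChemError("Tversky weights must be non-negative")
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ChemError("descriptor vectors differ in length")
    common = float(np.count_nonzero(a & b))
    only_a = float(np.count_nonzero(a & ~b))
    only_b = float(np.count_nonzero(b & ~a))
    denom = common + alpha * only_a + beta * only_b
    return common / denom if denom > 0 else 0.0


def pairwise_similarity(
    rows: DescriptorMatrix,
    cols: DescriptorMatrix | None = None,
    metric: str = "tanimoto",
    tversky_alpha: float = 0.0,
    tversky_beta: float = 1.0,
) -> SimilarityMatrix:
    """All-vs-all similarity between two descriptor sets (vectorised).

    With ``cols`` omitted the matrix is square over ``rows``.  Binary
    matrices use bit algebra; continuous matrices must already be
    normalised to [0, 1] (see :func:`normalize_columns`).
    """
    cols = cols if cols is not None else rows
    if rows.kind != cols.kind:
        raise ChemError("cannot mix binary and continuous descriptor matrices")
    A = rows.values.astype(float)
    B = cols.values.astype(float)
    if A.shape[1] != B.shape[1]:
        raise ChemError("descriptor matrices differ in feature length")
    ab = A @ B.T
    if metric == "tanimoto":
        a2 = (A * A).sum(axis=1)[:, None]
        b2 = (B * B).sum(axis=1)[None, :]
        denom = a2 + b2 - ab
    elif metric == "tversky":
        if rows.kind != "binary":
            raise ChemError("Tversky is defined for binary fingerprints only")
        a1 = A.sum(axis=1)[:, None]
        b1 = B.sum(axis=1)[None, :]
        denom = ab + tversky_alpha * (a1 - ab) + tversky_beta * (b1 - ab)
    else:
        raise ChemError(f"unknown similarity metric {metric!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, ab / denom, 0.0)
    return SimilarityMatrix(rows.ids, cols.ids, np.clip(sim, 0.0, 1.0))


def build_feature_matrix(S: SimilarityMatrix, alpha: float, scheme: str = "similarity") -> FeatureMatrix:
    """Threshold a similarity matrix at ``alpha`` (inclusive) and weight it."""
    return FeatureMatrix(S, alpha, scheme)


# ---------------------------------------------------------------------------
# TSV import/export

def read_descriptor_matrix(path, kind: str = "binary", normalize: bool = False) -> DescriptorMatrix:
    """Read a descriptor matrix from TSV (first column = compound ID)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy(dtype=float)
    if kind == "continuous" and normalize:
        values = normalize_columns(values)
    return DescriptorMatrix(tuple(str(i) for i in frame.index), values, kind=kind)


def write_descriptor_matrix(dm: DescriptorMatrix, path) -> None:
    dm.to_frame().to_csv(path, sep="\t")


def read_similarity_matrix(path) -> SimilarityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(
        tuple(str(i) for i in frame.index),
        tuple(str(c) for c in frame.columns),
        frame.to_numpy(dtype=float),
    )


def write_similarity_matrix(sm: SimilarityMatrix, path) -> None:
    pd.DataFrame(sm.values, index=list(sm.row_ids), columns=list(sm.col_ids)).to_csv(path, sep="\t")
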