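"""Drug-target interaction datasets: reading, writing, filtering, summarising.

The canonical interchange format is a tab-separated edge list with two
mandatory columns (drug ID, target ID) and optional ``activity_uM`` and
``date`` columns.  Yamanishi-style 0/1 adjacency matrices are also accepted
and converted to edge lists on read.  All identifiers are opaque strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

#: Activity types accepted by the bioactivity filter (case-insensitive).
ACTIVITY_TYPES = frozenset({"ki", "kd", "ic50", "ec50"})


class DatasetError(ValueError):
    """Raised on malformed or empty interaction data."""


@dataclass(frozen=True)
class InteractionDataset:
    """A bipartite set of drug-target interaction annotations.

    Parameters
    ----------
    drugs, targets
        Ordered, duplicate-free ID lists.  Order is first-appearance order
        when read from a file and is preserved through round trips.
    edges
        Annotated (drug, target) pairs.  The drug-target layer is unweighted:
        duplicate records collapse to a single edge.
    activities
        Optional bioactivity concentration (micromolar) per edge.
    dates
        Optional free-form date/version tag per edge.
    """

    drugs: tuple[str, ...]
    targets: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    activities: dict[tuple[str, str], float] = field(default_factory=dict)
    dates: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.drugs)) != len(self.drugs):
            raise DatasetError("duplicate drug IDs")
        if len(set(self.targets)) != len(self.targets):
            raise DatasetError("duplicate target IDs")
        dset, tset = set(self.drugs), set(self.targets)
        for d, t in self.edges:
            if d not in dset or t not in tset:
                raise DatasetError(f"edge ({d}, {t}) references unknown node")

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def drug_degree(self, drug: str) -> int:
        return sum(1 for d, _ in self.edges if d == drug)

    def target_degree(self, target: str) -> int:
        return sum(1 for _, t in self.edges if t == target)

    def targets_of(self, drug: str) -> set[str]:
        return {t for d, t in self.edges if d == drug}

    def drugs_of(self, target: str) -> set[str]:
        return {d for d, t in self.edges if t == target}

    def without_drug(self, drug: str) -> "InteractionDataset":
        """Remove one drug and all its edges (targets keep their slots)."""
        return InteractionDataset(
            drugs=tuple(d for d in self.drugs if d != drug),
            targets=self.targets,
            edges=frozenset(e for e in self.edges if e[0] != drug),
            activities={e: v for e, v in self.activities.items() if e[0] != drug},
            dates={e: v for e, v in self.dates.items() if e[0] != drug},
        )

    def without_drugs(self, drugs) -> "InteractionDataset":
        """Remove a set of drugs and all their edges (targets keep their slots)."""
        gone = set(drugs)
        return InteractionDataset(
            drugs=tuple(d for d in self.drugs if d not in gone),
            targets=self.targets,
            edges=frozenset(e for e in self.edges if e[0] not in gone),
            activities={e: v for e, v in self.activities.items() if e[0] not in gone},
            dates={e: v for e, v in self.dates.items() if e[0] not in gone},
        )

    def without_edges(self, removed) -> "InteractionDataset":
        removed = set(removed)
        return replace(
            self,
            edges=frozenset(e for e in self.edges if e not in removed),
            activities={e: v for e, v in self.activities.items() if e not in removed},
            dates={e: v for e, v in self.dates.items() if e not in removed},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.edges, key=lambda e: (self.drugs.index(e[0]), self.targets.index(e[1])))
        frame = pd.DataFrame(rows, columns=["drug", "target"])
        if self.activities:
            frame["activity_uM"] = [self.activities.get(e) for e in rows]
        if self.dates:
            frame["date"] = [self.dates.get(e) for e in rows]
        return frame


@dataclass(frozen=True)
class BioactivityRecord:
    """One measured compound-target activity, ChEMBL-table style."""

    compound: str
    target: str
    activity_type: str
    activity_uM: float
    n_heavy_atoms: int
    clinical_phase: int
    organism: str

    def __post_init__(self) -> None:
        if self.activity_uM <= 0:
            raise DatasetError("activity value must be positive")
        if self.n_heavy_atoms < 1:
            raise DatasetError("heavy-atom count must be >= 1")


@dataclass(frozen=True)
class DatasetStats:
    """Summary statistics of an interaction dataset."""

    n_ligands: int
    n_targets: int
    n_interactions: int
    mean_ligand_degree: float
    sd_ligand_degree: float
    mean_target_degree: float
    sd_target_degree: float
    density_pct: float
    atom_range: tuple[int, int] | None = None

    def as_row(self) -> dict:
        row = {
            "n_ligands": self.n_ligands,
            "n_targets": self.n_targets,
            "n_interactions": self.n_interactions,
            "k_ligands": f"{self.mean_ligand_degree:.2f} +/- {self.sd_ligand_degree:.2f}",
            "k_targets": f"{self.mean_target_degree:.2f} +/- {self.sd_target_degree:.2f}",
            "density_pct": round(self.density_pct, 2),
        }
        if self.atom_range is not None:
            row["n_atoms"] = f"[{self.atom_range[0]}, {self.atom_range[1]}]"
        return row


def _dataset_from_rows(rows: list[tuple], has_activity: bool, has_date: bool) -> InteractionDataset:
    drugs: list[str] = []
    targets: list[str] = []
    seen_d: set[str] = set()
    seen_t: set[str] = set()
    edges: set[tuple[str, str]] = set()
    activities: dict[tuple[str, str], float] = {}
    dates: dict[tuple[str, str], str] = {}
    for row in rows:
        d, t = row[0], row[1]
        if d not in seen_d:
            seen_d.add(d)
            drugs.append(d)
        if t not in seen_t:
            seen_t.add(t)
            targets.append(t)
        edges.add((d, t))
        idx = 2
        if has_activity and row[idx] is not None:
            activities[(d, t)] = float(row[idx])
        if has_activity:
            idx += 1
        if has_date and row[idx] is not None:
            dates[(d, t)] = str(row[idx])
    return InteractionDataset(
        drugs=tuple(drugs), targets=tuple(targets), edges=frozenset(edges),
        activities=activities, dates=dates,
    )


def read_interactions(path) -> InteractionDataset:
    """Read a TSV edge list (drug, target[, activity_uM][, date]).

    Duplicate edges are collapsed; drug/target order is first appearance.
    A header line is detected by the literal column names ``drug``/``target``.
    """
    rows: list[tuple] = []
    has_activity = has_date = False
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = [ln for ln in lines if ln.strip()]
    if not body:
        raise DatasetError(f"{path}: empty interaction file")
    start = 0
    header = body[0].rstrip("\n").split("\t")
    if header[0].strip().lower() == "drug":
        has_activity = "activity_uM" in header
        has_date = "date" in header
        start = 1
    elif len(header) >= 3:
        # headerless file: treat a numeric third column as activity
        try:
            float(header[2])
            has_activity = True
        except ValueError:
            has_date = True
        has_date = has_date or len(header) >= 4
    for lineno, line in enumerate(body[start:], start=start + 1):
        parts = [p.strip() for p in line.rstrip("\n").split("\t")]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise DatasetError(f"{path}:{lineno}: malformed row {line!r}")
        row: list = [parts[0], parts[1]]
        if has_activity:
            try:
                row.append(float(parts[2]) if len(parts) > 2 and parts[2] else None)
            except ValueError as exc:
                raise DatasetError(f"{path}:{lineno}: bad activity value") from exc
        if has_date:
            pos = 3 if has_activity else 2
            row.append(parts[pos] if len(parts) > pos and parts[pos] else None)
        rows.append(tuple(row))
    return _dataset_from_rows(rows, has_activity, has_date)


def write_interactions(ds: InteractionDataset, path) -> None:
    """Write the TSV edge list consumed by :func:`read_interactions`."""
    frame = ds.to_frame()
    frame.to_csv(path, sep="\t", index=False)


def read_adjacency_matrix(path) -> InteractionDataset:
    """Read a 0/1 adjacency matrix (rows = drugs, columns = targets) as TSV."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.empty:
        raise DatasetError(f"{path}: empty adjacency matrix")
    edges = {
        (str(d), str(t))
        for d in mat.index
        for t in mat.columns
        if mat.loc[d, t] != 0
    }
    return InteractionDataset(
        drugs=tuple(str(d) for d in mat.index),
        targets=tuple(str(t) for t in mat.columns),
        edges=frozenset(edges),
    )


def read_smiles(path) -> dict[str, str]:
    """Read a .smi file (``SMILES<whitespace>ID`` per line) into id -> SMILES."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise DatasetError(f"{path}:{lineno}: expected 'SMILES ID'")
            out[parts[1]] = parts[0]
    if not out:
        raise DatasetError(f"{path}: empty SMILES file")
    return out


def write_smiles(smiles: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for cid, smi in smiles.items():
            fh.write(f"{smi}\t{cid}\n")


def read_bioactivities(path) -> list[BioactivityRecord]:
    """Read a bioactivity TSV with the BioactivityRecord columns."""
    frame = pd.read_csv(path, sep="\t")
    required = {
        "compound", "target", "activity_type", "activity_uM",
        "n_heavy_atoms", "clinical_phase", "organism",
    }
    missing = required - set(frame.columns)
    if missing:
        raise DatasetError(f"{path}: missing columns {sorted(missing)}")
    return [
        BioactivityRecord(
            compound=str(r.compound), target=str(r.target),
            activity_type=str(r.activity_type), activity_uM=float(r.activity_uM),
            n_heavy_atoms=int(r.n_heavy_atoms), clinical_phase=int(r.clinical_phase),
            organism=str(r.organism),
        )
        for r in frame.itertuples()
    ]


def write_bioactivities(records: list[BioactivityRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t", index=False)


def dataset_stats(ds: InteractionDataset, atom_counts: dict[str, int] | None = None) -> DatasetStats:
    """Compute summary statistics (counts, degrees, density) of a dataset.

    Density is the percentage of all possible ligand-target pairs that are
    annotated.  Degree dispersions are population standard deviations over
    the declared ID lists (zero-degree nodes included).
    """
    from collections import Counter

    import numpy as np

    if ds.n_edges == 0 or ds.n_drugs == 0 or ds.n_targets == 0:
        raise DatasetError("cannot summarise an empty dataset")
    deg_d = Counter(d for d, _ in ds.edges)
    deg_t = Counter(t for _, t in ds.edges)
    dd = np.array([deg_d.get(d, 0) for d in ds.drugs], dtype=float)
    td = np.array([deg_t.get(t, 0) for t in ds.targets], dtype=float)
    atom_range = None
    if atom_counts:
        counts = [atom_counts[d] for d in ds.drugs if d in atom_counts]
        if counts:
            atom_range = (min(counts), max(counts))
    return DatasetStats(
        n_ligands=ds.n_drugs,
        n_targets=ds.n_targets,
        n_interactions=ds.n_edges,
        mean_ligand_degree=float(dd.mean()),
        sd_ligand_degree=float(dd.std()),
        mean_target_degree=float(td.mean()),
        sd_target_degree=float(td.std()),
        density_pct=100.0 * ds.n_edges / (ds.n_drugs * ds.n_targets),
        atom_range=atom_range,
    )


def filter_bioactivities(
    records: list[BioactivityRecord],
    activity_cutoff_uM: float = 10.0,
    min_atoms: int = 5,
    max_atoms: int = 80,
    min_phase: int = 1,
    organism: str = "Homo sapiens",
) -> InteractionDataset:
    """Apply the standard drug-likeness/activity filter and binarise to edges.

    A record is kept iff its activity type is one of Ki/Kd/IC50/EC50, the
    activity value is strictly below ``activity_cutoff_uM`` (micromolar), the
    heavy-atom count lies strictly between ``min_atoms`` and ``max_atoms``,
    the clinical phase is at least ``min_phase`` and the organism matches
    (case-insensitive).  Records with an unknown activity type are skipped
    with a logged warning.  Surviving duplicate (compound, target) pairs
    collapse to one unweighted edge.
    """
    if not records:
        raise DatasetError("no bioactivity records supplied")
    kept: list[tuple] = []
    for rec in records:
        if rec.activity_type.lower() not in ACTIVITY_TYPES:
            logger.warning(
                "skipping record (%s, %s): unknown activity type %r",
                rec.compound, rec.target, rec.activity_type,
            )
            continue
        if not (rec.activity_uM < activity_cutoff_uM):
            continue
        if not (min_atoms < rec.n_heavy_atoms < max_atoms):
            continue
        if rec.clinical_phase < min_phase:
            continue
        if rec.organism.strip().lower() != organism.strip().lower():
            continue
        kept.append((rec.compound, rec.target, rec.activity_uM))
    return _dataset_from_rows(kept, has_activity=True, has_date=False)


def time_split(
    train_raw: InteractionDataset, test_raw: InteractionDataset
) -> tuple[InteractionDataset, InteractionDataset]:
    """Build a chronological train/test pair from an older and a newer snapshot.

    Both datasets are restricted to the targets they share, and every edge
    already present in the older (training) snapshot is removed from the test
    set, so test interactions are genuinely new.  Test drugs may share IDs
    with training drugs; their previously known edges are simply dropped.
    """
    shared = [t for t in train_raw.targets if t in set(test_raw.targets)]
    if not shared:
        raise DatasetError("train and test share no targets")
    shared_set = set(shared)

    def _restrict(ds: InteractionDataset, drop_edges: frozenset) -> InteractionDataset:
        edges = frozenset(
            e for e in ds.edges if e[1] in shared_set and e not in drop_edges
        )
        drugs = tuple(d for d in ds.drugs if any(e[0] == d for e in edges))
        return InteractionDataset(
            drugs=drugs,
            targets=tuple(shared),
            edges=edges,
            activities={e: v for e, v in ds.activities.items() if e in edges},
            dates={e: v for e, v in ds.dates.items() if e in edges},
        )

    train = _restrict(train_raw, frozenset())
    test = _restrict(test_raw, train.edges)
    return train, test
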