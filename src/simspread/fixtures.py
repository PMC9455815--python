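"""Seeded generators of toy data with planted, recoverable structure.

These generators build the study conditions every test runs under: compound
libraries with clustered fingerprints (the similarity-property principle —
similar compounds share bioactivities — made literal), interaction datasets
where each chemical cluster owns a disjoint block of targets, and
bioactivity tables with rule violations planted at controlled rates.  All
generators are pure functions of one integer seed.

Fingerprints here are synthetic bit vectors, not molecules; a small curated
set of real drug SMILES (:data:`CURATED_SMILES`) is provided for end-to-end
tests that need genuine fingerprints and scaffolds.
"""

from __future__ import annotations

import numpy as np

from .chem import DescriptorMatrix
from .datasets import BioactivityRecord, InteractionDataset

#: Bit density of a cluster prototype within its reserved bit block.  Each
#: cluster's prototype occupies a disjoint block of the fingerprint (distinct
#: chemotypes set distinct substructure bits), so between-cluster similarity
#: comes only from flip noise (~0.05 in expectation) while within-cluster
#: similarity at 5% bit flips is ~0.6 — a robust separation on either side
#: of the default similarity cutoff 0.2.
PROTOTYPE_DENSITY = 0.6

#: Twenty approved drugs with verified SMILES for fingerprint/scaffold tests.
CURATED_SMILES: dict[str, str] = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "naproxen": "COc1ccc2cc(ccc2c1)C(C)C(=O)O",
    "diclofenac": "OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl",
    "celecoxib": "Cc1ccc(cc1)-c1cc(nn1-c1ccc(cc1)S(N)(=O)=O)C(F)(F)F",
    "propranolol": "CC(C)NCC(O)COc1cccc2ccccc12",
    "atenolol": "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",
    "metoprolol": "COCCc1ccc(OCC(O)CNC(C)C)cc1",
    "diazepam": "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",
    "lorazepam": "OC1N=C(c2ccccc2Cl)c2cc(Cl)ccc2NC1=O",
    "fluoxetine": "CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1",
    "sertraline": "CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc12",
    "imatinib": "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1",
    "gefitinib": "COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1",
    "sildenafil": "CCCc1nn(C)c2c1nc([nH]c2=O)-c1cc(ccc1OCC)S(=O)(=O)N1CCN(C)CC1",
    "warfarin": "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",
    "simvastatin": "CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C12",
    "chlorpromazine": "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21",
}


def generate_clustered_library(
    n_clusters: int = 4,
    compounds_per_cluster: int = 15,
    n_bits: int = 256,
    within_cluster_flip_prob: float = 0.05,
    seed: int = 0,
    prototype_density: float = PROTOTYPE_DENSITY,
) -> tuple[DescriptorMatrix, np.ndarray]:
    """Synthetic fingerprint library with planted chemical clusters.

    Each cluster draws a random prototype fingerprint whose set bits live in
    a cluster-reserved block of the bit space (bit density
    ``prototype_density`` within the block), emulating chemical series whose
    substructure vocabularies barely overlap; members copy their prototype
    with every bit flipped independently at ``within_cluster_flip_prob``.
    By construction within-cluster Tanimoto similarity exceeds the
    between-cluster one, which stems from flip noise alone.  Returns the
    library and the integer cluster label per compound.
    """
    if n_clusters < 1 or compounds_per_cluster < 1 or n_bits < n_clusters:
        raise ValueError("degenerate library size")
    if not (0.0 <= within_cluster_flip_prob < 0.5):
        raise ValueError("flip probability must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    block = n_bits // n_clusters
    ids, rows, labels = [], [], []
    for c in range(n_clusters):
        proto = np.zeros(n_bits, dtype=np.uint8)
        proto[c * block:(c + 1) * block] = rng.random(block) < prototype_density
        for m in range(compounds_per_cluster):
            flips = rng.random(n_bits) < within_cluster_flip_prob
            rows.append(np.where(flips, 1 - proto, proto))
            ids.append(f"c{c}_m{m}")
            labels.append(c)
    return DescriptorMatrix(tuple(ids), np.asarray(rows, dtype=np.uint8)), np.array(labels)


def generate_planted_dti(
    library: DescriptorMatrix,
    cluster_labels: np.ndarray,
    targets_per_cluster: int = 5,
    annotation_prob: float = 0.8,
    seed: int = 0,
) -> InteractionDataset:
    """Interaction dataset where each chemical cluster owns its own targets.

    Cluster ``c`` gets a disjoint block of ``targets_per_cluster`` targets;
    each member is annotated to each block target independently with
    ``annotation_prob``.  No cross-cluster edge is ever created, so a
    similarity-guided method should recover the block structure.  Every
    compound is guaranteed at least one edge (one block target is forced)
    so that no drug enters the network isolated.
    """
    if not (0.0 < annotation_prob <= 1.0):
        raise ValueError("annotation probability must lie in (0, 1]")
    labels = np.asarray(cluster_labels)
    if len(labels) != len(library.ids):
        raise ValueError("cluster label length mismatch")
    clusters = np.unique(labels)
    if any((labels == c).sum() == 0 for c in clusters):
        raise ValueError("empty cluster")
    rng = np.random.default_rng(seed)
    targets = tuple(
        f"t{c}_{j}" for c in clusters for j in range(targets_per_cluster)
    )
    edges = set()
    for cid, c in zip(library.ids, labels):
        block = [f"t{c}_{j}" for j in range(targets_per_cluster)]
        hits = [t for t in block if rng.random() < annotation_prob]
        if not hits:
            hits = [block[rng.integers(targets_per_cluster)]]
        edges.update((cid, t) for t in hits)
    return InteractionDataset(drugs=library.ids, targets=targets, edges=frozenset(edges))


#: Filter-rule names accepted by :func:`generate_bioactivity_table`.
BIOACTIVITY_RULES = ("activity_type", "activity_value", "atom_count", "phase", "organism")


def generate_bioactivity_table(
    n_records: int = 20,
    rule_satisfaction_fractions: dict[str, float] | None = None,
    seed: int = 0,
) -> list[BioactivityRecord]:
    """Bioactivity table with rule violations planted at controlled rates.

    For each filter rule, exactly ``round((1 - fraction) * n_records)``
    records are made to violate it (chosen without replacement,
    independently per rule), so the fully-compliant count is close to
    ``n_records * prod(fractions)`` and exactly ``round(fraction * n)``
    when only one rule has fraction < 1.  Compound-target pairs are unique
    by construction.
    """
    fractions = dict.fromkeys(BIOACTIVITY_RULES, 1.0)
    if rule_satisfaction_fractions:
        unknown = set(rule_satisfaction_fractions) - set(BIOACTIVITY_RULES)
        if unknown:
            raise ValueError(f"unknown rules {sorted(unknown)}")
        fractions.update(rule_satisfaction_fractions)
    if any(not (0.0 <= f <= 1.0) for f in fractions.values()):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    violates = {
        rule: set(rng.choice(n_records, size=round((1 - frac) * n_records), replace=False))
        for rule, frac in fractions.items()
    }
    records = []
    for i in range(n_records):
        records.append(BioactivityRecord(
            compound=f"cmpd{i}",
            target=f"prot{i % max(3, n_records // 4)}",
            activity_type=("percent_inhibition" if i in violates["activity_type"]
                           else str(rng.choice(["Ki", "Kd", "IC50", "EC50"]))),
            activity_uM=(float(rng.uniform(10.0, 500.0)) if i in violates["activity_value"]
                         else float(rng.uniform(0.001, 9.9))),
            n_heavy_atoms=(int(rng.choice([3, 5, 80, 120])) if i in violates["atom_count"]
                           else int(rng.integers(6, 80))),
            clinical_phase=(0 if i in violates["phase"] else int(rng.integers(1, 5))),
            organism=("Rattus norvegicus" if i in violates["organism"] else "Homo sapiens"),
        ))
    return records


def generate_random_dataset(
    n_drugs: int, n_targets: int, n_edges: int, seed: int = 0
) -> InteractionDataset:
    """Random bipartite dataset with exact node and edge counts.

    Every drug and every target receives at least one edge (requires
    ``n_edges >= max(n_drugs, n_targets)``), the remainder is sampled
    uniformly without replacement from the unused pairs.
    """
    if n_edges < max(n_drugs, n_targets):
        raise ValueError("need n_edges >= max(n_drugs, n_targets) to cover all nodes")
    if n_edges > n_drugs * n_targets:
        raise ValueError("more edges than possible pairs")
    rng = np.random.default_rng(seed)
    drugs = tuple(f"d{i}" for i in range(n_drugs))
    targets = tuple(f"t{j}" for j in range(n_targets))
    # cover all nodes: pair a permutation of drugs against cycled targets
    edges = set()
    t_perm = rng.permutation(n_targets)
    d_perm = rng.permutation(n_drugs)
    for k in range(max(n_drugs, n_targets)):
        edges.add((drugs[d_perm[k % n_drugs]], targets[t_perm[k % n_targets]]))
    while len(edges) < n_edges:
        edges.add((drugs[rng.integers(n_drugs)], targets[rng.integers(n_targets)]))
    return InteractionDataset(drugs=drugs, targets=targets, edges=frozenset(edges))


def shuffle_targets(ds: InteractionDataset, seed: int = 0) -> InteractionDataset:
    """Permute the target endpoints of all edges (y-scrambling control).

    Destroys any association between chemistry and annotation while
    preserving each drug's edge count and the overall target frequency
    profile; duplicate pairs created by the permutation collapse, so the
    edge count may shrink slightly.
    """
    rng = np.random.default_rng(seed)
    edges = sorted(ds.edges)
    shuffled_targets = rng.permutation([t for _, t in edges])
    return InteractionDataset(
        drugs=ds.drugs,
        targets=ds.targets,
        edges=frozenset((d, t) for (d, _), t in zip(edges, shuffled_targets)),
    )
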