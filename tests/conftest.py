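"""Shared fixtures: toy networks, planted libraries, random-instance makers."""

import numpy as np
import pytest

from simspread.datasets import InteractionDataset
from simspread.fixtures import generate_clustered_library, generate_planted_dti
from simspread.network import TripartiteNetwork


@pytest.fixture(scope="session")
def planted():
    """Clustered fingerprint library + block-structured interaction dataset."""
    library, labels = generate_clustered_library(
        n_clusters=3, compounds_per_cluster=6, n_bits=128,
        within_cluster_flip_prob=0.05, seed=7,
    )
    ds = generate_planted_dti(library, labels, targets_per_cluster=3,
                              annotation_prob=0.8, seed=7)
    return library, labels, ds


@pytest.fixture
def toy_dataset():
    """Three drugs, two targets, hand-checkable."""
    return InteractionDataset(
        drugs=("d1", "d2", "d3"),
        targets=("t1", "t2"),
        edges=frozenset({("d1", "t1"), ("d2", "t1"), ("d2", "t2"), ("d3", "t2")}),
    )


def random_tripartite(rng, max_nodes=10, weighted=True):
    """Random small F-D-T network; every F node and drug gets >=1 edge."""
    nF = rng.integers(1, max_nodes + 1)
    nD = rng.integers(1, max_nodes + 1)
    nT = rng.integers(1, max_nodes + 1)
    FD = (rng.random((nF, nD)) < 0.4).astype(float)
    for i in range(nF):  # connect isolated feature nodes
        if FD[i].sum() == 0:
            FD[i, rng.integers(nD)] = 1.0
    if weighted:
        FD *= rng.uniform(0.1, 1.0, size=FD.shape)
    DT = (rng.random((nD, nT)) < 0.4).astype(float)
    for j in range(nD):
        if DT[j].sum() == 0:
            DT[j, rng.integers(nT)] = 1.0
    return TripartiteNetwork(
        feature_ids=tuple(f"f{i}" for i in range(nF)),
        drug_ids=tuple(f"d{j}" for j in range(nD)),
        target_ids=tuple(f"t{k}" for k in range(nT)),
        FD=FD, DT=DT,
    )


def random_ranking(rng, n_min=4, n_max=30, tie_values=None):
    """Random scored/labelled target panel, with ties when tie_values given."""
    from simspread.metrics import LabeledRanking

    n = int(rng.integers(n_min, n_max + 1))
    if tie_values is not None:
        scores = rng.choice(tie_values, size=n).astype(float)
    else:
        scores = rng.random(n)
    labels = rng.random(n) < 0.4
    if not labels.any():
        labels[rng.integers(n)] = True
    if labels.all():
        labels[rng.integers(n)] = False
    return LabeledRanking(tuple(f"t{i}" for i in range(n)), scores, labels)
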