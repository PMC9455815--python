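"""Dataset reading, filtering, statistics and time-split behaviour."""

import numpy as np
import pytest

from simspread.datasets import (
    BioactivityRecord,
    DatasetError,
    InteractionDataset,
    dataset_stats,
    filter_bioactivities,
    read_adjacency_matrix,
    read_interactions,
    read_smiles,
    time_split,
    write_interactions,
    write_smiles,
)
from simspread.fixtures import generate_random_dataset


def _record(**kw):
    base = dict(compound="c1", target="t1", activity_type="Ki", activity_uM=1.0,
                n_heavy_atoms=30, clinical_phase=2, organism="Homo sapiens")
    base.update(kw)
    return BioactivityRecord(**base)


class TestReadInteractions:
    def test_duplicate_edges_collapse(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("d1\tt1\nd2\tt1\nd1\tt1\n")
        ds = read_interactions(p)
        assert ds.n_edges == 2
        assert ds.drugs == ("d1", "d2") and ds.targets == ("t1",)

    def test_identity_read_back(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("drug\ttarget\nd1\tt1\nd2\tt1\n")
        ds = read_interactions(p)
        assert (ds.n_drugs, ds.n_targets, ds.n_edges) == (2, 1, 2)

    def test_round_trip(self, tmp_path, toy_dataset):
        p = tmp_path / "rt.tsv"
        write_interactions(toy_dataset, p)
        again = read_interactions(p)
        assert again.edges == toy_dataset.edges
        assert set(again.drugs) == set(toy_dataset.drugs)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("d1\tt1\nonly-one-column\n")
        with pytest.raises(DatasetError, match=":2"):
            read_interactions(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(DatasetError):
            read_interactions(p)

    def test_adjacency_matrix_reader(self, tmp_path):
        p = tmp_path / "adj.tsv"
        p.write_text("\tt1\tt2\nd1\t1\t0\nd2\t1\t1\n")
        ds = read_adjacency_matrix(p)
        assert ds.edges == frozenset({("d1", "t1"), ("d2", "t1"), ("d2", "t2")})

    def test_smiles_round_trip(self, tmp_path):
        p = tmp_path / "c.smi"
        write_smiles({"benzene": "c1ccccc1", "ethanol": "CCO"}, p)
        assert read_smiles(p) == {"benzene": "c1ccccc1", "ethanol": "CCO"}


class TestDatasetStats:
    @pytest.mark.parametrize(
        "n_d, n_t, n_e, density, k_lig, k_tgt",
        [
            (54, 26, 90, 6.41, 1.67, 3.46),
            (445, 664, 2926, 0.99, 6.57, 4.41),
            (1, 1, 1, 100.0, 1.0, 1.0),
        ],
    )
    def test_density_and_degrees(self, n_d, n_t, n_e, density, k_lig, k_tgt):
        ds = generate_random_dataset(n_d, n_t, n_e, seed=0)
        st = dataset_stats(ds)
        assert st.density_pct == pytest.approx(density, abs=0.005)
        assert st.mean_ligand_degree == pytest.approx(k_lig, abs=0.01)
        assert st.mean_target_degree == pytest.approx(k_tgt, abs=0.01)

    def test_invariant_equations_on_random_datasets(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_d, n_t = rng.integers(2, 15, size=2)
            n_e = int(rng.integers(max(n_d, n_t), n_d * n_t + 1))
            ds = generate_random_dataset(int(n_d), int(n_t), n_e, seed=int(rng.integers(2**31)))
            st = dataset_stats(ds)
            assert st.density_pct == pytest.approx(100 * n_e / (n_d * n_t))
            assert st.mean_ligand_degree == pytest.approx(n_e / n_d)
            assert st.mean_target_degree == pytest.approx(n_e / n_t)

    def test_empty_dataset_errors(self):
        ds = InteractionDataset(("d1",), ("t1",), frozenset())
        with pytest.raises(DatasetError):
            dataset_stats(ds)

    def test_atom_range(self, toy_dataset):
        st = dataset_stats(toy_dataset, {"d1": 10, "d2": 40, "d3": 25})
        assert st.atom_range == (10, 40)


class TestFilterBioactivities:
    def test_weak_activity_excluded(self):
        ds = filter_bioactivities([_record(activity_type="IC50", activity_uM=20.0)])
        assert ds.n_edges == 0

    def test_atom_bound_is_strict(self):
        ds = filter_bioactivities([_record(n_heavy_atoms=5)])
        assert ds.n_edges == 0

    def test_hand_enumerated_records(self):
        records = [
            _record(),                                         # keeps
            _record(compound="c2", activity_type="Kd", activity_uM=9.99),  # keeps
            _record(compound="c3", activity_uM=10.0),          # cutoff strict
            _record(compound="c4", clinical_phase=0),          # preclinical
            _record(compound="c5", organism="Rattus norvegicus"),
            _record(compound="c6", n_heavy_atoms=80),
        ]
        ds = filter_bioactivities(records)
        assert ds.n_edges == 2
        assert set(d for d, _ in ds.edges) == {"c1", "c2"}

    def test_unknown_activity_type_skipped_with_warning(self, caplog):
        records = [_record(), _record(compound="c2", activity_type="percent")]
        with caplog.at_level("WARNING"):
            ds = filter_bioactivities(records)
        assert ds.n_edges == 1
        assert "unknown activity type" in caplog.text

    def test_duplicate_pairs_collapse(self):
        ds = filter_bioactivities([_record(activity_uM=1.0), _record(activity_uM=2.0)])
        assert ds.n_edges == 1

    def test_idempotent(self):
        records = [
            _record(), _record(compound="c2"), _record(compound="c3", activity_uM=50.0),
        ]
        once = filter_bioactivities(records)
        survivors = [r for r in records if (r.compound, r.target) in once.edges]
        assert filter_bioactivities(survivors).edges == once.edges


class TestTimeSplit:
    @staticmethod
    def _ds(edges):
        drugs = tuple(dict.fromkeys(d for d, _ in edges))
        targets = tuple(dict.fromkeys(t for _, t in edges))
        return InteractionDataset(drugs, targets, frozenset(edges))

    def test_shared_targets_and_known_edges_removed(self):
        train_raw = self._ds([("d1", "t1")])
        test_raw = self._ds([("d1", "t1"), ("d2", "t1"), ("d2", "t2")])
        train, test = time_split(train_raw, test_raw)
        assert train.edges == frozenset({("d1", "t1")})
        assert test.edges == frozenset({("d2", "t1")})
        assert set(train.targets) == set(test.targets) == {"t1"}

    def test_identical_snapshots_leave_empty_test(self):
        ds = self._ds([("d1", "t1"), ("d2", "t2")])
        _, test = time_split(ds, ds)
        assert test.n_edges == 0

    def test_disjoint_targets_error(self):
        with pytest.raises(DatasetError):
            time_split(self._ds([("d1", "t1")]), self._ds([("d2", "t2")]))

    def test_split_invariants_on_random_snapshots(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = generate_random_dataset(6, 5, int(rng.integers(6, 20)), seed=int(rng.integers(2**31)))
            b = generate_random_dataset(7, 5, int(rng.integers(7, 22)), seed=int(rng.integers(2**31)))
            train, test = time_split(a, b)
            assert set(train.targets) == set(test.targets)
            assert set(train.targets) <= set(a.targets) & set(b.targets)
            assert not (test.edges & train.edges)
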