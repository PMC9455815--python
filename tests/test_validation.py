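"""Cross-validation harnesses: splitting, masking, determinism, leakage."""

import numpy as np
import pandas as pd
import pytest

from simspread.datasets import DatasetError, InteractionDataset
from simspread.fixtures import generate_clustered_library, generate_planted_dti
from simspread.metrics import score_ranking
from simspread.validation import (
    PredictorConfig,
    dti_holdout_kfold,
    loocv,
    predict_scores,
    repeated_kfold,
    time_split_validate,
)


@pytest.fixture(scope="module")
def small_planted():
    library, labels = generate_clustered_library(
        n_clusters=2, compounds_per_cluster=5, n_bits=64, seed=3
    )
    ds = generate_planted_dti(library, labels, targets_per_cluster=3, seed=3)
    return library, ds


@pytest.fixture(scope="module")
def config(small_planted):
    library, _ = small_planted
    return PredictorConfig(method="simspread", features=library, alpha=0.2)


class TestLoocv:
    def test_one_unit_per_drug(self, small_planted, config):
        _, ds = small_planted
        report = loocv(ds, config)
        assert len(report.per_unit) == ds.n_drugs
        assert set(report.per_unit["unit"]) == set(ds.drugs)

    def test_target_with_single_ligand_is_masked(self):
        library, labels = generate_clustered_library(2, 3, 64, seed=5)
        ds = generate_planted_dti(library, labels, targets_per_cluster=2, seed=5)
        solo = InteractionDataset(
            ds.drugs, ds.targets + ("t_solo",),
            ds.edges | {(ds.drugs[0], "t_solo")},
        )
        cfg = PredictorConfig(method="simspread", features=library)
        report = loocv(solo, cfg)
        row = report.per_unit.set_index("unit").loc[solo.drugs[0]]
        assert row["n_masked"] >= 1

    def test_metrics_equal_manual_composition(self, small_planted, config):
        library, ds = small_planted
        drug = ds.drugs[0]
        report = loocv(ds, config)
        train = ds.without_drug(drug)
        pred = predict_scores(config, train, [drug])[drug]
        from simspread.metrics import LabeledRanking

        connected = {t for _, t in train.edges}
        labels = np.array([t in ds.targets_of(drug) for t in pred.target_ids])
        mask = np.array([t in connected for t in pred.target_ids])
        manual = score_ranking(LabeledRanking(pred.target_ids, pred.scores, labels, mask))
        row = report.per_unit.set_index("unit").loc[drug]
        for m, v in manual.items():
            assert row[m] == pytest.approx(v, nan_ok=True), m

    def test_needs_two_drugs(self, config):
        ds = InteractionDataset(("d",), ("t",), frozenset({("d", "t")}))
        with pytest.raises(DatasetError):
            loocv(ds, config)


class TestRepeatedKfold:
    def test_partition_properties(self, small_planted, config):
        _, ds = small_planted
        report = repeated_kfold(ds, config, folds=3, repeats=2, seed=4)
        drugs = report.per_drug
        for rep in (0, 1):
            sizes = drugs[drugs["repeat"] == rep].groupby("fold").size()
            assert sizes.max() - sizes.min() <= 1
            held = drugs[drugs["repeat"] == rep]["unit"]
            assert sorted(held) == sorted(ds.drugs)  # union = all, disjoint
        assert len(report.per_unit) == 6

    def test_same_seed_reproduces_report(self, small_planted, config):
        _, ds = small_planted
        a = repeated_kfold(ds, config, folds=3, repeats=2, seed=9)
        b = repeated_kfold(ds, config, folds=3, repeats=2, seed=9)
        pd.testing.assert_frame_equal(a.per_unit, b.per_unit)
        pd.testing.assert_frame_equal(a.per_drug, b.per_drug)

    def test_fold_value_is_mean_over_evaluable_drugs(self, small_planted, config):
        _, ds = small_planted
        report = repeated_kfold(ds, config, folds=2, repeats=1, seed=1)
        drugs = report.per_drug
        fold0 = drugs[(drugs["repeat"] == 0) & (drugs["fold"] == 0)]
        expected = fold0["auroc"].mean(skipna=True)
        got = report.per_unit.set_index("unit").loc["rep0_fold0", "auroc"]
        assert got == pytest.approx(expected, nan_ok=True)

    def test_too_many_folds(self, small_planted, config):
        _, ds = small_planted
        with pytest.raises(DatasetError):
            repeated_kfold(ds, config, folds=ds.n_drugs + 1, repeats=1, seed=0)


class TestDtiHoldout:
    def test_runs_nbi_on_drugs_with_training_edges(self, small_planted):
        _, ds = small_planted
        report = dti_holdout_kfold(ds, PredictorConfig(method="nbi"), folds=4, repeats=2, seed=2)
        # every evaluated drug kept at least one training edge in its fold
        assert (report.per_drug.groupby("unit").size() > 0).all()
        assert report.skipped["drugs_without_training_edges"] >= 0

    def test_edge_partition_union_and_disjointness(self, small_planted):
        _, ds = small_planted
        from simspread.validation import _fold_partition

        rng = np.random.default_rng(2)
        folds = _fold_partition(sorted(ds.edges), 4, rng)
        seen = [tuple(e) for f in folds for e in f]
        assert sorted(seen) == sorted(ds.edges)

    def test_toy_fold_equals_manual_composition(self, small_planted):
        _, ds = small_planted
        from simspread.validation import _fold_partition

        cfg = PredictorConfig(method="nbi")
        report = dti_holdout_kfold(ds, cfg, folds=2, repeats=1, seed=6)
        rng = np.random.default_rng(6 % 2**31)
        held = {tuple(e) for e in _fold_partition(sorted(ds.edges), 2, rng)[0]}
        train = ds.without_edges(held)
        drug = sorted({d for d, _ in held if train.drug_degree(d) > 0})[0]
        pred = predict_scores(cfg, train, [drug])[drug]
        from simspread.metrics import LabeledRanking

        connected = {t for _, t in train.edges}
        positives = {t for d, t in held if d == drug}
        retained = train.targets_of(drug)
        labels = np.array([t in positives for t in pred.target_ids])
        mask = np.array(
            [t in connected and t not in retained for t in pred.target_ids]
        )
        manual = score_ranking(LabeledRanking(pred.target_ids, pred.scores, labels, mask))
        row = report.per_drug
        row = row[(row["repeat"] == 0) & (row["fold"] == 0) & (row["unit"] == drug)].iloc[0]
        for m, v in manual.items():
            assert row[m] == pytest.approx(v, nan_ok=True), m


class TestTimeSplitValidate:
    def test_drug_without_shared_positive_skipped(self, small_planted, config):
        library, ds = small_planted
        train = ds.without_drug(ds.drugs[0])
        test = InteractionDataset(
            (ds.drugs[0], "loner"), ds.targets,
            frozenset({(ds.drugs[0], t) for t in ds.targets_of(ds.drugs[0])}),
        )
        # 'loner' has no edges at all -> no positive among training targets,
        # so it must be skipped before any fingerprint lookup happens
        report = time_split_validate(train, test, config)
        assert report.skipped["test_drugs_without_shared_positive"] == 1
        assert set(report.per_unit["unit"]) == {ds.drugs[0]}

    def test_deterministic_given_fixed_inputs(self, small_planted, config):
        _, ds = small_planted
        train = ds.without_drugs(ds.drugs[:3])
        test = InteractionDataset(
            ds.drugs[:3], ds.targets,
            frozenset(e for e in ds.edges if e[0] in ds.drugs[:3]),
        )
        a = time_split_validate(train, test, config)
        b = time_split_validate(train, test, config)
        pd.testing.assert_frame_equal(a.per_unit, b.per_unit)


class TestLeakage:
    def test_held_out_edges_cannot_influence_own_predictions(self, small_planted, config):
        _, ds = small_planted
        drug = ds.drugs[0]
        rewired = InteractionDataset(
            ds.drugs, ds.targets,
            frozenset(e for e in ds.edges if e[0] != drug) | {(drug, ds.targets[-1])},
        )
        a = loocv(ds, config, keep_predictions=True).predictions[drug]
        b = loocv(rewired, config, keep_predictions=True).predictions[drug]
        assert np.array_equal(a.scores, b.scores)

    def test_kfold_predictions_pure_function_of_training_fold(self, small_planted, config):
        _, ds = small_planted
        from simspread.validation import _fold_partition

        rng = np.random.default_rng(8)
        held = list(_fold_partition(list(ds.drugs), 2, rng)[0])
        train = ds.without_drugs(held)
        rewired = InteractionDataset(
            ds.drugs, ds.targets,
            frozenset(e for e in ds.edges if e[0] not in held)
            | {(d, ds.targets[0]) for d in held},
        )
        train2 = rewired.without_drugs(held)
        assert train.edges == train2.edges
        for q in held:
            a = predict_scores(config, train, [q])[q]
            b = predict_scores(config, train2, [q])[q]
            assert np.array_equal(a.scores, b.scores)

    def test_dti_holdout_predictions_depend_only_on_retained_edges(self, small_planted):
        # two datasets whose held-out edge sets differ but whose retained
        # training edges coincide must yield identical predictions
        _, ds = small_planted
        cfg = PredictorConfig(method="nbi")
        edges = sorted(ds.edges)
        held_a = set(edges[:5])
        extra = (edges[0][0], ds.targets[-1])
        assert extra not in ds.edges - held_a
        ds_b = InteractionDataset(
            ds.drugs, ds.targets, (ds.edges - held_a) | {extra}
        )
        train_a = ds.without_edges(held_a)
        train_b = ds_b.without_edges({extra})
        assert train_a.edges == train_b.edges
        drug = next(d for d in ds.drugs if train_a.drug_degree(d) > 0)
        a = predict_scores(cfg, train_a, [drug])[drug]
        b = predict_scores(cfg, train_b, [drug])[drug]
        assert np.array_equal(a.scores, b.scores)
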