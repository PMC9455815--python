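"""Cross-validation and time-split harnesses for any prediction method.

All splitting is drug-wise unless stated otherwise: when a drug is held out,
every one of its interactions is removed from the training network before
prediction.  Targets that lose all training edges in a split are
disconnected — they can never be predicted — and are masked out of the
metrics for that unit.  Units whose metrics are undefined (no evaluable
positive/negative) are kept in the report with NaN values and counted,
never silently dropped.

One integer seed drives every shuffle; per-repeat seeds are derived as
``(seed + repeat) mod 2^31`` so reports are bitwise reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import BipartiteNetwork, knn_predict, nbi_predict, sdtnbi_network
from .chem import DescriptorMatrix, build_feature_matrix, pairwise_similarity
from .datasets import DatasetError, InteractionDataset
from .metrics import METRIC_NAMES, LabeledRanking, score_ranking
from .network import PredictionScores, build_simspread_network, denovo_spread

logger = logging.getLogger(__name__)

METHODS = ("simspread", "sdtnbi", "nbi", "knn")


@dataclass(frozen=True)
class PredictorConfig:
    """Everything needed to instantiate a prediction method for one split.

    ``features`` must cover every drug that can appear in a training set or
    as a query (except for NBI, which needs no chemistry).  ``alpha`` is the
    similarity cutoff of the feature matrix, ``scheme`` the weighting of
    surviving entries, ``propagation`` how shares are normalised during
    spreading.
    """

    method: str = "simspread"
    features: DescriptorMatrix | None = None
    alpha: float = 0.2
    scheme: str = "similarity"
    propagation: str = "weighted"
    metric: str = "tanimoto"
    k: int = 1

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.method != "nbi" and self.features is None:
            raise ValueError(f"method {self.method!r} requires a descriptor matrix")

    def manifest(self) -> dict:
        out = {"method": self.method, "metric": self.metric}
        if self.method == "simspread":
            out.update(alpha=self.alpha, scheme=self.scheme, propagation=self.propagation)
        if self.method == "knn":
            out.update(k=self.k)
        if self.features is not None:
            out.update(descriptor_kind=self.features.kind,
                       n_descriptor_bits=int(self.features.values.shape[1]))
        return out


def predict_scores(
    config: PredictorConfig, train: InteractionDataset, query_ids
) -> dict[str, PredictionScores]:
    """Fit the configured method on ``train`` and score each query drug."""
    query_ids = list(query_ids)
    if config.method == "nbi":
        net = BipartiteNetwork.from_dataset(train)
        return {q: nbi_predict(net, q) for q in query_ids}
    feats = config.features
    if config.method == "simspread":
        net = build_simspread_network(train, feats, config.alpha, config.scheme, config.metric)
        train_fp = feats.subset(train.drugs)
        queries = feats.subset(query_ids)
        S_qd = pairwise_similarity(queries, train_fp, metric=config.metric)
        Sp = build_feature_matrix(S_qd, config.alpha, config.scheme)
        return {
            q: denovo_spread(net, Sp.values[i], config.propagation, query=q)
            for i, q in enumerate(query_ids)
        }
    if config.method == "sdtnbi":
        net = sdtnbi_network(train, feats)
        return {
            q: denovo_spread(net, feats.row(q).astype(float), "binary", query=q)
            for q in query_ids
        }
    # knn
    queries = feats.subset(query_ids)
    train_fp = feats.subset(train.drugs)
    sims = pairwise_similarity(queries, train_fp, metric=config.metric)
    return {q: knn_predict(train, sims, q, k=config.k) for q in query_ids}


@dataclass
class ValidationReport:
    """Per-unit metric table plus the manifest that reproduces it."""

    per_unit: pd.DataFrame
    manifest: dict
    skipped: dict = field(default_factory=dict)
    predictions: dict = field(default_factory=dict)
    per_drug: pd.DataFrame | None = None  # drug granularity when units are folds

    def summarize(self) -> pd.DataFrame:
        """Median, IQR, mean and SD of every metric over evaluable units."""
        rows = []
        for m in METRIC_NAMES:
            vals = self.per_unit[m].dropna()
            if vals.empty:
                rows.append({"metric": m, "n": 0})
                continue
            q1, q3 = vals.quantile([0.25, 0.75])
            rows.append({
                "metric": m, "n": len(vals),
                "median": vals.median(), "iqr": q3 - q1,
                "mean": vals.mean(), "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
            })
        return pd.DataFrame(rows).set_index("metric")

    def write(self, path_tsv, path_manifest=None) -> None:
        self.per_unit.to_csv(path_tsv, sep="\t", index=False)
        if path_manifest is not None:
            with open(path_manifest, "w") as fh:
                json.dump({**self.manifest, "skipped": self.skipped}, fh, indent=2, sort_keys=True)


def dataset_hash(ds: InteractionDataset) -> str:
    payload = json.dumps([sorted(ds.drugs), sorted(ds.targets), sorted(map(list, ds.edges))])
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _labeled_ranking(
    ds: InteractionDataset, train: InteractionDataset, drug: str,
    pred: PredictionScores, extra_mask: set[str] | None = None,
    positives: set[str] | None = None,
) -> LabeledRanking:
    """Labels = the drug's held-out edges; mask = disconnected targets (+extra)."""
    positives = ds.targets_of(drug) if positives is None else positives
    connected = {t for _, t in train.edges}
    ids = pred.target_ids
    labels = np.array([t in positives for t in ids], dtype=bool)
    mask = np.array([t in connected for t in ids], dtype=bool)
    if extra_mask:
        mask &= np.array([t not in extra_mask for t in ids])
    return LabeledRanking(ids, pred.scores, labels, mask)


def _drug_row(unit_id: str, r: LabeledRanking, pred: PredictionScores) -> dict:
    row = {"unit": unit_id, **score_ranking(r)}
    row["n_masked"] = int((~r.mask).sum())
    row["in_domain"] = pred.in_domain
    return row


def loocv(
    ds: InteractionDataset, config: PredictorConfig, keep_predictions: bool = False
) -> ValidationReport:
    """Leave-one-drug-out cross-validation.

    Each drug is removed with all its edges, the network rebuilt from the
    remainder, and the drug's targets predicted de novo; metrics are
    computed per drug with disconnected targets masked.  Out-of-domain
    drugs keep their all-zero scores (worst-case ranking) and are flagged.
    """
    if ds.n_drugs < 2:
        raise DatasetError("leave-one-out needs at least two drugs")
    rows, preds = [], {}
    for drug in ds.drugs:
        train = ds.without_drug(drug)
        pred = predict_scores(config, train, [drug])[drug]
        r = _labeled_ranking(ds, train, drug, pred)
        rows.append(_drug_row(drug, r, pred))
        if keep_predictions:
            preds[drug] = pred
    per_unit = pd.DataFrame(rows)
    skipped = {"undefined_metrics": int(per_unit["auroc"].isna().sum()),
               "out_of_domain": int((~per_unit["in_domain"]).sum())}
    manifest = {"protocol": "loocv", "dataset_hash": dataset_hash(ds), **config.manifest()}
    return ValidationReport(per_unit, manifest, skipped, preds)


def _fold_partition(items: list, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(len(items))
    return [np.array(items, dtype=object)[idx] for idx in np.array_split(order, folds)]


def repeated_kfold(
    ds: InteractionDataset, config: PredictorConfig,
    folds: int = 10, repeats: int = 10, seed: int = 0,
) -> ValidationReport:
    """Repeated drug-wise k-fold cross-validation.

    Drugs are partitioned into near-equal folds afresh per repeat; each
    fold's drugs are scored against the network built from the remaining
    drugs.  The per-fold metric value is the mean over the fold's evaluable
    drugs; drug-level rows are retained in ``per_drug``.
    """
    if folds > ds.n_drugs:
        raise DatasetError(f"cannot split {ds.n_drugs} drugs into {folds} folds")
    fold_rows, drug_rows = [], []
    for rep in range(repeats):
        rng = np.random.default_rng((seed + rep) % 2**31)
        for f, held in enumerate(_fold_partition(list(ds.drugs), folds, rng)):
            train = ds.without_drugs(held)
            preds = predict_scores(config, train, list(held))
            fold_metrics = []
            for drug in held:
                r = _labeled_ranking(ds, train, drug, preds[drug])
                row = _drug_row(drug, r, preds[drug])
                row.update(repeat=rep, fold=f)
                drug_rows.append(row)
                fold_metrics.append({m: row[m] for m in METRIC_NAMES})
            frame = pd.DataFrame(fold_metrics)
            fold_rows.append({
                "unit": f"rep{rep}_fold{f}", "repeat": rep, "fold": f,
                **frame.mean(skipna=True).to_dict(),
                "n_drugs": len(held),
                "n_evaluable": int(frame["auroc"].notna().sum()),
            })
    per_unit = pd.DataFrame(fold_rows)
    per_drug = pd.DataFrame(drug_rows)
    skipped = {"undefined_metrics": int(per_drug["auroc"].isna().sum()),
               "out_of_domain": int((~per_drug["in_domain"]).sum())}
    manifest = {
        "protocol": "repeated_kfold", "folds": folds, "repeats": repeats, "seed": seed,
        "dataset_hash": dataset_hash(ds), **config.manifest(),
    }
    return ValidationReport(per_unit, manifest, skipped, per_drug=per_drug)


def dti_holdout_kfold(
    ds: InteractionDataset, config: PredictorConfig,
    folds: int = 10, repeats: int = 10, seed: int = 0,
) -> ValidationReport:
    """Repeated k-fold over interactions (edges) rather than drugs.

    Designed for transductive methods (NBI) that cannot score unseen drugs:
    held-out edges are removed from training but their drugs remain in the
    network through their other edges.  Drugs that lose every training edge
    in a fold are skipped for that fold (logged).  A drug's retained
    training edges are masked during evaluation — they are known
    annotations, not prediction tasks.
    """
    if folds > ds.n_edges:
        raise DatasetError(f"cannot split {ds.n_edges} edges into {folds} folds")
    edges = sorted(ds.edges)
    fold_rows, drug_rows = [], []
    n_skipped_drugs = 0
    for rep in range(repeats):
        rng = np.random.default_rng((seed + rep) % 2**31)
        for f, held in enumerate(_fold_partition(edges, folds, rng)):
            held_set = {tuple(e) for e in held}
            train = ds.without_edges(held_set)
            fold_drugs = sorted({d for d, _ in held_set})
            evaluable = [d for d in fold_drugs if train.drug_degree(d) > 0]
            n_skipped_drugs += len(fold_drugs) - len(evaluable)
            for d in set(fold_drugs) - set(evaluable):
                logger.info("rep %d fold %d: drug %s lost all training edges; skipped", rep, f, d)
            if not evaluable:
                continue
            preds = predict_scores(config, train, evaluable)
            fold_metrics = []
            for drug in evaluable:
                positives = {t for dd, t in held_set if dd == drug}
                retained = train.targets_of(drug)
                r = _labeled_ranking(ds, train, drug, preds[drug],
                                     extra_mask=retained, positives=positives)
                row = _drug_row(drug, r, preds[drug])
                row.update(repeat=rep, fold=f)
                drug_rows.append(row)
                fold_metrics.append({m: row[m] for m in METRIC_NAMES})
            frame = pd.DataFrame(fold_metrics)
            fold_rows.append({
                "unit": f"rep{rep}_fold{f}", "repeat": rep, "fold": f,
                **frame.mean(skipna=True).to_dict(),
                "n_drugs": len(evaluable),
                "n_evaluable": int(frame["auroc"].notna().sum()),
            })
    per_unit = pd.DataFrame(fold_rows)
    per_drug = pd.DataFrame(drug_rows)
    skipped = {"drugs_without_training_edges": n_skipped_drugs,
               "undefined_metrics": int(per_drug["auroc"].isna().sum())}
    manifest = {
        "protocol": "dti_holdout_kfold", "folds": folds, "repeats": repeats, "seed": seed,
        "dataset_hash": dataset_hash(ds), **config.manifest(),
    }
    return ValidationReport(per_unit, manifest, skipped, per_drug=per_drug)


def time_split_validate(
    train: InteractionDataset, test: InteractionDataset, config: PredictorConfig,
    keep_predictions: bool = False,
) -> ValidationReport:
    """Chronological hold-out: train on the older snapshot, score newer drugs.

    Inputs should come from :func:`simspread.datasets.time_split` so the two
    snapshots share targets and no test edge is already known.  Test drugs
    without any positive among the training targets are skipped (logged).
    """
    panel = set(train.targets)
    rows, preds = [], {}
    eligible = [d for d in test.drugs if test.targets_of(d) & panel]
    for d in set(test.drugs) - set(eligible):
        logger.info("test drug %s has no annotation among training targets; skipped", d)
    scored = predict_scores(config, train, eligible)
    for drug in eligible:
        pred = scored[drug]
        r = _labeled_ranking(test, train, drug, pred)
        rows.append(_drug_row(drug, r, pred))
        if keep_predictions:
            preds[drug] = pred
    per_unit = pd.DataFrame(rows)
    skipped = {
        "test_drugs_without_shared_positive": len(test.drugs) - len(eligible),
        "undefined_metrics": int(per_unit["auroc"].isna().sum()) if not per_unit.empty else 0,
    }
    manifest = {
        "protocol": "time_split",
        "train_hash": dataset_hash(train), "test_hash": dataset_hash(test),
        **config.manifest(),
    }
    return ValidationReport(per_unit, manifest, skipped, preds)


def alpha_sweep(
    ds: InteractionDataset, config: PredictorConfig,
    alphas=None, protocol: str = "loocv", **protocol_kwargs,
) -> pd.DataFrame:
    """Re-run a validation protocol over a grid of similarity cutoffs.

    Default grid: 0 to 1 in steps of 0.05.  Returns one row per alpha with
    the median and mean of every metric, for choosing the operating cutoff.
    """
    from dataclasses import replace

    if alphas is None:
        alphas = np.round(np.arange(0.0, 1.0001, 0.05), 2)
    runners = {"loocv": loocv, "kfold": repeated_kfold}
    if protocol not in runners:
        raise ValueError(f"unknown protocol {protocol!r}")
    rows = []
    for a in alphas:
        rep = runners[protocol](ds, replace(config, alpha=float(a)), **protocol_kwargs)
        summary = rep.summarize()
        row = {"alpha": float(a)}
        for m in METRIC_NAMES:
            if "median" in summary.columns and not np.isnan(summary.loc[m].get("median", np.nan)):
                row[f"median_{m}"] = float(summary.loc[m, "median"])
                row[f"mean_{m}"] = float(summary.loc[m, "mean"])
        rows.append(row)
    return pd.DataFrame(rows)
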