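#!/usr/bin/env python
"""Re-run the published benchmark protocols on user-supplied datasets.

The full benchmark numbers (per-dataset cross-validation medians,
time-split medians, top-250 scaffold/target diversity counts and the
application-domain fraction) depend on the public benchmark datasets
(the four Yamanishi panels, the Global panel, and a ChEMBL-derived
chronological pair), which are not distributed with this package.  Supply
them as TSV edge lists plus SMILES files and this script reruns the whole
pipeline: leave-one-out and 10x10-fold cross-validation for every method,
time-split validation, and the diversity analysis of the pooled top-L
predictions.

Example:
    python scripts/external_benchmarks.py \
        --train chembl24.tsv --test chembl28.tsv \
        --train-smiles chembl24.smi --test-smiles chembl28.smi \
        --outdir results/external
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from simspread.chem import compute_fingerprints
from simspread.datasets import read_interactions, read_smiles, time_split
from simspread.exploration import diversity_curves
from simspread.validation import (
    PredictorConfig,
    loocv,
    repeated_kfold,
    time_split_validate,
)

METHOD_CONFIGS = {
    "simspread_sim": dict(method="simspread", scheme="similarity", propagation="weighted"),
    "simspread_bin": dict(method="simspread", scheme="binary", propagation="binary"),
    "sdtnbi": dict(method="sdtnbi"),
    "knn": dict(method="knn", k=1),
}


def main() -> None:
    parser = argparse.ArgumentParser(
        description=__doc__, formatter_class=argparse.RawDescriptionHelpFormatter
    )
    parser.add_argument("--train", required=True, type=Path,
                        help="training interactions TSV (older snapshot for time split)")
    parser.add_argument("--test", type=Path,
                        help="newer-snapshot interactions TSV (enables time-split mode)")
    parser.add_argument("--train-smiles", required=True, type=Path)
    parser.add_argument("--test-smiles", type=Path)
    parser.add_argument("--descriptor", default="ecfp4",
                        choices=["ecfp4", "fcfp4", "maccs", "fp2"])
    parser.add_argument("--alpha", type=float, default=0.2)
    parser.add_argument("--folds", type=int, default=10)
    parser.add_argument("--repeats", type=int, default=10)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--top-l", type=int, default=1000)
    parser.add_argument("--outdir", required=True, type=Path)
    args = parser.parse_args()

    args.outdir.mkdir(parents=True, exist_ok=True)
    smiles = read_smiles(args.train_smiles)
    if args.test_smiles:
        smiles.update(read_smiles(args.test_smiles))
    features = compute_fingerprints(smiles, args.descriptor)
    summaries = {}

    if args.test is None:
        ds = read_interactions(args.train)
        for name, kw in METHOD_CONFIGS.items():
            config = PredictorConfig(features=features, alpha=args.alpha, **kw)
            loo = loocv(ds, config)
            loo.write(args.outdir / f"{name}_loocv.tsv")
            kf = repeated_kfold(ds, config, folds=args.folds,
                                repeats=args.repeats, seed=args.seed)
            kf.write(args.outdir / f"{name}_kfold.tsv")
            summaries[name] = {
                "loocv": loo.summarize().to_dict(),
                "kfold": kf.summarize().to_dict(),
            }
    else:
        train, test = time_split(read_interactions(args.train), read_interactions(args.test))
        preds_for_pool = []
        for name, kw in METHOD_CONFIGS.items():
            config = PredictorConfig(features=features, alpha=args.alpha, **kw)
            report = time_split_validate(train, test, config, keep_predictions=True)
            report.write(args.outdir / f"{name}_timesplit.tsv")
            pooled = pd.concat(
                [p.to_frame() for p in report.predictions.values()], ignore_index=True
            )
            preds_for_pool.append((name, pooled))
            out_of_domain = sum(1 for p in report.predictions.values() if not p.in_domain)
            summaries[name] = {
                "timesplit": report.summarize().to_dict(),
                "out_of_domain_fraction": out_of_domain / max(len(report.predictions), 1),
            }
        test_structures = {d: smiles[d] for d in test.drugs if d in smiles}
        train_structures = {d: smiles[d] for d in train.drugs if d in smiles}
        for name, pooled in preds_for_pool:
            curves = diversity_curves(
                pooled, train, test_structures, train_structures,
                L_grid=range(10, args.top_l + 1, 10),
            )
            curves.to_csv(args.outdir / f"{name}_diversity.tsv", sep="\t", index=False)
    (args.outdir / "summary.json").write_text(json.dumps(summaries, indent=2, default=str))
    print(f"wrote {args.outdir}/summary.json")


if __name__ == "__main__":
    main()
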