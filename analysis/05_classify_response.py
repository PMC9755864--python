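#!/usr/bin/env python
"""Predict neoadjuvant-chemotherapy response from the selected features:
k-NN (k = 1), logistic regression and random forest under 100 stratified
80-20 hold-out repeats with SMOTE balancing of the training minority.
The same split plan is used for the 2D and 3D analyses.

Reads results/run/; writes metrics_{mode}.csv and patient_rates_{mode}.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ewing_radiomics.classify import make_split_plan, run_classification

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--outdir", type=Path, default=Path("results"))
parser.add_argument("--modes", nargs="+", default=["3D", "2D"])
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--repeats", type=int, default=100)
args = parser.parse_args()

run_dir = args.outdir / "run"
labels = pd.read_csv(run_dir / "labels.csv", index_col="patient_id")["label"]
plan = make_split_plan(labels, train_fraction=0.8, repeats=args.repeats,
                       seed=args.seed)

for mode in args.modes:
    features = pd.read_csv(run_dir / f"features_{mode}_original.csv",
                           index_col="patient_id")
    feats = list(pd.read_csv(run_dir / f"selection_{mode}.csv")["feature"])
    if not feats:
        print(f"{mode}: no selected features — nothing to classify")
        continue
    report = run_classification(features[feats], labels, plan, seed=args.seed)
    report.table().to_csv(run_dir / f"metrics_{mode}.csv")
    report.patient_rates.rename_axis("patient_id").to_csv(
        run_dir / f"patient_rates_{mode}.csv")
    print(f"=== {mode} ({len(feats)} features, {len(plan)} repeats) ===")
    print(report.table().to_string())
    for clf in report.metrics.columns:
        print(f"    {clf}: {report.n_patients_at_threshold(clf)}/30 patients "
              f"correct in >= 80% of their test appearances")
    print(f"    all classifiers: {report.n_patients_all_classifiers} patients")
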