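#!/usr/bin/env python
"""Reduce the stable feature set: Pearson collinearity pruning at
|r| > 0.8 followed by Wilcoxon rank-sum significance (p < 0.05, no
multiple-testing correction), ranked by p.

Reads results/run/; writes selection_{mode}.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ewing_radiomics.selection import select_features

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--outdir", type=Path, default=Path("results"))
parser.add_argument("--modes", nargs="+", default=["3D", "2D"])
args = parser.parse_args()

run_dir = args.outdir / "run"
labels = pd.read_csv(run_dir / "labels.csv", index_col="patient_id")["label"]

for mode in args.modes:
    features = pd.read_csv(run_dir / f"features_{mode}_original.csv",
                           index_col="patient_id")
    icc = pd.read_csv(run_dir / f"icc_{mode}.csv", index_col="feature")
    stable = list(icc.index[icc["stable"]])
    res = select_features(features[stable], labels)
    out = res.selected.rename_axis("feature").reset_index()
    out.to_csv(run_dir / f"selection_{mode}.csv", index=False)
    print(f"{mode}: {len(stable)} stable -> {len(res.survivors)} after "
          f"collinearity -> {len(res.selected)} selected (p < {res.alpha})")
    for feat, p in res.selected["p"].items():
        print(f"    p = {p:.4f}  {feat}")
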