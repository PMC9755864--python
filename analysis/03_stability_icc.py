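#!/usr/bin/env python
"""Quantify feature reproducibility under ROI translation: per-feature
ICC(2,1) over the five ROI variants, stability filter at ICC > 0.75, the
per-group stable fractions, and the Welch t-test comparing 2D vs 3D ICC
distributions.

Reads results/run/features_*; writes icc_{mode}.csv, icc_ranked_{mode}.csv,
stable_fraction_{mode}.csv and stability_comparison.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ewing_radiomics.pipeline import VARIANT_FILES
from ewing_radiomics.stability import (
    compare_stability,
    stability_filter,
    stable_fraction_summary,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--outdir", type=Path, default=Path("results"))
parser.add_argument("--modes", nargs="+", default=["3D", "2D"])
args = parser.parse_args()

run_dir = args.outdir / "run"
iccs = {}
for mode in args.modes:
    tables = [
        pd.read_csv(run_dir / f"features_{mode}_{fn}.csv", index_col="patient_id")
        for fn in VARIANT_FILES.values()
    ]
    icc = stability_filter(tables)
    icc.to_csv(run_dir / f"icc_{mode}.csv")
    icc.sort_values("icc", ascending=False).reset_index()[["feature", "icc"]].to_csv(
        run_dir / f"icc_ranked_{mode}.csv", index=False)
    summary = stable_fraction_summary(icc)
    summary.to_csv(run_dir / f"stable_fraction_{mode}.csv", index=False)
    iccs[mode] = icc
    print(f"{mode}: {int(icc['stable'].sum())}/{len(icc)} features stable "
          f"({icc['stable'].mean():.0%})")
    for _, row in summary.iterrows():
        print(f"    {row['group']:>11}: {row['stable_fraction']:.0%} "
              f"({row['n_stable']}/{row['n_features']})")

if {"2D", "3D"} <= set(iccs):
    comp = compare_stability(iccs["3D"], iccs["2D"])
    pd.DataFrame([comp]).to_csv(run_dir / "stability_comparison.csv", index=False)
    print(f"3D vs 2D ICC (Welch): t = {comp['t']:.2f}, "
          f"dof = {comp['dof']:.0f}, p = {comp['p']:.2g}")
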