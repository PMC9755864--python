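"""End-to-end experiment orchestration.

``run_pipeline`` drives: cohort generation (or NIfTI ingestion) ->
pre-processing -> 2D+3D feature extraction over the 5-ROI perturbation set
-> ICC stability filtering -> collinearity/rank-sum selection -> SMOTE-
balanced classification -> report files. All stage outputs are plain CSV /
JSON in the run directory, written deterministically (timestamps only in
the provenance log), and later stages re-read them, so stages can be rerun
individually.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import CLASSIFIERS, EvalReport, make_split_plan, run_classification
from .core import InvalidConfigError
from .features.extract import compute_sources, extract_feature_vector
from .preprocess import PreprocessParams, largest_area_slice, preprocess_case_images
from .selection import SelectionResult, select_features, wilcoxon_select
from .stability import (
    DEFAULT_ICC_THRESHOLD,
    TRANSLATION_FRACTION,
    build_perturbation_set,
    compare_stability,
    stability_filter,
    stable_fraction_summary,
)
from .synthetic import CohortConfig, PatientCase, generate_cohort, read_cohort, write_cohort

__all__ = ["RunConfig", "validate_config", "run_pipeline", "extract_mode_tables"]

VARIANT_FILES = {"original": "original", "x+": "xpos", "x-": "xneg", "y+": "ypos", "y-": "yneg"}


@dataclass
class RunConfig:
    """Serializable configuration of a full experiment run."""

    outdir: str = "results/run"
    cohort_dir: str | None = None          #: ingest mode; None -> synthetic
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    modes: tuple[str, ...] = ("3D", "2D")
    wavelets: bool = True
    perturbation_fraction: float = TRANSLATION_FRACTION
    icc_model: str = "icc2"
    icc_threshold: float = DEFAULT_ICC_THRESHOLD
    r_threshold: float = 0.8
    alpha: float = 0.05
    top_k: int | None = None
    selection_in_fold: bool = False
    classifiers: tuple[str, ...] = CLASSIFIERS
    train_fraction: float = 0.8
    repeats: int = 100
    stratified: bool = True
    smote_k: int = 5
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["preprocess"] = self.preprocess.to_dict()
        d["modes"] = list(self.modes)
        d["classifiers"] = list(self.classifiers)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["cohort"] = CohortConfig(**{k: tuple(v) if isinstance(v, list) else v
                                      for k, v in d["cohort"].items()})
        d["preprocess"] = PreprocessParams(**d["preprocess"])
        d["modes"] = tuple(d["modes"])
        d["classifiers"] = tuple(d["classifiers"])
        return cls(**d)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations (empty = ok)."""
    v = []
    if not 0 < config.train_fraction < 1:
        v.append(f"train_fraction {config.train_fraction} not in (0, 1)")
    if not 0 < config.perturbation_fraction < 1:
        v.append(f"perturbation_fraction {config.perturbation_fraction} not in (0, 1)")
    for name in ("icc_threshold", "r_threshold", "alpha"):
        val = getattr(config, name)
        if not 0 <= val <= 1:
            v.append(f"{name} {val} not in [0, 1]")
    if config.preprocess.bin_count < 2:
        v.append("bin_count must be >= 2")
    if config.repeats < 1:
        v.append("repeats must be >= 1")
    if config.icc_model not in ("icc2", "icc3"):
        v.append(f"unknown icc_model {config.icc_model!r}")
    for c in config.classifiers:
        if c not in CLASSIFIERS:
            v.append(f"unknown classifier {c!r}")
    for m in config.modes:
        if m not in ("2D", "3D"):
            v.append(f"unknown mode {m!r}")
    if config.cohort_dir is not None:
        d = Path(config.cohort_dir)
        if not d.is_dir():
            v.append(f"cohort_dir {d} does not exist")
        elif not (d / "labels.csv").exists():
            v.append(f"labels.csv missing in {d}")
    return v


def _log(log: list, stage: str, **info) -> None:
    entry = {"stage": stage, **info}
    log.append(entry)
    print(f"[{stage}] " + ", ".join(f"{k}={v}" for k, v in info.items()), file=sys.stderr)


def extract_mode_tables(
    cohort: list[PatientCase],
    mode: str,
    params: PreprocessParams,
    wavelets: bool = True,
    fraction: float = TRANSLATION_FRACTION,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Preprocess every case and extract features for the 5-ROI
    perturbation set in one ROI mode.

    Returns {variant -> patients x features table} (variants: original,
    x+, x-, y+, y-) and the list of excluded patients (perturbation
    failures). Source images (original + wavelet sub-bands) are computed
    once per patient and shared across the five ROI variants.
    """
    variant_rows: dict[str, dict] = {v: {} for v in VARIANT_FILES}
    excluded: list[str] = []
    for case in cohort:
        images, mask = preprocess_case_images(case.images, case.mask3d, params)
        if mode == "2D":
            _, mask = largest_area_slice(mask)
        pert = build_perturbation_set(mask, fraction=fraction)
        cache: dict = {}
        for variant, m in zip(pert.variant_names, pert.masks):
            vec, _flags = extract_feature_vector(
                images, m, mode, params=params, wavelets=wavelets, sources_cache=cache
            )
            variant_rows[variant][case.patient_id] = vec
    tables = {
        v: pd.DataFrame.from_dict(rows, orient="index")
        for v, rows in variant_rows.items()
    }
    return tables, excluded


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full experiment; returns the in-memory report bundle."""
    violations = validate_config(config)
    if violations:
        raise InvalidConfigError("; ".join(violations))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    t0 = time.time()

    # --- cohort ---------------------------------------------------------
    if config.cohort_dir is not None:
        cohort = read_cohort(config.cohort_dir)
        _log(log, "cohort", source=config.cohort_dir, n=len(cohort))
    else:
        cohort = generate_cohort(config.cohort)
        _log(log, "cohort", source="synthetic", n=len(cohort),
             n_good=config.cohort.n_good, n_poor=config.cohort.n_poor,
             seed=config.cohort.seed)
    labels = pd.Series({c.patient_id: c.label for c in cohort}, name="label")
    labels.rename_axis("patient_id").to_frame().to_csv(outdir / "labels.csv")

    bundle: dict = {"labels": labels, "modes": {}}
    manifest = {"version": __version__, "config": json.loads(config.to_json()),
                "feature_counts": {}}
    icc_tables: dict[str, pd.DataFrame] = {}

    plan = make_split_plan(labels, train_fraction=config.train_fraction,
                           repeats=config.repeats, seed=config.seed,
                           stratified=config.stratified)
    _log(log, "split_plan", repeats=len(plan), train_fraction=config.train_fraction,
         stratified=config.stratified, shared_across_modes=True)

    for mode in config.modes:
        mode_out: dict = {}
        # --- extraction over the perturbation set -----------------------
        tables, excluded = extract_mode_tables(
            cohort, mode, config.preprocess, wavelets=config.wavelets,
            fraction=config.perturbation_fraction,
        )
        for variant, tbl in tables.items():
            tbl.rename_axis("patient_id").to_csv(
                outdir / f"features_{mode}_{VARIANT_FILES[variant]}.csv"
            )
        features = tables["original"]
        n_per_patient = features.shape[1]
        manifest["feature_counts"][mode] = {
            "per_patient": int(n_per_patient),
            "per_sequence": int(n_per_patient // 2),
        }
        _log(log, "extract", mode=mode, patients=len(features),
             features_per_patient=n_per_patient, excluded=len(excluded))

        # --- stability ---------------------------------------------------
        icc = stability_filter([tables[v] for v in tables],
                               threshold=config.icc_threshold,
                               icc_model=config.icc_model)
        icc_tables[mode] = icc
        icc.to_csv(outdir / f"icc_{mode}.csv")
        summary = stable_fraction_summary(icc)
        summary.to_csv(outdir / f"stable_fraction_{mode}.csv", index=False)
        # ranked-ICC export (stability-profile curve)
        icc.sort_values("icc", ascending=False).reset_index()[["feature", "icc"]].to_csv(
            outdir / f"icc_ranked_{mode}.csv", index=False
        )
        stable_feats = list(icc.index[icc["stable"]])
        _log(log, "stability", mode=mode, icc_model=config.icc_model,
             threshold=config.icc_threshold, n_stable=len(stable_feats),
             stable_fraction=round(float(icc["stable"].mean()), 4))

        # --- selection ---------------------------------------------------
        sel = select_features(features[stable_feats], labels,
                              r_threshold=config.r_threshold,
                              alpha=config.alpha, top_k=config.top_k)
        sel_df = sel.selected.rename_axis("feature").reset_index()
        sel_df.to_csv(outdir / f"selection_{mode}.csv", index=False)
        with open(outdir / f"selection_{mode}.json", "w") as fh:
            json.dump({
                "survivors_after_collinearity": sel.survivors,
                "selected": {f: float(p) for f, p in sel.selected["p"].items()},
                "degenerate": sel.degenerate,
                "r_threshold": sel.r_threshold, "alpha": sel.alpha,
                "multiple_testing_correction": sel.multiple_testing_correction,
            }, fh, indent=2)
        selected = sel.selected_features
        _log(log, "select", mode=mode, survivors=len(sel.survivors),
             selected=len(selected))

        # --- classification ---------------------------------------------
        cls_features = selected
        if not cls_features:
            fallback = wilcoxon_select(features[sel.survivors], labels,
                                       alpha=1.1, top_k=4)
            cls_features = list(fallback.index)
            _log(log, "classify", mode=mode,
                 note="no feature passed alpha; using top-4 by p", n=len(cls_features))
        report = run_classification(features[cls_features], labels, plan,
                                    classifiers=config.classifiers,
                                    smote_k=config.smote_k, seed=config.seed)
        report.metrics.to_csv(outdir / f"metrics_mean_{mode}.csv")
        report.metrics_sd.to_csv(outdir / f"metrics_sd_{mode}.csv")
        report.table().to_csv(outdir / f"metrics_{mode}.csv")
        report.patient_rates.rename_axis("patient_id").to_csv(
            outdir / f"patient_rates_{mode}.csv"
        )
        _log(log, "classify", mode=mode,
             classifiers=",".join(config.classifiers),
             n_features=len(cls_features),
             n_at_80pct_all=report.n_patients_all_classifiers)

        mode_out.update({"features": features, "tables": tables, "icc": icc,
                         "stable_fraction": summary, "selection": sel,
                         "classification": report,
                         "classification_features": cls_features})
        bundle["modes"][mode] = mode_out

    # --- 2D vs 3D stability comparison ----------------------------------
    if {"2D", "3D"} <= set(icc_tables):
        comp = compare_stability(icc_tables["3D"], icc_tables["2D"])
        pd.DataFrame([comp]).to_csv(outdir / "stability_comparison.csv", index=False)
        bundle["stability_comparison"] = comp
        _log(log, "compare_stability", t=round(comp["t"], 3), p=comp["p"])

    with open(outdir / "run_config.json", "w") as fh:
        fh.write(config.to_json())
    manifest["stages"] = log
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "log.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle
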