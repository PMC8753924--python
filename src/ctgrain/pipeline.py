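"""File-based pipeline stages: simulate -> preprocess -> segment -> traits -> stats.

Stages communicate only through files under one run directory, so real CT
exports (PNG slice stacks plus a layout table) can replace the simulated
stage without code changes.  Every stage is deterministic in the config's
root seed; a manifest records inputs, seeds and versions, and re-running
with the same config reproduces byte-identical trait tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import FeatureSpec
from .phantom import ScanSpec, default_panel, simulate_study
from .preprocess import ContrastParams, enhance_contrast, to_8bit
from .segmentation import (
    ClassifierSpec,
    PixelClassifier,
    build_training_set,
    cross_validate,
    read_label_volume,
    segment,
    train_classifier,
    write_label_volume,
)
from .stackio import read_slice_stack, write_slice_stack
from .stats import analyze_trait_table
from .traits import build_trait_table, write_trait_csv, read_trait_csv

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "output_dir": "ctgrain_run",
    "phantom": {
        "n_genotypes": 19,
        "n_scans": 3,
        "n_rows": 3,
        "n_cols": 7,
        "check_genotype": "G01",
        "n_check_wells": 3,
        "kernels_per_well": 40,
        "well_voxel_extent": [64, 64, 64],
        "noise_sd": 5.0,
        "attenuation_gradient": 0.03,
        "voxel_size_mm": 0.25,
    },
    "contrast": {"saturated_fraction": 0.003},
    "features": {"sigmas": [1.0, 2.0, 4.0, 8.0]},
    "classifier": {"n_trees": 200, "features_per_node": 2},
    "training": {"n_samples": 8000, "slices_per_scan": 10},
    "stats": {"alpha": 0.05},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _run_dir(cfg: dict) -> Path:
    return Path(cfg["output_dir"])


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path}; run the '{stage}' stage first"
        )
    return path


def _scan_spec_from_cfg(cfg: dict, layout: pd.DataFrame, rep: int) -> ScanSpec:
    ph = cfg["phantom"]
    return ScanSpec(
        layout=layout,
        kernels_per_well=ph["kernels_per_well"],
        well_voxel_extent=tuple(ph["well_voxel_extent"]),
        noise_sd=ph["noise_sd"],
        attenuation_gradient=ph["attenuation_gradient"],
        voxel_size_mm=ph["voxel_size_mm"],
        seed=cfg["seed"],
        rep=rep,
    )


def _update_manifest(cfg: dict, stage: str, outputs: dict) -> None:
    run = _run_dir(cfg)
    mpath = run / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {
        "version": __version__,
        "seed": cfg["seed"],
        "stages": {},
    }
    manifest["stages"][stage] = outputs
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_simulate(cfg: dict) -> Path:
    """Generate the phantom study: PNG stacks, labels, layouts, true traits."""
    run = _run_dir(cfg)
    run.mkdir(parents=True, exist_ok=True)
    save_config(cfg, run / "config.yaml")
    ph = cfg["phantom"]
    panel = default_panel(ph["n_genotypes"], seed=cfg["seed"])
    study = simulate_study(
        panel,
        n_scans=ph["n_scans"],
        n_rows=ph["n_rows"],
        n_cols=ph["n_cols"],
        check_genotype=ph["check_genotype"],
        n_check_wells=ph["n_check_wells"],
        kernels_per_well=ph["kernels_per_well"],
        well_voxel_extent=tuple(ph["well_voxel_extent"]),
        attenuation_gradient=ph["attenuation_gradient"],
        noise_sd=ph["noise_sd"],
        voxel_size_mm=ph["voxel_size_mm"],
        seed=cfg["seed"],
    )
    true_tables = []
    for grid, truth, spec in study:
        sdir = run / "scans" / f"scan{spec.rep}"
        write_slice_stack(
            np.floor(grid + 0.5).astype(np.uint8),
            sdir,
            voxel_size_mm=spec.voxel_size_mm,
        )
        tdir = run / "truth"
        tdir.mkdir(exist_ok=True)
        write_label_volume(truth.label_volume, tdir / f"scan{spec.rep}_labels.npz")
        spec.layout.assign(rep=spec.rep).to_csv(
            tdir / f"scan{spec.rep}_layout.csv", index=False
        )
        true_tables.append(truth.per_unit_true_traits)
    pd.concat(true_tables, ignore_index=True).to_csv(
        run / "truth" / "true_traits.csv", index=False
    )
    _update_manifest(cfg, "simulate", {"n_scans": ph["n_scans"]})
    return run


def _load_scans(cfg: dict, subdir: str, stage: str):
    run = _run_dir(cfg)
    ph = cfg["phantom"]
    out = []
    for rep in range(1, ph["n_scans"] + 1):
        sdir = _require(run / subdir / f"scan{rep}", stage)
        grid, _ = read_slice_stack(sdir)
        layout = pd.read_csv(_require(run / "truth" / f"scan{rep}_layout.csv", "simulate"))
        out.append((rep, grid, _scan_spec_from_cfg(cfg, layout, rep)))
    return out


def run_preprocess(cfg: dict) -> Path:
    """8-bit conversion + stack-histogram contrast stretch, per scan."""
    run = _run_dir(cfg)
    params = ContrastParams(cfg["contrast"]["saturated_fraction"])
    for rep, grid, spec in _load_scans(cfg, "scans", "simulate"):
        enhanced = enhance_contrast(to_8bit(grid), params)
        write_slice_stack(
            enhanced, run / "preprocessed" / f"scan{rep}",
            voxel_size_mm=spec.voxel_size_mm,
        )
    _update_manifest(cfg, "preprocess", {"saturated_fraction": params.saturated_fraction})
    return run


def run_segment(cfg: dict) -> Path:
    """Train on ground-truth-annotated slices, cross-validate, predict tiles."""
    run = _run_dir(cfg)
    fspec = FeatureSpec(sigmas=tuple(cfg["features"]["sigmas"]))
    cspec = ClassifierSpec(
        n_trees=cfg["classifier"]["n_trees"],
        features_per_node=cfg["classifier"]["features_per_node"],
        seed=cfg["seed"],
    )
    scans = []
    for rep, grid, spec in _load_scans(cfg, "preprocessed", "preprocess"):
        labels = read_label_volume(
            _require(run / "truth" / f"scan{rep}_labels.npz", "simulate")
        )
        scans.append((rep, grid, labels, spec))
    ts = build_training_set(
        scans,
        n_samples=cfg["training"]["n_samples"],
        slices_per_scan=cfg["training"]["slices_per_scan"],
        seed=cfg["seed"],
        feature_spec=fspec,
    )
    report = cross_validate(ts, cspec, seed=cfg["seed"])
    (run / "eval_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    clf = train_classifier(ts, cspec)
    clf.save(run / "classifier.pkl")
    ldir = run / "labels"
    ldir.mkdir(exist_ok=True)
    for rep, grid, _labels, spec in scans:
        pred = segment(grid, clf, scan_spec=spec)
        write_label_volume(pred, ldir / f"scan{rep}_labels.npz")
    _update_manifest(
        cfg,
        "segment",
        {"percent_correct": report.percent_correct, "rmse": report.rmse,
         "n_training_samples": len(ts)},
    )
    return run


def run_traits(cfg: dict) -> Path:
    """Predicted labels + preprocessed stacks -> the per-unit trait table."""
    run = _run_dir(cfg)
    entries = []
    for rep, grid, spec in _load_scans(cfg, "preprocessed", "preprocess"):
        labels = read_label_volume(
            _require(run / "labels" / f"scan{rep}_labels.npz", "segment")
        )
        entries.append((labels, grid, spec))
    table = build_trait_table(entries)
    write_trait_csv(table, run / "traits.csv")
    _update_manifest(cfg, "traits", {"n_units": len(table)})
    return run


def run_stats(cfg: dict) -> Path:
    """Mixed-model analysis of the trait table; reports as JSON/CSV."""
    run = _run_dir(cfg)
    table = read_trait_csv(_require(run / "traits.csv", "traits"))
    results = analyze_trait_table(table, alpha=cfg["stats"]["alpha"])
    sdir = run / "stats"
    sdir.mkdir(exist_ok=True)
    for trait, fit in results["random"].items():
        report = fit.summary_dict()
        fx = results["fixed"][trait]
        report["blues"] = fx.blues.to_dict()
        report["eblups"] = fit.eblups.to_dict()
        report["hsd"] = fx.hsd
        report["letters"] = fx.letters.to_dict()
        report["prune_trace"] = fit.prune_trace
        (sdir / f"{trait}.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    results["correlations"]["r"].to_csv(sdir / "correlations_r.csv")
    results["correlations"]["p"].to_csv(sdir / "correlations_p.csv")
    _update_manifest(cfg, "stats", {"traits": sorted(results["random"])})
    return run


def run_all(cfg: dict) -> Path:
    run_simulate(cfg)
    run_preprocess(cfg)
    run_segment(cfg)
    run_traits(cfg)
    return run_stats(cfg)
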