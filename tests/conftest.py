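"""Shared fixtures: phantom studies, trained classifiers, pipeline runs.

The heavier fixtures are session-scoped because several tests interrogate
the same simulated study from different angles (classifier evaluation,
trait recovery, conservation identities).
"""

from __future__ import annotations

import numpy as np
import pytest

from ctgrain import phantom, preprocess, segmentation
from ctgrain.features import FeatureSpec

SEED = 0


@pytest.fixture(scope="session")
def study6():
    """Three-scan study: 6 genotypes (incl. waxy, void-prone, check) in 2x3
    wells of 64^3 voxels, 40 kernels/well, well-separated radiometry and
    geometrically exact (jitter-free) kernels — the recovery-validation
    conditions."""
    panel = phantom.default_panel(6, separated=True, jitter=False)
    return panel, phantom.simulate_study(
        panel,
        n_scans=3,
        n_rows=2,
        n_cols=3,
        check_genotype="G01",
        n_check_wells=1,
        noise_sd=4.0,
        seed=SEED,
    )


@pytest.fixture(scope="session")
def preprocessed6(study6):
    """(rep, preprocessed grid, truth labels, spec) per scan of study6."""
    _, study = study6
    out = []
    for grid, truth, spec in study:
        g8 = preprocess.preprocess_stack(grid)
        out.append((spec.rep, g8, truth.label_volume, spec))
    return out


@pytest.fixture(scope="session")
def training_full(preprocessed6):
    """Annotation-scale training set (52,966 voxels over 10 slices/scan)."""
    return segmentation.build_training_set(preprocessed6, n_samples=52_966, seed=SEED)


@pytest.fixture(scope="session")
def classifier_full(training_full):
    return segmentation.train_classifier(
        training_full, segmentation.ClassifierSpec(seed=SEED)
    )


@pytest.fixture(scope="session")
def predictions6(classifier_full, preprocessed6):
    """Tiled label predictions for every scan of study6, keyed by rep."""
    return {
        rep: segmentation.segment(g8, classifier_full, scan_spec=spec)
        for rep, g8, _labels, spec in preprocessed6
    }


@pytest.fixture(scope="session")
def cv_subset(training_full):
    """Stratified 8,000-voxel subset of the training set for CV timing."""
    rng = np.random.default_rng(SEED)
    idx = []
    per_class = 8000 // 5
    for cls in range(5):
        cls_idx = np.flatnonzero(training_full.y == cls)
        idx.append(rng.choice(cls_idx, size=per_class, replace=False))
    idx = np.concatenate(idx)
    return segmentation.TrainingSet(
        X=training_full.X[idx],
        y=training_full.y[idx],
        provenance=training_full.provenance.iloc[idx].reset_index(drop=True),
        feature_spec=training_full.feature_spec,
    )


@pytest.fixture(scope="session")
def tiny21():
    """A 21-well (3x7) phantom of 32^3 wells with 4 kernels each, plus a
    classifier on a short sigma ladder — small enough for whole-volume
    prediction, shaped like the scanned 21-tile layout."""
    panel = phantom.default_panel(19, separated=True)
    study = phantom.simulate_study(
        panel,
        n_scans=1,
        n_rows=3,
        n_cols=7,
        check_genotype="G01",
        n_check_wells=3,
        kernels_per_well=4,
        well_voxel_extent=(32, 32, 32),
        noise_sd=4.0,
        seed=SEED,
    )
    grid, truth, spec = study[0]
    g8 = preprocess.preprocess_stack(grid)
    fspec = FeatureSpec(sigmas=(1.0, 2.0))
    ts = segmentation.build_training_set(
        [(1, g8, truth.label_volume, spec)],
        n_samples=3000,
        seed=SEED,
        feature_spec=fspec,
    )
    clf = segmentation.train_classifier(ts, segmentation.ClassifierSpec(seed=SEED))
    return g8, truth, spec, clf


@pytest.fixture(scope="session")
def mini_run_config(tmp_path_factory):
    """Config for a small but complete end-to-end pipeline run."""
    import json

    from ctgrain.pipeline import DEFAULT_CONFIG

    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    cfg["seed"] = SEED
    cfg["phantom"].update(
        {
            "n_genotypes": 4,
            "n_scans": 3,
            "n_rows": 2,
            "n_cols": 2,
            "check_genotype": "G01",
            "n_check_wells": 1,
            "kernels_per_well": 6,
            "well_voxel_extent": [48, 48, 48],
        }
    )
    cfg["features"]["sigmas"] = [1.0, 2.0]
    cfg["training"]["n_samples"] = 1500
    return cfg


@pytest.fixture(scope="session")
def mini_runs(mini_run_config, tmp_path_factory):
    """Two independent end-to-end runs of the same config; returns the two
    run directories and the trait-table bytes of each."""
    import json

    from ctgrain import pipeline

    outputs = []
    for tag in ("a", "b"):
        cfg = json.loads(json.dumps(mini_run_config))
        cfg["output_dir"] = str(tmp_path_factory.mktemp(f"run_{tag}") / "run")
        pipeline.run_all(cfg)
        outputs.append(cfg["output_dir"])
    bytes_a = open(f"{outputs[0]}/traits.csv", "rb").read()
    bytes_b = open(f"{outputs[1]}/traits.csv", "rb").read()
    return outputs, bytes_a, bytes_b
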