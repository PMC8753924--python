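"""Training-set construction, random forest behavior, CV, counting."""

import numpy as np
import pandas as pd
import pytest

from ctgrain import phantom, segmentation
from ctgrain.classes import Tissue
from ctgrain.segmentation import (
    ClassifierSpec,
    TrainingSet,
    build_training_set,
    count_pixels,
    cross_validate,
    read_annotations,
    train_classifier,
)


def _toy_training_set(n_per_class=60, sep=6.0, n_features=4, seed=0, n_classes=5):
    """Well-separated Gaussian blobs, one per tissue class."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        X.append(rng.normal(c * sep, 1.0, size=(n_per_class, n_features)))
        y.append(np.full(n_per_class, c))
    return TrainingSet(
        X=np.concatenate(X).astype(np.float32),
        y=np.concatenate(y),
        provenance=pd.DataFrame(),
    )


class TestBuildTrainingSet:
    def test_per_scan_totals_within_one_of_equal_split(self, preprocessed6):
        ts = build_training_set(preprocessed6, n_samples=4000, seed=1)
        per_scan = ts.provenance.groupby("scan").size()
        assert len(ts) == 4000
        assert all(abs(c - 4000 / 3) <= 1 for c in per_scan)

    def test_every_class_and_genotype_represented(self, training_full):
        assert set(np.unique(training_full.y)) == {0, 1, 2, 3, 4}
        genos = set(training_full.provenance["genotype"].dropna())
        assert genos == {f"G{i:02d}" for i in range(1, 7)}

    def test_same_seed_reproduces_sample_coordinates(self, preprocessed6):
        a = build_training_set(preprocessed6, n_samples=300, seed=5)
        b = build_training_set(preprocessed6, n_samples=300, seed=5)
        pd.testing.assert_frame_equal(a.provenance, b.provenance)
        assert np.array_equal(a.X, b.X)

    def test_absent_class_error_names_the_class(self):
        # a kernel-free well has no embryo anywhere on the annotation slices
        layout = pd.DataFrame({"row": [1], "col": [1], "genotype": ["A"]})
        spec = phantom.ScanSpec(
            layout=layout, kernels_per_well=1, well_voxel_extent=(24, 24, 24),
            noise_sd=0.0, seed=0,
        )
        kspec = phantom.KernelSpec(embryo_fraction=0.0)
        grid, truth = phantom.make_scan(spec, {"A": kspec})
        with pytest.raises(ValueError, match="embryo"):
            build_training_set(
                [(1, grid.astype(np.uint8), truth.label_volume, spec)],
                n_samples=50,
                slices_per_scan=10,
                seed=0,
            )

    def test_annotation_reader_maps_names(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("scan,z,y,x,class\n1,0,1,2,pericarp\n1,3,4,5,background\n")
        df = read_annotations(p)
        assert df["class"].tolist() == [int(Tissue.PERICARP), int(Tissue.BACKGROUND)]


class TestClassifier:
    def test_separable_classes_fit_perfectly(self):
        ts = _toy_training_set()
        clf = train_classifier(ts, ClassifierSpec(n_trees=50, seed=0))
        assert (clf.predict(ts.X) == ts.y).all()

    def test_single_class_training_set_rejected(self):
        ts = _toy_training_set()
        ts.y[:] = 2
        with pytest.raises(ValueError, match="single class"):
            train_classifier(ts)

    def test_same_seed_gives_identical_predictions(self):
        ts = _toy_training_set(sep=1.5)
        probe = np.random.default_rng(9).normal(3, 3, size=(200, 4)).astype(np.float32)
        a = train_classifier(ts, ClassifierSpec(seed=3)).predict(probe)
        b = train_classifier(ts, ClassifierSpec(seed=3)).predict(probe)
        assert np.array_equal(a, b)

    def test_ensemble_beats_single_tree_on_average(self):
        # noisy, overlapping classes; average held-out accuracy over seeds
        accs = {1: [], 200: []}
        for seed in range(10):
            ts = _toy_training_set(n_per_class=80, sep=1.2, seed=seed)
            rng = np.random.default_rng(100 + seed)
            idx = rng.permutation(len(ts.y))
            tr, te = idx[:300], idx[300:]
            for n_trees in accs:
                sub = TrainingSet(ts.X[tr], ts.y[tr], pd.DataFrame())
                clf = train_classifier(sub, ClassifierSpec(n_trees=n_trees, seed=seed))
                accs[n_trees].append((clf.predict(ts.X[te]) == ts.y[te]).mean())
        assert np.mean(accs[200]) >= np.mean(accs[1])

    def test_serialization_round_trip(self, tmp_path):
        ts = _toy_training_set()
        clf = train_classifier(ts, ClassifierSpec(n_trees=20, seed=1))
        path = tmp_path / "clf.pkl"
        clf.save(path)
        loaded = segmentation.PixelClassifier.load(path)
        probe = ts.X[::7]
        assert np.array_equal(clf.predict(probe), loaded.predict(probe))

    def test_features_per_node_validated_against_channels(self):
        ts = _toy_training_set(n_features=3)
        with pytest.raises(ValueError, match="features_per_node"):
            train_classifier(ts, ClassifierSpec(features_per_node=10))


class TestCrossValidate:
    def test_separable_set_scores_100(self):
        ts = _toy_training_set()
        rep = cross_validate(ts, ClassifierSpec(n_trees=30, seed=0), iterations=2)
        assert rep.percent_correct == 100.0
        assert rep.rmse < 0.12

    def test_permuted_labels_score_near_chance(self):
        ts = _toy_training_set(n_per_class=100)
        rng = np.random.default_rng(0)
        ts.y = rng.permutation(ts.y)
        rep = cross_validate(ts, ClassifierSpec(n_trees=30, seed=0), iterations=2)
        assert rep.percent_correct == pytest.approx(20.0, abs=6.0)

    def test_same_seed_identical_report(self):
        ts = _toy_training_set(sep=1.5)
        spec = ClassifierSpec(n_trees=20, seed=2)
        a = cross_validate(ts, spec, iterations=2, seed=4)
        b = cross_validate(ts, spec, iterations=2, seed=4)
        assert a.percent_correct == b.percent_correct and a.rmse == b.rmse
        assert np.array_equal(a.confusion, b.confusion)

    def test_confusion_rows_sum_to_class_counts(self):
        ts = _toy_training_set(sep=2.0)
        rep = cross_validate(ts, ClassifierSpec(n_trees=20, seed=0), iterations=2)
        per_class = np.bincount(ts.y, minlength=5) * rep.iterations
        assert np.array_equal(rep.confusion.sum(axis=1), per_class)


class TestCountPixels:
    def test_empty_well_counts_only_background(self):
        layout = pd.DataFrame({"row": [1, 1], "col": [1, 2], "genotype": ["A", "B"]})
        spec = phantom.ScanSpec(
            layout=layout, kernels_per_well=1, well_voxel_extent=(8, 8, 8), seed=0
        )
        labels = np.zeros((8, 8, 16), dtype=np.uint8)
        labels[:, :, 8:] = 4  # well B all hard endosperm
        counts = count_pixels(labels, spec).set_index("genotype")
        assert counts.loc["A", "background"] == 512
        assert counts.loc["A", "hard_endosperm"] == 0
        assert counts.loc["B", "hard_endosperm"] == 512

    def test_counts_match_ground_truth_records(self, study6):
        _, study = study6
        _, truth, spec = study[0]
        counts = count_pixels(truth.label_volume, spec)
        class_cols = ["background", "pericarp", "embryo", "soft_endosperm", "hard_endosperm"]
        merged = counts.merge(
            truth.unit_counts, on=["genotype", "row", "col"], suffixes=("", "_gt")
        )
        for c in class_cols:
            assert (merged[c] == merged[f"{c}_gt"]).all()

    def test_shifted_layout_permutes_counts(self):
        layout = pd.DataFrame({"row": [1, 1], "col": [1, 2], "genotype": ["A", "B"]})
        swapped = pd.DataFrame({"row": [1, 1], "col": [1, 2], "genotype": ["B", "A"]})
        labels = np.zeros((4, 4, 8), dtype=np.uint8)
        labels[:, :, :4] = 1
        spec_a = phantom.ScanSpec(layout=layout, well_voxel_extent=(4, 4, 4), seed=0)
        spec_b = phantom.ScanSpec(layout=swapped, well_voxel_extent=(4, 4, 4), seed=0)
        ca = count_pixels(labels, spec_a).set_index("genotype")
        cb = count_pixels(labels, spec_b).set_index("genotype")
        assert ca.loc["A", "pericarp"] == cb.loc["B", "pericarp"] == 64


class TestSegment:
    def test_pure_background_grid_is_all_background(self, tiny21):
        _g8, _truth, _spec, clf = tiny21
        rng = np.random.default_rng(0)
        flat = rng.normal(8, 3, size=(24, 24, 24)).clip(0, 255).astype(np.uint8)
        pred = segmentation.segment(flat, clf)
        assert (pred == int(Tissue.BACKGROUND)).mean() > 0.999

    def test_insufficient_halo_rejected(self, tiny21):
        g8, _truth, spec, clf = tiny21
        with pytest.raises(ValueError, match="halo"):
            segmentation.segment(g8, clf, scan_spec=spec, halo=2)
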