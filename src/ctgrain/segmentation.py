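"""Five-class voxel segmentation with a random forest.

The classifier follows the trainable-segmentation recipe: a random forest
(200 trees, 2 candidate features per split) over the multiscale
mean/variance/Hessian feature bank, trained on voxels annotated on ten
sequential slices per scan with representation across scans, genotypes and
classes, evaluated by ten iterations of stratified fivefold
cross-validation, and applied tile-by-tile (one tile per well, padded by a
feature halo) so that tiled prediction is voxel-identical to whole-volume
prediction.

On synthetic phantoms the manual annotation step is replaced by sampling
ground-truth labels; :func:`read_annotations` ingests a voxel-coordinate
CSV for real, hand-annotated data.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .classes import CLASS_NAMES, Tissue
from .features import FeatureSpec, compute_feature_stack, required_halo

log = logging.getLogger(__name__)

_PROBA_BATCH = 1_000_000  # voxels per predict_proba call; bounds memory


@dataclass(frozen=True)
class ClassifierSpec:
    """Random-forest hyperparameters: 200 trees, 2 random features per node."""

    n_trees: int = 200
    features_per_node: int = 2
    seed: int = 0

    def validate(self, n_channels: int | None = None) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.features_per_node < 1:
            raise ValueError("features_per_node must be >= 1")
        if n_channels is not None and self.features_per_node > n_channels:
            raise ValueError(
                f"features_per_node {self.features_per_node} exceeds "
                f"channel count {n_channels}"
            )


@dataclass
class TrainingSet:
    """Feature rows, labels, and voxel provenance of the annotated samples."""

    X: np.ndarray
    y: np.ndarray
    provenance: pd.DataFrame  # scan, z, y, x, genotype
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class EvalReport:
    percent_correct: float
    rmse: float
    confusion: np.ndarray  # summed over iterations; rows = truth
    folds: int
    iterations: int
    per_iteration_percent_correct: list[float]

    def to_dict(self) -> dict:
        return {
            "percent_correct": self.percent_correct,
            "rmse": self.rmse,
            "folds": self.folds,
            "iterations": self.iterations,
            "per_iteration_percent_correct": self.per_iteration_percent_correct,
            "confusion": self.confusion.tolist(),
        }


def annotation_window(
    n_slices: int, slices_per_scan: int = 10, start: int | None = None
) -> tuple[int, int]:
    """A run of ``slices_per_scan`` consecutive slices: [start, stop).

    Defaults to the central run; ``start`` pins the window to whichever
    slices are most informative (annotators pick slices that show every
    tissue, not necessarily the middle of the stack).
    """
    if n_slices < slices_per_scan:
        raise ValueError(
            f"scan has {n_slices} slices, fewer than the {slices_per_scan} "
            "annotation slices requested"
        )
    if start is None:
        start = (n_slices - slices_per_scan) // 2
    if not 0 <= start <= n_slices - slices_per_scan:
        raise ValueError(f"annotation window [{start}, {start + slices_per_scan}) "
                         f"falls outside the {n_slices}-slice stack")
    return start, start + slices_per_scan


def _genotype_map(scan_spec) -> np.ndarray:
    """Array mapping each (y, x) voxel column to its well's genotype index."""
    genos = sorted(set(scan_spec.layout["genotype"]))
    lut = {g: i for i, g in enumerate(genos)}
    _, ny, nx = scan_spec.grid_shape
    gmap = np.full((ny, nx), -1, dtype=np.int32)
    for _, well in scan_spec.layout.iterrows():
        box = scan_spec.well_box(int(well["row"]), int(well["col"]))
        gmap[box[1], box[2]] = lut[well["genotype"]]
    return gmap, genos


def build_training_set(
    scans,
    n_samples: int = 52_966,
    slices_per_scan: int = 10,
    seed: int = 0,
    feature_spec: FeatureSpec | None = None,
    class_proportions: dict[int, float] | None = None,
    window_start: int | None = None,
) -> TrainingSet:
    """Sample an annotated training set from labeled scans.

    ``scans`` is a sequence of ``(scan_id, grid, labels, scan_spec)`` with
    preprocessed 8-bit grids.  Samples come from ``slices_per_scan``
    consecutive central slices of each scan, stratified so every scan and
    every class contributes (per-scan totals within one sample of
    ``n_samples / n_scans``) and so every genotype present on the
    annotation slices is represented.  Features for the annotation window
    are computed on the window plus a halo, which is exact.
    """
    if feature_spec is None:
        feature_spec = FeatureSpec()
    if class_proportions is None:
        class_proportions = {int(t): 1.0 / len(Tissue) for t in Tissue}
    total_prop = sum(class_proportions.values())
    n_scans = len(scans)
    if n_scans == 0:
        raise ValueError("no scans supplied")
    quotas = [n_samples // n_scans] * n_scans
    for i in range(n_samples - sum(quotas)):
        quotas[i] += 1

    halo = required_halo(feature_spec.sigmas)
    rows_X, rows_y, prov = [], [], []
    for si, ((scan_id, grid, labels, scan_spec), quota) in enumerate(zip(scans, quotas)):
        rng = np.random.default_rng(np.random.SeedSequence((seed, si)))
        z0, z1 = annotation_window(grid.shape[0], slices_per_scan, window_start)
        zlo, zhi = max(0, z0 - halo), min(grid.shape[0], z1 + halo)
        feats = compute_feature_stack(grid[zlo:zhi], feature_spec)[z0 - zlo : z1 - zlo]
        win_labels = labels[z0:z1]
        gmap, genos = _genotype_map(scan_spec)

        # Exact largest-remainder apportionment of the scan quota over classes,
        # so per-scan totals land within one sample of n_samples / n_scans.
        shares = np.array(
            [quota * class_proportions[int(c)] / total_prop for c in Tissue]
        )
        wants = np.floor(shares).astype(int)
        wants = np.maximum(wants, 1)
        remainder_order = np.argsort(-(shares - np.floor(shares)), kind="stable")
        for idx in remainder_order:
            if wants.sum() >= quota:
                break
            wants[idx] += 1

        chosen: list[tuple[int, int, int]] = []
        for cls in Tissue:
            cls_vox = np.argwhere(win_labels == int(cls))
            if cls_vox.size == 0:
                raise ValueError(
                    f"class {cls.name.lower()} absent from the annotation slices "
                    f"of scan {scan_id}"
                )
            want = int(wants[int(cls)])
            take = rng.choice(len(cls_vox), size=min(want, len(cls_vox)), replace=len(cls_vox) < want)
            chosen += [tuple(v) for v in cls_vox[take]]
        # Guarantee every genotype appears, swapping rather than appending so
        # the per-scan total stays exact.
        seen = {gmap[zy, zx] for _, zy, zx in chosen if gmap[zy, zx] >= 0}
        for gi in range(len(genos)):
            if gi in seen:
                continue
            cand = np.argwhere((win_labels > 0) & (gmap[None, :, :] == gi))
            if len(cand):
                chosen.pop(int(rng.integers(len(chosen))))
                chosen.append(tuple(cand[rng.integers(len(cand))]))
        for z, y, x in chosen:
            rows_X.append(feats[z, y, x])
            rows_y.append(int(win_labels[z, y, x]))
            g = gmap[y, x]
            prov.append(
                {
                    "scan": scan_id,
                    "z": z + z0,
                    "y": y,
                    "x": x,
                    "genotype": genos[g] if g >= 0 else None,
                }
            )
    X = np.asarray(rows_X, dtype=np.float32)
    y = np.asarray(rows_y, dtype=np.int64)
    missing = set(int(t) for t in Tissue) - set(np.unique(y).tolist())
    if missing:
        names = [Tissue(m).name.lower() for m in sorted(missing)]
        raise ValueError(f"classes missing from training set: {names}")
    return TrainingSet(X=X, y=y, provenance=pd.DataFrame(prov), feature_spec=feature_spec)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a manual-annotation CSV: columns scan, z, y, x, class.

    ``class`` may be an integer label or a class name.
    """
    df = pd.read_csv(path)
    req = {"scan", "z", "y", "x", "class"}
    if not req <= set(df.columns):
        raise ValueError(f"annotation file must have columns {sorted(req)}")
    if df["class"].dtype == object:
        lut = {n: i for i, n in enumerate(CLASS_NAMES)}
        df["class"] = df["class"].str.lower().map(lut)
        if df["class"].isna().any():
            raise ValueError("unknown class names in annotation file")
    return df


class PixelClassifier:
    """Trained voxel classifier: random forest + its feature specification.

    Prediction is the argmax of the ensemble vote fractions; ties break
    toward the lower class index (background < pericarp < embryo < soft <
    hard), which makes output independent of tree evaluation order.
    """

    FORMAT_VERSION = 1

    def __init__(self, forest: RandomForestClassifier, feature_spec: FeatureSpec,
                 classifier_spec: ClassifierSpec):
        self.forest = forest
        self.feature_spec = feature_spec
        self.classifier_spec = classifier_spec

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Vote-fraction probabilities over the five classes."""
        proba = np.zeros((len(X), len(Tissue)))
        proba[:, self.forest.classes_.astype(int)] = self.forest.predict_proba(X)
        return proba

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X), dtype=np.uint8)
        for lo in range(0, len(X), _PROBA_BATCH):
            sl = slice(lo, lo + _PROBA_BATCH)
            out[sl] = np.argmax(self.predict_proba(X[sl]), axis=1)
        return out

    def save(self, path: str | Path) -> None:
        import sklearn

        payload = {
            "format_version": self.FORMAT_VERSION,
            "sklearn_version": sklearn.__version__,
            "forest": self.forest,
            "feature_spec": self.feature_spec,
            "classifier_spec": self.classifier_spec,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "PixelClassifier":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError(
                f"unsupported classifier file version {payload.get('format_version')}"
            )
        return cls(payload["forest"], payload["feature_spec"], payload["classifier_spec"])


def _make_forest(spec: ClassifierSpec, n_channels: int, seed: int) -> RandomForestClassifier:
    spec.validate(n_channels)
    return RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=spec.features_per_node,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def train_classifier(ts: TrainingSet, spec: ClassifierSpec | None = None) -> PixelClassifier:
    """Fit the random forest on the training set; deterministic under seed."""
    if spec is None:
        spec = ClassifierSpec()
    if len(np.unique(ts.y)) < 2:
        raise ValueError("training set contains a single class; cannot train")
    forest = _make_forest(spec, ts.X.shape[1], spec.seed)
    forest.fit(ts.X, ts.y)
    return PixelClassifier(forest, ts.feature_spec, spec)


def cross_validate(
    ts: TrainingSet,
    spec: ClassifierSpec | None = None,
    folds: int = 5,
    iterations: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Repeated stratified k-fold evaluation of the classifier.

    ``percent_correct`` is the held-out accuracy averaged over iterations;
    ``rmse`` is the root mean squared difference between one-hot truth and
    predicted class probabilities (averaged over samples and classes), the
    probability-error convention the reference tooling reports.
    """
    if spec is None:
        spec = ClassifierSpec()
    if len(ts) < folds:
        raise ValueError(f"training set of {len(ts)} rows cannot make {folds} folds")
    n_classes = len(Tissue)
    min_count = np.bincount(ts.y, minlength=n_classes)[np.unique(ts.y)].min()
    stratified = min_count >= folds
    if not stratified:
        log.warning("a class has fewer samples than folds; using unstratified folds")
    pc_list, sq_sum, n_pred = [], 0.0, 0
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    for it in range(iterations):
        it_seed = seed + it
        splitter = (
            StratifiedKFold(folds, shuffle=True, random_state=it_seed)
            if stratified
            else KFold(folds, shuffle=True, random_state=it_seed)
        )
        correct = 0
        for fold_idx, (tr, te) in enumerate(splitter.split(ts.X, ts.y)):
            forest = _make_forest(spec, ts.X.shape[1], spec.seed + 1000 * it + fold_idx)
            forest.fit(ts.X[tr], ts.y[tr])
            clf = PixelClassifier(forest, ts.feature_spec, spec)
            proba = clf.predict_proba(ts.X[te])
            pred = np.argmax(proba, axis=1)
            correct += int((pred == ts.y[te]).sum())
            onehot = np.zeros_like(proba)
            onehot[np.arange(len(te)), ts.y[te]] = 1.0
            sq_sum += float(((proba - onehot) ** 2).sum())
            n_pred += len(te) * n_classes
            np.add.at(confusion, (ts.y[te], pred), 1)
        pc_list.append(100.0 * correct / len(ts))
    return EvalReport(
        percent_correct=float(np.mean(pc_list)),
        rmse=float(np.sqrt(sq_sum / n_pred)),
        confusion=confusion,
        folds=folds,
        iterations=iterations,
        per_iteration_percent_correct=pc_list,
    )


def segment(
    grid: np.ndarray,
    classifier: PixelClassifier,
    scan_spec=None,
    halo: int | None = None,
) -> np.ndarray:
    """Predict a label volume, tile-by-tile when a scan layout is given.

    With ``scan_spec`` the volume is subdivided into one tile per well (the
    scanned layout allocates one genotype per tile) padded by ``halo``
    voxels of context; the result is voxel-identical to whole-volume
    prediction as long as ``halo`` covers the feature support.  Without a
    layout the whole volume is processed at once.
    """
    need = required_halo(classifier.feature_spec.sigmas)
    if halo is None:
        halo = need
    if halo < need:
        raise ValueError(
            f"halo {halo} is smaller than the feature support {need} "
            f"(4 x sigma_max); tiled output would differ from whole-volume output"
        )
    if scan_spec is None:
        feats = compute_feature_stack(grid, classifier.feature_spec)
        return classifier.predict(feats.reshape(-1, feats.shape[-1])).reshape(grid.shape)

    out = np.zeros(grid.shape, dtype=np.uint8)
    for _, well in scan_spec.layout.iterrows():
        box = scan_spec.well_box(int(well["row"]), int(well["col"]))
        padded = tuple(
            slice(max(0, b.start - halo), min(n, b.stop + halo))
            for b, n in zip(box, grid.shape)
        )
        tile = grid[padded]
        feats = compute_feature_stack(tile, classifier.feature_spec)
        pred = classifier.predict(feats.reshape(-1, feats.shape[-1])).reshape(tile.shape)
        crop = tuple(
            slice(b.start - p.start, b.stop - p.start) for b, p in zip(box, padded)
        )
        out[box] = pred[crop]
    return out


def count_pixels(labels: np.ndarray, scan_spec) -> pd.DataFrame:
    """Per-experimental-unit class voxel counts.

    One row per well with columns genotype, row, col and one count per
    class; voxels outside every well box are reported on a reserved
    ``_unassigned`` row.
    """
    rows = []
    assigned = np.zeros(len(Tissue), dtype=np.int64)
    for _, well in scan_spec.layout.iterrows():
        box = scan_spec.well_box(int(well["row"]), int(well["col"]))
        counts = np.bincount(labels[box].ravel(), minlength=len(Tissue))
        assigned += counts
        rows.append(
            {"genotype": well["genotype"], "row": int(well["row"]), "col": int(well["col"]),
             **{name: int(c) for name, c in zip(CLASS_NAMES, counts)}}
        )
    total = np.bincount(labels.ravel(), minlength=len(Tissue))
    leftover = total - assigned
    if leftover.sum() > 0:
        rows.append(
            {"genotype": "_unassigned", "row": 0, "col": 0,
             **{name: int(c) for name, c in zip(CLASS_NAMES, leftover)}}
        )
    return pd.DataFrame(rows)


def write_label_volume(labels: np.ndarray, path: str | Path) -> None:
    """Store a label volume as a compressed integer array."""
    np.savez_compressed(path, labels=labels.astype(np.uint8))


def read_label_volume(path: str | Path) -> np.ndarray:
    with np.load(path) as z:
        return z["labels"]


def write_qc_slices(labels: np.ndarray, directory: str | Path, every: int = 16) -> None:
    """Color-coded PNG slices of a label volume for visual QC."""
    import imageio.v3 as iio

    from .classes import CLASS_COLORS

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    palette = np.array(CLASS_COLORS, dtype=np.uint8)
    for z in range(0, labels.shape[0], every):
        iio.imwrite(directory / f"labels_{z:04d}.png", palette[labels[z]])
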