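"""Per-zone random-forest wetland-type classification and accuracy assessment.

The legend carries five wetland classes plus an explicit non-wetland
background class (code 0).  Control points are split 50/50 into training and
testing halves, stratified per class; variable screening uses mean decrease
impurity (MDI) aggregated over repeated forest fits; the final classifier is
a random forest with 500 trees by default and mtry = floor(sqrt(p)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .grids_io import RasterLayer
from .indices import FeatureStack

__all__ = [
    "WETLAND_CLASSES",
    "CLASS_CODES",
    "ControlPointSet",
    "ImportanceReport",
    "AccuracyReport",
    "split_control_points",
    "variable_importance",
    "select_variables",
    "train_classifier",
    "predict_map",
    "accuracy_report",
    "FittedClassifier",
]

#: Wetland legend; code 0 is the non-wetland background.
WETLAND_CLASSES = ("non-wetland", "marsh", "mangrove", "swamp", "peatland", "seasonal")
CLASS_CODES = {name: code for code, name in enumerate(WETLAND_CLASSES)}


@dataclass
class ControlPointSet:
    """Labelled ground-control samples: x, y, class, zone, train/test split."""

    frame: pd.DataFrame  # columns: x, y, cls, zone, split

    REQUIRED = ("x", "y", "cls", "zone")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"control-point table lacks columns {missing}")
        if "split" not in self.frame.columns:
            self.frame = self.frame.assign(split="unassigned")
        bad = set(self.frame["cls"]) - set(WETLAND_CLASSES)
        if bad:
            raise ValueError(f"classes outside the legend: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, split: str) -> "ControlPointSet":
        return ControlPointSet(self.frame[self.frame["split"] == split].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ControlPointSet":
        return cls(pd.read_csv(path))


def split_control_points(points: ControlPointSet, fraction: float = 0.5, seed: int = 0) -> ControlPointSet:
    """Assign each point to train or test, stratified per class within zone.

    Per class the training share is ``round(fraction * n)``; assignment is a
    seeded permutation, so a fixed seed reproduces the split exactly.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"split fraction must lie in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    frame = points.frame.copy()
    split = np.empty(len(frame), dtype=object)
    for (_, _), idx in frame.groupby(["zone", "cls"]).groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            raise ValueError("a class with fewer than 2 points cannot be split")
        n_train = int(round(fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        perm = rng.permutation(len(idx))
        split[idx[perm[:n_train]]] = "train"
        split[idx[perm[n_train:]]] = "test"
    frame["split"] = split
    return ControlPointSet(frame)


def _extract_training_matrix(stack: FeatureStack, points: ControlPointSet):
    t = stack.frame.transform
    nrows, ncols = stack.frame.shape
    rows, cols, keep = [], [], []
    for i, (x, y) in enumerate(zip(points.frame["x"], points.frame["y"])):
        r, c = t.rowcol(float(x), float(y))
        if 0 <= r < nrows and 0 <= c < ncols:
            rows.append(r)
            cols.append(c)
            keep.append(i)
        else:
            raise ValueError(f"control point ({x}, {y}) falls outside the raster extent")
    X = stack.array().reshape(nrows * ncols, -1)[np.asarray(rows) * ncols + np.asarray(cols)]
    y_lab = points.frame["cls"].to_numpy()[keep]
    valid = ~np.isnan(X).any(axis=1)
    return X[valid], y_lab[valid]


@dataclass
class ImportanceReport:
    """Per-run, per-feature MDI scores (each run normalised to sum 1)."""

    runs: pd.DataFrame  # index: run id, columns: feature names
    zero_variance: list[str] = field(default_factory=list)

    @property
    def mean_scores(self) -> pd.Series:
        return self.runs.mean(axis=0)

    def ranking(self) -> list[str]:
        """Features by descending mean MDI; ties broken by declared order."""
        scores = self.mean_scores
        order = list(self.runs.columns)
        return sorted(order, key=lambda n: (-scores[n], order.index(n)))


def variable_importance(stack: FeatureStack, train: ControlPointSet, n_runs: int = 5,
                        ntree: int = 500, seed: int = 0) -> ImportanceReport:
    """MDI variable importance over repeated random-forest fits.

    The forest is refit ``n_runs`` times with derived seeds; per-run MDI
    scores (already normalised to sum 1 across features) are aggregated by
    their arithmetic mean.
    """
    X, y = _extract_training_matrix(stack, train)
    if len(np.unique(y)) < 2:
        raise ValueError("variable importance needs at least two classes in the training data")
    zero_var = [name for j, name in enumerate(stack.names) if np.nanstd(X[:, j]) == 0]
    rows = []
    for run in range(n_runs):
        rf = RandomForestClassifier(n_estimators=ntree, max_features="sqrt",
                                    random_state=(seed + 7919 * run) % (2**31 - 1), n_jobs=1)
        rf.fit(X, y)
        imp = rf.feature_importances_
        total = imp.sum()
        rows.append(imp / total if total > 0 else imp)
    runs = pd.DataFrame(rows, columns=stack.names)
    return ImportanceReport(runs, zero_variance=zero_var)


def select_variables(report: ImportanceReport, k: int) -> list[str]:
    """Top-k features by aggregate mean MDI (ties → declared feature order)."""
    n = report.runs.shape[1]
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    return report.ranking()[:k]


@dataclass
class FittedClassifier:
    """A trained random forest plus the feature-name contract it expects."""

    model: RandomForestClassifier
    feature_names: list[str]
    classes: list[str]


def train_classifier(stack: FeatureStack, train: ControlPointSet, ntree: int = 500,
                     mtry: int | str = "auto", seed: int = 0) -> FittedClassifier:
    """Fit the per-zone random forest on control points sampled from ``stack``.

    ``mtry`` defaults to floor(sqrt(number of features)).  Training is
    reproducible under a fixed seed.
    """
    if ntree < 1:
        raise ValueError("ntree must be >= 1")
    X, y = _extract_training_matrix(stack, train)
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training data holds a single class; nothing to learn")
    max_features = "sqrt" if mtry == "auto" else int(mtry)
    rf = RandomForestClassifier(n_estimators=ntree, max_features=max_features,
                                random_state=seed % (2**31 - 1), n_jobs=1)
    rf.fit(X, y)
    return FittedClassifier(rf, list(stack.names), [str(c) for c in rf.classes_])


def predict_map(model: FittedClassifier, stack: FeatureStack) -> RasterLayer:
    """Classify every raster cell; nodata wherever any feature is nodata.

    The stack must carry exactly the training features, by name and order.
    """
    if stack.names != model.feature_names:
        raise ValueError(
            f"feature contract violated: model expects {model.feature_names}, stack has {stack.names}"
        )
    frame = stack.frame
    X = stack.array()
    valid = ~np.isnan(X).any(axis=1)
    out = np.zeros(X.shape[0], dtype=np.int16)
    nodata = -1
    out[:] = nodata
    if valid.any():
        labels = model.model.predict(X[valid])
        out[valid] = [CLASS_CODES[l] for l in labels]
    return RasterLayer(out.reshape(frame.shape), frame.transform, frame.crs, nodata=nodata)


def predict_points(model: FittedClassifier, stack: FeatureStack,
                   points: ControlPointSet) -> tuple[np.ndarray, np.ndarray]:
    """(predicted, reference) label pairs at control-point locations.

    Points whose features are nodata are dropped from both vectors.
    """
    if stack.names != model.feature_names:
        raise ValueError("feature contract violated")
    X, y = _extract_training_matrix(stack, points)
    return model.model.predict(X), y


@dataclass
class AccuracyReport:
    """Confusion matrix (rows = reference, cols = predicted) and the derived
    overall accuracy, Cohen's kappa and per-class producer's/user's accuracy.

    A class absent from the reference (or never predicted) has no defined
    producer's (user's) accuracy and is reported as NaN, not 0.
    """

    confusion: pd.DataFrame
    overall_accuracy: float
    kappa: float
    producers_accuracy: pd.Series
    users_accuracy: pd.Series

    def to_json_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "kappa": self.kappa,
            "producers_accuracy": {k: (None if np.isnan(v) else v) for k, v in self.producers_accuracy.items()},
            "users_accuracy": {k: (None if np.isnan(v) else v) for k, v in self.users_accuracy.items()},
        }


def accuracy_report(predicted, reference, labels: list[str] | None = None) -> AccuracyReport:
    """Accuracy assessment of predictions against reference labels.

    OA = trace/total; PA_c = diag_c / row-sum_c (recall on reference);
    UA_c = diag_c / col-sum_c (precision on predictions);
    kappa = (p_o - p_e) / (1 - p_e) with p_e from the row/column margins.
    """
    predicted = np.asarray(predicted)
    reference = np.asarray(reference)
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference label vectors differ in length")
    if predicted.size == 0:
        raise ValueError("empty label vectors")
    if labels is None:
        labels = sorted(set(predicted) | set(reference))
    else:
        seen = set(predicted) | set(reference)
        outside = seen - set(labels)
        if outside:
            raise ValueError(f"labels outside the legend: {sorted(outside)}")
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    cm = np.zeros((n, n), dtype=np.int64)
    for r, p in zip(reference, predicted):
        cm[index[r], index[p]] += 1
    total = cm.sum()
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    diag = np.diag(cm)
    p_o = diag.sum() / total
    p_e = float((row * col).sum()) / float(total) ** 2
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(row > 0, diag / np.where(row > 0, row, 1), np.nan)
        ua = np.where(col > 0, diag / np.where(col > 0, col, 1), np.nan)
    confusion = pd.DataFrame(cm, index=labels, columns=labels)
    return AccuracyReport(
        confusion=confusion,
        overall_accuracy=float(p_o),
        kappa=float(kappa),
        producers_accuracy=pd.Series(pa, index=labels),
        users_accuracy=pd.Series(ua, index=labels),
    )
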