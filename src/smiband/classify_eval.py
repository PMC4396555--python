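"""Supervised evaluation of band subsets by pixel classification.

Labeled pixels (background label 0 excluded) are split per class into 55%
training / 45% testing, features are the selected bands' intensities
z-scored with training statistics, and a one-versus-all RBF-kernel SVM is
fit — one binary machine per class, prediction by maximal decision value.
Overall accuracy (correct test pixels / all test pixels) is the figure of
merit; ``accuracy_vs_k`` sweeps it over subset sizes and selection
strategies to compare metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .band_select import BandSubset, agglomerative_cluster, cut_tree, representative_bands
from .infometrics import pairwise_dissimilarity
from .raster_io import HyperspectralCube, LabelMap

__all__ = [
    "SplitIndices",
    "AccuracyReport",
    "stratified_split",
    "build_feature_table",
    "train_eval_classifier",
    "evaluate_subset",
    "random_subset",
    "accuracy_vs_k",
    "summarize_curve",
]

DEFAULT_SVM_PARAMS = {"kernel": "rbf", "C": 1.0, "gamma": "scale"}


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/test pixel positions covering all labeled pixels."""

    train: np.ndarray  # (n_train, 2) int (row, col)
    test: np.ndarray  # (n_test, 2)
    seed: int
    fraction: float


@dataclass(frozen=True)
class AccuracyReport:
    overall_accuracy: float
    per_class_accuracy: dict[int, float]
    n_train: int
    n_test: int
    subset: BandSubset | None
    classifier_params: dict


def _labels_array(labels) -> np.ndarray:
    return labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)


def stratified_split(labels, fraction: float = 0.55, seed: int = 0) -> SplitIndices:
    """Randomly split each class's pixels into train/test at ``fraction``.

    Per class of ``n`` pixels, ``round(n * fraction)`` (half-up) go to
    training, guarded so any class with >= 2 pixels keeps at least one
    pixel on each side.  Background pixels (label 0) never appear.
    Bit-identical output for a fixed seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    lab = _labels_array(labels)
    classes = np.unique(lab)
    classes = classes[classes > 0]
    if len(classes) == 0:
        raise ValueError("label map holds no non-background pixels")
    rng = np.random.default_rng(seed)
    train_parts: list[np.ndarray] = []
    test_parts: list[np.ndarray] = []
    for c in classes:
        pos = np.argwhere(lab == c)
        n = len(pos)
        n_train = int(np.floor(n * fraction + 0.5))
        if n >= 2:
            n_train = min(max(n_train, 1), n - 1)
        else:
            warnings.warn(f"class {int(c)} has a single pixel; it goes to training")
            n_train = 1
        perm = rng.permutation(n)
        train_parts.append(pos[perm[:n_train]])
        test_parts.append(pos[perm[n_train:]])
    train = np.vstack(train_parts)
    test = np.vstack(test_parts) if any(len(t) for t in test_parts) else np.empty((0, 2), dtype=int)
    return SplitIndices(train=train, test=test, seed=seed, fraction=fraction)


def build_feature_table(
    cube: HyperspectralCube,
    subset,
    positions: np.ndarray,
    labels=None,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Assemble the (pixels x selected bands) feature table, z-scored.

    When ``stats`` is None the table's own per-band mean/std are used and
    returned — do this for the training table, then pass the returned
    stats when building the test table so standardization uses training
    statistics only.  Returns ``(features, label_vector_or_None, stats)``.
    """
    idx = list(subset.indices) if isinstance(subset, BandSubset) else list(subset)
    if len(idx) == 0:
        raise ValueError("band subset is empty")
    positions = np.asarray(positions)
    X = cube.data[positions[:, 0], positions[:, 1]][:, idx].astype(float)
    if stats is None:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std == 0, 1.0, std)
        stats = (mean, std)
    X = (X - stats[0]) / stats[1]
    y = None
    if labels is not None:
        lab = _labels_array(labels)
        y = lab[positions[:, 0], positions[:, 1]]
    return X, y, stats


def train_eval_classifier(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    params: dict | None = None,
    subset: BandSubset | None = None,
    classifier=None,
) -> AccuracyReport:
    """Fit a one-vs-all RBF SVM and score it on the held-out table.

    ``classifier`` may be any object honouring fit/predict to substitute
    the default; whatever runs is recorded in ``classifier_params``.
    A class present only in the test table triggers a warning and its
    pixels count as misclassified (the machine cannot predict it).
    """
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    merged = {**DEFAULT_SVM_PARAMS, **(params or {})}
    if classifier is None:
        classifier = OneVsRestClassifier(SVC(**merged))
        recorded = {"classifier": "one-vs-all SVC", **merged}
    else:
        recorded = {"classifier": type(classifier).__name__, **(params or {})}
    missing = sorted(set(np.unique(y_test)) - set(np.unique(y_train)))
    if missing:
        warnings.warn(
            f"classes {missing} appear in the test split only; "
            "their pixels will count as misclassified"
        )
    classifier.fit(X_train, y_train)
    pred = np.asarray(classifier.predict(X_test))
    if len(y_test) == 0:
        raise ValueError("empty test set")
    correct = pred == y_test
    per_class = {
        int(c): float(correct[y_test == c].mean()) for c in np.unique(y_test)
    }
    return AccuracyReport(
        overall_accuracy=float(correct.mean()),
        per_class_accuracy=per_class,
        n_train=len(y_train),
        n_test=len(y_test),
        subset=subset,
        classifier_params=recorded,
    )


def evaluate_subset(
    cube: HyperspectralCube,
    labels,
    subset,
    fraction: float = 0.55,
    seed: int = 0,
    params: dict | None = None,
) -> AccuracyReport:
    """Split, build feature tables, train and score — one call."""
    split = stratified_split(labels, fraction=fraction, seed=seed)
    X_tr, y_tr, stats = build_feature_table(cube, subset, split.train, labels)
    X_te, y_te, _ = build_feature_table(cube, subset, split.test, labels, stats=stats)
    sub = subset if isinstance(subset, BandSubset) else BandSubset(tuple(sorted(subset)))
    return train_eval_classifier(X_tr, y_tr, X_te, y_te, params=params, subset=sub)


def random_subset(n_bands: int, k: int, seed: int) -> BandSubset:
    """A uniformly random size-``k`` subset — the no-information baseline."""
    rng = np.random.default_rng([seed, k, 0x5EED])
    idx = rng.choice(n_bands, size=k, replace=False)
    return BandSubset(indices=tuple(sorted(int(i) for i in idx)),
                      provenance={"metric": "random", "k": k, "seed": seed})


def accuracy_vs_k(
    cube: HyperspectralCube,
    labels,
    k_range: Iterable[int],
    metrics: Sequence[str] = ("smi", "mi"),
    seeds: Sequence[int] = (0,),
    bins: int | None = None,
    linkage: str = "average",
    fraction: float = 0.55,
    svm_params: dict | None = None,
) -> pd.DataFrame:
    """Overall accuracy for every (selection metric, k, seed) combination.

    Metrics are "smi", "mi", "smi-scalar" (each: one dissimilarity matrix,
    one dendrogram, cuts at every k) or "random" (a fresh uniform subset
    per seed and k).  Identical split and SVM settings across metrics keep
    the comparison fair.  Returns a tidy frame with one row per evaluation.
    """
    k_list = sorted(set(int(k) for k in k_range))
    if not k_list or k_list[0] < 1 or k_list[-1] > cube.band_count:
        raise ValueError(f"k_range must lie within [1, {cube.band_count}]")
    splits = {s: stratified_split(labels, fraction=fraction, seed=s) for s in seeds}

    subsets: dict[tuple[str, int, int], BandSubset] = {}
    for metric in metrics:
        if metric == "random":
            for s in seeds:
                for k in k_list:
                    subsets[(metric, k, s)] = random_subset(cube.band_count, k, s)
        else:
            dm = pairwise_dissimilarity(cube, metric=metric, bins=bins)
            dend = agglomerative_cluster(dm, linkage=linkage)
            for k in k_list:
                sub = representative_bands(cut_tree(dend, k), dm)
                for s in seeds:
                    subsets[(metric, k, s)] = sub

    rows = []
    for metric in metrics:
        for k in k_list:
            for s in seeds:
                sub = subsets[(metric, k, s)]
                split = splits[s]
                X_tr, y_tr, stats = build_feature_table(cube, sub, split.train, labels)
                X_te, y_te, _ = build_feature_table(cube, sub, split.test, labels, stats=stats)
                rep = train_eval_classifier(
                    X_tr, y_tr, X_te, y_te, params=svm_params, subset=sub
                )
                rows.append(
                    {
                        "metric": metric,
                        "k": k,
                        "seed": s,
                        "accuracy": rep.overall_accuracy,
                        "n_train": rep.n_train,
                        "n_test": rep.n_test,
                    }
                )
    return pd.DataFrame(rows)


def summarize_curve(curve: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Mean/std accuracy per (metric, k), plus each metric's mean over k.

    The mean over the whole k range is the single summary number used to
    compare selection strategies.
    """
    per_k = (
        curve.groupby(["metric", "k"])["accuracy"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    over_k = curve.groupby("metric")["accuracy"].mean().to_dict()
    return per_k, {str(m): float(v) for m, v in over_k.items()}
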