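"""LDA over labeled spectral pixels: supervised 2-D projection and
stratified fivefold cross-validated classification with confusion
matrices."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .core import HyperCube

__all__ = [
    "LabeledPixelSet",
    "LDAModel",
    "ConfusionMatrix",
    "extract_labeled_pixels",
    "lda_fit_project",
    "lda_cross_validate",
]

ROI = tuple[str, tuple[int, int], int]  # (label, (top, left), square size)


@dataclass
class LabeledPixelSet:
    """Feature matrix of pixels x wavenumbers with class labels."""

    features: np.ndarray
    labels: np.ndarray  # str labels, one per row
    wavenumbers: list[float]
    rois: list[ROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels)
        if feats.ndim != 2 or feats.shape[1] != len(self.wavenumbers):
            raise ValueError("features must be (n_pixels, n_wavenumbers)")
        if labels.shape != (feats.shape[0],):
            raise ValueError("labels must cover every feature row")
        if not np.all(np.isfinite(feats)):
            raise ValueError("features contain non-finite values")
        if len(np.unique(labels)) < 2:
            raise ValueError("at least two classes are required")
        self.features, self.labels = feats, labels

    @property
    def classes(self) -> list[str]:
        return sorted(np.unique(self.labels).tolist())


def _roi_bounds(roi: ROI) -> tuple[int, int, int, int]:
    _, (top, left), size = roi
    return top, left, top + size, left + size


def extract_labeled_pixels(
    cube: HyperCube, rois: Sequence[ROI], wavenumbers: Sequence[float]
) -> LabeledPixelSet:
    """Slice labeled square ROIs out of a cube, restricted to a band subset."""
    if not rois:
        raise ValueError("no ROIs given: cannot build a labeled pixel set")
    h, w, _ = cube.shape
    for i, roi in enumerate(rois):
        t, l, b, r = _roi_bounds(roi)
        if t < 0 or l < 0 or b > h or r > w:
            raise ValueError(f"ROI {roi[0]!r} out of bounds for image {(h, w)}")
        for other in rois[i + 1 :]:
            t2, l2, b2, r2 = _roi_bounds(other)
            if t < b2 and t2 < b and l < r2 and l2 < r:
                raise ValueError(f"ROIs {roi[0]!r} and {other[0]!r} overlap")
    band_idx = [cube.band_index(nu) for nu in wavenumbers]
    blocks, labels = [], []
    for name, (top, left), size in rois:
        block = cube.data[top : top + size, left : left + size][:, :, band_idx]
        blocks.append(block.reshape(-1, len(band_idx)))
        labels.extend([name] * (size * size))
    return LabeledPixelSet(
        features=np.vstack(blocks),
        labels=np.asarray(labels),
        wavenumbers=[float(nu) for nu in wavenumbers],
        rois=list(rois),
    )


@dataclass
class LDAModel:
    """Fitted discriminant model: shared-covariance Gaussian classifier."""

    classes: list[str]
    class_means: np.ndarray  # (n_classes, n_features)
    covariance: np.ndarray  # pooled within-class covariance
    directions: np.ndarray  # (n_features, <= n_classes - 1) discriminant axes
    priors: np.ndarray
    estimator: LinearDiscriminantAnalysis

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(features, dtype=float))

    def project(self, features: np.ndarray, n_components: int = 2) -> np.ndarray:
        coords = self.estimator.transform(np.asarray(features, dtype=float))
        return coords[:, : min(n_components, coords.shape[1])]


def _fit_lda(features: np.ndarray, labels: np.ndarray) -> LDAModel:
    est = LinearDiscriminantAnalysis(solver="svd", store_covariance=True)
    with warnings.catch_warnings():
        # collinear spectral features are expected; the svd solver handles them
        warnings.filterwarnings("ignore", message="Variables are collinear")
        est.fit(features, labels)
    cov = est.covariance_
    if np.linalg.matrix_rank(cov) < cov.shape[0]:
        warnings.warn(
            "within-class covariance is singular; using its pseudo-inverse "
            "(svd solver)",
            stacklevel=3,
        )
    return LDAModel(
        classes=est.classes_.tolist(),
        class_means=est.means_,
        covariance=cov,
        directions=est.scalings_,
        priors=est.priors_,
        estimator=est,
    )


def lda_fit_project(data: LabeledPixelSet) -> tuple[LDAModel, np.ndarray]:
    """Fit LDA on all pixels and project onto the first two discriminants.

    With two classes only one discriminant exists and the projection is 1-D.
    """
    counts = np.unique(data.labels, return_counts=True)[1]
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 pixels")
    model = _fit_lda(data.features, data.labels)
    return model, model.project(data.features, n_components=2)


@dataclass
class ConfusionMatrix:
    """Cross-validated confusion counts indexed (true class, predicted class)."""

    classes: list[str]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    @property
    def per_class_accuracy(self) -> dict[str, float]:
        rows = self.counts.sum(axis=1)
        return {
            c: float(self.counts[i, i] / rows[i])
            for i, c in enumerate(self.classes)
        }

    def rate(self, true: str, predicted: str) -> float:
        i, j = self.classes.index(true), self.classes.index(predicted)
        return float(self.counts[i, j] / self.counts[i].sum())


def lda_cross_validate(
    data: LabeledPixelSet, folds: int = 5, seed: int = 0
) -> ConfusionMatrix:
    """Stratified k-fold cross-validation; every pixel is tested exactly once."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    classes, counts = np.unique(data.labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} pixels; needs >= {folds} folds"
        )
    class_list = classes.tolist()
    index = {c: i for i, c in enumerate(class_list)}
    matrix = np.zeros((len(class_list), len(class_list)), dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(data.features, data.labels):
        model = _fit_lda(data.features[train], data.labels[train])
        predicted = model.predict(data.features[test])
        for t, p in zip(data.labels[test], predicted):
            matrix[index[t], index[p]] += 1
    return ConfusionMatrix(classes=class_list, counts=matrix)
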