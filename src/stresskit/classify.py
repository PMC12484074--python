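"""Stress classifiers: the 1D CNN and the LDA / linear-SVM baselines.

All three consume the same :class:`FeatureMatrix` and
:class:`SplitAssignment`: features are fixed-length per-sample sequences
(RFE-selected band reflectances ordered by wavelength, optionally followed
by the [MLVI, H_VSI] index pair; or PCA scores; or NDVI alone), and the
split is a stratified, seeded 70/15/15 train/validation/test assignment
with largest-remainder rounding so per-class proportions deviate by at
most one sample from the target fractions.

The CNN trains on the train split only and uses the validation split for
its plateau scheduler and best-weight selection; the test split influences
nothing until evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

from .errors import ContractError, ParameterError, StratificationError
from .nn import CNN1D, CNNConfig, TrainingHistory

TRAIN, VAL, TEST = 0, 1, 2
_SPLIT_NAMES = {TRAIN: "train", VAL: "validation", TEST: "test"}


@dataclass
class FeatureMatrix:
    """Per-sample feature sequences plus a provenance tag for the mode."""

    values: np.ndarray          # (n_samples, length)
    mode: str                   # e.g. "rfe+indices", "indices", "pca", "ndvi"
    feature_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ContractError("feature matrix contains non-finite values")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.values.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]


@dataclass
class SplitAssignment:
    assignment: np.ndarray      # (n_samples,) of TRAIN/VAL/TEST codes
    fractions: tuple
    seed: int

    def indices(self, which: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == which)

    @property
    def train(self) -> np.ndarray:
        return self.indices(TRAIN)

    @property
    def validation(self) -> np.ndarray:
        return self.indices(VAL)

    @property
    def test(self) -> np.ndarray:
        return self.indices(TEST)


def stratified_split(
    labels, fractions: tuple = (0.70, 0.15, 0.15), seed: int = 0
) -> SplitAssignment:
    """Seeded stratified 70/15/15 split with largest-remainder rounding.

    Within each class the samples are shuffled and allocated to splits; the
    per-class counts are ``floor(frac * n_c)`` plus one extra for the splits
    with the largest fractional remainders.  Every class needs >= 3 samples.
    """
    labels = np.asarray(labels, dtype=int)
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) < 0:
        raise ParameterError("fractions must be three non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.size, dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 3:
            raise StratificationError(f"class {c} has {idx.size} sample(s); >= 3 required")
        rng.shuffle(idx)
        exact = np.array(fractions) * idx.size
        counts = np.floor(exact).astype(int)
        remainder = idx.size - counts.sum()
        # largest-remainder: extras go to the biggest fractional parts
        for j in np.argsort(-(exact - counts))[:remainder]:
            counts[j] += 1
        bounds = np.cumsum(counts)
        assignment[idx[: bounds[0]]] = TRAIN
        assignment[idx[bounds[0] : bounds[1]]] = VAL
        assignment[idx[bounds[1] :]] = TEST
    return SplitAssignment(assignment=assignment, fractions=fractions, seed=seed)


@dataclass
class ClassifierModel:
    """A trained stress classifier (CNN, LDA or SVM) with provenance."""

    kind: str                   # "cnn" | "lda" | "svm"
    model: object
    feature_mode: str
    n_classes: int
    history: Optional[TrainingHistory] = None


def train_cnn(
    features: FeatureMatrix,
    labels,
    split: SplitAssignment,
    config: Optional[CNNConfig] = None,
) -> ClassifierModel:
    """Train the 1D CNN on the train split, scheduling on the validation split."""
    labels = np.asarray(labels, dtype=int)
    config = config or CNNConfig()
    net = CNN1D(input_length=features.length, config=config)
    tr, va = split.train, split.validation
    history = net.fit(
        features.values[tr], labels[tr], features.values[va], labels[va]
    )
    return ClassifierModel(
        kind="cnn",
        model=net,
        feature_mode=features.mode,
        n_classes=config.n_classes,
        history=history,
    )


def train_lda(
    features: FeatureMatrix,
    labels,
    split: SplitAssignment,
    shrinkage: float = 0.01,
    n_classes: int = 6,
) -> ClassifierModel:
    """Linear discriminant analysis on the pooled within-class covariance.

    A small shrinkage toward the diagonal keeps the covariance invertible on
    nearly collinear spectral features.
    """
    labels = np.asarray(labels, dtype=int)
    tr = split.train
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    lda.fit(features.values[tr], labels[tr])
    return ClassifierModel(kind="lda", model=lda, feature_mode=features.mode, n_classes=n_classes)


def train_svm(
    features: FeatureMatrix,
    labels,
    split: SplitAssignment,
    C: float = 1.0,
    seed: int = 0,
    n_classes: int = 6,
) -> ClassifierModel:
    """Linear maximum-margin one-vs-rest SVM with probability calibration."""
    labels = np.asarray(labels, dtype=int)
    tr = split.train
    svm = CalibratedClassifierCV(
        SVC(kernel="linear", C=C, decision_function_shape="ovr", random_state=seed),
        ensemble=False,
    )
    svm.fit(features.values[tr], labels[tr])
    return ClassifierModel(kind="svm", model=svm, feature_mode=features.mode, n_classes=n_classes)


def predict(model: ClassifierModel, features: FeatureMatrix):
    """Class probabilities and argmax labels; deterministic at inference.

    The feature mode must match the mode the model was trained with.
    """
    if features.mode != model.feature_mode:
        raise ContractError(
            f"feature mode {features.mode!r} does not match training mode "
            f"{model.feature_mode!r}"
        )
    if model.kind == "cnn":
        proba = model.model.predict_proba(features.values)
    else:
        raw = model.model.predict_proba(features.values)
        # sklearn may omit columns for classes absent at fit time; re-expand
        proba = np.zeros((features.n_samples, model.n_classes))
        for j, c in enumerate(model.model.classes_):
            proba[:, int(c)] = raw[:, j]
        norm = proba.sum(axis=1, keepdims=True)
        proba = proba / np.where(norm > 0, norm, 1.0)
    return proba, proba.argmax(axis=1)
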