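"""Binary wrapper feature selection driven by continuous CGO.

A continuous seed in ``[0, 1]^Dim`` is thresholded into a Boolean feature
mask (bit j set iff the coordinate strictly exceeds 0.5).  Each mask is
scored by the composite wrapper fitness

    Fit = lambda * gamma + (1 - lambda) * |BX| / Dim

where ``gamma`` is the cross-validated classification error of a
classifier trained on the selected columns of the *training* partition
only, and ``|BX| / Dim`` is the selected-feature ratio.  ``lambda`` close
to 1 makes the error term dominate and the ratio act as a sparsity
tie-break.  Lower fitness is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.svm import LinearSVC

from .cgo import CGOParams, OptimizerTrace, optimize
from .datasets import FeatureTable

#: An error surrogate usable in place of a classifier during search.
ErrorFn = Callable[["BinaryMask", FeatureTable], float]

CLASSIFIER_NAMES = ("svm", "knn", "sgd")


@dataclass
class BinaryMask:
    """Boolean feature-inclusion vector."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("mask bits must be 0 or 1")
        self.bits = bits.astype(np.uint8)

    @property
    def dim(self) -> int:
        return self.bits.shape[0]

    @property
    def selected_count(self) -> int:
        return int(self.bits.sum())

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def to_line(self) -> str:
        return "".join(map(str, self.bits.tolist()))

    @classmethod
    def from_line(cls, line: str) -> "BinaryMask":
        return cls(np.array([int(ch) for ch in line.strip()], dtype=np.uint8))


def binarize(position: np.ndarray) -> BinaryMask:
    """Threshold a continuous seed at 0.5 (strict: 0.5 itself maps to 0)."""
    return BinaryMask((np.asarray(position, float) > 0.5).astype(np.uint8))


def make_classifier(spec: str, seed: int = 0):
    """Deterministic scikit-learn classifier for a short name.

    ``svm`` is a linear support-vector machine, ``knn`` 5-nearest
    neighbours, ``sgd`` a stochastic-gradient linear model with fixed seed
    and iteration cap so repeated fits are identical.
    """
    if spec == "svm":
        return LinearSVC(C=1.0, max_iter=5000, tol=1e-4)
    if spec == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if spec == "sgd":
        return SGDClassifier(
            loss="hinge", max_iter=1000, tol=1e-3, random_state=seed
        )
    raise ValueError(f"unknown classifier {spec!r}; choose from {CLASSIFIER_NAMES}")


@dataclass(frozen=True)
class FitnessConfig:
    """How the composite wrapper fitness is computed.

    ``lambda_weight`` in [0, 1] balances classification error against the
    selected-feature ratio (0.99 default: error dominates, subset size
    tie-breaks).  ``classifier`` is one of ``svm``/``knn``/``sgd`` or a
    callable ``(mask, table) -> error`` surrogate.  The error protocol is
    stratified k-fold cross-validation on the training partition with a
    fixed shuffle seed, so fitness is a pure function of the mask.  An
    empty mask never reaches the classifier; it is scored
    ``empty_mask_fitness`` directly.
    """

    lambda_weight: float = 0.99
    classifier: str | ErrorFn = "svm"
    n_folds: int = 5
    shuffle_seed: int = 0
    classifier_seed: int = 0
    empty_mask_fitness: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError(
                f"lambda_weight must lie in [0, 1], got {self.lambda_weight}"
            )
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if isinstance(self.classifier, str) and self.classifier not in CLASSIFIER_NAMES:
            raise ValueError(
                f"classifier must be one of {CLASSIFIER_NAMES} or a callable"
            )


@dataclass
class FSResult:
    """Outcome of one feature-selection run."""

    best_mask: BinaryMask
    best_fitness: float
    best_error: float
    trace: OptimizerTrace
    selected_feature_indices: list[int]
    n_unique_masks_evaluated: int = 0


def classification_error(
    mask: BinaryMask, table: FeatureTable, config: FitnessConfig
) -> float:
    """Mean (1 - accuracy) of the configured classifier under stratified
    k-fold cross-validation on the training partition, masked columns only.
    """
    if mask.selected_count == 0:
        raise ValueError("empty mask: handled by the empty-mask policy upstream")
    x, y = table.partition("train")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training partition has a single class")
    if config.n_folds > counts.min():
        raise ValueError(
            f"n_folds={config.n_folds} exceeds smallest class count {counts.min()}"
        )
    x = x[:, mask.selected_indices]
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.shuffle_seed
    )
    errors = []
    for tr, te in skf.split(x, y):
        clf = make_classifier(config.classifier, config.classifier_seed)
        clf.fit(x[tr], y[tr])
        errors.append(1.0 - float(np.mean(clf.predict(x[te]) == y[te])))
    return float(np.mean(errors))


def wrapper_fitness(
    mask: BinaryMask, table: FeatureTable, config: FitnessConfig
) -> float:
    """Composite fitness ``lambda * gamma + (1 - lambda) * |BX| / Dim``."""
    lam = config.lambda_weight
    if mask.selected_count == 0:
        return config.empty_mask_fitness
    if callable(config.classifier):
        gamma = float(config.classifier(mask, table))
    else:
        gamma = classification_error(mask, table, config)
    return lam * gamma + (1.0 - lam) * mask.selected_count / mask.dim


def select_features(
    table: FeatureTable,
    cgo: CGOParams,
    config: FitnessConfig,
    optimizer=optimize,
) -> FSResult:
    """End-to-end wrapper selection: CGO over ``[0, 1]^Dim`` with the
    composite fitness as objective, training rows only.

    The continuous objective is the fitness of the binarized seed; since
    fitness depends on the seed only through its mask, evaluations are
    cached per mask (identical results, far fewer classifier fits).
    Any optimizer honouring the ``(objective, params)`` contract may be
    plugged in; CGO is the default.
    """
    if not table.train_mask.any():
        raise ValueError("table has no training partition")
    if cgo.dim != table.n_features:
        raise ValueError(
            f"cgo.dim={cgo.dim} != number of feature columns {table.n_features}"
        )
    lo, hi = cgo.bounds()
    if not (np.all(lo == 0.0) and np.all(hi == 1.0)):
        raise ValueError("feature-selection search requires bounds L=0, U=1")
    train = table.training_only()  # test rows never reach fitness

    cache: dict[bytes, tuple[float, float]] = {}

    lam = config.lambda_weight

    def objective(x: np.ndarray) -> float:
        mask = binarize(x)
        key = mask.bits.tobytes()
        hit = cache.get(key)
        if hit is None:
            if mask.selected_count == 0:
                hit = (config.empty_mask_fitness, float("nan"))
            else:
                if callable(config.classifier):
                    gamma = float(config.classifier(mask, train))
                else:
                    gamma = classification_error(mask, train, config)
                fit = lam * gamma + (1.0 - lam) * mask.selected_count / mask.dim
                hit = (fit, gamma)
            cache[key] = hit
        return hit[0]

    pop, trace = optimizer(objective, cgo)
    best_mask = binarize(pop.global_best)
    best_fitness, best_error = cache[best_mask.bits.tobytes()]
    return FSResult(
        best_mask=best_mask,
        best_fitness=best_fitness,
        best_error=best_error,
        trace=trace,
        selected_feature_indices=best_mask.selected_indices.tolist(),
        n_unique_masks_evaluated=len(cache),
    )
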