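"""Synthetic feature tables with planted structure.

Emulates the kind of fixed-length image embeddings (128-dimensional by
default) a wrapper feature selector consumes: a handful of *informative*
dimensions whose class means are shifted apart, *redundant* dimensions
correlated with an informative source, and the rest pure standard-normal
noise.  Because the informative set is known by construction, selection
quality can be scored exactly (``recovery_score``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRAIN, TEST = "train", "test"


@dataclass
class FeatureTable:
    """Sample-by-feature matrix with labels and a train/test split."""

    values: np.ndarray  # (n, dim) float
    labels: np.ndarray  # (n,)
    split: np.ndarray  # (n,) of {"train", "test"}
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        self.labels = np.asarray(self.labels)
        self.split = np.asarray(self.split)
        n = self.values.shape[0]
        if not (len(self.labels) == len(self.split) == n):
            raise ValueError("values, labels and split lengths differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")
        bad = set(np.unique(self.split)) - {TRAIN, TEST}
        if bad:
            raise ValueError(f"split contains values other than train/test: {bad}")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.n_features)]
        if len(self.feature_names) != self.n_features:
            raise ValueError("feature_names length mismatch")
        train_classes = set(np.unique(self.labels[self.split == TRAIN]))
        if set(np.unique(self.labels)) - train_classes:
            raise ValueError("every class must appear in the training partition")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def train_mask(self) -> np.ndarray:
        return self.split == TRAIN

    def partition(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) of one partition, as copies."""
        m = self.split == which
        return self.values[m].copy(), self.labels[m].copy()

    def training_only(self) -> "FeatureTable":
        """A table holding only the training rows (leakage guard)."""
        m = self.train_mask
        return FeatureTable(
            values=self.values[m].copy(),
            labels=self.labels[m].copy(),
            split=np.full(int(m.sum()), TRAIN),
            feature_names=list(self.feature_names),
        )


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one planted-structure table.

    ``informative_indices`` get a per-class mean shift of
    ``class_separation * class_index`` on unit-variance noise; each
    ``(target, source, rho)`` triple in ``redundant_specs`` makes column
    ``target`` equal ``rho * column[source] + sqrt(1 - rho^2) * noise``;
    all remaining columns are standard normal.  The split is stratified.
    """

    n_samples_per_class: tuple[int, ...]
    dim: int = 128
    informative_indices: tuple[int, ...] = ()
    redundant_specs: tuple[tuple[int, int, float], ...] = ()
    class_separation: float = 1.0
    split_fraction: float = 0.75
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_samples_per_class) < 2:
            raise ValueError("need at least 2 classes")
        if any(n < 2 for n in self.n_samples_per_class):
            raise ValueError("need >= 2 samples per class (train and test)")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.class_separation <= 0:
            raise ValueError("class_separation must be > 0")
        info = set(self.informative_indices)
        red = {t for t, _, _ in self.redundant_specs}
        if info & red:
            raise ValueError("informative and redundant index sets overlap")
        idx = info | red
        if idx and (min(idx) < 0 or max(idx) >= self.dim):
            raise ValueError("planted indices outside [0, dim)")
        for t, s, rho in self.redundant_specs:
            if s not in info:
                raise ValueError(f"redundant source {s} is not informative")
            if not -1 <= rho <= 1:
                raise ValueError(f"correlation {rho} outside [-1, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.n_samples_per_class)

    @property
    def noise_indices(self) -> tuple[int, ...]:
        planted = set(self.informative_indices) | {
            t for t, _, _ in self.redundant_specs
        }
        return tuple(j for j in range(self.dim) if j not in planted)

    @classmethod
    def simple(
        cls,
        n_per_class: int = 100,
        n_classes: int = 2,
        dim: int = 128,
        n_informative: int = 5,
        n_redundant: int = 0,
        rho: float = 0.9,
        class_separation: float = 1.0,
        split_fraction: float = 0.75,
        rng_seed: int = 0,
    ) -> "GeneratorSpec":
        """Convenience layout: informative first, then redundant copies."""
        info = tuple(range(n_informative))
        red = tuple(
            (n_informative + i, i % max(n_informative, 1), rho)
            for i in range(n_redundant)
        )
        return cls(
            n_samples_per_class=(n_per_class,) * n_classes,
            dim=dim,
            informative_indices=info,
            redundant_specs=red,
            class_separation=class_separation,
            split_fraction=split_fraction,
            rng_seed=rng_seed,
        )


def make_feature_table(spec: GeneratorSpec) -> FeatureTable:
    """Generate the table described by ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(spec.rng_seed)
    n = sum(spec.n_samples_per_class)
    labels = np.repeat(np.arange(spec.n_classes), spec.n_samples_per_class)

    values = rng.standard_normal((n, spec.dim))
    for j in spec.informative_indices:
        values[:, j] += spec.class_separation * labels
    for target, source, rho in spec.redundant_specs:
        noise = values[:, target]  # reuse the standard-normal draw
        values[:, target] = rho * values[:, source] + np.sqrt(1 - rho**2) * noise

    split = np.full(n, TEST, dtype=object)
    start = 0
    for size in spec.n_samples_per_class:
        n_train = int(round(spec.split_fraction * size))
        n_train = min(max(n_train, 1), size - 1)  # both partitions non-empty
        chosen = rng.choice(size, size=n_train, replace=False)
        split[start + chosen] = TRAIN
        start += size

    order = rng.permutation(n)
    return FeatureTable(
        values=values[order],
        labels=labels[order],
        split=split[order].astype(str),
    )


def recovery_score(spec: GeneratorSpec, mask) -> tuple[float, float]:
    """Precision and recall of a mask against the planted informative set.

    Precision: fraction of selected columns that are informative.
    Recall: fraction of informative columns that were selected.
    """
    bits = np.asarray(getattr(mask, "bits", mask)).astype(bool)
    if bits.shape != (spec.dim,):
        raise ValueError(f"mask length {bits.shape} != dim {spec.dim}")
    informative = np.zeros(spec.dim, bool)
    informative[list(spec.informative_indices)] = True
    n_sel = int(bits.sum())
    n_hit = int((bits & informative).sum())
    precision = n_hit / n_sel if n_sel else 0.0
    recall = n_hit / informative.sum() if informative.any() else 0.0
    return precision, recall
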