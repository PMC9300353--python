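"""Readers, writers, run configuration and the experiment runner.

All on-disk formats are plain text: CSV (comma, header row, UTF-8, "."
decimal) for feature tables, traces and reports; one 0/1 string per line
for mask files; YAML for run configuration.  Every output is regenerated
bit-identically from the same configuration and seeds — no timestamps or
environment state leak into files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cgo import OPTIMIZERS, CGOParams, OptimizerTrace
from .datasets import TRAIN, TEST, FeatureTable, GeneratorSpec, make_feature_table
from .metrics import BenchmarkResult, final_evaluate, friedman_mean_ranks
from .selection import BinaryMask, FitnessConfig, select_features

logger = logging.getLogger("chaosfs")

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df["label"] = table.labels
    df["split"] = table.split
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_table(
    path: str | Path,
    labels_col: str = "label",
    split_col: str | None = "split",
    split_fraction: float = 0.75,
    seed: int = 0,
) -> FeatureTable:
    """Read a delimited feature table.

    Feature columns must parse as numbers; the first offending cell is
    named by row and column.  If ``split_col`` is absent a seeded
    stratified split at ``split_fraction`` is created and recorded.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty file")
    if labels_col not in df.columns:
        raise ValueError(f"{path}: missing label column {labels_col!r}")
    labels = df[labels_col].to_numpy()
    drop = [labels_col]

    if split_col is not None and split_col in df.columns:
        split = df[split_col].astype(str).to_numpy()
        drop.append(split_col)
    else:
        split = _stratified_split(labels, split_fraction, seed)

    feats = df.drop(columns=drop)
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & feats.notna()
    if bad.any().any():
        col = bad.any().idxmax()
        row = int(bad[col].idxmax())
        raise ValueError(
            f"{path}: non-numeric cell at row {row}, column {col!r}: "
            f"{feats.loc[row, col]!r}"
        )
    if numeric.isna().any().any():
        col = numeric.isna().any().idxmax()
        row = int(numeric[col].isna().idxmax())
        raise ValueError(f"{path}: missing value at row {row}, column {col!r}")
    return FeatureTable(
        values=numeric.to_numpy(float),
        labels=labels,
        split=split,
        feature_names=list(feats.columns),
    )


def _stratified_split(labels, fraction: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    split = np.full(len(labels), TEST, dtype=object)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        n_train = min(max(int(round(fraction * len(idx))), 1), len(idx) - 1)
        split[rng.choice(idx, size=n_train, replace=False)] = TRAIN
    return split.astype(str)


def write_masks(masks, path: str | Path) -> None:
    """One 0/1 string per line; round-trips bit-exactly."""
    if isinstance(masks, BinaryMask):
        masks = [masks]
    Path(path).write_text("".join(m.to_line() + "\n" for m in masks))


def read_masks(path: str | Path) -> list[BinaryMask]:
    return [
        BinaryMask.from_line(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


def write_trace(trace: OptimizerTrace, path: str | Path) -> None:
    """Delimited trace: iteration, best_fitness, evaluations (cumulative)."""
    d = len(trace.best_fitness_per_iteration)
    df = pd.DataFrame(
        {
            "iteration": np.arange(1, d + 1),
            "best_fitness": trace.best_fitness_per_iteration,
            "evaluations": trace.cumulative_evaluations(),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


@dataclass(frozen=True)
class RunConfig:
    """One experiment: datasets x classifiers x repeat seeds."""

    datasets: tuple[GeneratorSpec, ...] = ()
    dataset_paths: tuple[str, ...] = ()
    optimizers: tuple[str, ...] = ("cgo",)
    classifiers: tuple[str, ...] = ("sgd",)
    seeds: tuple[int, ...] = (0,)
    population_size: int = 50
    max_iterations: int = 60
    lambda_weight: float = 0.99
    fitness_classifier: str = "svm"
    n_folds: int = 5
    metric: str = "balanced_accuracy"
    out_dir: str = "chaosfs_runs"

    def __post_init__(self) -> None:
        if not self.datasets and not self.dataset_paths:
            raise ValueError("config names no dataset")
        unknown = set(self.optimizers) - set(OPTIMIZERS)
        if unknown:
            raise ValueError(f"unknown optimizers: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        datasets = tuple(
            GeneratorSpec(
                **{
                    k: tuple(tuple(x) for x in v)
                    if k == "redundant_specs"
                    else tuple(v)
                    if isinstance(v, list)
                    else v
                    for k, v in d.items()
                }
            )
            for d in raw.pop("datasets", [])
        )
        for key in ("optimizers", "classifiers", "seeds", "dataset_paths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(datasets=datasets, **raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_datasets(config: RunConfig) -> dict[str, FeatureTable]:
    out: dict[str, FeatureTable] = {}
    for i, spec in enumerate(config.datasets):
        out[f"synthetic{i}"] = make_feature_table(spec)
    for p in config.dataset_paths:
        out[Path(p).stem] = read_feature_table(p)
    return out


def run_experiment(config: RunConfig) -> tuple[pd.DataFrame, BenchmarkResult | None]:
    """Run the full grid and write all artifacts under ``config.out_dir``.

    For every (optimizer, dataset, classifier, seed) cell: select features
    on the training partition, refit the final classifier, score the test
    partition.  Writes one metrics row per run, the aggregate table, and
    (when at least two optimizers and two datasets are present) the
    Friedman mean-rank table on ``config.metric``.  A failing cell is
    logged and left missing rather than aborting the grid.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logger.info("experiment %s -> %s", chash, out)
    datasets = _load_datasets(config)

    rows = []
    for opt_name in config.optimizers:
        for ds_name, table in datasets.items():
            for clf in config.classifiers:
                for seed in config.seeds:
                    tag = f"{opt_name}_{ds_name}_{clf}_seed{seed}"
                    try:
                        row = _run_cell(config, opt_name, table, clf, seed, out, tag)
                    except Exception:
                        logger.exception("cell %s failed; marked missing", tag)
                        continue
                    row.update(
                        optimizer=opt_name, dataset=ds_name,
                        classifier=clf, seed=seed, config_hash=chash,
                    )
                    rows.append(row)
                    logger.info(
                        "%s: %s=%.4f selected=%d", tag,
                        config.metric, row[config.metric], row["selected_count"],
                    )
    results = pd.DataFrame(rows)
    results.to_csv(out / "runs.csv", index=False, float_format=_FLOAT_FMT)

    ranks = None
    if not results.empty:
        agg = (
            results.groupby(["optimizer", "dataset"])[config.metric]
            .mean()
            .unstack("dataset")
        )
        agg.to_csv(out / "aggregate.csv", float_format=_FLOAT_FMT)
        if agg.shape[0] >= 2 and agg.shape[1] >= 2 and not agg.isna().any().any():
            ranks = friedman_mean_ranks(agg)
            rank_out = ranks.ranks.copy()
            rank_out["mean_rank"] = ranks.mean_ranks
            rank_out.to_csv(out / "friedman_ranks.csv", float_format=_FLOAT_FMT)
    return results, ranks


def _run_cell(config, opt_name, table, clf, seed, out: Path, tag: str) -> dict:
    cgo = CGOParams(
        dim=table.n_features,
        population_size=config.population_size,
        max_iterations=config.max_iterations,
        lower_bound=0.0,
        upper_bound=1.0,
        rng_seed=seed,
    )
    fitness = FitnessConfig(
        lambda_weight=config.lambda_weight,
        classifier=config.fitness_classifier,
        n_folds=config.n_folds,
        shuffle_seed=seed,
    )
    result = select_features(table, cgo, fitness, optimizer=OPTIMIZERS[opt_name])
    report = final_evaluate(table, result.best_mask, classifier_spec=clf)
    write_masks(result.best_mask, out / f"{tag}_mask.txt")
    write_trace(result.trace, out / f"{tag}_trace.csv")
    row = report.as_dict()
    row.update(
        selected_count=result.best_mask.selected_count,
        search_fitness=result.best_fitness,
        search_error=result.best_error,
    )
    return row
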