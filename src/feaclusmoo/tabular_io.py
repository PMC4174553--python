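"""Dataset and result containers plus CSV/JSON I/O.

A :class:`Dataset` is a plain numeric feature table (rows = samples) with an
optional class-label column and a "labeled subset": the indices of the small
fraction of samples (typically 10%) whose true class is treated as known by
the semi-supervised search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class Dataset:
    """Numeric feature table with optional partial labels.

    Attributes
    ----------
    points : (n, F) float array
    feature_names : list of F column names
    true_labels : optional (n,) integer array of class codes
    labeled_idx : sorted integer array of sample indices whose label is
        visible to semi-supervised variants; empty when unlabeled.
    """

    points: np.ndarray
    feature_names: list[str]
    true_labels: np.ndarray | None = None
    labeled_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        n, f = self.points.shape
        if n < 2 or f < 1:
            raise ValueError(f"need n >= 2 samples and F >= 1 features, got {n}x{f}")
        if len(self.feature_names) != f:
            raise ValueError("feature_names length must match feature count")
        if np.isnan(self.points).any():
            raise ValueError("dataset contains missing values")
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels)
            if self.true_labels.shape[0] != n:
                raise ValueError("true_labels length must match sample count")
        self.labeled_idx = np.asarray(self.labeled_idx, dtype=np.int64)
        if self.labeled_idx.size:
            if self.true_labels is None:
                raise ValueError("labeled_idx requires true_labels")
            if self.labeled_idx.min() < 0 or self.labeled_idx.max() >= n:
                raise ValueError("labeled_idx out of range")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def n_features(self) -> int:
        return self.points.shape[1]


@dataclass
class RunResult:
    """Outcome of one optimisation run: the final archive of mutually
    non-dominated solutions, the index of the selected one, and the
    partition it induces."""

    archive_solutions: list[dict]  # each: {"mask": 0/1 str, "centers": [[...]], "objectives": [...]}
    best_solution: int
    partition: np.ndarray
    metadata: dict

    def __post_init__(self) -> None:
        if not self.archive_solutions:
            raise ValueError("a run always yields at least one solution")
        if not 0 <= self.best_solution < len(self.archive_solutions):
            raise ValueError("best_solution out of range")
        self.partition = np.asarray(self.partition, dtype=np.int64)


def draw_labeled_idx(n: int, fraction: float, seed: int, labels=None, stratified: bool = False) -> np.ndarray:
    """Sample round(fraction*n) indices without replacement (round-half-even).

    With ``stratified=True`` the draw is proportional per class (requires
    ``labels``); otherwise uniform over all samples.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"labeled fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    size = round(fraction * n)
    if not stratified:
        return np.sort(rng.choice(n, size=size, replace=False))
    if labels is None:
        raise ValueError("stratified sampling requires labels")
    labels = np.asarray(labels)
    picked: list[np.ndarray] = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        k = round(fraction * members.size)
        picked.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(picked)) if picked else np.empty(0, dtype=np.int64)


def read_dataset(
    path,
    label_column: str | None = None,
    labeled_fraction: float = 0.1,
    seed: int = 0,
    stratified: bool = False,
) -> Dataset:
    """Load a comma-separated table (header row required, '.' decimal).

    When ``label_column`` is given, that column supplies the true classes and
    a labeled subset of size round(labeled_fraction*n) is drawn
    deterministically from ``seed``.  Rows with missing values are rejected.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if label_column is not None and label_column not in frame.columns:
        raise KeyError(f"label column {label_column!r} not found in {path.name}")
    if frame.isna().any().any():
        row, col = next(
            (i, c) for c in frame.columns for i in frame.index[frame[c].isna()]
        )
        raise ValueError(f"missing value at row {row}, column {col!r} in {path.name}")

    labels = None
    if label_column is not None:
        labels = pd.Categorical(frame[label_column]).codes.astype(np.int64)
        frame = frame.drop(columns=[label_column])
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else 0
            raise ValueError(f"non-numeric value at row {row}, column {col!r} in {path.name}")

    points = frame.to_numpy(dtype=float)
    labeled_idx = np.empty(0, dtype=np.int64)
    if labels is not None:
        labeled_idx = draw_labeled_idx(
            points.shape[0], labeled_fraction, seed, labels=labels, stratified=stratified
        )
    return Dataset(
        points=points,
        feature_names=list(frame.columns),
        true_labels=labels,
        labeled_idx=labeled_idx,
    )


# -- results -------------------------------------------------------------


def write_result(result: RunResult, path) -> None:
    """Serialise a run to JSON (masks as 0/1 strings).  Writes are
    byte-deterministic: keys sorted, fixed float formatting."""
    payload = {
        "archive_solutions": result.archive_solutions,
        "best_solution": result.best_solution,
        "partition": result.partition.tolist(),
        "metadata": result.metadata,
    }
    Path(path).write_text(
        json.dumps(payload, sort_keys=True, separators=(",", ":")) + "\n",
        encoding="utf-8",
    )


def read_result(path) -> RunResult:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return RunResult(
        archive_solutions=payload["archive_solutions"],
        best_solution=payload["best_solution"],
        partition=np.asarray(payload["partition"], dtype=np.int64),
        metadata=payload["metadata"],
    )


def write_partition_csv(result: RunResult, path) -> None:
    """Export the selected partition as two-column CSV (sample_id,cluster)."""
    frame = pd.DataFrame(
        {"sample_id": np.arange(result.partition.size), "cluster": result.partition}
    )
    frame.to_csv(path, index=False)
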