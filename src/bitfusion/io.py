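"""Tabular dataset container and delimited-text I/O.

A :class:`Dataset` is the in-memory form of a numeric feature table with one
categorical label column — the shape shared by the UCI-style clinical and
gene-expression benchmarks this package targets. Class identifiers are kept
in first-appearance order; that order fixes the class axis of every support
tensor and weight matrix downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset", "load_table", "write_table"]


@dataclass
class Dataset:
    """Numeric feature table with a categorical label per instance.

    Parameters
    ----------
    features : ndarray of shape (n, m)
        Finite real feature matrix.
    labels : ndarray of shape (n,)
        Class identifier per instance; every value must occur in ``class_set``.
    class_set : tuple
        The p >= 2 distinct class identifiers, in a fixed (first-appearance)
        order. This order indexes the class axis everywhere in the package.
    feature_names : list of str, optional
        Column names; defaults to ``f0 .. f{m-1}``.
    """

    features: np.ndarray
    labels: np.ndarray
    class_set: tuple
    feature_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels)
        self.class_set = tuple(self.class_set)
        n, m = self.features.shape
        if n < 1 or m < 1:
            raise ValueError("need at least one instance and one feature")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} instances")
        if len(self.class_set) < 2:
            raise ValueError("class_set must contain at least 2 classes")
        if len(set(self.class_set)) != len(self.class_set):
            raise ValueError("class_set contains duplicates")
        if not np.all(np.isfinite(self.features)):
            bad = np.argwhere(~np.isfinite(self.features))[0]
            raise ValueError(
                f"non-finite feature value at row {bad[0]}, column {bad[1]}"
            )
        known = set(self.class_set)
        for i, lab in enumerate(self.labels):
            if lab not in known:
                raise ValueError(f"label {lab!r} at row {i} not in class_set")
        if self.feature_names is not None and len(self.feature_names) != m:
            raise ValueError("feature_names length must equal feature count")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def m(self) -> int:
        return self.features.shape[1]

    @property
    def p(self) -> int:
        return len(self.class_set)

    def label_indices(self) -> np.ndarray:
        """Labels encoded as integer indices into ``class_set``."""
        lookup = {c: i for i, c in enumerate(self.class_set)}
        return np.array([lookup[lab] for lab in self.labels], dtype=int)

    def subset(self, idx) -> "Dataset":
        """Row subset sharing this dataset's class_set (order preserved)."""
        return Dataset(
            self.features[idx],
            self.labels[idx],
            self.class_set,
            self.feature_names,
        )


def load_table(path, label_column, delimiter: str = ",") -> Dataset:
    """Read a delimited numeric table with one label column.

    ``label_column`` selects the label column by header name (str) or
    positional index (int). Rejects missing values (naming the offending
    cell), non-numeric feature cells, and single-class files.
    """
    header = 0 if isinstance(label_column, str) else None
    df = pd.read_csv(
        path, sep=delimiter, header=header, float_precision="round_trip"
    )
    if isinstance(label_column, str):
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found in {path}")
        label_key = label_column
    else:
        if not 0 <= label_column < df.shape[1]:
            raise ValueError(f"label column index {label_column} out of range")
        label_key = df.columns[label_column]

    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        col = df.columns[df.isna().any(axis=0).argmax()]
        raise ValueError(f"missing value at row {row}, column {col!r} in {path}")

    labels = df[label_key].to_numpy()
    feats = df.drop(columns=[label_key])
    try:
        features = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature cell in {path}: {exc}") from exc

    # class_set in first-appearance order
    class_set = tuple(pd.unique(labels))
    if len(class_set) < 2:
        raise ValueError(f"file {path} contains a single class {class_set!r}")
    names = [str(c) for c in feats.columns]
    return Dataset(features, labels, class_set, names)


def write_table(dataset: Dataset, path, delimiter: str = ",",
                label_column: str = "label") -> None:
    """Write a Dataset as delimited text; inverse of :func:`load_table`."""
    names = dataset.feature_names or [f"f{i}" for i in range(dataset.m)]
    df = pd.DataFrame(dataset.features, columns=names)
    df[label_column] = dataset.labels
    df.to_csv(path, sep=delimiter, index=False)
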