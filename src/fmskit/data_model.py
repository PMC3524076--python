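"""Core data containers and table preprocessing.

A 16S rRNA survey arrives as a taxon-by-sample table of relative abundances.
In memory we keep samples as rows (all statistics index samples); the TSV/CSV
reader accepts the conventional taxon-table orientation (features as rows) and
transposes.  Abundances are stored as percentages: every sample row sums to
100.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "ClassSummary",
    "class_summary",
    "to_relative_abundance",
    "drop_zero_variance",
    "standardize",
    "read_table",
    "read_labels",
    "write_table",
]

ROW_SUM_TARGET = 100.0  # percentages, not proportions


@dataclass
class AbundanceTable:
    """Samples × features abundance matrix with aligned identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Non-negative relative abundances (percent scale after
        :func:`to_relative_abundance`).
    sample_ids : list of str
    feature_labels : list of str
        Taxon names; must be unique.
    labels : ndarray of str, optional
        Class identifier per sample (aligned with rows).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_labels: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples × features matrix")
        n, d = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.feature_labels) != d:
            raise ValueError(
                f"{len(self.feature_labels)} feature labels for {d} columns"
            )
        if len(set(self.feature_labels)) != d:
            dupes = sorted(
                {x for x in self.feature_labels if self.feature_labels.count(x) > 1}
            )
            raise ValueError(f"duplicate feature labels: {dupes}")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_labels[j]!r}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels must align with sample rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ClassSummary:
    """Class composition of a labelled sample set.

    Class order is order of first appearance in the label vector; this order
    is the tie-break authority everywhere a "first class" is needed.
    """

    class_names: tuple
    counts: tuple[int, ...]

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def class_summary(labels: Sequence) -> ClassSummary:
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    names = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    counts = tuple(int(np.sum(labels == c)) for c in names)
    if len(names) < 2:
        raise ValueError("supervised operations need at least 2 classes")
    return ClassSummary(tuple(names), counts)


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Rescale every sample row to sum to 100 (percent abundances).

    Idempotent.  A sample with no observed taxa cannot be normalised and is
    rejected by name.
    """
    sums = table.values.sum(axis=1)
    empty = np.nonzero(sums <= 0)[0]
    if empty.size:
        raise ValueError(
            f"empty sample (all-zero row): {table.sample_ids[empty[0]]!r}"
        )
    values = table.values * (ROW_SUM_TARGET / sums[:, None])
    return replace(table, values=values)


def drop_zero_variance(
    table: AbundanceTable,
) -> tuple[AbundanceTable, list[int]]:
    """Remove features whose unbiased sample variance is exactly zero.

    Returns the reduced table and the removed column indices (ascending).
    Constant non-zero columns are removed too — zero variance, not zero value.
    """
    var = table.values.var(axis=0, ddof=1) if table.n_samples > 1 else np.zeros(
        table.n_features
    )
    removed = np.nonzero(var == 0.0)[0]
    if removed.size == table.n_features:
        raise ValueError("all features have zero variance; nothing to model")
    keep = np.nonzero(var > 0.0)[0]
    out = replace(
        table,
        values=table.values[:, keep],
        feature_labels=[table.feature_labels[j] for j in keep],
    )
    return out, [int(j) for j in removed]


def standardize(
    matrix: np.ndarray,
    means: np.ndarray | None = None,
    stds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise zero-mean unit-variance transform.

    When ``means``/``stds`` are given (training statistics) they are applied
    as-is, so held-out data gets the training transform.  Variance is the
    unbiased sample variance.
    """
    matrix = np.asarray(matrix, dtype=float)
    if means is None or stds is None:
        means = matrix.mean(axis=0)
        stds = matrix.std(axis=0, ddof=1)
        if np.any(stds == 0.0):
            j = int(np.nonzero(stds == 0.0)[0][0])
            raise ValueError(
                f"zero-variance column {j}; run drop_zero_variance first"
            )
    return (matrix - means) / stds, np.asarray(means), np.asarray(stds)


# ---------------------------------------------------------------------------
# TSV/CSV I/O.  First column = feature labels, header row = sample ids; the
# conventional taxon-table orientation is features-as-rows and is transposed
# on read.  Labels live in a separate two-column file.
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: str) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_table(
    path: str,
    *,
    orientation: str = "features_as_rows",
    delimiter: str | None = None,
) -> AbundanceTable:
    """Read an abundance table from TSV/CSV.

    orientation: ``features_as_rows`` (taxon-table convention, transposed on
    read) or ``samples_as_rows``.
    """
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "features_as_rows":
        df = df.T  # now samples × features
    return AbundanceTable(
        values=df.to_numpy(dtype=float),
        sample_ids=[str(s) for s in df.index],
        feature_labels=[str(f) for f in df.columns],
    )


def read_labels(path: str, *, delimiter: str | None = None) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>class`` file into a dict."""
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"label file {path!r} needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def attach_labels(table: AbundanceTable, mapping: dict[str, str]) -> AbundanceTable:
    missing = [s for s in table.sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"samples without class label: {missing[:5]}")
    labels = np.array([mapping[s] for s in table.sample_ids])
    return replace(table, labels=labels)


def write_table(
    table: AbundanceTable,
    path: str,
    *,
    orientation: str = "features_as_rows",
    delimiter: str = "\t",
) -> None:
    df = pd.DataFrame(
        table.values, index=table.sample_ids, columns=table.feature_labels
    )
    if orientation == "features_as_rows":
        df = df.T
    df.to_csv(path, sep=delimiter)


def write_labels(table: AbundanceTable, path: str, *, delimiter: str = "\t") -> None:
    if table.labels is None:
        raise ValueError("table has no class labels")
    with open(path, "w") as fh:
        for s, c in zip(table.sample_ids, table.labels):
            fh.write(f"{s}{delimiter}{c}\n")
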