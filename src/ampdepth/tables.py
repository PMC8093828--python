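"""Core containers for ASV community tables.

An :class:`AsvTable` holds a samples x ASVs matrix of non-negative integer
read counts together with one categorical class label per sample (e.g. a
biotic-index category, a geographic origin, or a production phase).  A
:class:`RelativeAbundanceTable` holds the same axes with per-sample
proportions.

On disk, count matrices follow the common amplicon-export convention of
ASVs as rows and samples as columns (first column = ASV id, header row =
sample ids); metadata is a TSV with a ``sample_id`` column plus one or more
label columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AsvTable",
    "RelativeAbundanceTable",
    "AmpdepthError",
    "ParameterError",
    "ValidationError",
    "EmptyTableError",
    "ClassEliminationError",
    "read_asv_table",
    "write_asv_table",
    "read_metadata",
]


class AmpdepthError(Exception):
    """Base class for errors raised by this package."""


class ParameterError(AmpdepthError, ValueError):
    """An argument is outside its legal range."""


class ValidationError(AmpdepthError, ValueError):
    """An input table violates a structural invariant."""


class EmptyTableError(AmpdepthError):
    """A filtering step removed every ASV (or every sample)."""


class ClassEliminationError(AmpdepthError):
    """A filtering step removed every sample of one class.

    A classification task cannot proceed without the class, so this is an
    error rather than a silent shrink of the label set.
    """

    def __init__(self, classes: list[str]):
        self.classes = list(classes)
        super().__init__(
            "sample filtering eliminated every sample of class(es): "
            + ", ".join(map(str, self.classes))
        )


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if list(ids).count(x) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class AsvTable:
    """Samples x ASVs integer count matrix with per-sample class labels.

    Parameters
    ----------
    counts
        DataFrame with sample ids as the index and ASV ids as columns;
        values must be non-negative integers.
    labels
        Series of categorical class labels indexed like ``counts``.
    """

    counts: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            raise ValidationError("counts must be a pandas DataFrame")
        _check_unique(list(self.counts.index), "sample ids")
        _check_unique(list(self.counts.columns), "ASV ids")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                bad = np.argwhere(values != np.round(values))[0]
                raise ValidationError(
                    f"non-integer count at sample {self.counts.index[bad[0]]!r}, "
                    f"ASV {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.counts.index[bad[0]]!r}, "
                f"ASV {self.counts.columns[bad[1]]!r}"
            )
        self.labels = pd.Series(self.labels)
        if len(self.labels) != len(self.counts):
            raise ValidationError(
                f"{len(self.labels)} labels for {len(self.counts)} samples"
            )
        if not (self.labels.index == self.counts.index).all():
            self.labels = self.labels.reindex(self.counts.index)
            if self.labels.isna().any():
                missing = list(self.labels.index[self.labels.isna()])
                raise ValidationError(f"samples without a label: {missing[:5]}")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    @property
    def classes(self) -> list:
        return sorted(self.labels.unique())

    def class_sizes(self) -> pd.Series:
        """Number of samples per class, in sorted class order."""
        return self.labels.value_counts().sort_index()

    def subset_samples(self, sample_ids) -> "AsvTable":
        keep = list(sample_ids)
        return AsvTable(self.counts.loc[keep], self.labels.loc[keep])

    def copy(self) -> "AsvTable":
        return AsvTable(self.counts.copy(), self.labels.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AsvTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.labels.equals(other.labels)


@dataclass
class RelativeAbundanceTable:
    """Samples x ASVs matrix of within-sample proportions (rows sum to 1)."""

    values: pd.DataFrame
    labels: pd.Series
    _SUM_TOL = 1e-9

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=1)
        if len(sums) and not np.allclose(sums, 1.0, atol=self._SUM_TOL, rtol=0):
            worst = sums.sub(1.0).abs().idxmax()
            raise ValidationError(
                f"sample {worst!r} proportions sum to {sums[worst]!r}, not 1"
            )
        self.labels = pd.Series(self.labels).reindex(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# -- TSV I/O ------------------------------------------------------------------


def read_asv_table(
    counts_path: str | Path,
    metadata_path: str | Path,
    label_column: str = "label",
    *,
    samples_as_rows: bool = False,
) -> AsvTable:
    """Read a count matrix TSV plus a metadata TSV into an :class:`AsvTable`.

    The matrix file has ASVs as rows and samples as columns unless
    ``samples_as_rows`` is set.  Metadata must contain ``sample_id`` and the
    requested label column; every sample in the matrix must appear there.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.columns.duplicated().any() or counts.index.duplicated().any():
        raise ValidationError(f"duplicate ids in {counts_path}")
    if not samples_as_rows:
        counts = counts.T
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    meta = read_metadata(metadata_path, label_column)
    unknown = [s for s in counts.index if s not in meta.index]
    if unknown:
        raise ValidationError(
            f"samples in matrix but not in metadata: {unknown[:5]}"
        )
    labels = meta.loc[counts.index, label_column]
    return AsvTable(counts, labels)


def read_metadata(path: str | Path, label_column: str = "label") -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValidationError(f"metadata {path} lacks a 'sample_id' column")
    if label_column not in meta.columns:
        raise ValidationError(f"metadata {path} lacks label column {label_column!r}")
    if meta["sample_id"].duplicated().any():
        raise ValidationError(f"duplicate sample_id in metadata {path}")
    return meta.set_index("sample_id")


def write_asv_table(
    table: AsvTable,
    counts_path: str | Path,
    metadata_path: str | Path,
    label_column: str = "label",
) -> None:
    """Write the table as an ASVs-as-rows TSV plus a metadata TSV."""
    table.counts.T.rename_axis("asv_id").to_csv(counts_path, sep="\t")
    meta = pd.DataFrame(
        {"sample_id": table.sample_ids, label_column: table.labels.to_numpy()}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)
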