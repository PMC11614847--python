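"""Core data model and I/O for two-group differential expression analysis.

The central containers are :class:`CountMatrix` (a validated genes x samples
integer matrix) and :class:`SampleSheet` (sample metadata restricted to a
two-level contrast).  Both are thin, validated wrappers around pandas
DataFrames so that downstream code can rely on their invariants instead of
re-checking raw user input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("decombine")

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "read_counts",
    "write_counts",
    "read_metadata",
    "align",
]


@dataclass
class CountMatrix:
    """Raw counts for ``n_genes`` genes in ``n_samples`` samples.

    Parameters
    ----------
    counts
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.  Values must be nonnegative integers.

    Raises
    ------
    ValueError
        If identifiers are duplicated or any count is negative/non-integral.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise ValueError(f"duplicated gene identifiers: {dups}")
        if df.columns.duplicated().any():
            dups = sorted(set(df.columns[df.columns.duplicated()]))
            raise ValueError(f"duplicated sample identifiers: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            frac = values != np.floor(values)
            if frac.any() or np.isnan(values).any():
                g, s = np.argwhere(frac | np.isnan(values))[0]
                raise ValueError(
                    f"non-integer count {values[g, s]!r} for gene "
                    f"{df.index[g]!r} in sample {df.columns[s]!r}"
                )
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
        if values.size and (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count {values[g, s]} for gene {df.index[g]!r} "
                f"in sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.counts.columns]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def values(self) -> np.ndarray:
        """Counts as an int64 array (genes x samples)."""
        return self.counts.to_numpy(dtype=np.int64)

    def library_sizes(self) -> np.ndarray:
        """Per-sample total counts."""
        return self.counts.sum(axis=0).to_numpy(dtype=float)

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)])


@dataclass
class SampleSheet:
    """Sample metadata for a two-level contrast.

    ``test_level`` is the second level named in the contrast: its mean goes
    in the numerator of every reported log2 fold change.  Extra metadata
    columns are carried through but ignored by the DE engines.
    """

    table: pd.DataFrame
    condition_col: str
    ref_level: str
    test_level: str

    def __post_init__(self) -> None:
        t = self.table
        if self.condition_col not in t.columns:
            raise ValueError(f"condition column {self.condition_col!r} missing")
        if t.index.duplicated().any():
            dups = sorted(set(t.index[t.index.duplicated()]))
            raise ValueError(f"duplicated sample identifiers: {dups}")
        levels = set(t[self.condition_col])
        if levels != {self.ref_level, self.test_level}:
            raise ValueError(
                f"conditions {sorted(levels)} do not match contrast "
                f"({self.ref_level!r}, {self.test_level!r})"
            )
        for level in (self.ref_level, self.test_level):
            n = int((t[self.condition_col] == level).sum())
            if n < 2:
                raise ValueError(
                    f"condition level {level!r} has {n} sample(s); "
                    "at least 2 replicates per level are required"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    @property
    def condition(self) -> pd.Series:
        return self.table[self.condition_col]

    def indicator(self) -> np.ndarray:
        """0/1 vector: 1 for samples in the test class."""
        return (self.condition == self.test_level).to_numpy(dtype=float)

    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """(reference mask, test mask) boolean arrays in sheet order."""
        x = self.indicator().astype(bool)
        return ~x, x


def _read_table(path, dialect: str | None) -> pd.DataFrame:
    if dialect is None:
        dialect = "csv" if str(path).endswith(".csv") else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    return pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})


def read_counts(path, dialect: str | None = None) -> CountMatrix:
    """Read a count matrix (genes in rows, header of sample ids).

    The first column must hold gene identifiers.  Cells must parse as
    nonnegative integers; violations raise ``ValueError`` naming the
    offending gene and sample.
    """
    df = _read_table(path, dialect)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path, dialect: str = "tsv") -> None:
    sep = "\t" if dialect == "tsv" else ","
    cm.counts.to_csv(path, sep=sep, index_label="gene")


def read_metadata(
    path,
    condition_col: str,
    contrast: tuple[str, str],
    dialect: str | None = None,
) -> SampleSheet:
    """Read sample metadata and restrict it to a two-level contrast.

    ``contrast = (reference, test)``: the second level is the test class
    whose mean enters the log2FC numerator.
    """
    df = _read_table(path, dialect)
    df.index = df.index.astype(str)
    if condition_col not in df.columns:
        raise ValueError(f"condition column {condition_col!r} not in metadata")
    ref, test = contrast
    for level in (ref, test):
        if level not in set(df[condition_col]):
            raise ValueError(f"contrast level {level!r} absent from metadata")
    sub = df[df[condition_col].isin([ref, test])]
    return SampleSheet(sub, condition_col, ref_level=ref, test_level=test)


def align(cm: CountMatrix, sheet: SampleSheet) -> CountMatrix:
    """Reorder count columns to the sheet's sample order.

    Count columns not in the sheet are dropped with a warning; sheet samples
    missing from the counts are an error.
    """
    counts_ids = set(cm.sample_ids)
    missing = [s for s in sheet.sample_ids if s not in counts_ids]
    if missing:
        raise ValueError(f"samples in metadata but not in counts: {missing}")
    extra = [s for s in cm.sample_ids if s not in set(sheet.sample_ids)]
    if len(extra) == cm.n_samples:
        raise ValueError("no overlap between count columns and metadata samples")
    if extra:
        logger.warning("dropping %d count column(s) not in metadata: %s", len(extra), extra)
    return CountMatrix(cm.counts[sheet.sample_ids])
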