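"""Abundance and clinical tables: containers, TSV/CSV I/O, and abundance filters.

The central container is :class:`AbundanceTable`, a features x samples matrix of
counts or relative abundances.  Downstream network inference expects relative
abundances that have passed the prevalence/mean-abundance screen implemented by
:func:`prevalence_abundance_filter` (occurrence in more than 70% of samples and
mean relative abundance above 0.001% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "ClinicalTable",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_clinical_csv",
    "write_clinical_csv",
    "to_relative",
    "prevalence_abundance_filter",
    "top_k_features",
]

_REL_TOL = 1e-6


@dataclass
class AbundanceTable:
    """Features x samples abundance matrix.

    Parameters
    ----------
    data
        DataFrame with feature ids as the index and sample ids as columns.
        Entries must be non-negative and finite.
    kind
        ``"counts"`` for integer-like count data, ``"relative"`` for
        compositions whose columns sum to one (all-zero columns exempt).
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("abundance table contains non-finite entries")
        if values.size and (values < 0).any():
            rows, cols = np.where(values < 0)
            raise ValueError(
                "negative abundance at feature "
                f"{self.data.index[rows[0]]!r}, sample {self.data.columns[cols[0]]!r}"
            )
        if self.kind == "relative" and values.size:
            # columns sum to 1 for a full composition; feature filtering
            # yields sub-compositions, so sums below 1 are legal, above 1 not
            sums = values.sum(axis=0)
            bad = np.flatnonzero(sums > 1.0 + _REL_TOL)
            if bad.size:
                raise ValueError(
                    f"relative table columns must sum to at most 1; sample "
                    f"{self.data.columns[bad[0]]!r} sums to {sums[bad[0]]:.6g}"
                )

    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        """Matrix as float ndarray (features x samples)."""
        return self.data.to_numpy(dtype=float)

    def subset_features(self, feature_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(feature_ids)], kind=self.kind)

    def __eq__(self, other) -> bool:  # value equality for round-trip checks
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.array_equal(self.values(), other.values())
        )


@dataclass
class ClinicalTable:
    """Samples x indicators table of clinical measurements (missing allowed).

    ``units`` carries the measurement unit string per indicator (e.g. ALB in
    g/L, BUN in mmol/L, UA in umol/L); it is metadata and never interpreted.
    """

    data: pd.DataFrame
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def indicators(self) -> list:
        return list(self.data.columns)


def read_abundance_tsv(path, kind: str = "counts") -> AbundanceTable:
    """Read a feature x sample TSV (first column feature id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AbundanceTable(df.astype(float), kind=kind)


def write_abundance_tsv(table: AbundanceTable, path) -> None:
    df = table.data.copy()
    df.index.name = df.index.name or "feature_id"
    df.to_csv(path, sep="\t")


def read_clinical_csv(path) -> ClinicalTable:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical_csv(table: ClinicalTable, path) -> None:
    df = table.data.copy()
    df.index.name = df.index.name or "sample_id"
    df.to_csv(path)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Normalise each sample (column) to sum to one.

    All-zero columns are preserved as zeros and reported through a warning;
    rank order within every sample is unchanged.
    """
    if table.kind == "relative":
        return table
    values = table.values()
    if values.size == 0:
        return AbundanceTable(table.data.copy(), kind="relative")
    sums = values.sum(axis=0)
    zero_cols = np.flatnonzero(sums == 0)
    if zero_cols.size:
        warnings.warn(
            f"all-zero samples left as zeros: {[table.sample_ids[i] for i in zero_cols]}",
            stacklevel=2,
        )
    safe = np.where(sums > 0, sums, 1.0)
    rel = values / safe
    return AbundanceTable(
        pd.DataFrame(rel, index=table.data.index, columns=table.data.columns),
        kind="relative",
    )


def prevalence_abundance_filter(
    table: AbundanceTable,
    min_occurrence: float = 0.70,
    min_mean_abund: float = 1e-5,
    groups=None,
) -> AbundanceTable:
    """Keep features strictly exceeding both prevalence and mean-abundance cuts.

    Occurrence is the fraction of samples where the feature is strictly
    positive; the mean is taken over all samples, zeros included.  Defaults
    mirror the network-construction screen: occurrence > 70% and mean
    relative abundance > 0.001% (1e-5).  The screen is cohort-wide by
    default; passing ``groups`` (mapping sample id -> group label) keeps a
    feature that passes both cuts within at least one group.  Feature order
    is preserved and the operation is idempotent.
    """
    if table.kind != "relative":
        raise ValueError("prevalence_abundance_filter expects a relative table")
    for name, thr in (("min_occurrence", min_occurrence), ("min_mean_abund", min_mean_abund)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {thr}")
    if table.n_features == 0 or table.n_samples == 0:
        return AbundanceTable(table.data.copy(), kind=table.kind)

    def passes(df: pd.DataFrame) -> np.ndarray:
        values = df.to_numpy(dtype=float)
        occurrence = (values > 0).mean(axis=1)
        mean_abund = values.mean(axis=1)
        return (occurrence > min_occurrence) & (mean_abund > min_mean_abund)

    if groups is None:
        keep = passes(table.data)
    else:
        labels = pd.Series([groups[s] for s in table.sample_ids], index=table.sample_ids)
        keep = np.zeros(table.n_features, dtype=bool)
        for _, samples in labels.groupby(labels).groups.items():
            keep |= passes(table.data[list(samples)])
    return AbundanceTable(table.data.loc[keep], kind=table.kind)


def top_k_features(table: AbundanceTable, k: int = 50) -> AbundanceTable:
    """The ``k`` features with highest mean abundance, ranked descending.

    Ties in the mean are broken lexicographically by feature id (smaller id
    ranks first).  Asking for more features than exist returns them all with
    a warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    means = table.data.mean(axis=1)
    order = sorted(table.feature_ids, key=lambda f: (-means[f], str(f)))
    if k > len(order):
        warnings.warn(
            f"requested top {k} of {len(order)} features; returning all", stacklevel=2
        )
        k = len(order)
    return AbundanceTable(table.data.loc[order[:k]], kind=table.kind)
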