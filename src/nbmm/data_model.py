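"""Data structures and file I/O for longitudinal microbiome count data.

A longitudinal microbiome study measures each subject at several time
points; every sample carries read counts for *m* taxa, a total read count
(library size) and subject-level host covariates.  The in-memory container
here is a pair of aligned pandas DataFrames: per-sample metadata (subject,
time, total reads, covariates) and a samples x taxa count matrix.

On disk the counts live in the de-facto OTU-table text format: a
tab-delimited table, taxa x samples, first column the taxon name and the
header row the sample IDs.  Metadata is a tab-delimited table with one row
per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalDataset",
    "ScanResult",
    "read_dataset",
    "write_dataset",
    "filter_taxa",
]


class LongitudinalDataset:
    """Long-format longitudinal microbiome dataset.

    Parameters
    ----------
    samples : pandas.DataFrame
        One row per sample, indexed by sample ID.  Must contain the
        subject, time and total-read columns; any remaining columns are
        treated as host covariates.
    counts : pandas.DataFrame
        Samples x taxa nonnegative integer counts, indexed like ``samples``.
    subject_col, time_col, total_reads_col : str
        Column names in ``samples``.

    Rows are sorted by (subject, time) on construction so that
    order-based AR(1) correlation matrices follow measurement order.
    Duplicated (subject, time) pairs are rejected; total reads need not
    bound the taxon counts (the modeled taxa may be a subset of the
    library) but must be at least 1.
    """

    def __init__(
        self,
        samples: pd.DataFrame,
        counts: pd.DataFrame,
        subject_col: str = "subject",
        time_col: str = "time",
        total_reads_col: str = "total_reads",
    ):
        if not samples.index.equals(counts.index):
            missing = sorted(set(samples.index) ^ set(counts.index))
            raise ValueError(
                f"sample IDs of metadata and counts differ: {missing[:10]}"
            )
        for col in (subject_col, time_col, total_reads_col):
            if col not in samples.columns:
                raise ValueError(f"metadata is missing required column {col!r}")

        samples = samples.copy()
        counts = counts.copy()

        if samples[subject_col].isna().any():
            raise ValueError("missing subject IDs")
        time = pd.to_numeric(samples[time_col], errors="coerce")
        if time.isna().any():
            raise ValueError("missing or non-numeric time values")
        samples[time_col] = time.astype(float)

        total = samples[total_reads_col].to_numpy()
        if not np.all(np.isfinite(total.astype(float))) or np.any(total < 1):
            raise ValueError("total_reads must be >= 1 for every sample")
        if np.any(np.asarray(total, dtype=float) % 1 != 0):
            raise ValueError("total_reads must be integral")
        samples[total_reads_col] = np.asarray(total, dtype=np.int64)

        cvals = counts.to_numpy()
        if not np.issubdtype(cvals.dtype, np.number):
            raise ValueError("taxon counts must be numeric integers")
        if np.any(~np.isfinite(cvals.astype(float))) or np.any(cvals < 0):
            raise ValueError("taxon counts must be finite and nonnegative")
        if np.any(np.asarray(cvals, dtype=float) % 1 != 0):
            raise ValueError("taxon counts must be integral")
        counts = counts.astype(np.int64)

        dup = samples.duplicated(subset=[subject_col, time_col])
        if dup.any():
            pairs = samples.loc[dup, [subject_col, time_col]].to_records(index=False)
            raise ValueError(f"duplicated (subject, time) pairs: {list(pairs)[:10]}")

        order = samples.sort_values(
            [subject_col, time_col], kind="stable"
        ).index
        self.samples = samples.loc[order]
        self.counts = counts.loc[order]
        self.subject_col = subject_col
        self.time_col = time_col
        self.total_reads_col = total_reads_col

    # -- convenience accessors -------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_subjects(self) -> int:
        return self.samples[self.subject_col].nunique()

    @property
    def subjects(self) -> np.ndarray:
        return self.samples[self.subject_col].to_numpy()

    @property
    def times(self) -> np.ndarray:
        return self.samples[self.time_col].to_numpy(dtype=float)

    @property
    def total_reads(self) -> np.ndarray:
        return self.samples[self.total_reads_col].to_numpy(dtype=np.int64)

    def taxon_counts(self, taxon: str) -> np.ndarray:
        if taxon not in self.counts.columns:
            raise KeyError(f"taxon {taxon!r} not present in the dataset")
        return self.counts[taxon].to_numpy(dtype=np.int64)

    def covariate(self, name: str) -> pd.Series:
        if name not in self.samples.columns:
            raise KeyError(f"covariate {name!r} not present in the metadata")
        return self.samples[name]

    def __eq__(self, other) -> bool:
        if not isinstance(other, LongitudinalDataset):
            return NotImplemented
        return self.samples.equals(other.samples) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return (
            f"LongitudinalDataset(n_samples={self.n_samples}, "
            f"n_subjects={self.n_subjects}, n_taxa={len(self.taxa)})"
        )


@dataclass
class ScanResult:
    """Per-taxon association results from a differential-abundance scan.

    ``table`` has one row per (taxon, tested term) with columns
    taxon, term, estimate, se, t, df, p, p_adj, theta, converged.
    """

    table: pd.DataFrame

    COLUMNS = (
        "taxon",
        "term",
        "estimate",
        "se",
        "t",
        "df",
        "p",
        "p_adj",
        "theta",
        "converged",
    )

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"ScanResult table missing columns {missing}")
        p = self.table["p"].to_numpy(dtype=float)
        ok = np.isnan(p) | ((p >= 0) & (p <= 1))
        if not ok.all():
            raise ValueError("p-values must lie in [0, 1]")

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "ScanResult":
        return cls(pd.read_csv(path, sep="\t"))


def read_dataset(
    counts_path,
    metadata_path,
    key: str,
    orientation: str = "taxa_by_samples",
    subject_col: str = "subject",
    time_col: str = "time",
    total_reads_col: str | None = None,
) -> LongitudinalDataset:
    """Assemble a :class:`LongitudinalDataset` from two tab-delimited tables.

    Parameters
    ----------
    counts_path : path
        Tab-delimited count table.  With ``orientation="taxa_by_samples"``
        (the OTU-table convention) the first column holds taxon names and
        the header holds sample IDs; ``"samples_by_taxa"`` is the transpose.
        The orientation is never auto-detected.
    metadata_path : path
        Tab-delimited per-sample metadata; column ``key`` carries the
        sample IDs matching the counts table.
    total_reads_col : str, optional
        Metadata column holding library sizes.  When omitted, total reads
        are computed as the per-sample column sums of the counts table.
    """
    if orientation not in ("taxa_by_samples", "samples_by_taxa"):
        raise ValueError(f"unknown orientation {orientation!r}")

    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if orientation == "taxa_by_samples":
        counts = counts.T
    counts.index = counts.index.astype(str)

    meta = pd.read_csv(metadata_path, sep="\t", dtype={key: str})
    if key not in meta.columns:
        raise ValueError(f"metadata is missing the sample-ID column {key!r}")
    if meta[key].duplicated().any():
        dups = meta.loc[meta[key].duplicated(), key].tolist()
        raise ValueError(f"duplicated sample IDs in metadata: {dups[:10]}")
    meta = meta.set_index(key)

    only_counts = sorted(set(counts.index) - set(meta.index))
    only_meta = sorted(set(meta.index) - set(counts.index))
    if only_counts or only_meta:
        raise ValueError(
            "sample IDs do not match one-to-one; "
            f"only in counts: {only_counts[:10]}, only in metadata: {only_meta[:10]}"
        )
    counts = counts.loc[meta.index]

    if total_reads_col is None:
        meta = meta.copy()
        meta["total_reads"] = counts.sum(axis=1).astype(np.int64)
        total_reads_col = "total_reads"

    return LongitudinalDataset(
        meta,
        counts,
        subject_col=subject_col,
        time_col=time_col,
        total_reads_col=total_reads_col,
    )


def write_dataset(ds: LongitudinalDataset, counts_path, metadata_path) -> None:
    """Write a dataset back to the tab-delimited OTU-table pair.

    Counts are written taxa x samples (first column = taxon name); metadata
    keeps the sample ID as the first column under the name ``sample``.
    Round-tripping through :func:`read_dataset` reproduces the dataset
    bit-exactly.
    """
    ct = ds.counts.T
    ct.index.name = "taxon"
    ct.to_csv(counts_path, sep="\t")
    meta = ds.samples.copy()
    meta.index.name = "sample"
    meta.to_csv(metadata_path, sep="\t")


def filter_taxa(ds: LongitudinalDataset, min_nonzero_prop: float) -> LongitudinalDataset:
    """Prevalence filter: keep taxa observed (count > 0) in at least a
    fraction ``min_nonzero_prop`` of samples.

    Mostly-zero taxa violate the negative binomial assumption (the model
    does not handle zero-inflation), so a prevalence cut is applied before
    a per-taxon scan.  ``min_nonzero_prop=0`` keeps every taxon.  Retained
    taxa names are available as ``result.taxa``.
    """
    if not 0 <= min_nonzero_prop <= 1:
        raise ValueError("min_nonzero_prop must lie in [0, 1]")
    prev = (ds.counts > 0).mean(axis=0)
    keep = prev.index[prev.to_numpy() >= min_nonzero_prop]
    if len(keep) == 0:
        warnings.warn("no taxa pass the prevalence filter", stacklevel=2)
    return LongitudinalDataset(
        ds.samples,
        ds.counts[list(keep)],
        subject_col=ds.subject_col,
        time_col=ds.time_col,
        total_reads_col=ds.total_reads_col,
    )
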