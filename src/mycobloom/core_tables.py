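"""Core data model: ASV count table with taxonomy and dated sample metadata.

An :class:`AsvTable` bundles three aligned pandas objects — an integer count
matrix (ASVs × samples), a PR2-style eight-rank taxonomy with a fungal flag,
and per-sample metadata (collection date, size fraction, station).  Counts are
the single source of truth: every relative quantity downstream is derived on
demand and never stored.

Readers accept a dense TSV (first column ``asv_id``, one column per sample) or
a sparse triplet TSV (``asv_id``, ``sample_id``, ``count``); taxonomy is a TSV
and metadata a CSV with ISO-8601 dates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SIZE_FRACTIONS = ("gt3um", "0.2-3um")

TAXONOMY_RANKS = (
    "domain",
    "supergroup",
    "division",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


class MycobloomError(Exception):
    """Base class for all package errors."""


class DataError(MycobloomError):
    """Invalid or inconsistent input data."""


@dataclass(frozen=True)
class SampleFilterPolicy:
    """Global sample-retention thresholds.

    ``min_total_reads`` drops whole samples before any analysis; samples with
    exactly the threshold are kept ("less than" is removed).
    ``min_fungal_reads_for_diversity`` is applied only by the alpha-diversity
    stage, which needs enough fungal reads for within-kingdom proportions.
    """

    min_total_reads: int = 1000
    min_fungal_reads_for_diversity: int = 50

    def __post_init__(self) -> None:
        if self.min_total_reads < 0 or self.min_fungal_reads_for_diversity < 0:
            raise DataError("filter thresholds must be >= 0")


@dataclass
class AsvTable:
    """ASV counts with taxonomy and dated sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame indexed by ``asv_id`` with one column
        per ``sample_id``.
    taxonomy
        DataFrame indexed by ``asv_id`` with the eight PR2 ranks plus a
        boolean ``is_fungal`` column.  Ranks may be ``"unassigned"``.
    samples
        DataFrame indexed by ``sample_id`` with columns ``date``
        (datetime64), ``size_fraction`` and ``station``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self._validate()

    # -- validation ----------------------------------------------------
    def _validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate asv_ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample_ids: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("counts must be numeric")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise DataError(
                f"negative count at asv_id={c.index[i]!r}, sample_id={c.columns[j]!r}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise DataError(
                    f"non-integer count at asv_id={c.index[i]!r}, "
                    f"sample_id={c.columns[j]!r}"
                )
            self.counts = c.astype(np.int64)
        missing_tax = self.counts.index.difference(self.taxonomy.index)
        if len(missing_tax):
            raise DataError(f"missing taxonomy for ASVs: {missing_tax.tolist()}")
        missing_meta = self.counts.columns.difference(self.samples.index)
        if len(missing_meta):
            raise DataError(f"missing metadata for samples: {missing_meta.tolist()}")
        if "is_fungal" not in self.taxonomy.columns:
            raise DataError("taxonomy must carry an is_fungal column")

        # drop (with a warning) taxonomy / metadata rows never referenced
        extra_tax = self.taxonomy.index.difference(self.counts.index)
        if len(extra_tax):
            logger.warning("dropping %d unreferenced taxonomy rows", len(extra_tax))
            self.taxonomy = self.taxonomy.loc[self.counts.index]
        extra_meta = self.samples.index.difference(self.counts.columns)
        if len(extra_meta):
            logger.warning("dropping %d unreferenced metadata rows", len(extra_meta))
        # align orders
        self.taxonomy = self.taxonomy.loc[self.counts.index]
        self.samples = self.samples.loc[self.counts.columns]

        if not np.issubdtype(self.samples["date"].dtype, np.datetime64):
            try:
                self.samples = self.samples.assign(
                    date=pd.to_datetime(self.samples["date"], format="ISO8601")
                )
            except (ValueError, TypeError) as exc:
                raise DataError(f"unparseable date in metadata: {exc}") from exc
        bad_frac = set(self.samples["size_fraction"]) - set(SIZE_FRACTIONS)
        if bad_frac:
            raise DataError(
                f"unknown size fraction(s) {sorted(bad_frac)}; valid: {SIZE_FRACTIONS}"
            )
        for frac, grp in self.samples.groupby("size_fraction"):
            if grp["date"].duplicated().any():
                dup_dates = grp.loc[grp["date"].duplicated(), "date"].dt.date.tolist()
                logger.warning(
                    "duplicate sampling dates within fraction %s: %s", frac, dup_dates
                )

    # -- derived quantities --------------------------------------------
    @property
    def asv_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def total_reads(self) -> pd.Series:
        """Per-sample total read count (column sums; never stored)."""
        return self.counts.sum(axis=0)

    def fungal_ids(self) -> pd.Index:
        return self.taxonomy.index[self.taxonomy["is_fungal"].astype(bool)]

    def fungal_reads(self) -> pd.Series:
        """Per-sample reads assigned to Fungi."""
        return self.counts.loc[self.fungal_ids()].sum(axis=0)

    def dates(self) -> pd.Series:
        return self.samples["date"]

    # -- convenience ---------------------------------------------------
    def select_samples(self, sample_ids: Sequence[str]) -> "AsvTable":
        keep = self.counts.columns.intersection(pd.Index(sample_ids))
        return AsvTable(
            counts=self.counts[keep].copy(),
            taxonomy=self.taxonomy.copy(),
            samples=self.samples.loc[keep].copy(),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_counts(path: Path) -> pd.DataFrame:
    header = pd.read_csv(path, sep="\t", nrows=0)
    cols = [c.strip() for c in header.columns]
    if cols[:3] == ["asv_id", "sample_id", "count"] and len(cols) == 3:
        trip = pd.read_csv(path, sep="\t", dtype={"asv_id": str, "sample_id": str})
        if trip.duplicated(["asv_id", "sample_id"]).any():
            raise DataError("duplicate (asv_id, sample_id) pairs in triplet counts")
        wide = (
            trip.pivot(index="asv_id", columns="sample_id", values="count")
            .fillna(0)
            .astype(np.int64)
        )
        wide.index.name = "asv_id"
        wide.columns.name = None
        return wide
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "asv_id"
    return df


def read_table(counts_path, taxonomy_path, metadata_path) -> AsvTable:
    """Read and validate an :class:`AsvTable` from three text files.

    ``counts_path`` may be either a dense TSV or a sparse triplet TSV
    (detected from the header).  Errors are raised for duplicate ids,
    negative counts (naming the offending cell), ASVs without a taxonomy
    record, and unparseable dates (naming the sample row).
    """
    counts = _read_counts(Path(counts_path))
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col="asv_id", dtype=str)
    if taxonomy.index.has_duplicates:
        raise DataError("duplicate asv_ids in taxonomy")
    taxonomy["is_fungal"] = (
        taxonomy["is_fungal"].str.strip().str.lower().map({"true": True, "false": False})
    )
    if taxonomy["is_fungal"].isna().any():
        raise DataError("is_fungal must be 'true' or 'false' for every ASV")
    samples = pd.read_csv(metadata_path, index_col="sample_id", dtype=str)
    if samples.index.has_duplicates:
        raise DataError("duplicate sample_ids in metadata")
    parsed = pd.to_datetime(samples["date"], format="ISO8601", errors="coerce")
    if parsed.isna().any():
        bad = samples.index[parsed.isna()][0]
        raise DataError(
            f"unparseable date {samples.loc[bad, 'date']!r} for sample_id={bad!r}"
        )
    samples = samples.assign(date=parsed)
    return AsvTable(counts=counts, taxonomy=taxonomy, samples=samples)


def write_table(table: AsvTable, counts_path, taxonomy_path, metadata_path,
                sparse: bool = False) -> None:
    """Write the three standard files; ``sparse=True`` emits triplet counts."""
    if sparse:
        stacked = table.counts.stack()
        trip = stacked[stacked > 0].rename("count").reset_index()
        trip.columns = ["asv_id", "sample_id", "count"]
        trip.to_csv(counts_path, sep="\t", index=False)
    else:
        table.counts.to_csv(counts_path, sep="\t", index_label="asv_id")
    tax = table.taxonomy.copy()
    tax["is_fungal"] = tax["is_fungal"].map({True: "true", False: "false"})
    tax.to_csv(taxonomy_path, sep="\t", index_label="asv_id")
    meta = table.samples.copy()
    meta["date"] = meta["date"].dt.strftime("%Y-%m-%d")
    meta.to_csv(metadata_path, index_label="sample_id")


# ---------------------------------------------------------------------------
# global sample filters
# ---------------------------------------------------------------------------

def filter_samples(table: AsvTable, policy: SampleFilterPolicy | None = None) -> AsvTable:
    """Drop samples whose total read count is below ``policy.min_total_reads``.

    The boundary is inclusive: a sample with exactly the threshold is kept.
    Idempotent; raises :class:`DataError` if nothing would remain.
    """
    policy = policy or SampleFilterPolicy()
    totals = table.total_reads()
    keep = totals[totals >= policy.min_total_reads].index
    removed = totals.index.difference(keep)
    if len(keep) == 0:
        raise DataError(
            f"all {table.n_samples} samples fall below "
            f"min_total_reads={policy.min_total_reads}"
        )
    if len(removed):
        logger.info(
            "filter_samples removed %d sample(s) below %d reads: %s",
            len(removed), policy.min_total_reads, removed.tolist(),
        )
    return table.select_samples(keep)


def subset_fraction(table: AsvTable, fraction: str) -> AsvTable:
    """Restrict to one size fraction; all-zero ASV rows are retained."""
    if fraction not in SIZE_FRACTIONS:
        raise DataError(
            f"unknown size fraction {fraction!r}; valid labels: {list(SIZE_FRACTIONS)}"
        )
    keep = table.samples.index[table.samples["size_fraction"] == fraction]
    if len(keep) == 0:
        raise DataError(f"no samples in size fraction {fraction!r}")
    return table.select_samples(keep)
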