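"""Bloom detection, dominance profiling, persistence and monthly frequency.

A fungal bloom is operationally a sample in which Fungi make up at least 5%
of eukaryotic reads (inclusive threshold).  Within a bloom the dominance
profile m(p) is the minimal number of fungal ASVs whose reads cover a
fraction p of the fungal reads — blooms at this site are typically driven by
one or two ASVs.  Persistence asks whether the community stays above a
relative-abundance threshold across *consecutive* sampling points, where
"consecutive" respects the observed calendar: points further apart than
``max_gap_days`` never extend a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_tables import AsvTable, DataError

DEFAULT_LEVELS = (0.5, 0.9)


@dataclass(frozen=True)
class DominanceProfile:
    """Minimal ASV counts m(p) covering each fraction p of fungal reads."""

    m: Mapping[float, int]
    levels: tuple

    def __getitem__(self, p: float) -> int:
        return self.m[p]


@dataclass(frozen=True)
class BloomEvent:
    sample_id: str
    date: pd.Timestamp
    size_fraction: str
    ra_fungi: float
    dominance: DominanceProfile


def dominance_profile(fungal_counts, levels: Sequence[float] = DEFAULT_LEVELS) -> DominanceProfile:
    """m(p) = smallest k with the k largest ASV counts summing to >= p * total.

    ``fungal_counts`` is a pandas Series (asv_id -> reads) or array; ties in
    count are broken by ascending ASV id.  Requires at least one fungal read.
    """
    if isinstance(fungal_counts, pd.Series):
        s = fungal_counts.sort_index()
        counts = s.to_numpy(dtype=float)
    else:
        counts = np.asarray(fungal_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise DataError("dominance_profile requires at least one fungal read")
    # stable sort on ascending id then descending count keeps id tie-break
    order = np.argsort(-counts, kind="stable")
    csum = np.cumsum(counts[order])
    m = {}
    for p in levels:
        if not 0 < p <= 1:
            raise DataError(f"coverage level {p} outside (0, 1]")
        target = p * total
        m[float(p)] = int(np.searchsorted(csum, target - 1e-9 * total) + 1)
    return DominanceProfile(m=m, levels=tuple(float(p) for p in levels))


def detect_blooms(table: AsvTable, threshold: float = 0.05,
                  levels: Sequence[float] = DEFAULT_LEVELS) -> list[BloomEvent]:
    """Samples where fungal RA among all reads >= ``threshold`` (inclusive).

    Returns events sorted by date (then sample_id), each with its dominance
    profile.  An empty list is a valid result.
    """
    totals = table.total_reads().astype(float)
    fungal = table.fungal_reads().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ra = (fungal / totals.where(totals > 0)).fillna(0.0)
    # a bloom needs fungal reads; matters only at threshold 0
    hits = ra.index[(ra >= threshold) & (fungal > 0)]
    fungal_counts = table.counts.loc[table.fungal_ids()]
    events = []
    for sid in hits:
        events.append(
            BloomEvent(
                sample_id=sid,
                date=table.samples.loc[sid, "date"],
                size_fraction=table.samples.loc[sid, "size_fraction"],
                ra_fungi=float(ra[sid]),
                dominance=dominance_profile(fungal_counts[sid], levels),
            )
        )
    events.sort(key=lambda e: (e.date, e.sample_id))
    return events


def bloom_fraction_by_month(events: Sequence[BloomEvent], table: AsvTable) -> dict[int, float | None]:
    """Fraction of each calendar month's samples (pooling years) that bloom.

    Months with no samples map to None (undefined rather than 0).
    """
    months = table.samples["date"].dt.month
    bloom_ids = {e.sample_id for e in events}
    out: dict[int, float | None] = {}
    for month in range(1, 13):
        sids = months.index[months == month]
        if len(sids) == 0:
            out[month] = None
        else:
            out[month] = sum(s in bloom_ids for s in sids) / len(sids)
    return out


@dataclass(frozen=True)
class PersistenceReport:
    threshold: float
    max_run: int
    runs: list
    max_gap_days: float


def persistence(dates, values, threshold: float, max_gap_days: float = 8.0) -> PersistenceReport:
    """Runs of consecutive above-threshold points on the observed calendar.

    Two successive points belong to the same run only if both exceed
    ``threshold`` (strictly) and are separated by at most ``max_gap_days``.
    Isolated exceedances count as runs of length 1.  Dates must be strictly
    increasing; at least one point is required.
    """
    dates = pd.to_datetime(pd.Index(dates))
    vals = np.asarray(values, dtype=float)
    if len(dates) < 1:
        raise DataError("persistence requires at least one point")
    if len(dates) != len(vals):
        raise DataError("dates and values differ in length")
    diffs = np.diff(dates.view("int64")) / 86_400_000_000_000  # ns -> days
    if np.any(diffs <= 0):
        raise DataError("dates must be strictly increasing")
    above = vals > threshold
    runs = []
    start = None
    for i in range(len(vals)):
        if above[i]:
            if start is None:
                start = i
            elif diffs[i - 1] > max_gap_days:
                runs.append((start, i - 1))
                start = i
        else:
            if start is not None:
                runs.append((start, i - 1))
                start = None
    if start is not None:
        runs.append((start, len(vals) - 1))
    out = [(dates[a], dates[b], b - a + 1) for a, b in runs]
    max_run = max((r[2] for r in out), default=0)
    return PersistenceReport(threshold=threshold, max_run=max_run, runs=out,
                             max_gap_days=max_gap_days)
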