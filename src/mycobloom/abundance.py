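"""Relative abundance and Cumulative Relative Abundance (CRA).

For a taxon *i* nested in a reference group *G*, the relative abundance in
sample *s* is ``RA_i^{G,s} = N_i^s / N_G^s`` where *N* are raw read counts.
The Cumulative Relative Abundance of *i* within *G* aggregates a whole series:

    CRA_i^G = sum_s RA_i^{Total,s} / sum_s RA_G^{Total,s}
            = mean(RA_i^{Total}) / mean(RA_G^{Total})

i.e. the fraction of *G*'s reads carried by *i* if every sample contributed
the same number of reads and all samples were pooled.  CRA ranks taxa by
whole-series importance without letting deep samples dominate.

Samples with zero reads in the reference group have an undefined RA (0/0);
they are marked missing and excluded from CRA sums rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_tables import AsvTable, DataError, TAXONOMY_RANKS


def resolve_taxa(table: AsvTable, selector) -> pd.Index:
    """Resolve a taxon selector to a set of ASV ids.

    Accepts ``"Total"`` (all ASVs), ``"Fungi"`` (the is_fungal flag), any
    lineage value appearing at one of the eight ranks (e.g. ``"Ascomycota"``),
    a single asv_id, or an explicit iterable of asv_ids.
    """
    if isinstance(selector, str):
        if selector == "Total":
            return table.asv_ids
        if selector == "Fungi":
            return table.fungal_ids()
        if selector in table.asv_ids:
            return pd.Index([selector])
        mask = np.zeros(len(table.asv_ids), dtype=bool)
        for rank in TAXONOMY_RANKS:
            if rank in table.taxonomy.columns:
                mask |= (table.taxonomy[rank] == selector).to_numpy()
        if not mask.any():
            raise DataError(f"selector {selector!r} matches no ASV or lineage value")
        return table.asv_ids[mask]
    ids = pd.Index(list(selector))
    unknown = ids.difference(table.asv_ids)
    if len(unknown):
        raise DataError(f"unknown asv_ids in selector: {unknown.tolist()}")
    return ids


@dataclass
class RelAbundance:
    """Per-sample fractions of taxa within a reference group.

    ``values`` holds fractions in [0, 1], indexed by (taxon_id, sample_id);
    samples where the group has zero reads hold NaN (undefined, never 0).
    ``source_sample_totals`` are the per-sample group read counts used as
    denominators.
    """

    values: pd.DataFrame
    group: str
    source_sample_totals: pd.Series


def relative_abundance(table: AsvTable, taxa="Total", group: str = "Total") -> RelAbundance:
    """Per-sample relative abundance of ``taxa`` within ``group``.

    Every selected taxon must be nested in the reference group.  Returns one
    row per selected ASV; aggregate a lineage by summing rows.
    """
    taxa_ids = resolve_taxa(table, taxa)
    group_ids = resolve_taxa(table, group)
    if not set(taxa_ids).issubset(set(group_ids)):
        raise DataError(
            f"taxa selector {taxa!r} is not nested in group {group!r}"
        )
    denom = table.counts.loc[group_ids].sum(axis=0).astype(float)
    num = table.counts.loc[taxa_ids].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = num.div(denom.where(denom > 0), axis=1)
    label = group if isinstance(group, str) else "custom"
    return RelAbundance(values=vals, group=label, source_sample_totals=denom)


@dataclass(frozen=True)
class CraRecord:
    taxon_id: str
    group: str
    cra: float
    n_samples: int


def cumulative_relative_abundance(table: AsvTable, taxon, group="Total") -> CraRecord:
    """Cumulative Relative Abundance of ``taxon`` within ``group``.

    Both numerator and denominator are sums of total-normalised RAs over the
    same sample set (samples with zero total reads excluded).  The identity
    with the ratio of mean RAs is verified internally to 1e-12.
    """
    taxon_ids = resolve_taxa(table, taxon)
    group_ids = resolve_taxa(table, group)
    if not set(taxon_ids).issubset(set(group_ids)):
        raise DataError(f"taxon {taxon!r} is not nested in group {group!r}")
    totals = table.total_reads().astype(float)
    usable = totals[totals > 0].index
    if len(usable) == 0:
        raise DataError("no samples with reads")
    ra_i = (table.counts.loc[taxon_ids, usable].sum(axis=0) / totals[usable])
    ra_g = (table.counts.loc[group_ids, usable].sum(axis=0) / totals[usable])
    denom = ra_g.sum()
    if denom == 0:
        raise DataError(f"group {group!r} absent from all samples")
    cra = float(ra_i.sum() / denom)
    # ratio-of-means identity (same S in numerator and denominator)
    alt = float(ra_i.mean() / ra_g.mean())
    assert abs(cra - alt) <= 1e-12 * max(1.0, abs(cra))
    label = taxon if isinstance(taxon, str) else ",".join(map(str, taxon_ids))
    glabel = group if isinstance(group, str) else "custom"
    return CraRecord(taxon_id=label, group=glabel, cra=cra, n_samples=len(usable))


def cra_table(table: AsvTable, members="Fungi", group="Fungi") -> list[CraRecord]:
    """Per-ASV CRA records for every ASV in ``members``, within ``group``."""
    ids = resolve_taxa(table, members)
    return [cumulative_relative_abundance(table, [i], group=group) for i in ids]


@dataclass
class MajorSet:
    """Shortest descending-CRA prefix covering ``threshold`` of the group."""

    taxon_ids: list[str]
    cumulative_coverage: list[float]
    threshold: float

    @property
    def coverage(self) -> float:
        return self.cumulative_coverage[-1]


def select_major_taxa(cra_records: Sequence[CraRecord], threshold: float) -> MajorSet:
    """Smallest set of taxa whose summed CRA reaches ``threshold``.

    Taxa are ranked by descending CRA, ties broken by ascending taxon_id for
    determinism; the result is the shortest prefix with cumulative CRA >=
    threshold.
    """
    if not 0 < threshold <= 1:
        raise DataError("threshold must be in (0, 1]")
    groups = {r.group for r in cra_records}
    if len(groups) != 1:
        raise DataError(f"records span multiple groups: {sorted(groups)}")
    ranked = sorted(cra_records, key=lambda r: (-r.cra, r.taxon_id))
    cum = np.cumsum([r.cra for r in ranked])
    total = float(cum[-1]) if len(cum) else 0.0
    if total < threshold - 1e-12:
        raise DataError(
            f"records only cover {total:.6f} of the group, below threshold {threshold}"
        )
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    return MajorSet(
        taxon_ids=[r.taxon_id for r in ranked[:k]],
        cumulative_coverage=[float(c) for c in cum[:k]],
        threshold=threshold,
    )
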