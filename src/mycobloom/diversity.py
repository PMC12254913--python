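"""Alpha diversity of the fungal community, rarefaction and group tests.

Diversity is computed on fungal-normalised proportions (each fungal ASV's
reads divided by the sample's fungal read total), using only samples with at
least 50 fungal reads — shallow fungal sampling makes the indices
meaningless.  Shannon entropy is in nats by default; Gini-Simpson is
1 - sum(p_i^2).  Seasons follow calendar quarters with winter = Jan-Mar.

Rarefaction gives the expected ASV richness in a without-replacement
subsample of d reads:  E[S_d] = sum_i (1 - C(N - N_i, d) / C(N, d)),
evaluated through log-gamma for numerical stability.

Group differences use the tie-corrected Kruskal-Wallis test followed by
Dunn's pairwise z tests with Benjamini-Hochberg adjustment across the pairs
of one grouping variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .core_tables import AsvTable, DataError

SEASONS = {1: "winter", 2: "winter", 3: "winter",
           4: "spring", 5: "spring", 6: "spring",
           7: "summer", 8: "summer", 9: "summer",
           10: "autumn", 11: "autumn", 12: "autumn"}


def shannon_index(counts, base: float | None = None) -> float:
    """Shannon entropy of a count vector (natural log unless ``base``)."""
    p = np.asarray(counts, dtype=float)
    total = p.sum()
    if total <= 0:
        raise DataError("shannon_index needs positive total count")
    p = p[p > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def gini_simpson_index(counts) -> float:
    """1 - sum(p_i^2); probability two random reads are different ASVs."""
    p = np.asarray(counts, dtype=float)
    total = p.sum()
    if total <= 0:
        raise DataError("gini_simpson_index needs positive total count")
    p = p / total
    return float(1.0 - (p * p).sum())


def alpha_diversity(table: AsvTable, min_fungal_reads: int = 50,
                    base: float | None = None) -> pd.DataFrame:
    """Per-sample fungal Shannon and Gini-Simpson indices.

    Only samples with at least ``min_fungal_reads`` fungal reads qualify;
    proportions are within-Fungi (each fungal ASV over the fungal total).
    Returns a DataFrame indexed by sample_id with columns date, month,
    season, size_fraction, shannon, gini_simpson, n_fungal_reads.
    """
    fungal = table.counts.loc[table.fungal_ids()]
    totals = fungal.sum(axis=0)
    qualify = totals.index[totals >= min_fungal_reads]
    if len(qualify) == 0:
        raise DataError(
            f"no samples with >= {min_fungal_reads} fungal reads"
        )
    rows = []
    for sid in qualify:
        vec = fungal[sid].to_numpy()
        meta = table.samples.loc[sid]
        rows.append({
            "sample_id": sid,
            "date": meta["date"],
            "month": int(meta["date"].month),
            "season": SEASONS[meta["date"].month],
            "size_fraction": meta["size_fraction"],
            "shannon": shannon_index(vec, base=base),
            "gini_simpson": gini_simpson_index(vec),
            "n_fungal_reads": int(totals[sid]),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def rarefaction_curve(sample_counts, depths: Sequence[int]) -> np.ndarray:
    """Expected richness at each subsampling depth, without replacement.

    ``depths`` must be positive and no larger than the total read count.
    """
    counts = np.asarray(sample_counts, dtype=np.int64)
    counts = counts[counts > 0]
    n_total = int(counts.sum())
    depths = np.asarray(depths, dtype=np.int64)
    if np.any(depths < 1) or np.any(depths > n_total):
        raise DataError(f"depths must lie in [1, {n_total}]")
    # log C(N - N_i, d) - log C(N, d); term is 0 (certain presence) when
    # N - N_i < d because no subsample can avoid ASV i
    out = np.empty(len(depths), dtype=float)
    for k, d in enumerate(depths):
        rest = n_total - counts
        log_p_miss = np.where(
            rest >= d,
            gammaln(rest + 1) - gammaln(rest - d + 1)
            - (gammaln(n_total + 1) - gammaln(n_total - d + 1)),
            -np.inf,
        )
        out[k] = float((1.0 - np.exp(log_p_miss)).sum())
    return out


@dataclass
class GroupComparison:
    """Kruskal-Wallis omnibus plus Dunn pairwise results.

    ``pairwise`` rows are (group_a, group_b, z, p_raw, p_adjusted) with the
    Benjamini-Hochberg adjustment applied across all pairs of this family.
    """

    groups: list[str]
    h_statistic: float
    p_value: float
    pairwise: list[tuple]


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray,
                   groups: list[str]) -> list[tuple]:
    n = len(values)
    ranks = stats.rankdata(values)
    # tie correction term for the pooled ranking
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
            )
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((a, b, float(z), float(p)))
    return rows


def compare_groups(values_by_group: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis with Dunn / Benjamini-Hochberg post hoc.

    ``values_by_group`` maps a group label to its observations; every group
    needs at least 2 observations and at least 2 groups are required.
    Degenerate input where every observation is identical yields H = 0,
    p = 1 (no evidence of any difference).
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise DataError("compare_groups needs at least 2 groups")
    for g in groups:
        if len(values_by_group[g]) < 2:
            raise DataError(f"group {g!r} has fewer than 2 observations")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    labels = np.concatenate([np.repeat(g, len(a)) for g, a in zip(groups, arrays)])
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
        pairs = [(a, b, 0.0, 1.0) for i, a in enumerate(groups) for b in groups[i + 1:]]
    else:
        h, p = stats.kruskal(*arrays)
        pairs = _dunn_pairwise(pooled, labels, groups)
    raw = [r[3] for r in pairs]
    adj = multipletests(raw, method="fdr_bh")[1] if raw else []
    pairwise = [(a, b, z, pr, float(pa)) for (a, b, z, pr), pa in zip(pairs, adj)]
    return GroupComparison(groups=groups, h_statistic=float(h),
                           p_value=float(p), pairwise=pairwise)


def compare_diversity(records: pd.DataFrame, index: str = "shannon",
                      by: str = "season") -> GroupComparison:
    """Group an :func:`alpha_diversity` table by month/season/fraction."""
    if by not in records.columns:
        raise DataError(f"grouping column {by!r} not in records")
    grouped = {str(k): v[index].to_numpy() for k, v in records.groupby(by, sort=True)}
    return compare_groups(grouped)
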