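"""Scoring analysis output against simulation ground truth.

These helpers close the loop on the synthetic generator: they run the
bloom-detection, rhythmicity and major-taxa stages on a simulated table and
score the results against the latent values the generator planted.  Each
fungal ASV is classified in its dominant size fraction (the one holding the
larger share of its intensity); a trajectory absent from that fraction
counts as a misclassification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .abundance import cra_table, select_major_taxa
from .blooms import detect_blooms
from .core_tables import AsvTable, DataError, subset_fraction
from .rhythm import RhythmRules, classify_rhythm
from .simulate import GroundTruth


def _fraction_series(table: AsvTable, fraction: str):
    sub = subset_fraction(table, fraction)
    ordered = sub.samples.sort_values("date")
    ordered = ordered[~ordered["date"].duplicated()]
    times = (ordered["date"] - ordered["date"].iloc[0]).dt.days.to_numpy(float)
    totals = sub.total_reads().loc[ordered.index].to_numpy(float)
    return sub, ordered.index, times, totals


def classification_accuracy(table: AsvTable, truth: GroundTruth,
                            rules: RhythmRules | None = None) -> tuple[float, pd.DataFrame]:
    """Fraction of fungal ASVs whose archetype label is recovered.

    Returns (accuracy, per-ASV DataFrame with truth/predicted labels).
    """
    rules = rules or RhythmRules()
    cache = {f: _fraction_series(table, f)
             for f in sorted(set(table.samples["size_fraction"]))}
    rows = []
    for aid, info in truth.asv_info.iterrows():
        frac = "gt3um" if info["mix_gt3um"] >= 0.5 else "0.2-3um"
        sub, sids, times, totals = cache[frac]
        values = sub.counts.loc[aid, sids].to_numpy(float) / totals
        try:
            predicted = classify_rhythm(times, values, rules=rules).label
        except DataError:
            predicted = "absent"
        rows.append({"asv_id": aid, "truth": info["archetype"],
                     "predicted": predicted, "fraction": frac})
    df = pd.DataFrame(rows).set_index("asv_id")
    accuracy = float((df["truth"] == df["predicted"]).mean())
    return accuracy, df


def bloom_recall(table: AsvTable, truth: GroundTruth, latent_min: float = 0.08,
                 threshold: float = 0.05) -> tuple[float, int]:
    """Recall of detect_blooms on samples whose latent fungal RA >= latent_min.

    Returns (recall, number of planted bloom samples considered).
    """
    planted = [s for s in truth.fungal_total_ra[truth.fungal_total_ra >= latent_min].index
               if s in set(table.sample_ids)]
    if not planted:
        raise DataError(f"no planted samples with latent fungal RA >= {latent_min}")
    detected = {e.sample_id for e in detect_blooms(table, threshold=threshold)}
    recall = float(np.mean([s in detected for s in planted]))
    return recall, len(planted)


def major_set_latent_coverage(table: AsvTable, truth: GroundTruth,
                              threshold: float = 0.9) -> tuple[float, int]:
    """Latent CRA coverage of the observed major-ASV set.

    Selects the major fungal set from observed counts, then measures the
    share of summed *latent* fungal RA that the selected ASVs carry.
    Returns (coverage, size of the major set).
    """
    records = cra_table(table, members="Fungi", group="Fungi")
    major = select_major_taxa(records, threshold)
    latent_mass = truth.latent_ra.sum(axis=1)
    coverage = float(latent_mass[major.taxon_ids].sum() / latent_mass.sum())
    return coverage, len(major.taxon_ids)
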