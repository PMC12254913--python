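# mycobloom

Time-series analytics for marine **mycoplankton** — planktonic fungi observed
through 18S rRNA metabarcoding. Coastal monitoring series show that fungi sit
at low relative abundance most of the year and then bloom for a few days,
often driven by one or two amplicon sequence variants (ASVs). Standard
community-ecology toolkits handle none of the specifics well: irregular
sampling calendars, compositional read counts, day-scale bloom events, and
the question of whether such bursts are even biologically feasible as
in-situ growth. `mycobloom` packages those analyses for ecologists working
with ASV count tables (taxa × samples) plus taxonomy and dated sample
metadata.

## What it computes

**Relative abundance and CRA.** For taxon *i* nested in reference group *G*
(all eukaryotes, Fungi, a phylum, …), per-sample relative abundance is
`RA_i^{G,s} = N_i^s / N_G^s` with `N` raw read counts. The Cumulative
Relative Abundance aggregates a whole series:

```
CRA_i^G = Σ_s RA_i^{Total,s} / Σ_s RA_G^{Total,s} = mean(RA_i) / mean(RA_G)
```

— the share of *G* carried by *i* if every sample were weighted equally. The
*major set* is the smallest group of ASVs whose CRA sums past a threshold
(default 90%).

**Blooms and dominance.** A fungal bloom is a sample with
`RA_Fungi^Total ≥ 5%` (inclusive). Each bloom carries a dominance profile
`m(p)`: the minimal number of ASVs covering a fraction *p* of that sample's
fungal reads. Persistence scans for consecutive above-threshold sampling
points, where "consecutive" requires a calendar gap of at most
`max_gap_days` (default 8).

**Rhythmicity.** Each ASV trajectory gets a classical Lomb–Scargle
periodogram (periods 2–900 d, variance-normalised power, peak p-value
`1 − (1 − e^{−z})^M`) and one of three archetype labels: *rhythmic*
(annually recurring presence), *chaotic* (repeated but unorganised),
*ephemeral* (a single never-repeated appearance).

**Diversity.** Shannon (nats) and Gini-Simpson indices on within-Fungi
proportions for samples with ≥ 50 fungal reads; exact expected rarefaction
curves; Kruskal–Wallis + Dunn + Benjamini–Hochberg comparisons across
months, seasons (winter = Jan–Mar) and size fractions.

**Growth feasibility.** The specific growth rate (doublings/hour) an
organism needs to multiply its relative abundance *x*-fold in *t* hours from
an initial cell fraction *y*:

```
μ = (1/t) · log2(x − 1 + 1/(1 − x·y))
```

with an exact two-population inversion `μ = (1/t)·log2(x(1−y)/(1−x·y))`
available as a second mode, and verdicts against published fungal growth
rates (0.01–0.27 h⁻¹).

**Synthetic data.** `simulate_table` generates a ground-truthed series with
the right statistical structure — fortnightly/twice-weekly-winter calendar,
log-normal depths (median ≈ 37,000 reads), a seasonal background community,
and fungal ASVs of the three archetypes split across two size fractions —
so every stage can be validated against what was planted.

## Worked example

```python
import mycobloom as mb

table, truth = mb.simulate_table(mb.SimulationConfig(seed=42))
table = mb.filter_samples(table)                 # drop samples < 1000 reads
events = mb.detect_blooms(table, threshold=0.05)
print(f"{table.n_samples} samples, {len(events)} fungal blooms "
      f"({100 * len(events) / table.n_samples:.1f}%)")

first = events[0]
print(f"first bloom: {first.date.date()} ({first.size_fraction}), "
      f"RA_Fungi = {100 * first.ra_fungi:.1f}%, "
      f"m(50%) = {first.dominance[0.5]} ASV(s)")

records = mb.cra_table(table, members="Fungi", group="Fungi")
major = mb.select_major_taxa(records, threshold=0.9)
print(f"major fungal set: {len(major.taxon_ids)} of {len(records)} ASVs "
      f"cover {100 * major.coverage:.1f}% of fungal reads")

mu = mb.required_mu(x=1e5, y=2.5e-6, t=72.0)
print(f"required growth rate: {mu:.2f} h^-1 "
      f"-> {mb.feasibility(mu).verdict} the cultured range {mb.DEFAULT_REFERENCE_RANGE}")
```

prints

```
444 samples, 102 fungal blooms (23.0%)
first bloom: 2013-05-16 (gt3um), RA_Fungi = 5.4%, m(50%) = 1 ASV(s)
major fungal set: 27 of 40 ASVs cover 90.7% of fungal reads
required growth rate: 0.23 h^-1 -> within the cultured range (0.01, 0.27)
```

Read as: of 444 simulated samples, 102 cross the 5% bloom threshold; the
first bloom is half-covered by a single ASV; 27 ASVs carry 90.7% of all
fungal reads series-wide; and an undetected-to-25% burst in three days
demands ~0.23 doublings per hour — fast, but inside what cultured marine
fungi achieve.

The same stages are available from the shell:

```
mycobloom simulate --seed 42 --out sim/
mycobloom blooms --counts sim/counts.tsv --taxonomy sim/taxonomy.tsv \
    --metadata sim/metadata.csv --threshold 0.05
mycobloom growth --x 1e5 --y 2.5e-6 --t 72
mycobloom run --config run.yaml --out results/   # full pipeline + manifest
```

## Layout

- `src/mycobloom/core_tables.py` — data model, readers/writers, sample filters
- `src/mycobloom/abundance.py` — RA, CRA, major-set selection
- `src/mycobloom/blooms.py` — bloom detection, dominance, persistence
- `src/mycobloom/rhythm.py` — Lomb–Scargle, presence windows, classification
- `src/mycobloom/diversity.py` — alpha diversity, rarefaction, group tests
- `src/mycobloom/growth.py` — growth-rate feasibility
- `src/mycobloom/simulate.py` — ground-truthed synthetic series
- `src/mycobloom/recovery.py` — scoring analyses against ground truth
- `src/mycobloom/pipeline.py`, `cli.py` — pipeline runner and `mycobloom` CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
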