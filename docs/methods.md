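# Methods

This note documents the models behind `mycobloom`, the parameter defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Data model and filters

Counts are the single source of truth. An `AsvTable` stores the integer
count matrix, an eight-rank PR2-style taxonomy with a precomputed
`is_fungal` flag (an "unassigned" kingdom-level lineage counts as
non-fungal), and dated sample metadata. All relative quantities are derived
on demand; nothing stores percentages. Two global filters exist:

- `min_total_reads = 1000` — whole samples below 1000 total reads are
  dropped before any analysis; the boundary is inclusive (exactly 1000 is
  kept, "less than" removed).
- `min_fungal_reads_for_diversity = 50` — applied only by the
  alpha-diversity stage, which computes within-Fungi proportions and needs
  a minimally sampled fungal community.

Size-fraction subsetting keeps all-zero ASV rows so that ASV identifiers
remain stable across fractions. When filtering and fraction-splitting are
combined, filtering is applied after splitting, so a fraction's sample set
never depends on reads observed in the other fraction.

## Relative abundance and CRA

`RA_i^{G,s} = N_i^s / N_G^s`. Samples where the reference group has zero
reads yield an undefined RA (0/0); these are represented as missing values,
never as 0, and excluded from CRA sums rather than imputed — the CRA of a
taxon within a group is then a ratio of sums over the same retained sample
set, which keeps the identity `CRA = mean(RA_i)/mean(RA_G)` exact. That
identity is asserted internally to 1e-12 on every call, so a violation
surfaces immediately rather than as silent drift.

Statistics pooled over "both size fractions" treat the two fractions'
samples as independent observations in one computation. This pooling rule
is a package decision (exposed by simply passing the pooled table); any
other pooling can be had by subsetting first.

Major-set selection sorts by descending CRA with ties broken by ascending
taxon id (determinism), and returns the shortest prefix whose cumulative
CRA reaches the threshold — "smallest set reaching the threshold", not
"every taxon above a cutoff".

## Blooms, dominance, persistence

A bloom is a sample with fungal RA among all reads at or above the
threshold (default 0.05, inclusive per its "at least 5%" definition).
Dominance ranks fungal ASVs by their raw counts within the sample
(equivalent to within-Fungi RA), ties again by ASV id; `m(p)` is the
smallest k whose top-k counts reach `p` of the fungal total. Because the
counts are sorted descending, the greedy prefix is provably the true
minimum over all subsets; the tests confirm this against exhaustive search.

Persistence treats "consecutive sampling points" on the observed calendar:
two above-threshold points extend a run only when separated by at most
`max_gap_days` (default 8 days, spanning both the twice-weekly winter and
weekly regimes while refusing to bridge month-scale gaps). Exceedance is
strict (`> threshold`), matching the "never greater than" phrasing of the
claim this statistic exists to check.

## Lomb-Scargle periodogram

The classical periodogram with Scargle's time offset tau, computed directly
(vectorised over a frequency grid), with "standard" normalisation: power =
explained sum of squares of the best-fit sinusoid divided by `2·var(y)`
(ddof = 1). Under this scaling a noiseless sinusoid scores ≈ (N−1)/2 and
Gaussian noise has unit-exponential peak heights, giving the peak p-value
`1 − (1 − e^{−z})^M` with `M` = number of grid frequencies (the
Horne-Baliunas style effective-frequency estimate is deliberately not the
default; at oversampling 1 the grid size is the natural choice).

Grid: frequencies from `1/max_period` (900 d) to `1/min_period` (2 d) in
steps of `1/(oversampling × span)`, oversampling 1 by default. Equality
with an explicit least-squares sinusoid fit at every grid frequency is a
tested invariant (to 1e-8; observed agreement ~1e-12), as is invariance
under value shifts and positive rescaling.

Note on aliasing: with *perfectly* periodic sampling the scan range extends
far beyond the Nyquist frequency, and a noiseless sinusoid has exact
equal-power aliases at `f0 + k/Δt`; the peak may then land on an alias.
Real (and simulated) calendars are jittered, which suppresses these
replicas — the tests use jittered quasi-regular sampling for this reason.

## Rhythmicity classification

The field practice this codifies is visual: annually recurring taxa versus
scattered repeaters versus one-off appearances. The package makes the rules
explicit and configurable (`RhythmRules`), with defaults:

- presence threshold `epsilon = 0.001` of eukaryotic reads — an ASV is
  "present" when it exceeds 0.1% of the community, well above typical
  detection limits (~1/40,000) but low enough to catch bloom shoulders;
- `merge_gap_days = 21` — presence windows are maximal chains of qualifying
  samples at most 21 days apart; this merges runs broken by a few
  below-threshold samples and splits appearances separated by long gaps;
- ephemeral: exactly one presence window;
- rhythmic: ≥ 2 windows and *either* a significant periodogram peak
  (p ≤ 0.01) in the annual band 300–430 days, *or* day-of-year recurrence:
  some ±45-day band around a window midpoint contains windows from ≥ 3
  distinct years *and* at least 75% of all windows. The second condition is
  what "reappearing at regular frequencies" means operationally — without
  it, any taxon with many scattered spikes eventually places three of them
  in the same seasonal band by accident and would be mislabelled;
- chaotic: everything else. A trajectory with zero presence windows cannot
  be classified (error).

These rules are validated purely by synthetic recovery (≥ 90% accuracy
required, ~94–97% observed across seeds); they are *not* claimed to
reproduce any expert's per-taxon labels on real data, where hybrid dynamics
(rhythmic in some years only) blur the archetypes. Classification series
are RAs among all eukaryotes, not fungal-normalised, so a fungal ASV's
signal is not distorted by other fungi. Missing dates are simply absent
points; no interpolation.

## Alpha diversity and group tests

Shannon (natural log; base configurable) and Gini-Simpson on within-Fungi
proportions, samples with ≥ 50 fungal reads only. Seasons are calendar
quarters anchored at winter = January–March. Rarefaction uses the exact
hypergeometric expectation `E[S_d] = Σ_i (1 − C(N−N_i,d)/C(N,d))` computed
through log-gamma (stable for deep samples); a term with `N − N_i < d` is
certain presence. Group comparison: scipy's tie-corrected Kruskal–Wallis;
Dunn's pairwise z from pooled mean ranks with the standard tie term
`Σ(t³−t)/(12(N−1))`, two-sided p; Benjamini–Hochberg applied across the
pairs of one grouping variable (one family per grouping). The degenerate
all-values-identical case returns H = 0, p = 1 rather than the 0/0 the tie
correction would produce.

## Growth feasibility

Two modes, both in doublings per hour:

- printed: `μ = (1/t)·log2(x − 1 + 1/(1 − x·y))`;
- exact: `μ = (1/t)·log2(x·(1−y)/(1 − x·y))`, the algebraic inversion of
  "cells `y·2^{μt}` against a constant background `1 − y` reach `x·y`
  relative abundance".

For the detection-limit scenario (x = 1e5, y = 2.5e-6, t = 72 h) they give
0.2307 and 0.2365 h⁻¹ respectively. The printed form is the default; the
discrepancy is a documented property of the formulas, not resolved by the
package. Both modes converge to `log2(x)/t` as y → 0 (first-order
difference ≈ (x−2)·y/(t·ln 2), so "agreement" claims only make sense while
x·y is tiny). The feasibility verdict compares μ inclusively against a
configurable published range, default 0.01–0.27 h⁻¹ from cultured marine
fungi, with 0.045 h⁻¹ (the highest in-situ estimate) available as the
`IN_SITU_BENCHMARK` annotation.

## Synthetic generator

What it emulates: a ~5-year calendar starting 2013-05-01 with 14-day
baseline spacing, 3.5-day spacing in January–March and ±1 day jitter;
log-normal read depths (median ≈ 37,000, log-sd 0.2); ~150 background
eukaryote ASVs with log-normal baselines (log-sd 1.5) modulated by annual
sinusoids (amplitude up to 0.6, random phase); and fungal ASVs of the three
archetypes. Fungal events are Gaussian bumps in a latent "absolute" scale:
rhythmic — one bump per year at a fixed day-of-year (per-year jitter sd
10 d, bump sd 5 d, peak 3–20%); chaotic — Poisson(1/yr) bumps at uniform
times (at least 2, so the label is honest by construction; sd 2.5 d, peak
3–20%); ephemeral — a single bump (duration 7–30 d, peak 3–20%). Peak
intensities of 3–20% reflect that every planted fungal ASV is a
bloom-former; the realised series averages ~3% fungal RA with ~20–25%
bloom samples, denser than a real coastal series (where most fungal taxa
never bloom) but with the same event structure.

Relative abundances close exactly: fungal RA = intensity /(B + Σ
intensities) with background size B (normally 1), and the background fills
the remainder proportionally to its seasonal weights. An optional
background crash (B shrunk in a window) produces compositional "false
blooms" where fungal RA rises with no fungal growth. Two size fractions
split each fungal ASV's intensity by a Beta(4,2)-distributed weight for the
large fraction. Counts are single multinomial draws at the sample's depth.
Every latent value — per-ASV per-sample RA, total fungal RA, event times,
archetype labels, mixing weights — is exported as `GroundTruth`.

What it does not emulate: sequencing error and chimeras, taxonomic
misassignment, rRNA copy-number bias between taxa, year-over-year trends,
environmental covariates, and dependence between the two fractions' depths.
Passing recovery tests therefore demonstrates that the *algorithms* recover
planted structure under realistic sampling and counting noise — not that
real fungal dynamics are this clean.

Determinism: calendar, ASV parameters and count draws use three child
streams of one seed sequence; identical configs give byte-identical output
files.

## Problem sizes and numerics

The test suite and the acceptance script run entirely on synthetic input:
the recovery benchmark uses the default 5-year two-fraction series with 30
ASVs per archetype (90 fungal + 150 background ASVs, ~440 samples), sizes
at which the whole suite completes in well under a minute while every
statistic has comfortable signal. Monte-Carlo oracles use 2×10⁴ draws in
unit tests and 10⁵ in the acceptance script; the Kruskal–Wallis
permutation null is exhaustive (34,650 partitions of 3×4 observations).
Floating-point tie-breaks: major-set and dominance thresholds use a 1e-9
relative slack inside `searchsorted` so exact-boundary prefixes are not
lost to rounding; CRA identities are asserted at 1e-12; periodogram-oracle
agreement at 1e-8.

## Known limitations

- Bloom statistics are per-sample, not per-event: a bloom sampled twice in
  a dense winter week counts twice.
- The rhythm classifier emits a single label; genuinely hybrid
  trajectories get whichever archetype dominates, with diagnostics
  (window count, peak period, p-value) exposed for manual review.
- CRA weights every retained sample equally; a series with very uneven
  coverage between years weights well-sampled years more.
- The growth model ignores losses (grazing, lysis, export), so required
  rates are lower bounds on the true demand of an in-situ explanation.
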