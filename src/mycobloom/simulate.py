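"""Synthetic coastal metabarcoding time series with known ground truth.

Emulates the statistical structure of a multi-year coastal 18S V4 ASV
series: an irregular calendar (fortnightly baseline, twice-weekly in the
January-March winters, +-1 day jitter), log-normal per-sample read depths
with a median around 37,000 reads, a seasonally modulated background
eukaryote community of ~150 ASVs, and sparse fungal ASVs following three
dynamic archetypes:

* rhythmic   - a Gaussian abundance bump every year at a fixed day-of-year
  (jittered by a few days from year to year);
* chaotic    - bumps at seeded uniform-random times with no annual
  organisation (at least two, so the archetype differs from ephemeral by
  construction);
* ephemeral  - a single bump that never recurs.

Abundances are generated in latent "absolute" units: fungal intensities
f_i(t) against a background of total size B(t) (normally 1; optionally
crashed to mimic compositional false blooms).  Latent relative abundances
are f_i / (B + sum f) for fungal ASVs, with the background filling the
remainder proportionally to seasonal weights — so latent RAs sum to exactly
1.  Observed counts are a single multinomial draw per sample at its depth.
Two size fractions split each fungal ASV's intensity with an ASV-specific
mixing weight.  Every latent value is exported as :class:`GroundTruth` so
downstream operations can be scored against what was actually planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_tables import AsvTable, DataError, TAXONOMY_RANKS, write_table

DAYS_PER_YEAR = 365.25
WINTER_MONTHS = (1, 2, 3)

_FUNGAL_CLASSES = ("Ascomycota", "Basidiomycota", "Chytridiomycota", "Cryptomycota")
_BACKGROUND_DIVISIONS = (
    "Dinoflagellata", "Ochrophyta", "Ciliophora", "Chlorophyta",
    "Haptophyta", "Cercozoa", "Metazoa", "Radiolaria",
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions.

    Depth parameters give a log-normal with median ~37,000 reads and a
    coefficient of variation around 20%.  Archetype RA ranges refer to the
    latent intensity at an event peak, before fraction splitting.
    """

    seed: int = 42
    years: float = 5.0
    start_date: str = "2013-05-01"
    baseline_interval_days: float = 14.0
    winter_interval_days: float = 3.5
    jitter_days: float = 1.0

    n_background_asvs: int = 150
    n_rhythmic: int = 10
    n_chaotic: int = 20
    n_ephemeral: int = 10

    depth_log_mean: float = math.log(37_000.0)
    depth_log_sd: float = 0.2

    background_seasonal_amplitude: float = 0.6
    background_log_sd: float = 1.5

    rhythmic_peak_ra: tuple = (0.03, 0.20)
    rhythmic_day_jitter_sd: float = 10.0
    rhythmic_bloom_width_days: float = 5.0  # Gaussian sd

    chaotic_spikes_per_year: float = 1.0
    chaotic_spike_ra: tuple = (0.03, 0.20)
    chaotic_spike_width_days: float = 2.5  # Gaussian sd

    ephemeral_duration_days: tuple = (7.0, 30.0)
    ephemeral_ra: tuple = (0.03, 0.20)

    fractions: tuple = ("gt3um", "0.2-3um")
    mixing_beta: tuple = (4.0, 2.0)  # gt3um share ~ Beta(a, b)
    station: str = "SOLA"

    # optional compositional "false bloom": background shrinks to
    # (1 - crash_magnitude) between crash_start and crash_start + crash_duration
    crash_start_day: float | None = None
    crash_duration_days: float = 10.0
    crash_magnitude: float = 0.8

    def __post_init__(self) -> None:
        if self.years <= 0 or self.baseline_interval_days <= 0 or self.winter_interval_days <= 0:
            raise DataError("calendar parameters must be positive")
        for lo, hi in (self.rhythmic_peak_ra, self.chaotic_spike_ra, self.ephemeral_ra):
            if not 0 < lo <= hi < 1:
                raise DataError("archetype RA ranges must lie inside (0, 1)")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    asv_info: pd.DataFrame          # fungal ASVs: archetype, mixing weight, ...
    latent_ra: pd.DataFrame         # fungal ASV x sample latent RA
    fungal_total_ra: pd.Series      # per sample: latent sum over fungal ASVs
    event_times: dict               # asv_id -> sorted event centres (days)
    times_days: pd.Series           # per sample: days since series start
    config: SimulationConfig


# ---------------------------------------------------------------------------
# calendar
# ---------------------------------------------------------------------------

def make_calendar(config: SimulationConfig) -> np.ndarray:
    """Strictly increasing sampling dates (datetime64[D]) for one station.

    Fortnightly spacing outside January-March, ``winter_interval_days``
    inside, each step jittered by +-``jitter_days`` (uniform, seeded).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    start = np.datetime64(config.start_date, "D")
    horizon = config.years * DAYS_PER_YEAR
    days: list[int] = []
    t = 0.0
    while t <= horizon:
        day = int(round(t))
        if not days or day > days[-1]:
            days.append(day)
        month = int(str((start + days[-1]).astype("datetime64[M]"))[5:7])
        base = (config.winter_interval_days if month in WINTER_MONTHS
                else config.baseline_interval_days)
        step = base + rng.uniform(-config.jitter_days, config.jitter_days)
        t = days[-1] + max(1.0, step)
    return start + np.array(days, dtype="timedelta64[D]")


# ---------------------------------------------------------------------------
# latent intensities
# ---------------------------------------------------------------------------

def _gaussian_bumps(t: np.ndarray, centres: np.ndarray, amps: np.ndarray,
                    sd: float) -> np.ndarray:
    if len(centres) == 0:
        return np.zeros_like(t)
    d = t[:, None] - centres[None, :]
    return (amps[None, :] * np.exp(-0.5 * (d / sd) ** 2)).sum(axis=1)


def simulate_table(config: SimulationConfig | None = None) -> tuple[AsvTable, GroundTruth]:
    """Generate an :class:`AsvTable` plus full latent ground truth.

    Deterministic under a fixed ``config.seed``: the calendar, all ASV
    parameters, depths and multinomial draws derive from independent child
    streams of the same seed sequence.
    """
    config = config or SimulationConfig()
    dates = make_calendar(config)
    t_days = (dates - dates[0]).astype(float)
    n_t = len(t_days)
    span = float(t_days[-1])
    start_doy = float(
        (dates[0] - dates[0].astype("datetime64[Y]").astype("datetime64[D]")).astype(float)
    )

    rng_params = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rng_counts = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    # ---- fungal archetype parameters and event times -------------------
    n_fungal = config.n_rhythmic + config.n_chaotic + config.n_ephemeral
    fungal_ids = [f"FASV{i:03d}" for i in range(1, n_fungal + 1)]
    archetypes = (["rhythmic"] * config.n_rhythmic
                  + ["chaotic"] * config.n_chaotic
                  + ["ephemeral"] * config.n_ephemeral)
    mix = rng_params.beta(*config.mixing_beta, size=n_fungal)

    event_times: dict[str, list[float]] = {}
    peak_doys = np.full(n_fungal, np.nan)
    amp_by_event: dict[str, np.ndarray] = {}
    sd_by_asv = np.empty(n_fungal)
    n_years = int(math.ceil(config.years)) + 1
    for k, (aid, kind) in enumerate(zip(fungal_ids, archetypes)):
        if kind == "rhythmic":
            doy = rng_params.uniform(0, DAYS_PER_YEAR)
            peak_doys[k] = doy
            amp = rng_params.uniform(*config.rhythmic_peak_ra)
            centres = []
            for year in range(-1, n_years):
                c = (year * DAYS_PER_YEAR + (doy - start_doy) % DAYS_PER_YEAR
                     + rng_params.normal(0, config.rhythmic_day_jitter_sd))
                centres.append(c)
            centres = [c for c in centres if -60 <= c <= span + 60]
            amps = np.full(len(centres), amp)
            sd_by_asv[k] = config.rhythmic_bloom_width_days
        elif kind == "chaotic":
            n_spk = max(2, rng_params.poisson(config.chaotic_spikes_per_year * config.years))
            centres = sorted(rng_params.uniform(0, span, size=n_spk))
            amps = rng_params.uniform(*config.chaotic_spike_ra, size=n_spk)
            sd_by_asv[k] = config.chaotic_spike_width_days
        else:  # ephemeral
            duration = rng_params.uniform(*config.ephemeral_duration_days)
            centres = [rng_params.uniform(0.05, 0.95) * span]
            amps = np.array([rng_params.uniform(*config.ephemeral_ra)])
            sd_by_asv[k] = duration / 4.0
        event_times[aid] = sorted(float(c) for c in centres)
        amp_by_event[aid] = np.asarray(amps, dtype=float)

    fungal_intensity = np.zeros((n_fungal, n_t))
    for k, aid in enumerate(fungal_ids):
        fungal_intensity[k] = _gaussian_bumps(
            t_days, np.asarray(event_times[aid]), amp_by_event[aid], sd_by_asv[k]
        )

    # ---- background community ------------------------------------------
    nb = config.n_background_asvs
    bg_ids = [f"BG{i:04d}" for i in range(1, nb + 1)]
    doy_t = (start_doy + t_days) % DAYS_PER_YEAR
    bg_weights = {}
    for frac in config.fractions:
        base = rng_params.lognormal(0.0, config.background_log_sd, size=nb)
        amp = config.background_seasonal_amplitude * rng_params.uniform(0, 1, size=nb)
        phase = rng_params.uniform(0, DAYS_PER_YEAR, size=nb)
        season = 1.0 + amp[:, None] * np.sin(
            2 * np.pi * (doy_t[None, :] - phase[:, None]) / DAYS_PER_YEAR
        )
        bg_weights[frac] = base[:, None] * season  # (nb, n_t), positive

    # background absolute size, optionally crashed
    b_total = np.ones(n_t)
    if config.crash_start_day is not None:
        in_crash = ((t_days >= config.crash_start_day)
                    & (t_days <= config.crash_start_day + config.crash_duration_days))
        b_total[in_crash] = 1.0 - config.crash_magnitude

    # ---- assemble samples ----------------------------------------------
    frac_code = {"gt3um": "L", "0.2-3um": "S"}
    columns, meta_rows = [], []
    latent_cols = {}
    counts_cols = {}
    for frac in config.fractions:
        share = mix if frac == "gt3um" else (1.0 - mix)
        f_frac = fungal_intensity * share[:, None]  # (n_fungal, n_t)
        ftot = f_frac.sum(axis=0)
        if np.any(ftot >= 1.0):
            raise DataError(
                "summed fungal intensities reach 1; reduce archetype RA parameters"
            )
        denom = b_total + ftot
        latent_f = f_frac / denom[None, :]
        w = bg_weights[frac]
        latent_bg = (w / w.sum(axis=0)[None, :]) * (b_total / denom)[None, :]
        for j, date in enumerate(dates):
            sid = f"{config.station}-{str(date).replace('-', '')}-{frac_code.get(frac, frac)}"
            columns.append(sid)
            meta_rows.append({
                "sample_id": sid,
                "date": pd.Timestamp(str(date)),
                "size_fraction": frac,
                "station": config.station,
            })
            p = np.concatenate([latent_f[:, j], latent_bg[:, j]])
            depth = int(round(rng_counts.lognormal(config.depth_log_mean,
                                                   config.depth_log_sd)))
            depth = max(depth, 100)
            counts_cols[sid] = rng_counts.multinomial(depth, p / p.sum())
            latent_cols[sid] = latent_f[:, j]

    all_ids = fungal_ids + bg_ids
    counts = pd.DataFrame(counts_cols, index=pd.Index(all_ids, name="asv_id"))

    # ---- taxonomy -------------------------------------------------------
    tax_rows = []
    for k, aid in enumerate(fungal_ids):
        cls = _FUNGAL_CLASSES[k % len(_FUNGAL_CLASSES)]
        tax_rows.append({"asv_id": aid, "domain": "Eukaryota",
                         "supergroup": "Opisthokonta", "division": "Fungi",
                         "class": cls, "order": "unassigned",
                         "family": "unassigned", "genus": "unassigned",
                         "species": "unassigned", "is_fungal": True})
    for k, aid in enumerate(bg_ids):
        div = _BACKGROUND_DIVISIONS[k % len(_BACKGROUND_DIVISIONS)]
        tax_rows.append({"asv_id": aid, "domain": "Eukaryota",
                         "supergroup": "unassigned", "division": div,
                         "class": "unassigned", "order": "unassigned",
                         "family": "unassigned", "genus": "unassigned",
                         "species": "unassigned", "is_fungal": False})
    taxonomy = pd.DataFrame(tax_rows).set_index("asv_id")
    samples = pd.DataFrame(meta_rows).set_index("sample_id")

    table = AsvTable(counts=counts, taxonomy=taxonomy, samples=samples)

    latent_ra = pd.DataFrame(latent_cols, index=pd.Index(fungal_ids, name="asv_id"))
    truth = GroundTruth(
        asv_info=pd.DataFrame({
            "archetype": archetypes,
            "mix_gt3um": mix,
            "peak_day_of_year": peak_doys,
            "n_events": [len(event_times[a]) for a in fungal_ids],
        }, index=pd.Index(fungal_ids, name="asv_id")),
        latent_ra=latent_ra,
        fungal_total_ra=latent_ra.sum(axis=0),
        event_times=event_times,
        times_days=pd.Series(
            {sid: float((samples.loc[sid, "date"] - pd.Timestamp(str(dates[0]))).days)
             for sid in counts.columns},
            name="days_since_start",
        ),
        config=config,
    )
    return table, truth


def write_simulation(table: AsvTable, truth: GroundTruth, outdir) -> dict[str, Path]:
    """Write the three standard input files plus ground-truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.csv",
        "truth_asvs": outdir / "truth_asvs.tsv",
        "truth_latent_ra": outdir / "truth_latent_ra.tsv",
    }
    write_table(table, paths["counts"], paths["taxonomy"], paths["metadata"])
    truth.asv_info.to_csv(paths["truth_asvs"], sep="\t")
    truth.latent_ra.to_csv(paths["truth_latent_ra"], sep="\t")
    return paths
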