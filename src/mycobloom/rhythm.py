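"""Lomb-Scargle periodograms and rhythmicity classification for ASV series.

Marker-gene time series are sampled irregularly (fortnightly baseline,
twice-weekly in winter, occasional gaps), which rules out FFT-based spectra.
The classical Lomb-Scargle periodogram handles arbitrary sampling: the power
at an angular frequency w equals the variance explained by the least-squares
sinusoid fit a*cos(wt) + b*sin(wt) to the mean-centred series, made
computable in closed form through Scargle's time offset tau with
tan(2*w*tau) = sum(sin(2*w*t_i)) / sum(cos(2*w*t_i)).

Power here uses the "standard" normalisation (divide by twice the sample
variance), under which the tallest peak of pure Gaussian noise is
exponentially distributed and the peak p-value is
1 - (1 - exp(-z))^M with M independent frequencies.

Classification assigns each trajectory one of three dynamic archetypes:

* ephemeral - a single presence window, never reappearing;
* rhythmic  - recurring presence locked to the annual cycle, evidenced
  either by a significant periodogram peak in the annual band or by
  presence windows clustering at the same day-of-year across >= 3 years;
* chaotic   - repeated presence with no annual organisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_tables import DataError

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class PeriodogramParams:
    """Grid and significance settings for :func:`lomb_scargle`.

    Defaults scan periods from 2 to 900 days at oversampling 1 (frequency
    step 1 / time span), testing the top peak at alpha = 0.01.
    """

    min_period: float = 2.0
    max_period: float = 900.0
    oversampling: float = 1.0
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.min_period < self.max_period:
            raise DataError("need 0 < min_period < max_period")
        if self.oversampling <= 0:
            raise DataError("oversampling must be > 0")


@dataclass
class PeriodogramResult:
    periods: np.ndarray
    power: np.ndarray
    peak_period: float
    peak_power: float
    p_value: float
    params: PeriodogramParams

    @property
    def n_frequencies(self) -> int:
        return len(self.periods)


def lomb_scargle(times, values, params: PeriodogramParams | None = None) -> PeriodogramResult:
    """Classical Lomb-Scargle periodogram, standard (variance) normalisation.

    Parameters
    ----------
    times
        Sampling times in days since the series start, strictly increasing.
    values
        Observed values (relative abundances); must not be constant.
    params
        Grid and significance settings; see :class:`PeriodogramParams`.

    The frequency grid runs from 1/max_period to 1/min_period in steps of
    1/(oversampling * span).  Power at each frequency equals the explained
    sum of squares of the best-fit sinusoid divided by twice the sample
    variance (ddof=1), so a noiseless sinusoid scores ~ (N-1)/2 and pure
    noise scores ~ 1.  The reported p-value is for the tallest peak,
    1 - (1 - exp(-z))^M with M the number of grid frequencies.
    """
    params = params or PeriodogramParams()
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise DataError("times and values must be 1-D and equal length")
    if len(t) < 4:
        raise DataError("lomb_scargle requires at least 4 points")
    if np.any(np.diff(t) <= 0):
        raise DataError("times must be strictly increasing")
    var = y.var(ddof=1)
    if var == 0:
        raise DataError("zero variance: constant series has no spectrum")

    span = t[-1] - t[0]
    df = 1.0 / (params.oversampling * span)
    fmin, fmax = 1.0 / params.max_period, 1.0 / params.min_period
    nf = int(np.floor((fmax - fmin) / df)) + 1
    freqs = fmin + df * np.arange(nf)

    yc = y - y.mean()
    omega = 2.0 * np.pi * freqs[:, None]  # (nf, 1)
    wt = omega * t[None, :]               # (nf, n)
    # Scargle's offset makes the cos/sin basis orthogonal at each frequency
    tau_arg = 0.5 * np.arctan2(np.sin(2 * wt).sum(axis=1), np.cos(2 * wt).sum(axis=1))
    arg = wt - tau_arg[:, None]
    c, s = np.cos(arg), np.sin(arg)
    cc = (c * c).sum(axis=1)
    ss = (s * s).sum(axis=1)
    yccos = (yc[None, :] * c).sum(axis=1)
    ycsin = (yc[None, :] * s).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        power = (np.where(cc > 0, yccos**2 / cc, 0.0)
                 + np.where(ss > 0, ycsin**2 / ss, 0.0)) / (2.0 * var)

    ipeak = int(np.argmax(power))
    peak_power = float(power[ipeak])
    # P(max of M unit-exponential powers > z), numerically stable for large z
    with np.errstate(over="ignore"):
        log_cdf = nf * np.log1p(-min(np.exp(-peak_power), 1.0 - 1e-16))
    p_value = float(min(1.0, max(0.0, -np.expm1(log_cdf))))
    return PeriodogramResult(
        periods=1.0 / freqs,
        power=power,
        peak_period=float(1.0 / freqs[ipeak]),
        peak_power=peak_power,
        p_value=p_value,
        params=params,
    )


# ---------------------------------------------------------------------------
# presence windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PresenceWindow:
    start: float
    end: float
    n_samples: int


def presence_windows(times, values, epsilon: float,
                     merge_gap_days: float) -> list[PresenceWindow]:
    """Maximal groups of qualifying samples separated by short gaps.

    A window is a maximal set of samples with value >= epsilon in which
    successive qualifying samples are at most ``merge_gap_days`` apart.
    Below-epsilon samples in between do not split a window (a brief observed
    absence is merged), while a long stretch without presence — sampled or
    not — does.  ``n_samples`` counts only the qualifying samples.  Zero
    windows is a valid result.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DataError("times must be strictly increasing")
    windows: list[list[float]] = []  # [start, end, n]
    for i in np.flatnonzero(v >= epsilon):
        if windows and t[i] - windows[-1][1] <= merge_gap_days:
            windows[-1][1] = t[i]
            windows[-1][2] += 1
        else:
            windows.append([t[i], t[i], 1])
    return [PresenceWindow(start=a, end=b, n_samples=int(n)) for a, b, n in windows]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RhythmRules:
    """Decision thresholds for the archetype classifier.

    ``epsilon`` is the presence threshold on RA among eukaryotes (default
    0.001 = 0.1% of reads); ``merge_gap_days`` merges presence runs broken by
    a few below-threshold samples; ``annual_band`` is the accepted peak
    period range (days) for the periodogram route; ``recurrence_tol_days``
    and ``min_recurrence_years`` govern the day-of-year clustering route,
    with ``min_band_window_fraction`` requiring that most windows (not just
    three) fall inside the same seasonal band.
    """

    epsilon: float = 0.001
    merge_gap_days: float = 21.0
    annual_band: tuple = (300.0, 430.0)
    recurrence_tol_days: float = 45.0
    min_recurrence_years: int = 3
    min_band_window_fraction: float = 0.75
    alpha: float = 0.01


@dataclass(frozen=True)
class RhythmClass:
    label: str  # rhythmic | chaotic | ephemeral
    n_windows: int
    peak_period: float | None
    p_value: float | None
    epsilon: float


def _circular_doy_distance(a: np.ndarray, b: float) -> np.ndarray:
    d = np.abs(a - b) % DAYS_PER_YEAR
    return np.minimum(d, DAYS_PER_YEAR - d)


def _annual_recurrence(window_mid_days: np.ndarray, rules: RhythmRules) -> bool:
    """True if window midpoints cluster at a common day-of-year.

    Requires some +-tol band around a window midpoint to contain windows from
    >= min_recurrence_years distinct years AND >= min_band_window_fraction of
    all windows.
    """
    if len(window_mid_days) < rules.min_recurrence_years:
        return False
    doy = window_mid_days % DAYS_PER_YEAR
    years = np.floor(window_mid_days / DAYS_PER_YEAR).astype(int)
    n = len(window_mid_days)
    for centre in doy:
        inside = _circular_doy_distance(doy, centre) <= rules.recurrence_tol_days
        if (len(np.unique(years[inside])) >= rules.min_recurrence_years
                and inside.sum() / n >= rules.min_band_window_fraction):
            return True
    return False


def classify_rhythm(times, values, periodogram: PeriodogramResult | None = None,
                    rules: RhythmRules | None = None) -> RhythmClass:
    """Assign rhythmic / chaotic / ephemeral to one ASV trajectory.

    ``times`` are days since the series start (day-of-year arithmetic uses
    day 0 = series start; recurrence compares positions modulo the year, so
    the absolute calendar origin is irrelevant).  A trajectory with zero
    presence windows cannot be classified and raises an error.
    """
    rules = rules or RhythmRules()
    windows = presence_windows(times, values, rules.epsilon, rules.merge_gap_days)
    if len(windows) == 0:
        raise DataError("absent taxon: no presence windows above epsilon")

    peak_period: float | None = None
    p_value: float | None = None
    ls_rhythmic = False
    try:
        pg = periodogram or lomb_scargle(times, values)
        peak_period, p_value = pg.peak_period, pg.p_value
        lo, hi = rules.annual_band
        ls_rhythmic = p_value <= rules.alpha and lo <= peak_period <= hi
    except DataError:
        pass  # too short or constant: fall back to the recurrence route

    if len(windows) == 1:
        label = "ephemeral"
    else:
        mids = np.array([(w.start + w.end) / 2.0 for w in windows])
        label = "rhythmic" if (ls_rhythmic or _annual_recurrence(mids, rules)) else "chaotic"
    return RhythmClass(
        label=label,
        n_windows=len(windows),
        peak_period=peak_period,
        p_value=p_value,
        epsilon=rules.epsilon,
    )
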