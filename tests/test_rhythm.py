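import numpy as np
import pytest
from scipy.signal import lombscargle as scipy_lombscargle

from mycobloom import (DataError, PeriodogramParams, classify_rhythm,
                       lomb_scargle, presence_windows)
from mycobloom.rhythm import RhythmRules


def lstsq_power(times, values, periods):
    """Independent oracle: variance explained by the best-fit sinusoid."""
    yc = values - values.mean()
    var = values.var(ddof=1)
    out = np.empty(len(periods))
    for i, period in enumerate(periods):
        w = 2 * np.pi / period
        X = np.column_stack([np.cos(w * times), np.sin(w * times)])
        beta, *_ = np.linalg.lstsq(X, yc, rcond=None)
        out[i] = (yc @ yc - ((yc - X @ beta) ** 2).sum()) / (2 * var)
    return out


class TestLombScargle:
    def test_pure_annual_sinusoid_peak(self):
        # quasi-regular sampling: perfectly even spacing would alias the
        # annual line to exact replicas above the Nyquist frequency inside
        # the default 2-900 d scan; jitter (the field reality) removes them
        rng = np.random.default_rng(0)
        t = np.linspace(0, 5 * 365.0, 120) + rng.uniform(-2, 2, 120)
        t.sort()
        y = 0.05 * np.sin(2 * np.pi * t / 365.0)
        res = lomb_scargle(t, y)
        assert abs(res.peak_period - 365.0) / 365.0 < 0.02
        assert res.p_value < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_least_squares_fit(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 120)
        t = np.sort(rng.uniform(0, 1800, n))
        t += np.arange(n) * 1e-6  # enforce strict increase
        y = rng.normal(0, 1, n) + 0.5 * np.sin(2 * np.pi * t / 400)
        res = lomb_scargle(t, y)
        oracle = lstsq_power(t, y, res.periods)
        assert np.max(np.abs(res.power - oracle)) < 1e-8

    def test_matches_scipy_classical_periodogram(self):
        rng = np.random.default_rng(9)
        t = np.sort(rng.uniform(0, 1500, 80))
        y = rng.normal(0, 1, 80)
        res = lomb_scargle(t, y)
        scipy_pow = scipy_lombscargle(t, y - y.mean(), 2 * np.pi / res.periods)
        assert np.allclose(res.power, scipy_pow / y.var(ddof=1), atol=1e-9)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        t = np.sort(rng.uniform(0, 1000, 60))
        y = rng.normal(0, 1, 60)
        base = lomb_scargle(t, y)
        shifted = lomb_scargle(t, 3.5 * y + 11.0)
        assert np.allclose(base.power, shifted.power, atol=1e-9)
        assert base.peak_period == shifted.peak_period

    def test_white_noise_rarely_significant(self):
        """Monte-Carlo null: the peak p-value is calibrated at alpha=0.01."""
        rng = np.random.default_rng(123)
        n_sig = 0
        for _ in range(200):
            t = np.sort(rng.uniform(0, 1825, 120))
            y = rng.normal(0, 1, 120)
            if lomb_scargle(t, y).p_value <= 0.01:
                n_sig += 1
        assert 200 - n_sig >= 190  # p > 0.01 in at least 95% of replicates

    def test_constant_series_rejected(self):
        with pytest.raises(DataError, match="zero variance"):
            lomb_scargle([0, 10, 20, 30], [1.0, 1.0, 1.0, 1.0])

    def test_short_series_rejected(self):
        with pytest.raises(DataError, match="4 points"):
            lomb_scargle([0, 10, 20], [0.0, 1.0, 0.5])

    def test_grid_respects_period_bounds(self):
        t = np.linspace(0, 1800, 100)
        y = np.sin(t / 50.0)
        res = lomb_scargle(t, y, PeriodogramParams(min_period=2, max_period=900))
        assert res.periods.max() <= 900 + 1e-9
        assert res.periods.min() >= 2 - 1e-9


class TestPresenceWindows:
    def test_simple_window(self):
        w = presence_windows([0, 3, 6, 9], [0, 0.01, 0.02, 0], epsilon=0.005,
                             merge_gap_days=21)
        assert len(w) == 1
        assert w[0].n_samples == 2
        assert (w[0].start, w[0].end) == (3, 6)

    def test_epsilon_above_max_gives_none(self):
        assert presence_windows([0, 3], [0.1, 0.2], epsilon=0.5,
                                merge_gap_days=21) == []

    def test_merge_across_short_gap(self):
        t = [0, 3, 30, 33]
        v = [0.1, 0.1, 0.1, 0.1]
        merged = presence_windows(t, v, 0.05, merge_gap_days=27)
        split = presence_windows(t, v, 0.05, merge_gap_days=21)
        assert len(merged) == 1 and merged[0].n_samples == 4
        assert len(split) == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_linear_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        t = np.cumsum(rng.uniform(1, 20, n))
        v = np.where(rng.random(n) < 0.25, rng.uniform(0.01, 0.2, n), 0.0)
        eps, gap = 0.005, 25.0
        windows = presence_windows(t, v, eps, gap)
        # oracle: direct scan
        expected = []
        for i in range(n):
            if v[i] >= eps:
                if expected and t[i] - expected[-1][1] <= gap:
                    expected[-1][1] = t[i]
                    expected[-1][2] += 1
                else:
                    expected.append([t[i], t[i], 1])
        assert [(w.start, w.end, w.n_samples) for w in windows] == \
               [tuple(e) for e in expected]


def annual_series(rng, years=5, peak_doy=60, jitter_sd=10, amp=0.1, sd=6.0):
    t = np.sort(rng.uniform(0, years * 365.25, 140))
    y = np.zeros_like(t)
    for k in range(years + 1):
        centre = k * 365.25 + peak_doy + rng.normal(0, jitter_sd)
        y += amp * np.exp(-0.5 * ((t - centre) / sd) ** 2)
    return t, y


class TestClassifyRhythm:
    def test_annual_bloom_is_rhythmic(self):
        rng = np.random.default_rng(21)
        t, y = annual_series(rng)
        assert classify_rhythm(t, y).label == "rhythmic"

    def test_single_window_is_ephemeral(self):
        t = np.arange(0, 1800, 14.0)
        y = 0.1 * np.exp(-0.5 * ((t - 700) / 8.0) ** 2)
        assert classify_rhythm(t, y).label == "ephemeral"

    def test_scattered_spikes_are_chaotic(self):
        rng = np.random.default_rng(17)
        t = np.arange(0, 1825, 7.0)
        y = np.zeros_like(t)
        for centre in rng.uniform(0, 1825, 5):  # uniform random spike times
            y += rng.uniform(0.05, 0.2) * np.exp(-0.5 * ((t - centre) / 4.0) ** 2)
        assert classify_rhythm(t, y).label == "chaotic"

    def test_absent_taxon_errors(self):
        t = np.arange(0, 100, 10.0)
        with pytest.raises(DataError, match="absent"):
            classify_rhythm(t, np.zeros_like(t))

    def test_rules_are_configurable(self):
        rng = np.random.default_rng(21)
        t, y = annual_series(rng)
        strict = RhythmRules(epsilon=0.5)  # nothing is ever present
        with pytest.raises(DataError, match="absent"):
            classify_rhythm(t, y, rules=strict)
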