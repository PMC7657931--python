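"""Lomb-Scargle and Morlet wavelet detectors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronomove.periodicity import (lomb_scargle, morlet_power, peak_pvalue,
                                    wavelet_significance)


def ols_power_oracle(t, y, period):
    """Independent least-squares sinusoid-fit oracle for normalized power.

    Fits a*cos + b*sin at the frequency to the centred series; normalized
    power is the explained sum of squares over twice the sample variance.
    """
    yc = y - y.mean()
    w = 2 * np.pi / period
    x = np.column_stack([np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(x, yc, rcond=None)
    ss_exp = yc @ yc - np.sum((yc - x @ beta) ** 2)
    return ss_exp / (2.0 * np.var(y, ddof=1))


def _uneven_series(rng, n):
    t = np.sort(rng.uniform(0, 24 * 7, n))
    t += np.arange(n) * 1e-4          # enforce strict increase
    y = (np.sin(2 * np.pi * t / 11.0) + rng.normal(0, 1.0, n))
    return t, y


class TestLombScargle:
    def test_matches_least_squares_oracle(self, rng):
        for _ in range(5):
            t, y = _uneven_series(rng, 200)
            res = lomb_scargle(t, y, 2, 36, oversampling=3)
            for k in rng.choice(len(res.periods), 10, replace=False):
                oracle = ols_power_oracle(t, y, res.periods[k])
                assert res.power[k] == pytest.approx(oracle, abs=1e-8)

    def test_even_sampling_reduces_to_classical_periodogram(self):
        rng = np.random.default_rng(3)
        n = 168
        y = rng.normal(0, 1, n)
        t = np.arange(n, dtype=float)
        yc = y - y.mean()
        # classical periodogram at exact Fourier frequencies
        for k in (7, 14, 21):          # periods 24, 12, 8 h
            f = k / n
            # grid starts exactly at 1/period_max, i.e. at the Fourier freq
            res = lomb_scargle(t, y, 1.0 / f - 1.0, 1.0 / f, oversampling=4)
            fft_power = np.abs(np.exp(-2j * np.pi * f * t) @ yc) ** 2 / n
            assert res.power[0] == pytest.approx(
                fft_power / np.var(y, ddof=1), abs=1e-10)

    def test_sinusoid_peak_recovered(self, rng):
        t = np.arange(168.0)
        y = np.cos(2 * np.pi * t / 24.0) + rng.normal(0, 0.1, 168)
        res = lomb_scargle(t, y, 18, 36)
        res = peak_pvalue(t, y, res, n_perm=199, rng=rng)
        assert res.peak_period == pytest.approx(24.0, abs=0.5)
        assert res.peak_pvalue < 0.01

    def test_noiseless_peak_within_one_grid_step(self):
        t = np.arange(7 * 24, dtype=float)
        for period in (6.0, 10.0, 14.0, 22.0, 30.0):
            y = np.sin(2 * np.pi * t / period)
            res = lomb_scargle(t, y, 2, 36, oversampling=4)
            grid = np.abs(np.diff(1.0 / res.periods)).max()
            err = abs(1.0 / res.peak_period - 1.0 / period)
            assert err <= grid

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            lomb_scargle(np.arange(50.0), np.ones(50), 2, 36)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            lomb_scargle(np.arange(5.0), np.arange(5.0), 2, 36)

    def test_full_variance_sinusoid_attains_half_n(self):
        n = 240
        t = np.arange(float(n))
        y = np.sin(2 * np.pi * t / 12.0)
        res = lomb_scargle(t, y, 10, 14, oversampling=8)
        assert res.peak_power == pytest.approx(n / 2, rel=0.02)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(shift=st.floats(-1e3, 1e3), offset=st.floats(-50, 50))
def test_lsp_invariant_to_time_shift_and_value_offset(shift, offset):
    rng = np.random.default_rng(8)
    t, y = _uneven_series(rng, 120)
    base = lomb_scargle(t, y, 2, 36)
    moved = lomb_scargle(t + shift, y + offset, 2, 36)
    np.testing.assert_allclose(moved.power, base.power, atol=1e-7)


class TestPeakPvalue:
    def test_strong_signal_attains_minimum_pvalue(self, rng):
        t = np.arange(168.0)
        y = np.sin(2 * np.pi * t / 12.0) + rng.normal(0, 0.05, 168)
        res = lomb_scargle(t, y, 2, 18)
        res = peak_pvalue(t, y, res, n_perm=199, rng=rng)
        assert res.peak_pvalue == pytest.approx(1.0 / 200.0)

    def test_pvalue_monotone_in_amplitude(self):
        t = np.arange(168.0)
        noise = np.random.default_rng(4).normal(0, 1.0, 168)
        pvals = []
        for amp in (0.0, 0.3, 0.6, 1.2, 2.5):
            y = amp * np.sin(2 * np.pi * t / 12.0) + noise
            res = lomb_scargle(t, y, 2, 18)
            res = peak_pvalue(t, y, res, n_perm=299,
                              rng=np.random.default_rng(0))
            pvals.append(res.peak_pvalue)
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_analytic_mode_agrees_in_order_of_magnitude(self, rng):
        t = np.arange(168.0)
        y = np.sin(2 * np.pi * t / 12.0) + rng.normal(0, 0.5, 168)
        res = lomb_scargle(t, y, 2, 18)
        perm = peak_pvalue(t, y, res, n_perm=999, rng=rng).peak_pvalue
        ana = peak_pvalue(t, y, res, method="analytic").peak_pvalue
        assert (perm < 0.01) == (ana < 0.01)

    def test_too_few_permutations_rejected(self, rng):
        t, y = _uneven_series(rng, 100)
        res = lomb_scargle(t, y, 2, 18)
        with pytest.raises(ValueError):
            peak_pvalue(t, y, res, n_perm=50, rng=rng)


class TestWavelet:
    def test_single_tone_ridge_at_24h(self):
        t = np.arange(24.0 * 30)
        y = np.sin(2 * np.pi * t / 24.0)
        spec = morlet_power(y, period_min_h=2, period_max_h=64)
        ridge = spec.periods_h[np.argmax(spec.power, axis=0)]
        inside = spec.inside_coi[np.argmax(spec.power, axis=0),
                                 np.arange(spec.power.shape[1])]
        assert np.median(ridge[inside]) == pytest.approx(24.0, rel=0.06)

    def test_changepoint_ridge_switches(self):
        """A 12 h tone switching to 24 h mid-series moves the ridge within
        +/- 2 days of the changepoint."""
        half = 24 * 30
        t = np.arange(2.0 * half)
        y = np.where(t < half, np.sin(2 * np.pi * t / 12.0),
                     np.sin(2 * np.pi * t / 24.0))
        spec = morlet_power(y, period_min_h=4, period_max_h=64)
        band12 = (spec.periods_h > 9) & (spec.periods_h < 15)
        band24 = (spec.periods_h > 18) & (spec.periods_h < 30)
        dominant24 = (spec.power[band24].max(axis=0)
                      > spec.power[band12].max(axis=0))
        switch = np.flatnonzero(dominant24)[0]
        assert abs(switch - half) < 48

    def test_noise_significance_fraction_near_alpha(self):
        rng = np.random.default_rng(12)
        y = rng.normal(0, 1, 1500)
        spec = morlet_power(y, period_min_h=2, period_max_h=64)
        mask = wavelet_significance(spec, n_boot=60, seed=5)
        frac = mask[spec.inside_coi].mean()
        assert 0.01 < frac < 0.10

    def test_significance_mask_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        y = np.sin(2 * np.pi * np.arange(500.0) / 24) + rng.normal(0, 1, 500)
        spec = morlet_power(y, period_min_h=2, period_max_h=64)
        m1 = wavelet_significance(spec, n_boot=30, seed=7).copy()
        m2 = wavelet_significance(spec, n_boot=30, seed=7)
        assert (m1 == m2).all()

    def test_strong_tone_ridge_significant(self):
        t = np.arange(24.0 * 20)
        rng = np.random.default_rng(0)
        y = 3 * np.sin(2 * np.pi * t / 24.0) + rng.normal(0, 0.5, len(t))
        spec = morlet_power(y, period_min_h=4, period_max_h=64)
        mask = wavelet_significance(spec, n_boot=40, seed=1)
        k = np.argmin(np.abs(spec.periods_h - 24.0))
        inside = spec.inside_coi[k]
        assert mask[k][inside].mean() > 0.9

    def test_gappy_series_interpolated_or_rejected(self):
        t = np.arange(500.0)
        y = np.sin(2 * np.pi * t / 24)
        keep = np.ones(500, bool)
        keep[[50, 51, 200]] = False
        spec = morlet_power(y[keep], times_h=t[keep])
        assert len(spec.times_h) == 500
        keep[100:300] = False
        with pytest.raises(ValueError, match="gap"):
            morlet_power(y[keep], times_h=t[keep])


def test_writers_round_trip(tmp_path):
    import pandas as pd

    from chronomove.periodicity import write_periodogram, write_spectrum
    t = np.arange(300.0)
    y = np.sin(2 * np.pi * t / 24) + 0.1 * np.cos(2 * np.pi * t / 7)
    res = lomb_scargle(t, y, 2, 36)
    write_periodogram(res, tmp_path / "pgram.csv")
    back = pd.read_csv(tmp_path / "pgram.csv")
    np.testing.assert_allclose(back["power"], res.power, rtol=1e-6)
    spec = morlet_power(y, period_min_h=2, period_max_h=64)
    write_spectrum(spec, tmp_path / "grid.tsv", tmp_path / "spec.png")
    grid = pd.read_csv(tmp_path / "grid.tsv", sep="\t", index_col=0)
    assert grid.shape == spec.power.shape
    assert (tmp_path / "spec.png").exists()
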