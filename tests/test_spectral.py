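"""Decomposition identities, periodogram calibration, dominant-peak and
net-shift arithmetic, and the cross-correlogram lag convention."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rheokit.core import DataError, InsufficientDataError
from rheokit.spectral import (
    DominantPeaks,
    cross_correlate,
    decompose,
    dominant_peaks,
    net_shift,
    periodogram,
)

T = np.arange(300) * 0.1  # 30 s of 100-ms bins


class TestDecompose:
    def test_linear_ramp_has_no_periodicity(self):
        d = decompose(2.0 + 0.5 * T)
        v = d.valid
        assert np.max(np.abs(d.periodic[v])) < 1e-9
        assert np.nanmax(np.abs(d.noise[v])) < 1e-9
        assert np.allclose(d.trend[v], (2.0 + 0.5 * T)[v], atol=1e-9)

    def test_planted_1hz_sine_lands_in_periodic(self):
        obs = np.sin(2 * np.pi * 1.0 * T)
        d = decompose(obs)
        v = d.valid
        assert np.nanmax(np.abs(d.trend[v])) < 1e-6
        assert np.max(np.abs(d.periodic[v] - obs[v])) < 1e-6

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(0)
        obs = np.cumsum(rng.normal(size=300)) + np.sin(2 * np.pi * T)
        d = decompose(obs)
        v = d.valid
        recon = (d.trend + d.periodic + d.noise)[v]
        assert np.max(np.abs(recon - d.observed[v])) < 1e-9

    def test_periodic_component_has_zero_phase_mean(self):
        rng = np.random.default_rng(1)
        d = decompose(rng.normal(size=300))
        assert abs(d.periodic[:10].sum()) < 1e-9

    def test_missing_bins_are_bridged_and_flagged(self):
        obs = np.sin(2 * np.pi * T)
        obs[40] = np.nan
        d = decompose(obs)
        assert d.bridged[40]
        assert np.isfinite(d.observed[40])

    def test_too_short_series(self):
        with pytest.raises(InsufficientDataError):
            decompose(np.ones(25))


class TestPeriodogram:
    def test_pure_sine_line(self):
        x = np.sin(2 * np.pi * 0.5 * T)
        ps = periodogram(x - x.mean())
        top = ps.freqs[np.argmax(ps.density)]
        assert abs(top - 0.5) <= ps.df + 1e-12

    def test_parseval(self):
        rng = np.random.default_rng(2)
        for n in (300, 301):
            x = rng.normal(size=n)
            x = x - x.mean()
            ps = periodogram(x)
            assert ps.density.sum() * ps.df == pytest.approx(
                x.var(), rel=1e-6
            )

    def test_two_equal_lines(self):
        x = np.sin(2 * np.pi * 0.2 * T) + np.sin(2 * np.pi * 2.0 * T)
        ps = periodogram(x - x.mean())
        pk = dominant_peaks(ps, k=2)
        freqs = sorted(f for f, _ in pk.peaks)
        assert freqs[0] == pytest.approx(0.2, abs=ps.df)
        assert freqs[1] == pytest.approx(2.0, abs=ps.df)
        d0, d1 = (d for _, d in pk.peaks)
        assert d0 == pytest.approx(d1, rel=0.05)

    def test_white_noise_rarely_crosses_null_max_threshold(self):
        # periodogram ordinates of white noise are ~exponential; the max of
        # m ordinates exceeds mean * ln(m / alpha) with probability ~alpha
        rng = np.random.default_rng(3)
        crossings = 0
        B = 60
        for _ in range(B):
            x = rng.normal(size=300)
            ps = periodogram(x - x.mean())
            d = ps.density[1:]  # DC excluded (mean-removed anyway)
            thr = d.mean() * np.log(d.size / 0.05)
            crossings += d.max() > thr
        assert crossings / B <= 0.15

    def test_constant_series_flagged_zero(self):
        ps = periodogram(np.full(100, 3.3))
        assert ps.constant
        assert np.allclose(ps.density, 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        x -= x.mean()
        a = periodogram(x)
        b = periodogram(3.0 * x)
        assert np.allclose(b.density, 9.0 * a.density, rtol=1e-9)
        assert dominant_peaks(a).peaks[0][0] == dominant_peaks(b).peaks[0][0]


class TestPeaksAndShifts:
    def test_direct_arithmetic(self):
        a = DominantPeaks(peaks=[(0.1, 4.0), (0.3, 2.0), (1.0, 1.0)],
                          k_requested=3)
        b = DominantPeaks(peaks=[(0.2, 3.0), (0.5, 2.0), (1.5, 2.0)],
                          k_requested=3)
        ns = net_shift(b, a)
        assert ns.dfreq == pytest.approx(0.8)
        assert ns.ddensity == pytest.approx(0.0)
        assert ns.freq_label == "upshift"

    def test_identical_spectra_shift_nothing(self):
        a = DominantPeaks(peaks=[(0.1, 4.0)], k_requested=1)
        ns = net_shift(a, a)
        assert ns.dfreq == 0.0 and ns.ddensity == 0.0

    def test_ranking_is_by_density_not_frequency(self):
        rng = np.random.default_rng(5)
        d = rng.random(80)
        from rheokit.spectral import PowerSpectrum

        spec = PowerSpectrum(freqs=np.linspace(0, 5, 80), density=d,
                             n=160, fs=10.0)
        pk = dominant_peaks(spec, k=3)
        # brute-force oracle: enumerate all strict local maxima, sort
        locs = [i for i in range(1, 79)
                if d[i] > d[i - 1] and d[i] > d[i + 1]]
        expect = sorted(locs, key=lambda i: d[i], reverse=True)[:3]
        assert [f for f, _ in pk.peaks] == [spec.freqs[i] for i in expect]

    def test_fewer_maxima_than_requested_is_flagged(self):
        from rheokit.spectral import PowerSpectrum

        d = np.array([0.0, 1.0, 0.0, 0.0])
        spec = PowerSpectrum(freqs=np.arange(4.0), density=d, n=8, fs=10.0)
        pk = dominant_peaks(spec, k=3)
        assert len(pk.peaks) == 1 and pk.fewer_than_requested


class TestCrossCorrelogram:
    def test_planted_shift_convention(self):
        rng = np.random.default_rng(6)
        lin = rng.normal(size=240)
        ang = np.empty(240)
        ang[3:] = lin[:-3]  # the angular change happens 3 bins later
        ang[:3] = rng.normal(size=3)
        cc = cross_correlate(lin - lin.mean(), ang - ang.mean(), max_lag=10)
        assert cc.strongest[0] == 3
        assert cc.strongest[1] == pytest.approx(1.0, abs=1e-9)
        assert cc.significant

    def test_swap_symmetry(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=200)
        b = 0.3 * np.roll(a, 2) + rng.normal(size=200)
        f = cross_correlate(a, b, max_lag=12)
        g = cross_correlate(b, a, max_lag=12)
        assert np.allclose(f.r, g.r[::-1], atol=1e-12)

    def test_white_noise_mostly_inside_ci(self):
        rng = np.random.default_rng(8)
        quiet = 0
        B = 40
        for _ in range(B):
            a = rng.normal(size=300)
            b = rng.normal(size=300)
            cc = cross_correlate(a, b, max_lag=5)
            if np.nanmax(np.abs(cc.r)) <= cc.ci * 1.5:
                quiet += 1
        assert quiet / B >= 0.9

    def test_degenerate_series_rejected(self):
        with pytest.raises(DataError):
            cross_correlate(np.zeros(100), np.arange(100.0), max_lag=5)
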