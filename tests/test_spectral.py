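"""Spectral estimators: normalization, taper rules, Parseval, wavelets."""

import numpy as np
import pytest
from scipy.signal import windows

import ephystream as es
from ephystream import spectral, synthdata
from ephystream.errors import EngineError, ParameterError
from ephystream.spectral import PaddingSpec, taper_count, zero_pad


def _harmonic(freq, amplitude=1.0, n_trials=1, n_samples=1000, fs=1000.0,
              n_channels=1):
    spec = synthdata.GeneratorSpec(n_trials=n_trials, n_samples=n_samples,
                                   n_channels=n_channels, samplerate=fs, seed=4)
    return synthdata.harmonic(spec, freq=freq, amplitude=amplitude)


class TestTaperCount:
    @pytest.mark.parametrize(
        "tapsmofrq,duration,expected",
        [(2.0, 1.0, 3), (4.0, 0.25, 1), (3.0, 1.0, 5), (10.0, 0.5, 9),
         (1.0, 2.0, 3)],
    )
    def test_shannon_minus_one_rule(self, tapsmofrq, duration, expected):
        assert taper_count(tapsmofrq, duration) == expected

    def test_too_small_smoothing_suggests_minimum(self):
        with pytest.raises(ParameterError, match="1"):
            taper_count(0.5, 1.0)

    def test_dpss_tapers_orthonormal_with_decreasing_concentration(self):
        n, nw, k = 1000, 4.0, 7
        tapers = windows.dpss(n, nw, Kmax=k, norm=2, return_ratios=False)
        gram = tapers @ tapers.T
        assert np.max(np.abs(gram - np.eye(k))) < 1e-8
        _, ratios = windows.dpss(n, nw, Kmax=k, norm=2, return_ratios=True)
        assert np.all(np.diff(ratios) < 0)


class TestMtmfft:
    def test_boxcar_sinusoid_power_is_half_amplitude_squared(self):
        d = _harmonic(10.0, amplitude=2.0)
        out = spectral.mtmfft(d, taper="boxcar")
        p = out.trial(0)[0, 0, :, 0]
        i10 = int(np.argmin(np.abs(out.freqs - 10.0)))
        assert p[i10] == pytest.approx(2.0, rel=1e-6)
        others = np.delete(p, i10)
        assert np.max(others) < 1e-10

    def test_parseval_boxcar_no_padding(self, small_noise):
        out = spectral.mtmfft(small_noise, taper="boxcar")
        for i in range(small_noise.n_trials):
            x = np.asarray(small_noise.trial(i), dtype=np.float64)
            p = np.asarray(out.trial(i)[0, 0], dtype=np.float64)
            msq = (x**2).mean(axis=0)
            np.testing.assert_allclose(p.sum(axis=0), msq, rtol=1e-6)

    def test_fourier_output_reproduces_power(self, small_noise):
        pw = spectral.mtmfft(small_noise, taper="dpss", tapsmofrq=3.0)
        fo = spectral.mtmfft(small_noise, taper="dpss", tapsmofrq=3.0,
                             output="fourier")
        for i in range(small_noise.n_trials):
            via_fourier = (np.abs(fo.trial(i).astype(np.complex128)) ** 2).mean(
                axis=1
            )
            np.testing.assert_allclose(
                via_fourier, pw.trial(i)[:, 0], rtol=1e-4, atol=1e-7
            )

    def test_multitaper_variance_reduction(self):
        # spectrum variance across white-noise realizations drops ~1/K
        spec = synthdata.GeneratorSpec(n_trials=200, n_samples=1000,
                                       n_channels=1, seed=17)
        noise = synthdata.white_noise(spec)
        multi = spectral.mtmfft(noise, taper="dpss", tapsmofrq=3.0)  # K = 5
        single = spectral.mtmfft(noise, taper="boxcar")
        pm = np.asarray(multi.data[...])[:, 0, 50:450, 0]
        ps = np.asarray(single.data[...])[:, 0, 50:450, 0]
        ratio = pm.var(axis=0).mean() / ps.var(axis=0).mean()
        assert 1 / 5 * 0.6 < ratio < 1 / 5 * 1.6

    def test_foilim_crops_grid(self, small_noise):
        out = spectral.mtmfft(small_noise, taper="hann", foilim=[10, 90])
        assert out.freqs[0] >= 10 and out.freqs[-1] <= 90
        with pytest.raises(ParameterError):
            spectral.mtmfft(small_noise, taper="hann", foilim=[10, 900])

    def test_power_nonnegative(self, small_noise):
        out = spectral.mtmfft(small_noise, taper="dpss", tapsmofrq=2.0)
        assert np.all(np.asarray(out.data[...]) >= 0)


class TestPadding:
    def test_nextpow2(self):
        x = np.zeros((1000, 1), np.float32)
        assert zero_pad(x, "nextpow2", 1000.0).shape[0] == 1024

    def test_absolute_densifies_grid(self):
        d = _harmonic(10.0)
        out = spectral.mtmfft(d, taper="boxcar", pad=PaddingSpec("absolute", 2.0))
        assert np.allclose(np.diff(out.freqs), 0.5)

    def test_absolute_shorter_than_trial_rejected(self):
        d = _harmonic(10.0)
        with pytest.raises((ParameterError, EngineError)):
            spectral.mtmfft(d, taper="boxcar", pad=PaddingSpec("absolute", 0.5))

    def test_sinusoid_peak_power_invariant_to_padding(self):
        d = _harmonic(10.0, amplitude=2.0)
        plain = spectral.mtmfft(d, taper="boxcar")
        padded = spectral.mtmfft(d, taper="boxcar",
                                 pad=PaddingSpec("absolute", 2.0))
        p0 = plain.trial(0)[0, 0, :, 0].max()
        p1 = padded.trial(0)[0, 0, :, 0].max()
        assert abs(p1 / p0 - 1) < 0.01


class TestStft:
    def test_window_count(self):
        d = _harmonic(10.0)  # 1 s trial
        out = spectral.stft(d, 0.25, overlap=0.5)
        assert out.trial_shape(0)[0] == 7

    def test_stationary_power_constant_over_time(self):
        d = _harmonic(40.0, n_samples=2000)
        out = spectral.stft(d, 0.25, overlap=0.5)
        i40 = int(np.argmin(np.abs(out.freqs - 40.0)))
        series = out.trial(0)[:, 0, i40, 0]
        assert series.std() / series.mean() < 0.01

    def test_transient_localized_in_time(self):
        x = np.zeros((2000, 1), np.float32)
        t = np.arange(1000) / 1000.0
        x[1000:, 0] = np.sin(2 * np.pi * 50 * t)
        d = es.AnalogData.from_array(x, 1000.0)
        out = spectral.stft(d, 0.25, overlap=0.5)
        i50 = int(np.argmin(np.abs(out.freqs - 50.0)))
        tv = out.time_vector
        early = out.trial(0)[tv < 0.8, 0, i50, 0]
        late = out.trial(0)[tv > 1.2, 0, i50, 0]
        assert early.max() < 0.01 * late.max()

    def test_window_longer_than_trial_rejected(self):
        d = _harmonic(10.0)
        with pytest.raises((ParameterError, EngineError)):
            spectral.stft(d, 2.0)

    def test_single_hann_window_equals_mtmfft(self):
        d = _harmonic(10.0)
        st = spectral.stft(d, 1.0, overlap=0.0, taper="hann")
        mt = spectral.mtmfft(d, taper="hann")
        np.testing.assert_allclose(
            np.asarray(st.data[...]), np.asarray(mt.data[...]), rtol=1e-6
        )


class TestWelch:
    def test_single_window_equals_periodogram(self, small_noise):
        w = spectral.welch(small_noise, 0.5, overlap=0.0, taper="hann")
        mt = spectral.mtmfft(small_noise, taper="hann")
        # same estimator on the same segment when the window spans the trial
        w_full = spectral.welch(small_noise, 0.5, overlap=0.0)
        assert w.shape == w_full.shape
        d1 = _harmonic(10.0)
        w1 = spectral.welch(d1, 1.0, overlap=0.0, taper="hann")
        m1 = spectral.mtmfft(d1, taper="hann")
        np.testing.assert_allclose(np.asarray(w1.data[...]),
                                   np.asarray(m1.data[...]), rtol=1e-6)

    def test_averaging_reduces_variance(self):
        spec = synthdata.GeneratorSpec(n_trials=500, n_samples=1024,
                                       n_channels=1, seed=23)
        noise = synthdata.white_noise(spec)
        w8 = spectral.welch(noise, 0.128, overlap=0.0)
        w1 = spectral.welch(noise, 1.024, overlap=0.0)
        v8 = np.asarray(w8.data[...])[:, 0, 20:40, 0].var(axis=0).mean()
        # compare at matched frequencies (different grids)
        f_lo = w8.freqs[20:40]
        idx = np.searchsorted(w1.freqs, f_lo)
        v1 = np.asarray(w1.data[...])[:, 0, idx, 0].var(axis=0).mean()
        # 8 windows halve the bin count, each window holds 1/8 of the data:
        # per-bin variance ratio ~ (1/8) * (bin-width factor 8)**2 -> compare
        # fractional fluctuation instead, which is bin-width independent
        m8 = np.asarray(w8.data[...])[:, 0, 20:40, 0].mean()
        m1 = np.asarray(w1.data[...])[:, 0, idx, 0].mean()
        rel8 = v8 / m8**2
        rel1 = v1 / m1**2
        assert 1 / 8 * 0.7 < rel8 / rel1 < 1 / 8 * 1.3

    def test_white_noise_total_power_is_variance(self):
        spec = synthdata.GeneratorSpec(n_trials=20, n_samples=2000,
                                       n_channels=1, seed=29)
        noise = synthdata.white_noise(spec)
        w = spectral.welch(noise, 0.25, overlap=0.5)
        total = np.asarray(w.data[...])[:, 0, :, 0].sum(axis=1).mean()
        assert abs(total - 1.0) < 0.05


class TestWavelet:
    def test_peak_at_oscillation_frequency(self):
        d = _harmonic(20.0, n_samples=2000)
        freqs = np.arange(5, 60, 2.5)
        out = spectral.wavelet_cwt(d, freqs, width=7.0)
        power = out.trial(0)[500:1500, 0]  # interior times
        peak_freqs = freqs[np.argmax(power[:, :, 0], axis=1)]
        assert np.all(np.abs(peak_freqs - 20.0) <= 2.5)

    def test_constant_signal_has_no_power(self):
        # interior times where the wavelet support fits fully inside the trial
        d = es.AnalogData.from_array(np.full((1000, 1), 3.0, np.float32), 1000.0)
        out = spectral.wavelet_cwt(d, [20.0, 40.0, 80.0], width=7.0)
        assert np.max(out.trial(0)[300:700]) < 1e-6

    def test_bandwidth_shrinks_with_width(self):
        d = _harmonic(40.0, n_samples=4000)
        freqs = np.arange(20, 60, 0.5)

        def halfwidth(width):
            out = spectral.wavelet_cwt(d, freqs, width=width)
            prof = out.trial(0)[1000:3000, 0, :, 0].mean(axis=0)
            above = freqs[prof >= prof.max() / 2]
            return above[-1] - above[0]

        hw = [halfwidth(w) for w in (5.0, 7.0, 12.0)]
        assert hw[0] > hw[1] > hw[2]

    def test_frequency_above_nyquist_rejected(self):
        d = _harmonic(20.0)
        with pytest.raises(ParameterError):
            spectral.wavelet_cwt(d, [600.0])


class TestSuperlet:
    def test_order_one_equals_cwt(self):
        d = _harmonic(40.0)
        freqs = [20.0, 40.0, 60.0]
        cw = spectral.wavelet_cwt(d, freqs, width=3.0)
        sl = spectral.superlet(d, freqs, base_cycles=3.0, order_max=1)
        np.testing.assert_allclose(
            np.asarray(sl.data[...]), np.asarray(cw.data[...]), rtol=1e-6,
            atol=1e-12,
        )

    def test_spectral_dip_deepens_with_order(self):
        # two close tones: the valley between them deepens as order grows
        spec = synthdata.GeneratorSpec(n_trials=1, n_samples=4000, n_channels=1,
                                       samplerate=1000.0, seed=4)
        a = synthdata.harmonic(spec, freq=40.0)
        b = synthdata.harmonic(spec, freq=48.0)
        d = a + b
        freqs = np.array([40.0, 44.0, 48.0])

        def valley_ratio(order):
            out = spectral.superlet(d, freqs, base_cycles=3.0, order_max=order,
                                    adaptive=False)
            prof = out.trial(0)[1000:3000, 0, :, 0].mean(axis=0)
            return prof[1] / max(prof[0], prof[2])

        r = [valley_ratio(o) for o in (1, 5, 10)]
        assert r[0] > r[1] > r[2]

    def test_burst_time_resolution_not_degraded_by_order(self):
        x = np.zeros((2000, 1), np.float32)
        t = np.arange(100) / 1000.0
        x[950:1050, 0] = np.sin(2 * np.pi * 60 * t)  # 100 ms burst
        d = es.AnalogData.from_array(x, 1000.0)

        def fwhm(order):
            out = spectral.superlet(d, [60.0], base_cycles=3.0, order_max=order,
                                    adaptive=False)
            prof = out.trial(0)[:, 0, 0, 0]
            above = np.flatnonzero(prof >= prof.max() / 2)
            return above[-1] - above[0]

        widths = [fwhm(o) for o in (1, 3, 6)]
        assert widths[0] >= widths[1] >= widths[2]

    def test_adaptive_order_interpolation_monotone(self):
        d = _harmonic(30.0, n_samples=1500)
        freqs = np.linspace(10, 100, 10)
        out = spectral.superlet(d, freqs, base_cycles=3.0, order_max=5,
                                adaptive=True)
        assert np.all(np.asarray(out.data[...]) >= 0)
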