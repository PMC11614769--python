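"""Connectivity: CSD symmetry, coherence, PPC, Wilson/Granger, xcorr."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ephystream as es
from ephystream import connectivity as conn
from ephystream import spectral, synthdata
from ephystream.errors import ParameterError


def _var2_spectrum(fs=200.0, nf=257, coupling=0.25):
    """Analytic spectral matrix of a bivariate VAR(2), x -> y coupling only."""
    A1 = np.array([[0.55, 0.0], [coupling, 0.55]])
    A2 = np.array([[-0.8, 0.0], [0.0, -0.8]])
    Sigma = np.eye(2)
    freqs = np.linspace(0, fs / 2, nf)
    S = np.empty((nf, 2, 2), complex)
    H = np.empty((nf, 2, 2), complex)
    for k, f in enumerate(freqs):
        z = np.exp(-2j * np.pi * f / fs)
        Ainv = np.eye(2) - A1 * z - A2 * z**2
        H[k] = np.linalg.inv(Ainv)
        S[k] = H[k] @ Sigma @ H[k].conj().T
    return S, H, Sigma, freqs


@pytest.fixture(scope="module")
def common_signal_data():
    """x = s + n1, y = s + n2 with Var(s) = Var(n): analytic coherence 0.5."""
    spec_s = synthdata.GeneratorSpec(n_trials=400, n_samples=512, n_channels=1,
                                     seed=101)
    spec_n = synthdata.GeneratorSpec(n_trials=400, n_samples=512, n_channels=2,
                                     seed=202)
    s = synthdata.white_noise(spec_s)
    n = synthdata.white_noise(spec_n)
    trials = [
        np.hstack([st_[:, :1] + nt[:, :1], st_[:, :1] + nt[:, 1:]])
        for st_, nt in zip(s.trials, n.trials)
    ]
    data = es.from_trial_source(trials, 1000.0)
    yield data
    data.close()


class TestCSD:
    def test_diagonal_equals_power(self, small_noise):
        spec = spectral.mtmfft(small_noise, taper="hann", output="fourier")
        S = conn.csd(spec)
        pw = spectral.mtmfft(small_noise, taper="hann")
        mean_power = np.asarray(pw.data[...])[:, 0].mean(axis=0)
        diag = np.real(np.einsum("fii->fi", np.asarray(S.data[0])))
        np.testing.assert_allclose(diag, mean_power, rtol=1e-4)
        assert np.all(diag >= 0)

    def test_duplicated_channel_gives_real_positive_cross(self):
        rng = np.random.default_rng(3)
        trials = []
        for _ in range(5):
            x = rng.standard_normal((256, 1)).astype(np.float32)
            trials.append(np.hstack([x, x]))
        d = es.from_trial_source(trials, 1000.0)
        S = np.asarray(conn.csd(d).data[0])
        np.testing.assert_array_equal(S[:, 0, 1], S[:, 0, 0])
        assert np.all(np.real(S[:, 0, 1]) > 0)
        np.testing.assert_allclose(np.imag(S[:, 0, 1]), 0.0, atol=1e-12)

    def test_hermitian_symmetry(self, small_noise):
        S = np.asarray(conn.csd(small_noise).data[0])
        np.testing.assert_allclose(S, np.conj(S.transpose(0, 2, 1)), atol=1e-12)

    def test_power_input_rejected(self, small_noise):
        pw = spectral.mtmfft(small_noise, taper="hann")
        with pytest.raises(ParameterError, match="fourier"):
            conn.csd(pw)


class TestCoherence:
    def test_identical_channels_exactly_one(self):
        rng = np.random.default_rng(7)
        trials = []
        for _ in range(6):
            x = rng.standard_normal((200, 1)).astype(np.float32)
            trials.append(np.hstack([x, x]))
        d = es.from_trial_source(trials, 1000.0)
        C = np.asarray(conn.coherence(d).data[0])
        assert np.all(C[:, 0, 1] == 1.0)
        assert np.all(np.einsum("fii->fi", C) == 1.0)

    def test_common_signal_coherence_half(self, common_signal_data):
        C = np.asarray(conn.coherence(common_signal_data).data[0])
        interior = C[5:-5, 0, 1]
        assert abs(interior.mean() - 0.5) < 0.05

    def test_independent_noise_bias_level(self):
        # E[C^2] ~ 1/N for independent channels with N trial observations
        spec = synthdata.GeneratorSpec(n_trials=100, n_samples=256,
                                       n_channels=2, seed=55)
        d = synthdata.white_noise(spec)
        C = np.asarray(conn.coherence(d, squared=True).data[0])
        mean_c2 = C[5:-5, 0, 1].mean()
        assert 0.5 / 100 < mean_c2 < 1.5 / 100

    def test_range_and_diagonal(self, small_noise):
        C = np.asarray(conn.coherence(small_noise).data[0])
        assert np.all((C >= 0) & (C <= 1))
        np.testing.assert_allclose(np.einsum("fii->fi", C), 1.0)


class TestPPC:
    def test_identical_phases_give_one(self):
        rng = np.random.default_rng(9)
        trials = []
        x = rng.standard_normal((256, 1)).astype(np.float32)
        for _ in range(8):
            trials.append(np.hstack([x, x]))
        d = es.from_trial_source(trials, 1000.0)
        P = np.asarray(conn.ppc(d).data[0])
        np.testing.assert_allclose(P[1:-1, 0, 1], 1.0, atol=1e-6)

    def test_two_trials_closed_form(self):
        spec = synthdata.GeneratorSpec(n_trials=2, n_samples=256, n_channels=2,
                                       seed=3)
        d = synthdata.white_noise(spec)
        P = np.asarray(conn.ppc(d).data[0])
        fo = spectral.mtmfft(d, taper="hann", output="fourier")
        X0 = np.asarray(fo.trial(0)[0, 0], dtype=np.complex128)
        X1 = np.asarray(fo.trial(1)[0, 0], dtype=np.complex128)
        delta = np.angle(X0[:, 0] * np.conj(X0[:, 1])) - np.angle(
            X1[:, 0] * np.conj(X1[:, 1])
        )
        np.testing.assert_allclose(P[:, 0, 1], np.cos(delta), atol=1e-6)

    def test_null_mean_unbiased(self):
        # independent white channels: each frequency bin is an independent
        # draw of the PPC null; the across-bin mean must sit within 3 SE of 0
        spec = synthdata.GeneratorSpec(n_trials=20, n_samples=1024,
                                       n_channels=2, seed=77)
        d = synthdata.white_noise(spec)
        P = np.asarray(conn.ppc(d).data[0])[1:-1, 0, 1]
        se = P.std(ddof=1) / np.sqrt(P.size)
        assert abs(P.mean()) < 3 * se

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(min_value=3, max_value=12), st.integers(min_value=0,
                                                               max_value=10**6))
    def test_closed_form_matches_pairwise_sum(self, n, seed):
        """(|sum e^{i theta}|^2 - N) / (N (N-1)) == mean over distinct pairs
        of cos(theta_i - theta_j)."""
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 2 * np.pi, n)
        closed = (np.abs(np.exp(1j * theta).sum()) ** 2 - n) / (n * (n - 1))
        acc = [
            np.cos(theta[i] - theta[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
        assert closed == pytest.approx(np.mean(acc), abs=1e-12)

    def test_multitaper_input_rejected(self, small_noise):
        fo = spectral.mtmfft(small_noise, taper="dpss", tapsmofrq=3.0,
                             output="fourier")
        with pytest.raises(ParameterError, match="taper"):
            conn.ppc(fo)

    def test_single_trial_rejected(self):
        spec = synthdata.GeneratorSpec(n_trials=1, n_samples=128, n_channels=2,
                                       seed=5)
        d = synthdata.white_noise(spec)
        with pytest.raises(ParameterError, match="2 trials"):
            conn.ppc(d)


class TestWilson:
    def test_white_noise_factorization(self):
        nf = 65
        D = np.diag([2.0, 0.5])
        S = np.tile(D.astype(complex), (nf, 1, 1))
        fac = conn.wilson_factorize(S, tol=1e-10)
        assert fac.converged
        np.testing.assert_allclose(fac.Sigma, D, atol=1e-8)
        np.testing.assert_allclose(np.abs(fac.H), np.tile(np.eye(2), (nf, 1, 1)),
                                   atol=1e-8)

    def test_var_spectrum_reconstruction(self):
        S, _, _, _ = _var2_spectrum()
        fac = conn.wilson_factorize(S, tol=1e-9, max_iter=100)
        assert fac.converged
        assert fac.residual < 1e-6
        recon = fac.H @ fac.Sigma @ fac.H.conj().transpose(0, 2, 1)
        np.testing.assert_allclose(recon, S, atol=1e-6)

    def test_residual_within_ten_tol(self):
        S, _, _, _ = _var2_spectrum()
        tol = 1e-9
        fac = conn.wilson_factorize(S, tol=tol, max_iter=200)
        assert fac.converged
        assert fac.residual <= 10 * tol

    def test_rank_deficient_input_takes_regularization_path(self):
        nf = 33
        one = np.ones((2, 2), complex)  # duplicated channel: rank 1
        S = np.tile(one, (nf, 1, 1))
        with pytest.warns(RuntimeWarning, match="regularized"):
            fac = conn.wilson_factorize(S, tol=1e-8, max_iter=60)
        assert np.isfinite(fac.residual)


class TestGranger:
    def test_var_oracle_forward_peak_and_silent_reverse(self):
        S, H, Sigma, freqs = _var2_spectrum()
        G = conn._pairwise_granger_from_csd(S, tol=1e-9, max_iter=100)
        # parametric oracle from the true transfer function and noise cov
        s_yy = np.real(S[:, 1, 1])
        oracle = np.log(
            s_yy / (s_yy - (Sigma[0, 0] - Sigma[1, 0] ** 2 / Sigma[1, 1])
                    * np.abs(H[:, 1, 0]) ** 2)
        )
        fwd = G[:, 1, 0]  # x -> y stored at [target, source] = [1, 0]
        rev = G[:, 0, 1]
        assert abs(fwd.max() / oracle.max() - 1) < 0.10
        assert rev.max() < 0.10 * fwd.max()
        assert int(np.argmax(fwd)) == int(np.argmax(oracle))

    def test_independent_channels_near_zero(self):
        spec = synthdata.GeneratorSpec(n_trials=500, n_samples=512,
                                       n_channels=2, seed=91)
        d = synthdata.white_noise(spec)
        G = conn.granger(d)
        vals = np.asarray(G.data[0])
        assert np.all(vals[:, 0, 1] < 0.02)
        assert np.all(vals[:, 1, 0] < 0.02)
        assert np.all(np.einsum("fii->fi", vals) == 0)

    def test_invariant_to_channel_rescaling(self):
        S, _, _, _ = _var2_spectrum()
        a = 7.0
        D = np.diag([a, 1.0])
        S_scaled = np.einsum("ij,fjk,kl->fil", D, S, D)
        G = conn._pairwise_granger_from_csd(S, 1e-10, 200)
        Gs = conn._pairwise_granger_from_csd(S_scaled, 1e-10, 200)
        np.testing.assert_allclose(Gs, G, rtol=1e-3, atol=1e-9)

    def test_nonnegative_output(self):
        spec = synthdata.GeneratorSpec(n_trials=50, n_samples=256, n_channels=3,
                                       seed=13)
        d = synthdata.white_noise(spec)
        vals = np.asarray(conn.granger(d).data[0])
        assert np.all(vals >= 0)


class TestCrossCorrelation:
    def test_identical_channels_peak_one_at_zero_lag(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((400, 1)).astype(np.float32)
        d = es.AnalogData.from_array(np.hstack([x, x]), 1000.0)
        X = conn.cross_correlation(d, max_lag=0.02)
        r = np.asarray(X.data[0, :, 0, 1])
        mid = len(X.lags) // 2
        assert r[mid] == pytest.approx(1.0, abs=1e-6)
        assert np.argmax(r) == mid

    def test_delay_localizes_at_positive_lag(self):
        rng = np.random.default_rng(2)
        k = 7
        base = rng.standard_normal(600).astype(np.float32)
        delayed = np.roll(base, k)  # second channel lags the first by k
        d = es.AnalogData.from_array(np.column_stack([base, delayed]), 1000.0)
        X = conn.cross_correlation(d, max_lag=0.02)
        r = np.asarray(X.data[0, :, 0, 1])
        assert X.lags[np.argmax(r)] == pytest.approx(k / 1000.0)

    def test_independent_noise_within_null_envelope(self):
        spec = synthdata.GeneratorSpec(n_trials=30, n_samples=1000,
                                       n_channels=2, seed=41)
        d = synthdata.white_noise(spec)
        X = conn.cross_correlation(d, max_lag=0.05)
        r = np.asarray(X.data[0, :, 0, 1])
        # averaging over trials shrinks the null by sqrt(n_trials)
        bound = 4 / np.sqrt(1000 * 30)
        assert np.max(np.abs(r)) < bound

    def test_lag_longer_than_trial_rejected(self, small_noise):
        with pytest.raises(ParameterError, match="max_lag"):
            conn.cross_correlation(small_noise, max_lag=1.0)


class TestTrialOrderInvariance:
    def test_measures_invariant_under_trial_reordering(self, small_noise):
        perm = [3, 0, 5, 1, 4, 2]
        reordered = es.apply_selection(small_noise, es.Selection(trials=perm))
        for func in (conn.coherence, conn.ppc):
            a = np.asarray(func(small_noise).data[...])
            b = np.asarray(func(reordered).data[...])
            np.testing.assert_allclose(a, b, atol=1e-10)
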