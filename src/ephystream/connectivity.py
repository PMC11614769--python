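"""Channel-pair connectivity measures from trial spectra.

All frequency-domain measures start from the trial- and taper-averaged
cross-spectral density

    S_ij(f) = < X_i(f) conj(X_j(f)) >_{trials, tapers}

computed from complex (``output="fourier"``) spectra.  Passing an
:class:`~ephystream.datamodel.AnalogData` runs an implicit whole-trial
Fourier analysis (hann taper, next-power-of-two padding) first.

Measures
--------
``csd``                the cross-spectral density itself (complex, Hermitian).
``coherence``          ``|S_ij| / sqrt(S_ii S_jj)`` in [0, 1] (magnitude by
                       default; ``squared=True`` for the squared variant).
``ppc``                pairwise phase consistency, the bias-free phase-locking
                       estimator: mean over distinct trial pairs of
                       ``cos(theta_n - theta_m)`` of the trial-wise relative
                       phases, computed via the closed form
                       ``(|sum_n exp(i theta_n)|**2 - N) / (N (N - 1))``.
``wilson_factorize``   iterative Wilson spectral-matrix factorization
                       ``S = H Sigma H*`` (minimum-phase transfer function H,
                       innovation covariance Sigma).
``granger``            non-parametric pairwise Granger causality from the
                       factorization of each 2x2 channel submatrix:
                       ``G_{j->i}(f) = ln( S_ii / (S_ii - (Sigma_jj -
                       Sigma_ij**2 / Sigma_ii) |H_ij|**2) )``.
``cross_correlation``  trial-averaged Pearson cross-correlogram over lags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import engine
from .datamodel import AnalogData, CrossSpectralData, SpectralData, new_payload_path, _h5open
from .errors import EngineError, ParameterError, ValidationError

__all__ = [
    "SpectralFactorization",
    "csd",
    "coherence",
    "ppc",
    "wilson_factorize",
    "granger",
    "cross_correlation",
]


# --------------------------------------------------------------------------
# plumbing
# --------------------------------------------------------------------------

def _implicit_fourier(data: AnalogData, plan=None) -> SpectralData:
    from . import spectral

    return spectral.mtmfft(data, taper="hann", pad="nextpow2", output="fourier", plan=plan)


def _as_fourier(data, plan=None) -> SpectralData:
    if isinstance(data, AnalogData):
        return _implicit_fourier(data, plan)
    if isinstance(data, SpectralData):
        if not np.issubdtype(data.dtype, np.complexfloating):
            raise ParameterError(
                "connectivity requires complex spectra; rerun the spectral step "
                'with output="fourier"'
            )
        return data
    raise ParameterError(f"cannot derive spectra from {type(data).__name__}")


def _cross_container(
    arr: np.ndarray,
    samplerate: float,
    channels,
    measure: str,
    freqs=None,
    lags=None,
    log=None,
    op_name: str = "",
    **log_params,
) -> CrossSpectralData:
    """Wrap an in-memory (time, freq|lag, C, C) array in a disk container."""
    path = new_payload_path(measure)
    with _h5open(path, "w") as f:
        f.create_dataset("data", data=arr)
    out = CrossSpectralData(
        path,
        samplerate,
        channels,
        trialdefinition=[[0, arr.shape[0], 0]],
        freqs=freqs,
        lags=lags,
        time_vector=np.array([0.0]),
        measure=measure,
        trial_averaged=True,
        log=list(log) if log else None,
    )
    out.log_entry(op_name or measure, **log_params)
    return out


def _accumulate_csd(spec: SpectralData):
    """Stream trials, averaging X_i conj(X_j) over trials and tapers."""
    n_freq = len(spec.freqs)
    n_ch = len(spec.channels)
    acc = np.zeros((n_freq, n_ch, n_ch), dtype=np.complex128)
    count = 0
    for tr in spec.trials:
        # (time, taper, freq, channel); whole-trial spectra have one time bin
        X = tr.reshape(-1, n_freq, n_ch).astype(np.complex128)
        acc += np.einsum("kfi,kfj->fij", X, np.conj(X))
        count += X.shape[0]
    return acc / count, count


def csd(data, plan=None) -> CrossSpectralData:
    """Trial- and taper-averaged cross-spectral density matrix."""
    spec = _as_fourier(data, plan)
    S, n_obs = _accumulate_csd(spec)
    return _cross_container(
        S[None], spec.samplerate, spec.channels, "csd",
        freqs=spec.freqs, log=spec.log, n_observations=n_obs,
    )


def _csd_array(data, plan=None):
    """(S, freqs, channels, samplerate, log) from any accepted input."""
    if isinstance(data, CrossSpectralData):
        if data.measure != "csd":
            raise ParameterError(f"expected a CSD container, got measure={data.measure!r}")
        return (
            np.asarray(data.data[0], dtype=np.complex128),
            data.freqs,
            data.channels,
            data.samplerate,
            data.log,
        )
    spec = _as_fourier(data, plan)
    S, _ = _accumulate_csd(spec)
    return S, spec.freqs, spec.channels, spec.samplerate, spec.log


# --------------------------------------------------------------------------
# coherence and PPC
# --------------------------------------------------------------------------

def coherence(data, squared: bool = False, plan=None) -> CrossSpectralData:
    """Spectral coherence in [0, 1] from a trial-averaged CSD."""
    S, freqs, channels, fs, log = _csd_array(data, plan)
    auto = np.real(np.einsum("fii->fi", S))
    denom = auto[:, :, None] * auto[:, None, :]
    num = np.abs(S) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        c2 = num / denom
    bad = denom <= 0
    if np.any(bad):
        warnings.warn(
            "zero auto-spectrum encountered; coherence set to 0 there",
            RuntimeWarning,
            stacklevel=2,
        )
        c2 = np.where(bad, 0.0, c2)
    c2 = np.clip(c2, 0.0, 1.0)
    out = c2 if squared else np.sqrt(c2)
    return _cross_container(
        out[None], fs, channels, "coherence", freqs=freqs, log=log, squared=squared,
    )


def ppc(data, plan=None) -> CrossSpectralData:
    """Pairwise phase consistency across trials.

    Requires single-taper complex spectra (tapers carry distinct phase
    estimates of one trial and must not be pooled as if they were trials)
    and at least two trials.  Range: ``[-1/(N-1), 1]``; unbiased around 0
    for uniformly random relative phase.
    """
    spec = _as_fourier(data, plan)
    if spec.n_tapers != 1:
        raise ParameterError(
            "PPC requires single-taper spectra (got "
            f"{spec.n_tapers} tapers); use taper='hann' or another single taper"
        )
    n = spec.n_trials
    if n < 2:
        raise ParameterError("PPC requires at least 2 trials")
    n_freq = len(spec.freqs)
    n_ch = len(spec.channels)
    acc = np.zeros((n_freq, n_ch, n_ch), dtype=np.complex128)
    for tr in spec.trials:
        X = tr.reshape(n_freq, n_ch).astype(np.complex128)
        cross = X[:, :, None] * np.conj(X[:, None, :])
        mag = np.abs(cross)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(mag > 0, cross / mag, 0.0)
        acc += unit
    val = (np.abs(acc) ** 2 - n) / (n * (n - 1))
    return _cross_container(
        np.real(val)[None], spec.samplerate, spec.channels, "ppc",
        freqs=spec.freqs, log=spec.log, n_trials=n,
    )


# --------------------------------------------------------------------------
# Wilson factorization and Granger causality
# --------------------------------------------------------------------------

@dataclass
class SpectralFactorization:
    """Result of Wilson's spectral-matrix factorization ``S = H Sigma H*``."""

    H: np.ndarray          # (n_freqs, C, C) minimum-phase transfer function
    Sigma: np.ndarray      # (C, C) innovation covariance, symmetric PD
    residual: float        # max over freqs of ||S - H Sigma H*||_F / ||S||_F
    n_iterations: int
    converged: bool


def _regularize(S: np.ndarray) -> np.ndarray:
    """Nudge near-singular spectral matrices to positive definiteness."""
    n_ch = S.shape[-1]
    eigmin = np.linalg.eigvalsh(S).min()
    if eigmin > 0:
        return S
    eps = 1e-12
    tr = np.real(np.einsum("fii->f", S)).mean() / n_ch
    Sreg = S.copy()
    eye = np.eye(n_ch)
    while eps <= 1e-3:
        Sreg = S + eps * tr * eye
        if np.linalg.eigvalsh(Sreg).min() > 0:
            warnings.warn(
                f"spectral matrix regularized (eps={eps:g}) to restore positive "
                "definiteness",
                RuntimeWarning,
                stacklevel=3,
            )
            return Sreg
        eps *= 10
    raise ValidationError("spectral matrix could not be regularized to PD")


def _plus_operator(g: np.ndarray) -> np.ndarray:
    """Causal (non-negative lag) part of a spectral function on the circle."""
    n2 = g.shape[0]
    gam = np.fft.ifft(g, axis=0)
    beta0 = 0.5 * gam[0]
    gam[0] = np.triu(beta0)
    # strictly positive lags only; the shared middle lag of the even-length
    # circle belongs to both signs and must be dropped from the causal part
    gam[n2 // 2:] = 0.0
    return np.fft.fft(gam, axis=0)


def wilson_factorize(
    S,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> SpectralFactorization:
    """Factor a cross-spectral density into ``H Sigma H*`` (Wilson's method).

    ``S`` may be a CSD :class:`~ephystream.datamodel.CrossSpectralData` or a
    plain ``(n_freqs, C, C)`` Hermitian array on a uniform frequency grid
    running from 0 to the Nyquist frequency inclusive.  Iterates Wilson's
    Newton-type update until the maximal relative change of the spectral
    factor falls below ``tol``; non-convergence yields ``converged=False``
    with a warning (downstream Granger refuses such input).
    """
    if isinstance(S, CrossSpectralData):
        freqs = S.freqs
        fs = S.samplerate
        arr = np.asarray(S.data[0], dtype=np.complex128)
        df = np.diff(freqs)
        if freqs[0] != 0 or abs(freqs[-1] - fs / 2) > 1e-6 or np.ptp(df) > 1e-9 * fs:
            raise ParameterError(
                "Wilson factorization needs a uniform frequency grid from 0 to "
                "Nyquist inclusive (whole-trial spectra with foilim=None)"
            )
    else:
        arr = np.asarray(S, dtype=np.complex128)
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ParameterError("expected (n_freqs, C, C) spectral matrices")

    arr = _regularize(arr)
    m1 = arr.shape[0]
    n_ch = arr.shape[1]
    n2 = 2 * (m1 - 1)
    # Hermitian extension to the full circle: S(-f) = S(f)^T = conj(S(f))
    Sfull = np.empty((n2, n_ch, n_ch), dtype=np.complex128)
    Sfull[:m1] = arr
    Sfull[m1:] = np.conj(arr[m1 - 2:0:-1])

    gamma = np.fft.ifft(Sfull, axis=0)
    gamma0 = np.real(gamma[0])
    gamma0 = 0.5 * (gamma0 + gamma0.T)
    try:
        h = np.linalg.cholesky(gamma0).T.conj()
    except np.linalg.LinAlgError:
        gamma0 = gamma0 + 1e-12 * np.trace(gamma0) / n_ch * np.eye(n_ch)
        h = np.linalg.cholesky(gamma0).T.conj()
    psi = np.tile(h, (n2, 1, 1)).astype(np.complex128)

    eye = np.eye(n_ch)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # g = psi^{-1} S psi^{-H} + I, computed via two triangular-free solves
        tmp = np.linalg.solve(psi, Sfull)
        g = np.linalg.solve(psi, tmp.conj().transpose(0, 2, 1)).conj().transpose(0, 2, 1)
        g = g + eye
        gp = _plus_operator(g)
        psi_new = psi @ gp
        num = np.linalg.norm(psi_new - psi, axis=(1, 2))
        den = np.linalg.norm(psi, axis=(1, 2))
        rel = (num / np.where(den > 0, den, 1.0)).max()
        psi = psi_new
        if rel < tol:
            converged = True
            break

    gamma = np.fft.ifft(psi, axis=0)
    a0 = gamma[0]
    Sigma = np.real(a0 @ a0.conj().T)
    Sigma = 0.5 * (Sigma + Sigma.T)
    H = psi[:m1] @ np.linalg.inv(a0)

    recon = H @ Sigma @ H.conj().transpose(0, 2, 1)
    num = np.linalg.norm(recon - arr, axis=(1, 2))
    den = np.linalg.norm(arr, axis=(1, 2))
    residual = float((num / np.where(den > 0, den, 1.0)).max())

    if not converged:
        warnings.warn(
            f"Wilson factorization did not converge within {max_iter} iterations "
            f"(last relative update {rel:.3g}, residual {residual:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return SpectralFactorization(
        H=H, Sigma=Sigma, residual=residual, n_iterations=it, converged=converged
    )


def _pairwise_granger_from_csd(S: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """(n_freqs, C, C) directed Granger spectra; entry [i, j] holds j -> i."""
    n_freq, n_ch, _ = S.shape
    out = np.zeros((n_freq, n_ch, n_ch))
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            sub = S[:, [i, j], :][:, :, [i, j]]
            fac = wilson_factorize(sub, tol=tol, max_iter=max_iter)
            if not fac.converged:
                raise EngineError(
                    f"Wilson factorization for channel pair ({i}, {j}) did not "
                    f"converge (residual {fac.residual:.3g}); Granger computation "
                    "refused"
                )
            out[:, i, j] = _granger_pair(sub, fac.H, fac.Sigma, source=1, target=0)
            out[:, j, i] = _granger_pair(sub, fac.H, fac.Sigma, source=0, target=1)
    return out


def _granger_pair(S2, H, Sigma, source: int, target: int) -> np.ndarray:
    """Directed spectral Granger measure source -> target on a 2x2 system."""
    i, j = target, source
    s_ii = np.real(S2[:, i, i])
    sig_partial = Sigma[j, j] - Sigma[i, j] ** 2 / Sigma[i, i]
    denom = s_ii - sig_partial * np.abs(H[:, i, j]) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.log(s_ii / denom)
    g = np.nan_to_num(g, nan=0.0, posinf=0.0, neginf=0.0)
    if np.any(g < -1e-10):
        warnings.warn(
            "negative Granger values clipped to 0 (numerical noise)",
            RuntimeWarning,
            stacklevel=3,
        )
    return np.clip(g, 0.0, None)


def granger(data, tol: float = 1e-9, max_iter: int = 100, plan=None) -> CrossSpectralData:
    """Non-parametric pairwise Granger causality.

    Each channel pair's 2x2 cross-spectral submatrix is factorized with
    Wilson's algorithm and the directed measure evaluated from ``H`` and
    ``Sigma``.  Output entry ``[i, j]`` holds the influence ``j -> i``;
    the diagonal is 0.
    """
    S, freqs, channels, fs, log = _csd_array(data, plan)
    vals = _pairwise_granger_from_csd(S, tol, max_iter)
    return _cross_container(
        vals[None], fs, channels, "granger", freqs=freqs, log=log,
        tol=tol, max_iter=max_iter,
    )


# --------------------------------------------------------------------------
# cross-correlation
# --------------------------------------------------------------------------

def _xcorr_apply(trial, params):
    """Normalized cross-correlogram of one trial: (1, n_lags, C, C)."""
    max_lag = params["max_lag_samples"]
    x = trial.astype(np.float64)
    x = x - x.mean(axis=0)
    n, n_ch = x.shape
    n_fft = 1 << int(np.ceil(np.log2(2 * n)))
    X = np.fft.rfft(x, n=n_fft, axis=0)
    # r_ij(l) = sum_t x_i[t] x_j[t + l]  (positive lag: channel j lags i)
    cross = np.fft.irfft(
        np.conj(X)[:, :, None] * X[:, None, :], n=n_fft, axis=0
    )
    lags = np.arange(-max_lag, max_lag + 1)
    r = cross[lags % n_fft]  # negative lags wrap around
    auto0 = np.einsum("ti,ti->i", x, x)
    norm = np.sqrt(auto0[:, None] * auto0[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(norm > 0, r / norm, 0.0)
    return r[None].astype(np.float64)


def cross_correlation(data: AnalogData, max_lag: float, plan=None) -> CrossSpectralData:
    """Trial-averaged Pearson cross-correlation over lags.

    Per trial and channel pair, the mean is removed and the correlogram
    normalized by the lag-0 autocovariances; trials are then averaged.  The
    lag axis is in seconds, symmetric about 0; a positive lag at entry
    ``[i, j]`` means channel ``j`` lags channel ``i``.
    """
    data._require_trials()
    max_lag_samples = int(round(max_lag * data.samplerate))
    min_len = min(data.trial_shape(i)[0] for i in range(data.n_trials))
    if max_lag_samples >= min_len:
        raise ParameterError(
            f"max_lag ({max_lag} s = {max_lag_samples} samples) must be shorter "
            f"than the shortest trial ({min_len} samples)"
        )
    n_lags = 2 * max_lag_samples + 1
    n_ch = len(data.channels)

    def factory(path, trl):
        out = CrossSpectralData(
            path, data.samplerate, data.channels, trl,
            lags=np.arange(-max_lag_samples, max_lag_samples + 1) / data.samplerate,
            time_vector=np.zeros(1),
            measure="xcorr",
            trial_averaged=False,
            log=data.log,
        )
        return out

    kernel = engine.TrialKernel(
        name="cross_correlation",
        apply=_xcorr_apply,
        output_shape=lambda s, p: (1, n_lags, s[-1], s[-1]),
        output_dtype=np.float64,
        result_factory=factory,
    )
    per_trial = engine.compute(
        data, kernel, params={"max_lag_samples": max_lag_samples}, plan=plan
    )
    # stream-average the per-trial correlograms
    acc = np.zeros((n_lags, n_ch, n_ch))
    for tr in per_trial.trials:
        acc += tr[0]
    acc /= per_trial.n_trials
    out = _cross_container(
        acc[None], data.samplerate, data.channels, "xcorr",
        lags=np.arange(-max_lag_samples, max_lag_samples + 1) / data.samplerate,
        log=data.log, op_name="cross_correlation", max_lag=max_lag,
    )
    per_trial.close()
    return out
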