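"""Frequency and time-frequency estimation per trial.

Estimators
----------
``mtmfft``      whole-trial (multi)tapered Fourier transform; single tapers
                (hann, boxcar, ...) or DPSS multitapers whose count follows
                from the requested spectral smoothing ``tapsmofrq``.
``stft``        sliding-window Fourier transform (windows fully inside the
                trial; window centers define the time axis).
``welch``       time-average of the modified periodograms of ``stft``.
``wavelet_cwt`` Morlet continuous wavelet transform.
``superlet``    multiplicative superlets: geometric mean of Morlet
                magnitude responses with cycle counts ``k * base_cycles``,
                sharpening joint time-frequency resolution with order.

Normalization conventions
-------------------------
Tapers are unit-energy over the un-padded trial; zero-padding densifies the
frequency grid but power stays normalized by the original sample count.
One-sided power spectra carry the factor 2 on all interior bins (not on DC
and Nyquist), so that (i) a full-cycle sinusoid of amplitude A under a
boxcar taper shows one-sided power A**2/2 at its frequency, and (ii) the
sum of one-sided power bins of an un-padded boxcar spectrum equals the mean
square of the signal (Parseval).  ``output="fourier"`` stores per-taper
complex coefficients pre-scaled so the taper-mean of their squared moduli
reproduces ``output="pow"`` exactly.

Morlet wavelets are parameterized by their cycle count ``c`` (Gaussian
envelope SD ``sigma_t = c / (2 pi f)``) and amplitude-calibrated: the
magnitude response to a sinusoid ``A cos(2 pi f t)`` at its own frequency
is ``A``, so wavelet and superlet responses of different cycle counts are
directly comparable.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from . import engine
from .datamodel import AnalogData, SpectralData
from .errors import ParameterError

__all__ = [
    "PaddingSpec",
    "taper_count",
    "zero_pad",
    "mtmfft",
    "stft",
    "welch",
    "wavelet_cwt",
    "superlet",
]


@dataclass
class PaddingSpec:
    """Zero-padding: ``none``, ``nextpow2``, or ``absolute`` (pad every
    trial to ``target_seconds``)."""

    mode: str = "none"
    target_seconds: Optional[float] = None

    def __post_init__(self):
        if self.mode not in ("none", "nextpow2", "absolute"):
            raise ParameterError("pad mode must be 'none', 'nextpow2' or 'absolute'")
        if self.mode == "absolute" and (self.target_seconds is None or self.target_seconds <= 0):
            raise ParameterError("absolute padding requires target_seconds > 0")

    def n_padded(self, n_samples: int, samplerate: float) -> int:
        if self.mode == "none":
            return n_samples
        if self.mode == "nextpow2":
            return 1 << max(0, int(math.ceil(math.log2(max(n_samples, 1)))))
        target = int(round(self.target_seconds * samplerate))
        if target < n_samples:
            raise ParameterError(
                f"absolute padding target ({self.target_seconds} s = {target} samples) "
                f"is shorter than the trial ({n_samples} samples)"
            )
        return target


def _as_pad(pad) -> PaddingSpec:
    if pad is None:
        return PaddingSpec("none")
    if isinstance(pad, PaddingSpec):
        return pad
    if isinstance(pad, str):
        return PaddingSpec(pad)
    return PaddingSpec("absolute", float(pad))


def zero_pad(trial: np.ndarray, pad, samplerate: float) -> np.ndarray:
    """Append zeros along the first axis of one trial per the padding spec."""
    pad = _as_pad(pad)
    n = trial.shape[0]
    n_pad = pad.n_padded(n, samplerate)
    if n_pad == n:
        return trial
    out = np.zeros((n_pad,) + trial.shape[1:], dtype=trial.dtype)
    out[:n] = trial
    return out


def taper_count(tapsmofrq: float, duration: float) -> int:
    """DPSS taper count for a smoothing half-bandwidth (Hz) and duration (s).

    Uses the Shannon-number-minus-one convention
    ``K = max(1, floor(2 * T * W) - 1)`` with time-half-bandwidth product
    ``NW = T * W``; requires ``2 T W >= 2``.
    """
    if not tapsmofrq > 0 or not duration > 0:
        raise ParameterError("tapsmofrq and duration must be > 0")
    if 2 * duration * tapsmofrq < 2:
        raise ParameterError(
            f"smoothing tapsmofrq={tapsmofrq} Hz is too small for a {duration} s "
            f"window; minimum is 1/duration = {1 / duration:.6g} Hz"
        )
    return max(1, int(math.floor(2 * duration * tapsmofrq)) - 1)


@functools.lru_cache(maxsize=64)
def _dpss_tapers(n: int, nw: float, k: int) -> np.ndarray:
    tapers = sps.windows.dpss(n, nw, Kmax=k, norm=2)
    return np.atleast_2d(tapers)


@functools.lru_cache(maxsize=64)
def _single_taper(name: str, n: int) -> np.ndarray:
    win = sps.get_window(name, n, fftbins=True).astype(np.float64)
    win = win / np.linalg.norm(win)  # unit energy
    return win[None, :]


def _get_tapers(name: str, n: int, samplerate: float, tapsmofrq, n_tapers) -> np.ndarray:
    """(K, n) unit-energy taper matrix for a segment of n samples."""
    if name == "dpss":
        duration = n / samplerate
        if tapsmofrq is None:
            raise ParameterError("taper='dpss' requires tapsmofrq (half-bandwidth, Hz)")
        k = n_tapers if n_tapers is not None else taper_count(tapsmofrq, duration)
        return _dpss_tapers(n, duration * tapsmofrq, int(k))
    return _single_taper(name, n)


def _onesided_weights(n_pad: int) -> np.ndarray:
    n_freq = n_pad // 2 + 1
    w = np.full(n_freq, 2.0)
    w[0] = 1.0
    if n_pad % 2 == 0:
        w[-1] = 1.0
    return w


def _segment_fourier(seg: np.ndarray, params: dict) -> np.ndarray:
    """Scaled per-taper Fourier coefficients of one segment: (K, F, C)."""
    n = seg.shape[0]
    fs = params["samplerate"]
    tapers = _get_tapers(
        params["taper"], n, fs, params.get("tapsmofrq"), params.get("n_tapers")
    )
    n_pad = _as_pad(params.get("pad")).n_padded(n, fs)
    xt = tapers[:, :, None] * seg.astype(np.float64)[None, :, :]
    X = np.fft.rfft(xt, n=n_pad, axis=1)
    scale = np.sqrt(_onesided_weights(n_pad) / n)
    X *= scale[None, :, None]
    mask = params.get("_fmask")
    if mask is not None:
        X = X[:, mask, :]
    return X


def _freq_grid(n: int, params: dict):
    fs = params["samplerate"]
    n_pad = _as_pad(params.get("pad")).n_padded(n, fs)
    freqs = np.fft.rfftfreq(n_pad, 1.0 / fs)
    foilim = params.get("foilim")
    if foilim is not None:
        lo, hi = foilim
        if lo < 0 or hi > fs / 2 + 1e-9 or lo > hi:
            raise ParameterError(
                f"foilim {foilim} must be an ascending range within [0, {fs / 2}]"
            )
        mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    else:
        mask = np.ones_like(freqs, dtype=bool)
    return freqs[mask], mask


# --------------------------------------------------------------------------
# kernels
# --------------------------------------------------------------------------

def _mtmfft_apply(trial, params):
    X = _segment_fourier(trial, params)
    if params["output"] == "fourier":
        return X[None, :, :, :].astype(np.complex64)
    power = (np.abs(X) ** 2)
    if not params.get("keep_tapers"):
        power = power.mean(axis=0, keepdims=True)
    return power[None, :, :, :].astype(np.float32)


def _window_starts(n: int, win: int, hop: int) -> np.ndarray:
    if win > n:
        raise ParameterError(f"window ({win} samples) longer than trial ({n} samples)")
    return np.arange(0, n - win + 1, hop)


def _stft_apply(trial, params):
    win = params["win"]
    hop = params["hop"]
    starts = _window_starts(trial.shape[0], win, hop)
    segs = []
    for s in starts:
        segs.append(_segment_fourier(trial[s:s + win], params))
    X = np.stack(segs, axis=0)  # (n_win, K, F, C)
    if params["output"] == "fourier":
        return X.astype(np.complex64)
    power = np.abs(X) ** 2
    if not params.get("keep_tapers"):
        power = power.mean(axis=1, keepdims=True)
    if params.get("_welch"):
        power = power.mean(axis=0, keepdims=True)
    return power.astype(np.float32)


# --------------------------------------------------------------------------
# public estimators
# --------------------------------------------------------------------------

def _spectral_factory(data, freqs, time_vector, taper_info, output, op_name, log_params):
    def factory(path, trl):
        out = SpectralData(
            path,
            data.samplerate,
            data.channels,
            trl,
            freqs=freqs,
            time_vector=time_vector,
            taper=taper_info,
            output=output,
            log=data.log,
        )
        out.log_entry(op_name, **log_params)
        return out

    return factory


def _common_mtm_params(data, taper, tapsmofrq, n_tapers, pad, foilim, output, keep_tapers):
    if output not in ("pow", "fourier"):
        raise ParameterError("output must be 'pow' or 'fourier'")
    params = {
        "samplerate": data.samplerate,
        "taper": taper,
        "tapsmofrq": tapsmofrq,
        "n_tapers": n_tapers,
        "pad": _as_pad(pad),
        "foilim": tuple(foilim) if foilim is not None else None,
        "output": output,
        "keep_tapers": bool(keep_tapers) or output == "fourier",
    }
    return params


def _taper_k(params, n):
    tapers = _get_tapers(
        params["taper"], n, params["samplerate"], params.get("tapsmofrq"),
        params.get("n_tapers"),
    )
    return tapers.shape[0]


def mtmfft(
    data: AnalogData,
    taper: str = "hann",
    tapsmofrq: Optional[float] = None,
    n_tapers: Optional[int] = None,
    pad=None,
    foilim=None,
    output: str = "pow",
    keep_tapers: bool = False,
    plan=None,
) -> SpectralData:
    """Whole-trial (multi)tapered spectrum, one time bin per trial."""
    params = _common_mtm_params(data, taper, tapsmofrq, n_tapers, pad, foilim,
                                output, keep_tapers)
    n0 = data.trial_shape(0)[0]
    freqs, mask = _freq_grid(n0, params)
    params["_fmask"] = mask
    k = _taper_k(params, n0)
    k_out = k if params["keep_tapers"] else 1
    dtype = np.complex64 if output == "fourier" else np.float32

    def out_shape(s, p):
        return (1, k_out, int(mask.sum()), s[-1])

    taper_info = {"taper": taper, "tapsmofrq": tapsmofrq, "n_tapers": k}
    kernel = engine.TrialKernel(
        name="mtmfft",
        apply=_mtmfft_apply,
        output_shape=out_shape,
        output_dtype=dtype,
        result_factory=_spectral_factory(
            data, freqs, np.array([0.0]), taper_info, output, "mtmfft",
            dict(taper=taper, tapsmofrq=tapsmofrq, output=output),
        ),
    )
    return engine.compute(data, kernel, params=params, plan=plan)


def stft(
    data: AnalogData,
    window_length: float,
    overlap: float = 0.5,
    taper: str = "hann",
    tapsmofrq: Optional[float] = None,
    n_tapers: Optional[int] = None,
    foilim=None,
    output: str = "pow",
    keep_tapers: bool = False,
    plan=None,
) -> SpectralData:
    """Sliding-window Fourier transform (time-resolved spectra).

    Only windows entirely inside the trial are evaluated; their centers
    form the time axis.
    """
    if not 0 <= overlap < 1:
        raise ParameterError("overlap must lie in [0, 1)")
    win = int(round(window_length * data.samplerate))
    if win < 2:
        raise ParameterError("window_length too short")
    hop = max(1, int(round(win * (1 - overlap))))
    params = _common_mtm_params(data, taper, tapsmofrq, n_tapers, None, foilim,
                                output, keep_tapers)
    params.update({"win": win, "hop": hop})
    freqs, mask = _freq_grid(win, params)
    params["_fmask"] = mask
    k = _taper_k(params, win)
    k_out = k if params["keep_tapers"] else 1
    dtype = np.complex64 if output == "fourier" else np.float32

    start0, _stop0, off0 = data._trial_row(0)
    starts = _window_starts(data.trial_shape(0)[0], win, hop)
    time_vector = (off0 + starts + (win - 1) / 2) / data.samplerate

    def out_shape(s, p):
        return (len(_window_starts(s[0], win, hop)), k_out, int(mask.sum()), s[-1])

    taper_info = {"taper": taper, "tapsmofrq": tapsmofrq, "n_tapers": k}
    kernel = engine.TrialKernel(
        name="stft",
        apply=_stft_apply,
        output_shape=out_shape,
        output_dtype=dtype,
        result_factory=_spectral_factory(
            data, freqs, time_vector, taper_info, output, "stft",
            dict(window_length=window_length, overlap=overlap, taper=taper),
        ),
    )
    return engine.compute(data, kernel, params=params, plan=plan)


def welch(
    data: AnalogData,
    window_length: float,
    overlap: float = 0.5,
    taper: str = "hann",
    tapsmofrq: Optional[float] = None,
    plan=None,
) -> SpectralData:
    """Welch power estimate: mean over sliding-window modified periodograms."""
    if not 0 <= overlap < 1:
        raise ParameterError("overlap must lie in [0, 1)")
    win = int(round(window_length * data.samplerate))
    hop = max(1, int(round(win * (1 - overlap))))
    params = _common_mtm_params(data, taper, tapsmofrq, None, None, None, "pow", False)
    params.update({"win": win, "hop": hop, "_welch": True})
    freqs, mask = _freq_grid(win, params)
    params["_fmask"] = mask

    def out_shape(s, p):
        _window_starts(s[0], win, hop)  # validates window fits
        return (1, 1, int(mask.sum()), s[-1])

    k = _taper_k(params, win)
    taper_info = {"taper": taper, "tapsmofrq": tapsmofrq, "n_tapers": k}
    kernel = engine.TrialKernel(
        name="welch",
        apply=_stft_apply,
        output_shape=out_shape,
        output_dtype=np.float32,
        result_factory=_spectral_factory(
            data, freqs, np.array([0.0]), taper_info, "pow", "welch",
            dict(window_length=window_length, overlap=overlap, taper=taper),
        ),
    )
    return engine.compute(data, kernel, params=params, plan=plan)


# --------------------------------------------------------------------------
# wavelets and superlets
# --------------------------------------------------------------------------

def _morlet_kernel(freq: float, cycles: float, samplerate: float, n_max: int) -> np.ndarray:
    """Amplitude-calibrated complex Morlet: response to A*cos(2 pi f t) is A."""
    sigma = cycles / (2 * np.pi * freq)
    half = min(int(math.ceil(5 * sigma * samplerate)), max((n_max - 1) // 2, 1))
    t = np.arange(-half, half + 1) / samplerate
    env = np.exp(-(t**2) / (2 * sigma**2))
    wav = env * np.exp(2j * np.pi * freq * t)
    wav -= wav.mean()  # exact zero mean (admissibility, also under truncation)
    wav *= 2.0 / (sigma * samplerate * np.sqrt(2 * np.pi))
    return wav


def _cwt_response(trial: np.ndarray, freq: float, cycles: float, samplerate: float) -> np.ndarray:
    kern = _morlet_kernel(freq, cycles, samplerate, trial.shape[0])
    return sps.fftconvolve(trial.astype(np.float64), kern[:, None], mode="same", axes=0)


def _wavelet_apply(trial, params):
    freqs = params["freqs"]
    fs = params["samplerate"]
    width = params["width"]
    out = np.empty((trial.shape[0], 1, len(freqs), trial.shape[1]),
                   dtype=np.complex128)
    for j, f in enumerate(freqs):
        out[:, 0, j, :] = _cwt_response(trial, f, width, fs)
    if params["output"] == "fourier":
        return out.astype(np.complex64)
    return (np.abs(out) ** 2).astype(np.float32)


def _superlet_apply(trial, params):
    freqs = params["freqs"]
    fs = params["samplerate"]
    c1 = params["base_cycles"]
    orders = params["orders"]  # per-frequency (possibly fractional) order
    out = np.empty((trial.shape[0], 1, len(freqs), trial.shape[1]), dtype=np.float64)
    for j, (f, o) in enumerate(zip(freqs, orders)):
        m = int(math.floor(o))
        frac = o - m
        log_acc = np.zeros((trial.shape[0], trial.shape[1]))
        weight = 0.0
        tiny = 1e-300
        for k in range(1, m + 1):
            mag = np.abs(_cwt_response(trial, f, k * c1, fs))
            log_acc += np.log(mag + tiny)
            weight += 1.0
        if frac > 0:
            mag = np.abs(_cwt_response(trial, f, (m + 1) * c1, fs))
            log_acc += frac * np.log(mag + tiny)
            weight += frac
        out[:, 0, j, :] = np.exp(log_acc / weight) ** 2
    return out.astype(np.float32)


def wavelet_cwt(
    data: AnalogData,
    freqs: Sequence[float],
    width: float = 6.0,
    output: str = "pow",
    plan=None,
) -> SpectralData:
    """Morlet continuous wavelet transform at the requested frequencies.

    ``width`` is the wavelet's cycle count (Gaussian envelope SD
    ``width / (2 pi f)`` seconds); larger widths trade time resolution for
    frequency resolution.
    """
    freqs = np.asarray(sorted(freqs), dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= data.samplerate / 2):
        raise ParameterError("wavelet frequencies must lie in (0, samplerate/2)")
    if width < 1:
        raise ParameterError("width (cycles) must be >= 1; >= 3 recommended")
    if output not in ("pow", "fourier"):
        raise ParameterError("output must be 'pow' or 'fourier'")
    params = {
        "freqs": freqs,
        "width": float(width),
        "samplerate": data.samplerate,
        "output": output,
    }
    dtype = np.complex64 if output == "fourier" else np.float32

    start0, _s, off0 = data._trial_row(0)
    time_vector = (off0 + np.arange(data.trial_shape(0)[0])) / data.samplerate
    kernel = engine.TrialKernel(
        name="wavelet_cwt",
        apply=_wavelet_apply,
        output_shape=lambda s, p: (s[0], 1, len(freqs), s[-1]),
        output_dtype=dtype,
        result_factory=_spectral_factory(
            data, freqs, time_vector, {"taper": "morlet", "width": width},
            output, "wavelet_cwt", dict(width=width),
        ),
    )
    return engine.compute(data, kernel, params=params, plan=plan)


def superlet(
    data: AnalogData,
    freqs: Sequence[float],
    base_cycles: float = 3.0,
    order_max: int = 5,
    adaptive: bool = True,
    plan=None,
) -> SpectralData:
    """Multiplicative superlet transform (power).

    At order ``o`` the estimate at each time-frequency point is the squared
    geometric mean of the magnitude responses of Morlet wavelets with
    ``k * base_cycles`` cycles, ``k = 1..o``.  In adaptive mode the order
    grows linearly from 1 at ``min(freqs)`` to ``order_max`` at
    ``max(freqs)``; fractional orders weight the last wavelet
    geometrically.  Order 1 reduces exactly to ``wavelet_cwt`` with
    ``width = base_cycles``.
    """
    freqs = np.asarray(sorted(freqs), dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= data.samplerate / 2):
        raise ParameterError("superlet frequencies must lie in (0, samplerate/2)")
    if base_cycles < 1:
        raise ParameterError("base_cycles must be >= 1")
    if order_max < 1:
        raise ParameterError("order_max must be >= 1")
    if adaptive and len(freqs) > 1 and order_max > 1:
        fmin, fmax = freqs[0], freqs[-1]
        orders = 1.0 + (order_max - 1.0) * (freqs - fmin) / (fmax - fmin)
    else:
        orders = np.full(len(freqs), float(order_max))
    params = {
        "freqs": freqs,
        "base_cycles": float(base_cycles),
        "orders": orders,
        "samplerate": data.samplerate,
    }
    start0, _s, off0 = data._trial_row(0)
    time_vector = (off0 + np.arange(data.trial_shape(0)[0])) / data.samplerate
    kernel = engine.TrialKernel(
        name="superlet",
        apply=_superlet_apply,
        output_shape=lambda s, p: (s[0], 1, len(freqs), s[-1]),
        output_dtype=np.float32,
        result_factory=_spectral_factory(
            data, freqs, time_vector,
            {"taper": "superlet", "base_cycles": base_cycles, "order_max": order_max,
             "adaptive": adaptive},
            "pow", "superlet",
            dict(base_cycles=base_cycles, order_max=order_max, adaptive=adaptive),
        ),
    )
    return engine.compute(data, kernel, params=params, plan=plan)
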