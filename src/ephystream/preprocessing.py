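"""Per-trial signal conditioning for :class:`~ephystream.datamodel.AnalogData`.

All operations are per-trial, per-channel separable, run through the
compute engine (so they stream from disk and parallelize over trials), and
never change the number of trials.

Filtering uses Butterworth designs realized as cascaded second-order
sections for numerical stability at high order.  ``direction="zerophase"``
applies the filter forward and backward (zero phase distortion, effective
order doubled), with odd-reflection edge padding of three times the filter
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy import signal as sps

from . import engine
from .datamodel import AnalogData, TimeLockData
from .errors import ParameterError, ValidationError

__all__ = [
    "FilterSpec",
    "detrend",
    "normalize",
    "iir_filter",
    "analytic_signal",
    "downsample",
    "resample",
]

_KINDS = {"lowpass", "highpass", "bandpass", "bandstop"}


@dataclass
class FilterSpec:
    """Butterworth filter description.

    ``cutoff`` is one corner frequency in Hz for lowpass/highpass, or an
    ascending pair for bandpass/bandstop.  ``direction="zerophase"``
    (default) filters forward+backward; ``"onepass"`` filters causally.
    """

    kind: str
    cutoff: object
    order: int = 4
    direction: str = "zerophase"

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ParameterError(f"filter kind must be one of {sorted(_KINDS)}")
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")
        if self.direction not in ("onepass", "zerophase"):
            raise ParameterError("direction must be 'onepass' or 'zerophase'")
        cut = np.atleast_1d(np.asarray(self.cutoff, dtype=float))
        if self.kind in ("lowpass", "highpass"):
            if cut.size != 1:
                raise ParameterError(f"{self.kind} takes a single cutoff frequency")
        else:
            if cut.size != 2 or not cut[0] < cut[1]:
                raise ParameterError(f"{self.kind} takes two ascending cutoff frequencies")
        if np.any(cut <= 0):
            raise ParameterError("cutoff frequencies must be > 0 Hz")
        self.cutoff = cut

    def sos(self, samplerate: float) -> np.ndarray:
        if np.any(self.cutoff >= samplerate / 2):
            raise ParameterError(
                f"cutoff {self.cutoff.tolist()} Hz at or above Nyquist "
                f"({samplerate / 2} Hz)"
            )
        wn = self.cutoff / (samplerate / 2)
        return sps.butter(self.order, wn if wn.size > 1 else wn[0],
                          btype=self.kind, output="sos")


# --------------------------------------------------------------------------
# per-trial kernels (module level so they pickle to worker processes)
# --------------------------------------------------------------------------

def _detrend_apply(trial, params):
    return sps.detrend(trial, axis=0, type=params["mode"]).astype(np.float32)


def _zscore_apply(trial, params):
    mean = trial.mean(axis=0, dtype=np.float64)
    std = trial.std(axis=0, ddof=0, dtype=np.float64)
    bad = np.flatnonzero(std == 0)
    if bad.size:
        raise ValidationError(
            f"cannot z-score zero-variance channel(s) {bad.tolist()}"
        )
    return ((trial - mean) / std).astype(np.float32)


def _filter_apply(trial, params):
    sos = params["sos"]
    if params["direction"] == "zerophase":
        padlen = min(params["padlen"], trial.shape[0] - 1)
        out = sps.sosfiltfilt(sos, trial, axis=0, padtype="odd", padlen=padlen)
    else:
        out = sps.sosfilt(sos, trial, axis=0)
    return out.astype(np.float32)


def _hilbert_apply(trial, params):
    analytic = sps.hilbert(trial.astype(np.float64), axis=0)
    mode = params["output"]
    if mode == "envelope":
        return np.abs(analytic).astype(np.float32)
    if mode == "phase":
        return np.angle(analytic).astype(np.float32)
    return analytic.astype(np.complex64)


def _downsample_apply(trial, params):
    padlen = min(3 * params["aa_order"], trial.shape[0] - 1)
    low = sps.sosfiltfilt(params["sos"], trial, axis=0, padtype="odd", padlen=padlen)
    return low[:: params["factor"]].astype(np.float32)


def _resample_apply(trial, params):
    out = sps.resample_poly(trial.astype(np.float64), params["up"], params["down"], axis=0)
    return out.astype(np.float32)


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def _same_class_factory(data, op_name, new_samplerate=None, offset_scale=None,
                        extra_log=None):
    cls = AnalogData if not isinstance(data, TimeLockData) else TimeLockData

    def factory(path, trl):
        trl = np.asarray(trl, dtype=np.int64)
        if offset_scale is not None:
            old = data.trialdefinition
            trl[:, 2] = np.round(old[:, 2] * offset_scale).astype(np.int64)
        out = cls(
            path,
            new_samplerate if new_samplerate is not None else data.samplerate,
            data.channels,
            trl,
            log=data.log,
        )
        out.log_entry(op_name, **(extra_log or {}))
        return out

    return factory


def detrend(data: AnalogData, mode: str = "linear", plan=None) -> AnalogData:
    """Remove the per-channel mean (``"constant"``) or least-squares line
    (``"linear"``) from every trial."""
    if mode not in ("constant", "linear"):
        raise ParameterError("detrend mode must be 'constant' or 'linear'")
    kernel = engine.TrialKernel(
        name="detrend",
        apply=_detrend_apply,
        output_shape=lambda s, p: s,
        output_dtype=np.float32,
        result_factory=_same_class_factory(data, "detrend", extra_log={"mode": mode}),
        channel_separable=True,
    )
    return engine.compute(data, kernel, params={"mode": mode}, plan=plan)


def normalize(data: AnalogData, mode: str = "zscore", plan=None) -> AnalogData:
    """Z-score each channel of each trial (mean 0, variance 1)."""
    if mode != "zscore":
        raise ParameterError("only mode='zscore' is implemented")
    kernel = engine.TrialKernel(
        name="normalize",
        apply=_zscore_apply,
        output_shape=lambda s, p: s,
        output_dtype=np.float32,
        result_factory=_same_class_factory(data, "normalize", extra_log={"mode": mode}),
        channel_separable=True,
    )
    return engine.compute(data, kernel, plan=plan)


def iir_filter(data: AnalogData, spec: FilterSpec, plan=None) -> AnalogData:
    """Apply a Butterworth filter per trial and channel."""
    sos = spec.sos(data.samplerate)
    params = {
        "sos": sos,
        "direction": spec.direction,
        "padlen": 3 * spec.order,
    }
    kernel = engine.TrialKernel(
        name="iir_filter",
        apply=_filter_apply,
        output_shape=lambda s, p: s,
        output_dtype=np.float32,
        result_factory=_same_class_factory(
            data,
            "iir_filter",
            extra_log={
                "kind": spec.kind,
                "cutoff": spec.cutoff.tolist(),
                "order": spec.order,
                "direction": spec.direction,
            },
        ),
        channel_separable=True,
    )
    return engine.compute(data, kernel, params=params, plan=plan)


def analytic_signal(data: AnalogData, output: str = "envelope", plan=None) -> AnalogData:
    """Discrete analytic signal per channel (negative frequencies zeroed).

    ``output`` selects the envelope (modulus), instantaneous phase
    (argument) or the complex analytic signal itself.
    """
    if output not in ("envelope", "phase", "complex"):
        raise ParameterError("output must be 'envelope', 'phase' or 'complex'")
    if any(data.trial_shape(i)[0] < 2 for i in range(data.n_trials)):
        raise ParameterError("analytic signal requires trials of length >= 2")
    dtype = np.complex64 if output == "complex" else np.float32
    kernel = engine.TrialKernel(
        name="analytic_signal",
        apply=_hilbert_apply,
        output_shape=lambda s, p: s,
        output_dtype=dtype,
        result_factory=_same_class_factory(
            data, "analytic_signal", extra_log={"output": output}
        ),
        channel_separable=True,
    )
    return engine.compute(data, kernel, params={"output": output}, plan=plan)


def downsample(data: AnalogData, factor: int, plan=None) -> AnalogData:
    """Anti-alias lowpass (0.8 x new Nyquist) then keep every ``factor``-th
    sample.  Samplerate and trial definition are updated consistently."""
    if not isinstance(factor, (int, np.integer)) or isinstance(factor, bool):
        raise ParameterError("downsampling factor must be an integer")
    if factor < 2:
        raise ParameterError("downsampling factor must be >= 2")
    new_fs = data.samplerate / factor
    aa_order = 8
    aa = FilterSpec("lowpass", 0.8 * new_fs / 2, order=aa_order, direction="zerophase")
    params = {"sos": aa.sos(data.samplerate), "factor": int(factor), "aa_order": aa_order}
    kernel = engine.TrialKernel(
        name="downsample",
        apply=_downsample_apply,
        output_shape=lambda s, p: (-(-s[0] // p["factor"]),) + s[1:],
        output_dtype=np.float32,
        result_factory=_same_class_factory(
            data,
            "downsample",
            new_samplerate=new_fs,
            offset_scale=1.0 / factor,
            extra_log={"factor": int(factor)},
        ),
        channel_separable=True,
    )
    return engine.compute(data, kernel, params=params, plan=plan)


def resample(data: AnalogData, new_fs: float, plan=None) -> AnalogData:
    """Polyphase rational-ratio resampling to ``new_fs`` < samplerate."""
    if not new_fs < data.samplerate:
        raise ParameterError(
            f"new samplerate ({new_fs} Hz) must be below the current one "
            f"({data.samplerate} Hz); use downsample for integer factors"
        )
    frac = Fraction(new_fs / data.samplerate).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    params = {"up": up, "down": down}
    kernel = engine.TrialKernel(
        name="resample",
        apply=_resample_apply,
        output_shape=lambda s, p: (int(math.ceil(s[0] * p["up"] / p["down"])),) + s[1:],
        output_dtype=np.float32,
        result_factory=_same_class_factory(
            data,
            "resample",
            new_samplerate=data.samplerate * up / down,
            offset_scale=up / down,
            extra_log={"new_fs": float(new_fs)},
        ),
        channel_separable=True,
    )
    return engine.compute(data, kernel, params=params, plan=plan)
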