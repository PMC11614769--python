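"""Trial-level statistics: reductions, inter-trial coherence, jackknife
confidence intervals, spike PSTH.

``summary_stat`` reduces along any named axis of a container, including the
virtual ``"trials"`` axis (which requires time-locked, equal-shape trials).
``itc`` measures across-trial phase consistency of complex spectra.
``jackknife`` produces leave-one-trial-out standard errors and Student-t
confidence intervals for trial-averaged estimators such as coherence or
Granger causality; for linear statistics (the mean) it reproduces the
classical ``s / sqrt(n)`` standard error exactly.  ``psth`` bins spike
trains relative to each trial's t=0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import stats as sstats

from .datamodel import (
    AnalogData,
    BaseData,
    CrossSpectralData,
    SpectralData,
    SpikeData,
    new_payload_path,
    _h5open,
)
from .errors import ParameterError, StateError, ValidationError

__all__ = [
    "summary_stat",
    "itc",
    "jackknife",
    "JackknifeResult",
    "psth",
    "PSTHResult",
]


# --------------------------------------------------------------------------
# summary statistics
# --------------------------------------------------------------------------

_REDUCERS = {
    "mean": lambda a, axis: np.mean(a, axis=axis),
    "median": lambda a, axis: np.median(a, axis=axis),
    "std": lambda a, axis: np.std(a, axis=axis, ddof=1),
    "var": lambda a, axis: np.var(a, axis=axis, ddof=1),
}


def _wrap_like(template: BaseData, arr: np.ndarray, op_name: str, **log_params):
    """Store an in-memory reduction result as a dataset of the same class."""
    path = new_payload_path(op_name)
    with _h5open(path, "w") as f:
        f.create_dataset("data", data=arr)
    cls = type(template)
    kw = {}
    if isinstance(template, SpectralData):
        kw = dict(
            freqs=template.freqs,
            time_vector=template.time_vector,
            taper=template.taper,
            output=template.output,
        )
    elif isinstance(template, CrossSpectralData):
        kw = dict(
            freqs=template.freqs,
            lags=template.lags,
            time_vector=template.time_vector,
            measure=template.measure,
            trial_averaged=template.trial_averaged,
        )
        cls = CrossSpectralData
    if isinstance(template, AnalogData):
        cls = AnalogData
        kw = {}
    out = cls(
        path,
        template.samplerate,
        template.channels,
        [[0, arr.shape[0], 0]],
        log=template.log,
        **kw,
    )
    out.log_entry(op_name, **log_params)
    return out


def _axis_index(data: BaseData, axis: str) -> int:
    if axis not in data.dimord:
        raise ParameterError(
            f"axis {axis!r} not defined for {type(data).__name__}; "
            f"available: {list(data.dimord)} plus 'trials'"
        )
    return data.dimord.index(axis)


def summary_stat(data: BaseData, stat: str = "mean", axis: str = "trials"):
    """Reduce a container along a named axis.

    ``axis="trials"`` collapses across trials (engine-style streaming, one
    trial in memory at a time for mean/std/var) and requires all trials to
    share one shape; other axes reduce within each trial.  ``std``/``var``
    use the unbiased (n-1) denominator.  Returns a dataset of the same
    class when the reduced array still fits the class's dimension order,
    otherwise a plain NumPy array.
    """
    if stat not in _REDUCERS:
        raise ParameterError(f"stat must be one of {sorted(_REDUCERS)}")
    if isinstance(data, SpikeData):
        raise ParameterError("summary_stat is defined for continuous containers")

    if axis == "trials":
        shapes = {data.trial_shape(i) for i in range(data.n_trials)}
        if len(shapes) > 1:
            raise ValidationError(
                "trials have unequal shapes; apply a latency selection first"
            )
        n = data.n_trials
        if stat in ("mean", "std", "var"):
            acc = np.zeros(data.trial_shape(0), dtype=np.float64)
            for tr in data.trials:
                acc += tr
            mean = acc / n
            if stat == "mean":
                out = mean
            else:
                acc2 = np.zeros_like(mean)
                for tr in data.trials:
                    acc2 += (np.asarray(tr, dtype=np.float64) - mean) ** 2
                var = acc2 / max(n - 1, 1)
                out = var if stat == "var" else np.sqrt(var)
        else:  # median needs all trials at once
            stack = np.stack([np.asarray(tr) for tr in data.trials])
            out = np.median(stack, axis=0)
        # derived statistics keep double precision (unlike raw analog payloads)
        return _wrap_like(data, np.asarray(out, dtype=np.float64),
                          f"summary_stat[{stat}]", axis="trials")

    ax = _axis_index(data, axis)
    reducer = _REDUCERS[stat]
    pieces = [reducer(np.asarray(tr), ax) for tr in data.trials]
    return np.stack(pieces)


# --------------------------------------------------------------------------
# inter-trial coherence
# --------------------------------------------------------------------------

def itc(spec: SpectralData) -> SpectralData:
    """Inter-trial coherence of complex spectra, in [0, 1].

    Per time/frequency/channel bin: the magnitude of the across-trial mean
    of the unit-normalized complex values.  Identical trials (or a single
    trial) give 1; uniformly random phases give an expected value of
    ``sqrt(pi) / (2 sqrt(N))``.  Zero-magnitude bins contribute 0 with a
    warning.  Multiple tapers are averaged after normalization.
    """
    if not np.issubdtype(spec.dtype, np.complexfloating):
        raise ParameterError(
            'inter-trial coherence requires complex input; use output="fourier"'
        )
    n = spec.n_trials
    shape = spec.trial_shape(0)
    acc = np.zeros(shape, dtype=np.complex128)
    saw_zero = False
    for tr in spec.trials:
        X = np.asarray(tr, dtype=np.complex128)
        mag = np.abs(X)
        saw_zero = saw_zero or bool(np.any(mag == 0))
        acc += np.where(mag > 0, X / np.where(mag > 0, mag, 1.0), 0.0)
    if saw_zero:
        warnings.warn(
            "zero-magnitude spectral bins contribute 0 to the inter-trial coherence",
            RuntimeWarning,
            stacklevel=2,
        )
    vals = (np.abs(acc) / n).mean(axis=1, keepdims=True)  # average tapers
    path = new_payload_path("itc")
    with _h5open(path, "w") as f:
        f.create_dataset("data", data=vals.astype(np.float32))
    out = SpectralData(
        path,
        spec.samplerate,
        spec.channels,
        [[0, vals.shape[0], 0]],
        freqs=spec.freqs,
        time_vector=spec.time_vector,
        taper=spec.taper,
        output="pow",
        log=spec.log,
    )
    out.log_entry("itc", n_trials=n)
    return out


# --------------------------------------------------------------------------
# jackknife
# --------------------------------------------------------------------------

@dataclass
class JackknifeResult:
    """Leave-one-trial-out estimate with uncertainty.

    ``estimate`` is the bias-corrected point estimate (mean of the
    pseudo-values); ``raw_estimate`` the full-sample statistic; ``se`` the
    jackknife standard error; ``ci_lower``/``ci_upper`` the Student-t
    confidence band at ``level``, clipped to ``valid_range`` when the
    estimator has one.
    """

    estimate: np.ndarray
    raw_estimate: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    level: float
    n_leaveouts: int
    pseudovalues: Optional[np.ndarray] = None


def _trial_subset(data, keep: Sequence[int]):
    from .datamodel import Selection, apply_selection

    return apply_selection(data, Selection(trials=list(keep)))


_BUILTIN_ESTIMATORS = {}


def _est_mean(data):
    res = summary_stat(data, "mean", axis="trials")
    arr = np.asarray(res.data[...], dtype=np.float64)
    res.close()
    return arr


def _est_coherence(data):
    from . import connectivity

    res = connectivity.coherence(data)
    arr = np.asarray(res.data[0], dtype=np.float64)
    res.close()
    return arr


def _est_granger(data):
    from . import connectivity

    res = connectivity.granger(data)
    arr = np.asarray(res.data[0], dtype=np.float64)
    res.close()
    return arr


_BUILTIN_ESTIMATORS.update(
    {
        "mean": (_est_mean, None),
        "coherence": (_est_coherence, (0.0, 1.0)),
        "granger": (_est_granger, (0.0, None)),
    }
)


def jackknife(
    data,
    estimator: Union[str, Callable] = "mean",
    level: float = 0.95,
    keep_pseudovalues: bool = False,
    valid_range=None,
) -> JackknifeResult:
    """Leave-one-trial-out jackknife for trial-averaged estimators.

    ``estimator`` is ``"mean"``, ``"coherence"``, ``"granger"`` or any
    callable mapping a dataset to a NumPy array.  Replicates
    ``theta_(i)`` are computed on each leave-one-out subset; pseudo-values
    ``n * theta_hat - (n - 1) * theta_(i)`` yield the bias-corrected
    estimate, its standard error ``sqrt(Var(pseudo) / n)``, and a
    Student-t confidence interval clipped to the estimator's valid range.
    """
    n = data.n_trials
    if n < 2:
        raise ParameterError("jackknife requires at least 2 trials")
    if not 0 < level < 1:
        raise ParameterError("confidence level must lie in (0, 1)")
    if isinstance(estimator, str):
        if estimator not in _BUILTIN_ESTIMATORS:
            raise ParameterError(
                f"unknown estimator {estimator!r}; "
                f"built-ins: {sorted(_BUILTIN_ESTIMATORS)}"
            )
        func, default_range = _BUILTIN_ESTIMATORS[estimator]
        if valid_range is None:
            valid_range = default_range
    else:
        func = estimator

    theta_hat = np.asarray(func(data), dtype=np.float64)
    pseudo = np.empty((n,) + theta_hat.shape)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        sub = _trial_subset(data, keep)
        theta_i = np.asarray(func(sub), dtype=np.float64)
        sub.close()
        pseudo[i] = n * theta_hat - (n - 1) * theta_i

    estimate = pseudo.mean(axis=0)
    se = np.sqrt(pseudo.var(axis=0, ddof=1) / n)
    tq = sstats.t.ppf(0.5 + level / 2, df=n - 1)
    lo = estimate - tq * se
    hi = estimate + tq * se
    if valid_range is not None:
        vlo, vhi = valid_range
        if vlo is not None:
            lo = np.clip(lo, vlo, None)
            hi = np.clip(hi, vlo, None)
        if vhi is not None:
            lo = np.clip(lo, None, vhi)
            hi = np.clip(hi, None, vhi)
    return JackknifeResult(
        estimate=estimate,
        raw_estimate=theta_hat,
        se=se,
        ci_lower=lo,
        ci_upper=hi,
        level=level,
        n_leaveouts=n,
        pseudovalues=pseudo if keep_pseudovalues else None,
    )


# --------------------------------------------------------------------------
# PSTH
# --------------------------------------------------------------------------

@dataclass
class PSTHResult:
    """Peristimulus time histogram.

    ``values`` is (n_bins, n_units); ``bin_edges`` in seconds relative to
    each trial's t=0; ``normalization`` one of ``"count"`` (spikes summed
    over trials), ``"rate"`` (count / (bin_width * n_trials), spikes/s) or
    ``"proportion"`` (count / total in-window count per unit).
    """

    bin_edges: np.ndarray
    values: np.ndarray
    units: np.ndarray
    normalization: str
    n_trials: int


def psth(
    spikes: SpikeData,
    bin_width: float,
    latency: Optional[Sequence[float]] = None,
    output: str = "rate",
) -> PSTHResult:
    """Bin spike times relative to each trial's t=0 and sum over trials.

    Bins are half-open ``[left, right)`` tiles of the latency window
    anchored at t=0 (a spike exactly at the window end is excluded).
    """
    if output not in ("count", "rate", "proportion"):
        raise ParameterError("output must be 'count', 'rate' or 'proportion'")
    if not bin_width > 0:
        raise ParameterError("bin_width must be > 0 s")
    spikes._require_trials()
    n_trials = spikes.n_trials
    if latency is None:
        t_min = min(spikes.time_window(i)[0] for i in range(n_trials))
        t_max = max(spikes.time_window(i)[1] for i in range(n_trials))
        latency = (t_min, t_max)
    t0, t1 = float(latency[0]), float(latency[1])
    n_bins = int(np.floor((t1 - t0) / bin_width + 1e-9))
    if n_bins < 1:
        raise ParameterError(
            f"latency window [{t0}, {t1}] s holds no bin of width {bin_width} s"
        )
    edges = t0 + bin_width * np.arange(n_bins + 1)
    units = spikes.units
    unit_index = {int(u): k for k, u in enumerate(units)}
    counts = np.zeros((n_bins, len(units)), dtype=np.int64)
    for i in range(n_trials):
        rows = spikes.trial(i)
        times = spikes.trial_times(i)
        inside = (times >= edges[0]) & (times < edges[-1])
        if not np.any(inside):
            continue
        which = np.floor((times[inside] - t0) / bin_width).astype(np.int64)
        which = np.clip(which, 0, n_bins - 1)
        for b, u in zip(which, rows[inside, 2]):
            counts[b, unit_index[int(u)]] += 1
    if output == "count":
        values = counts.astype(np.float64)
    elif output == "rate":
        values = counts / (bin_width * n_trials)
    else:
        totals = counts.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(totals > 0, counts / totals, 0.0)
    return PSTHResult(
        bin_edges=edges,
        values=values,
        units=units,
        normalization=output,
        n_trials=n_trials,
    )
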