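"""Seeded synthetic-data generators.

Every generator is a pure function of its :class:`GeneratorSpec`: the same
spec yields a bitwise-identical dataset.  Trial ``t`` draws from an
independent random stream derived deterministically from ``(seed, t)`` via
:class:`numpy.random.SeedSequence`, so trials are statistically independent
and parallel generation would match sequential generation exactly.

Generators
----------
``white_noise``      i.i.d. standard-normal samples per channel.
``red_noise``        stationary AR(1): ``x_t = a x_{t-1} + eps_t``.
``phase_diffusion``  cosine of a random-walk phase — a noisy oscillator
                     whose across-trial phase coherence decays with the
                     diffusion strength, mimicking experimental LFP rhythms.
``harmonic``         deterministic sinusoid (the test fixture of choice).
``poisson_spikes``   homogeneous Poisson spike trains per unit and trial.

All analog generators stream trials one at a time into a disk-backed
:class:`~ephystream.datamodel.AnalogData`, so building a dataset far larger
than memory is fine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import AnalogData, SpikeData, from_trial_source
from .errors import ParameterError

__all__ = [
    "GeneratorSpec",
    "white_noise",
    "red_noise",
    "phase_diffusion",
    "harmonic",
    "poisson_spikes",
]


@dataclass
class GeneratorSpec:
    """Geometry and seeding of a synthetic dataset."""

    n_trials: int = 10
    n_samples: int = 1000
    n_channels: int = 2
    samplerate: float = 1000.0
    seed: int = 42

    def __post_init__(self):
        for name in ("n_trials", "n_samples", "n_channels"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not self.samplerate > 0:
            raise ParameterError("samplerate must be > 0 Hz")

    def rng(self, trial: int) -> np.random.Generator:
        """Independent, reproducible stream for one trial."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(trial)]))


def _build(spec: GeneratorSpec, make_trial, name: str, **log_params) -> AnalogData:
    def trials():
        for t in range(spec.n_trials):
            yield make_trial(t).astype(np.float32)

    data = from_trial_source(trials(), spec.samplerate)
    data.log_entry(name, **log_params, **vars(spec))
    return data


def white_noise(spec: GeneratorSpec) -> AnalogData:
    """I.i.d. standard normal noise, independently per channel and trial."""

    def make(t):
        return spec.rng(t).standard_normal((spec.n_samples, spec.n_channels))

    return _build(spec, make, "white_noise")


def red_noise(spec: GeneratorSpec, alpha: float) -> AnalogData:
    """Stationary AR(1) red noise with unit innovation variance.

    ``x_t = alpha * x_{t-1} + eps_t`` with ``eps ~ N(0, 1)``, initialized
    from the stationary distribution (variance ``1 / (1 - alpha**2)``), so
    there is no burn-in transient.
    """
    if not abs(alpha) < 1:
        raise ParameterError(f"AR coefficient must satisfy |alpha| < 1, got {alpha}")

    from scipy.signal import lfilter

    def make(t):
        rng = spec.rng(t)
        eps = rng.standard_normal((spec.n_samples, spec.n_channels))
        x0 = rng.standard_normal(spec.n_channels) / np.sqrt(1.0 - alpha**2)
        eps[0] = 0.0  # sample 0 is the stationary draw itself
        x, _ = lfilter([1.0], [1.0, -alpha], eps, axis=0, zi=x0[None, :])
        return x

    return _build(spec, make, "red_noise", alpha=alpha)


def phase_diffusion(spec: GeneratorSpec, freq: float, eps: float,
                    locked_phase: float = None) -> AnalogData:
    """Noisy oscillator ``x_t = cos(phi_t)`` with a diffusing phase.

    The phase performs a biased random walk,
    ``phi_{t+1} = phi_t + 2 pi f / fs + xi_t`` with
    ``xi ~ N(0, eps * 2 pi f / fs)`` (``eps`` is a dimensionless diffusion
    strength per cycle), and ``phi_0`` uniform on ``[0, 2 pi)``.  With
    ``eps = 0`` this degenerates to a pure sinusoid with random initial
    phase; growing ``eps`` broadens the spectral line while the power stays
    concentrated near ``freq``.

    By default ``phi_0`` is uniform on ``[0, 2 pi)`` per trial, so trials
    share a rhythm but no phase alignment (realistic ongoing LFP).  Pass
    ``locked_phase`` to start every trial at that phase instead — an evoked,
    stimulus-locked oscillation whose across-trial phase coherence then
    decays with ``eps``.
    """
    if not 0 < freq < spec.samplerate / 2:
        raise ParameterError(f"freq must lie in (0, fs/2), got {freq}")
    if eps < 0:
        raise ParameterError("diffusion strength eps must be >= 0")
    step = 2 * np.pi * freq / spec.samplerate

    def make(t):
        rng = spec.rng(t)
        if locked_phase is None:
            phi0 = rng.uniform(0, 2 * np.pi, spec.n_channels)
        else:
            phi0 = np.full(spec.n_channels, float(locked_phase))
        incr = step + rng.normal(
            0.0, np.sqrt(eps * step), (spec.n_samples, spec.n_channels)
        )
        incr[0] = 0.0
        phi = phi0[None, :] + np.cumsum(incr, axis=0)
        return np.cos(phi)

    return _build(spec, make, "phase_diffusion", freq=freq, eps=eps)


def harmonic(spec: GeneratorSpec, freq: float, amplitude: float = 1.0,
             phase: float = 0.0) -> AnalogData:
    """Deterministic sinusoid ``A cos(2 pi f t + phase)`` on every channel."""
    if not 0 < freq < spec.samplerate / 2:
        raise ParameterError(f"freq must lie in (0, fs/2), got {freq}")

    def make(t):
        tt = np.arange(spec.n_samples) / spec.samplerate
        x = amplitude * np.cos(2 * np.pi * freq * tt + phase)
        return np.tile(x[:, None], (1, spec.n_channels))

    return _build(spec, make, "harmonic", freq=freq, amplitude=amplitude, phase=phase)


def poisson_spikes(spec: GeneratorSpec, rate: float, n_units: int = 1) -> SpikeData:
    """Homogeneous Poisson spike trains.

    One independent Poisson process of the given ``rate`` (Hz) per unit and
    per trial, over the trial duration ``n_samples / samplerate``.  Event
    times are rounded to sample indices; channel id mirrors the unit id.
    """
    if not rate > 0:
        raise ParameterError("rate must be > 0 Hz")
    if n_units < 1:
        raise ParameterError("n_units must be >= 1")
    duration = spec.n_samples / spec.samplerate
    rows = []
    trl = []
    for t in range(spec.n_trials):
        rng = spec.rng(t)
        t0 = t * spec.n_samples
        for u in range(n_units):
            n = rng.poisson(rate * duration)
            times = np.sort(rng.uniform(0, duration, n))
            samples = t0 + np.minimum(
                np.round(times * spec.samplerate).astype(np.int64), spec.n_samples - 1
            )
            rows.append(
                np.column_stack(
                    [samples, np.full(n, u, np.int64), np.full(n, u, np.int64)]
                )
            )
        trl.append([t0, t0 + spec.n_samples, 0])
    table = np.vstack(rows) if rows else np.empty((0, 3), np.int64)
    data = SpikeData.from_array(table, spec.samplerate, trialdefinition=trl)
    data.log_entry("poisson_spikes", rate=rate, n_units=n_units, **vars(spec))
    return data
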