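# ephystream

Trial-parallel, out-of-core analysis of multi-channel electrophysiology
time series (LFP, EEG, MEG, spike trains) in Python.

Systems-neuroscience experiments repeat a task over many trials while
recording from tens to hundreds of channels at kilohertz rates, so datasets
routinely outgrow the memory of the machine that has to analyze them.
`ephystream` addresses this with one architectural idea: every container
keeps its numeric payload in an HDF5 file on disk (metadata lives in a JSON
sidecar), and every analysis is a pure per-trial map executed by a compute
engine that streams one trial at a time — sequentially or on a local
process pool — and writes each trial's result into its preallocated slot of
a new on-disk container.  Peak memory stays proportional to a single
trial's working set, independent of how many trials the recording holds,
and a parallel run is bitwise identical to a sequential one.

## What it computes

**Spectral estimation.**  Whole-trial (multi)tapered Fourier spectra with
DPSS tapers, where the spectral smoothing half-bandwidth `W` (Hz) is set
directly and the taper count follows `K = ⌊2TW⌋ − 1` for a trial of
duration `T`; sliding-window STFT; Welch's averaged periodograms; Morlet
continuous wavelet transforms; and multiplicative superlets — at order `o`
the squared geometric mean `(∏_{k=1}^{o} |R_k|)^{2/o}` of Morlet responses
with `k·c₁` cycles, which sharpens joint time-frequency resolution beyond
any single wavelet.

**Connectivity.**  From the trial- and taper-averaged cross-spectral
density `S_ij(f) = ⟨X_i(f) X_j*(f)⟩`:

- coherence `C_ij(f) = |S_ij| / √(S_ii S_jj)`;
- pairwise phase consistency, the bias-free phase-locking estimator
  `PPC = (|Σ_n e^{iθ_n}|² − N) / (N(N−1))` over trial-wise relative phases
  `θ_n`;
- non-parametric Granger causality: each pair's 2×2 spectral matrix is
  factorized with Wilson's algorithm, `S = H Σ H*`, and the directed
  measure is
  `G_{j→i}(f) = ln [ S_ii / (S_ii − (Σ_jj − Σ_ij²/Σ_ii) |H_ij|²) ]`;
- lag-domain Pearson cross-correlograms.

**Statistics.**  Trial reductions (mean/median/std/var along any axis),
inter-trial coherence `ITC = |⟨X/|X|⟩_trials|`, leave-one-trial-out
jackknife standard errors and Student-t confidence intervals for coherence
and Granger spectra, and peristimulus time histograms for spike tables.

**Synthetic data.**  Seeded, bitwise-reproducible generators — white
noise, AR(1) red noise, phase-diffusion oscillators, Poisson spike trains,
pure harmonics — used throughout the test suite and the memory benchmarks.

**Interop.**  Native HDF5+JSON datasets, NWB-layout import/export, plain
HDF5 / NumPy array import, quick-look plotting, and an `ephystream` CLI
(`synthdata`, `preprocess`, `freqanalysis`, `connectivity`, `stats`,
`benchmark`, `convert`).

## Worked example

A 100-trial, 2-channel recording: a shared 40 Hz rhythm (amplitude 0.5) in
independent unit-variance noise.

```python
import numpy as np
import ephystream as es
from ephystream import synthdata, spectral, connectivity, statistics

spec = synthdata.GeneratorSpec(n_trials=100, n_samples=1000, n_channels=2,
                               samplerate=1000.0, seed=42)
data = synthdata.harmonic(spec, freq=40.0, amplitude=0.5) \
     + synthdata.white_noise(spec)           # disk-backed, streamed arithmetic

power = spectral.mtmfft(data, taper="dpss", tapsmofrq=2.0)
coh   = connectivity.coherence(data)
jk    = statistics.jackknife(data, "coherence")
```

Inspecting the results prints:

```
<AnalogData: shape (100000, 2), dtype float32, 100 trials, fs=1000.0 Hz, 2 channels>
power at 40 Hz: 0.0415; background at 100 Hz: 0.0023
coherence ch1-ch2 at 40 Hz: 0.930; at 100 Hz: 0.145
jackknife 95% CI at 40 Hz: [0.915, 0.942]
inter-trial coherence at 40 Hz: 0.995
```

The 40 Hz bin carries the oscillation's power plus the noise floor spread
by the ±2 Hz multitaper smoothing; off-peak bins show only the noise floor.
The shared rhythm drives coherence to 0.93 at 40 Hz — the
signal-to-total-power ratio within the smoothing band — while the
jackknife interval quantifies its trial-to-trial uncertainty; at 100 Hz
coherence sits at the small-sample bias level.  The locked stimulus phase
yields an inter-trial coherence near 1 at the rhythm frequency.

Running the same pipeline with `plan=es.ExecutionPlan("parallel",
n_workers=4)` returns bitwise-identical results.

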