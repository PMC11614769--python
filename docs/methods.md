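# Methods

This note documents the models, conventions and numerical choices behind
`ephystream`, what the synthetic-data generators do and do not emulate, and
the known limitations of the implementation.

## Data model

All containers are disk-backed: the payload is one HDF5 dataset named
`data`, chunked as one trial per chunk (or ≤ 4 MB slabs inside long
trials) so trialwise streaming is I/O-efficient; all metadata — class,
dimension order, dtype, sampling rate, channel labels, trial definition,
frequency/time vectors, processing log, UUID — lives in a JSON sidecar
that is the single source of truth (the HDF5 file carries only a UUID
cross-reference).  Format version `"1.0"`.

A trial definition is an integer array of `[start, stop, offset]` rows
indexing the payload's first axis with half-open intervals `[start, stop)`;
sample `k` of a trial sits at time `(offset + k) / samplerate` seconds.
Rows may overlap.  Analog payloads are single-precision real (`float32`) —
at 4 bytes per sample, the 10-trial × 5000-sample × 50-channel benchmark
dataset occupies exactly 10 MB and one trial exactly 1 MB — and complex
spectra are stored as `complex64`.  Derived statistics (trial means,
variances, connectivity measures) are stored in double precision, since
they are no longer raw data.

Every public operation appends one `(timestamp, operation, parameters)`
entry to the dataset log; logs propagate through derived datasets, so any
result carries the provenance of its full producing chain.

## Compute engine

A `TrialKernel` is a pure function from one trial's array (plus a
parameter map) to an output array, together with a shape contract used to
preallocate the output container before any trial runs.  The engine
executes kernels one trial per task.  In parallel mode a local
`ProcessPoolExecutor` (spawn context) is used: workers open the input HDF5
file read-only by path, compute their trial, and return the result to the
submitting process, which owns the single output file and writes each
result into its slot.  Sequential and parallel execution run exactly the
same per-trial code, so results are bitwise identical across backends and
worker counts.  A failing trial aborts the run, removes the partial output
file, and raises an error naming the trial.  `ExecutionPlan` retains a
`scheduler_address` field for future remote schedulers; this build
supports local pools only and refuses the field.

Peak memory consumption (PMC) is measured by an in-package sampler thread
that reads `/proc/<pid>/statm` for the submitting process and all active
pool workers at ~200 Hz and keeps the maximum resident-set size observed
during a run; the garbage collector is forced between runs.  Because a
long-running process retains freed-but-mapped heap pages, each benchmark
grid point is measured in a fresh Python subprocess by default
(`isolate=True`), which is also how the per-measurement scripts of typical
cluster benchmarks behave.  Two derived quantities matter:

- **absolute PMC** is flat in the trial count (the out-of-core property);
- **net PMC** (peak minus the pre-run baseline RSS) isolates the
  algorithm's own working set; on desk-scale datasets this is the
  quantity in which coherence shows its quadratic channel scaling
  (`freqs × channels²` cross-spectral accumulator), since the interpreter
  baseline would otherwise mask it.

The shipped reduced-scale study conditions are 10 vs 100 trials of the
1 MB benchmark trial for the flatness check (3 runs each) and 3 trials ×
8192 samples over 2–64 channels for the coherence scaling slope (2 runs
each); the slope is a log-log least-squares fit over the six channel
counts.

## Preprocessing

Filters are Butterworth designs applied as cascaded second-order sections
(numerically stable at high order).  Default direction is zero-phase
(forward+backward, squared magnitude response, effective order doubled)
with odd-reflection edge padding of three times the filter order; edge
transients therefore differ between a signal and its time reverse within
roughly one filter length of the boundaries, while interior samples obey
the palindromic symmetry.  The analytic signal uses the standard discrete
construction (negative frequencies zeroed, even/odd lengths handled by
`scipy.signal.hilbert`).  Downsampling applies an order-8 zero-phase
anti-alias lowpass at 0.8× the new Nyquist before decimation — a
conservative, conventional guard band; resampling uses polyphase
rational-ratio filtering.  Trial definitions and sampling rates are
rescaled consistently.

## Spectral estimation

Tapers are normalized to unit energy over the **un-padded** trial; zeros
are appended after tapering.  Zero-padding therefore densifies the
frequency grid without changing power normalization (divide by the
original sample count).  One-sided spectra carry the factor 2 on interior
bins, not on DC or Nyquist.  Consequences, which the tests assert:

- a full-cycle sinusoid of amplitude `A` under a boxcar taper shows
  one-sided power `A²/2` at its bin, independent of padding;
- the sum of one-sided power bins of an un-padded boxcar spectrum equals
  the signal's mean square (Parseval), to double precision in the
  estimator (the stored `float32`/`complex64` payload rounds at ~1e-7).

`output="fourier"` stores per-taper coefficients pre-scaled by
`sqrt(w_f / N)` so the taper-mean of squared moduli reproduces
`output="pow"` exactly; the scaling is real and positive, so phases — and
everything downstream that uses them (CSD, coherence, PPC, ITC) — are
unaffected.

DPSS taper count: `K = max(1, ⌊2TW⌋ − 1)` (Shannon number minus one, the
FieldTrip-compatible convention) with time-half-bandwidth `NW = T·W`,
requiring `2TW ≥ 2`; `T` is the un-padded trial duration, consistent with
the taper-energy convention above.

Morlet wavelets are cycle-parameterized (Gaussian envelope SD
`σ_t = c / (2πf)`) and **amplitude-calibrated**: the magnitude response to
`A·cos(2πft)` at `f` is `A`.  This, rather than L2 normalization, puts
wavelets of different cycle counts on one scale — a prerequisite for the
multiplicative superlet, whose order-`o` estimate is the squared geometric
mean of the magnitude responses at cycle counts `k·c₁`, `k = 1..o`.
Kernels are truncated at ±5σ (clipped to the trial length) and explicitly
mean-subtracted so admissibility survives truncation.  Adaptive superlets
interpolate the order linearly from 1 at the lowest requested frequency to
`order_max` at the highest; fractional orders weight the last wavelet
geometrically.  Wavelet estimates within half a support of the trial edges
are distorted by the implicit zero boundary — use interior time windows.

## Connectivity

The CSD is accumulated streaming over trials, pooling tapers as extra
observations, in double precision.  Coherence is reported as magnitude by
default (`squared=True` for the squared variant); it is computed as
`sqrt(|S_ij|² / (S_ii·S_jj))` so that bitwise-identical channels give
exactly 1.  PPC uses the closed form `(|Σe^{iθ}|² − N)/(N(N−1))` over
trial-wise relative phases and requires single-taper spectra: tapers are
correlated estimates of one trial's phase and pooling them as if they were
independent trials would bias the estimator.

Wilson's spectral factorization iterates `ψ ← ψ·[ψ⁻¹ S ψ⁻ᴴ + I]₊` on the
full frequency circle (Hermitian extension of the 0..Nyquist grid), where
`[·]₊` keeps strictly positive lags plus half of lag 0 with the lag-0
block made upper triangular.  The shared middle lag of the even-length
circle belongs to both signs and is excluded from the causal part —
keeping it stalls the iteration on rough spectra.  Defaults: relative
update tolerance 1e-9, 100 iterations; spectral matrices whose smallest
eigenvalue is ≤ 0 are regularized by `ε·tr(S)/C·I` with ε escalating from
1e-12.  On smooth spectra (e.g. an analytic VAR spectral matrix) the
converged reconstruction residual `max_f ‖S − HΣH*‖/‖S‖` reaches ~1e-10.
On *estimated* spectra the factor's finite lag support (0..M−1 of 2M
circle points) cannot represent the lag-M covariance component, which for
a noisy CSD is O(1/√n_trials) estimation noise; the residual then
plateaus at that level regardless of iteration count.  `converged`
reports the iteration fixed point; the residual is reported separately,
and Granger refuses only non-converged input.

Granger causality is computed pairwise on 2×2 sub-factorizations (the
bivariate feedforward/feedback decomposition); conditional multivariate
Granger is out of scope.  Negative values from floating-point noise are
clipped to zero with a warning.  Cross-correlograms remove each trial's
mean, normalize by lag-0 autocovariances, and average over trials; a
positive lag at entry `[i, j]` means channel `j` lags channel `i`.

## Statistics

`std`/`var` use the unbiased (n−1) denominator.  Reductions over trials
stream one trial at a time (two passes for variance); the median requires
stacking all trials and is documented as the exception.  ITC averages
unit-normalized complex values across trials (zero-magnitude bins
contribute 0 with a warning); its null expectation under uniform phases is
`√π / (2√N)`.

The jackknife forms leave-one-trial-out replicates `θ₍ᵢ₎`, pseudo-values
`n·θ̂ − (n−1)·θ₍ᵢ₎`, the bias-corrected estimate (their mean), the standard
error `sqrt(Var(pseudo)/n)`, and a Student-t interval clipped to the
estimator's valid range ([0, 1] for coherence, [0, ∞) for Granger).  Both
the bias-corrected and the raw full-sample estimate are exposed.  For
linear statistics the pseudo-values equal the per-trial values and the SE
reduces to the classical `s/√n` exactly.

PSTH bins are half-open `[left, right)` tiles of the latency window
anchored at t = 0, consistent with the half-open trial convention (a spike
exactly at the window end is excluded); counts are summed over trials and
`rate` divides by `bin_width · n_trials`.  Trials with unequal windows are
aggregated by sum-then-normalize.

## Synthetic data

Each generator is a pure function of its `GeneratorSpec`; trial `t` draws
from `SeedSequence([seed, t])`, so datasets are bitwise reproducible and
trials independent, and parallel generation would match sequential
generation exactly.  The AR(1) process is initialized from its stationary
distribution (no burn-in).  The phase-diffusion oscillator uses increment
variance `eps · 2πf/fs` — `eps` is a dimensionless diffusion strength per
cycle — with the initial phase uniform per trial by default (ongoing
rhythm, no across-trial phase locking at any `eps`); passing
`locked_phase` models an evoked oscillation whose inter-trial coherence
then decays monotonically with `eps`.  Poisson spike times are rounded to
sample indices.

These generators emulate second-order structure (spectra, phase
consistency, Poisson counts) but none of the nonstationarity, 1/f
background mixtures, artifacts, volume conduction or spike-sorting errors
of real recordings; passing tests demonstrate estimator correctness under
the stated models, not robustness to real-data pathologies.

## Known limitations

- Parallelism is one trial per task on a local pool; no remote scheduler,
  no per-channel task splitting (channel blocking exists only inside a
  task for channel-separable kernels).
- NWB support is a minimal direct HDF5 mapping (acquisition series, units
  table, trials intervals) aimed at round-tripping this package's
  containers and reading similarly structured files; it is not a full NWB
  implementation, and exported files record the spike clock as a units
  attribute.
- Whole-trial spectra require equal trial lengths (or padding to a common
  grid); apply a latency selection first for unequal epochs.
- Spectral parameterization post-processing (1/f fitting) is a documented
  hook point, not implemented.
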