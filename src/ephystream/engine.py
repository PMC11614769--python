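"""Out-of-core, trial-parallel compute engine.

The engine realizes one idea: every analysis in this package is a pure
per-trial map.  A :class:`TrialKernel` describes the map (the function
applied to one trial's array plus the shape/dtype of its result), and
:func:`compute` executes it over all trials of a disk-backed container —
sequentially or on a process pool — writing each trial's result into its
preallocated slot of a new on-disk container.  Peak memory therefore stays
proportional to a single trial's working set, independent of the number of
trials.

Parallelism is one-trial-per-task: workers read their trial directly from
the input HDF5 file by path and return the result to the submitting
process, which owns the single output file.  A parallel run with any number
of workers is bitwise identical to a sequential run, because both execute
exactly the same per-trial code.

The module also hosts the peak-memory benchmark harness
(:func:`memory_benchmark`): it generates synthetic datasets over a grid of
(n_trials, n_samples, n_channels), runs a registered analysis pipeline on
each, and samples the resident-set size of the submitting process and the
pool workers at >= 10 Hz to record the peak memory consumption (PMC) per
run, with the garbage collector forced between runs.
"""

from __future__ import annotations

import csv
import gc
import os
import threading
import time as _time
from concurrent.futures import ProcessPoolExecutor, as_completed
from dataclasses import dataclass, field
from multiprocessing import get_context
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from . import datamodel
from .errors import CapabilityError, EngineError

__all__ = [
    "TrialKernel",
    "ExecutionPlan",
    "BenchmarkRecord",
    "compute",
    "memory_benchmark",
    "write_benchmark_csv",
    "BENCHMARK_ALGORITHMS",
]


@dataclass
class TrialKernel:
    """Contract for a per-trial computation.

    ``apply(trial, params)`` (or ``apply(trial, params, other)`` for binary
    kernels) must be a pure, module-level function so it can be shipped to
    worker processes.  ``output_shape(trial_shape, params)`` predicts the
    result shape for preallocation and is enforced against the actual
    output.  ``result_factory(payload_path, trialdefinition)`` wraps the
    finished payload in the proper container class.
    """

    name: str
    apply: Callable
    output_shape: Callable[[tuple, dict], tuple]
    output_dtype: np.dtype
    result_factory: Callable
    channel_separable: bool = False


@dataclass
class ExecutionPlan:
    """Where and how trials are processed.

    backend ``"sequential"`` runs trials in the submitting process;
    ``"parallel"`` uses a local process pool with ``n_workers`` workers.
    ``scheduler_address`` is reserved for attaching to an external task
    scheduler; this build only provides local pools and refuses it.
    """

    backend: str = "sequential"
    n_workers: int = 1
    scheduler_address: Optional[str] = None

    def __post_init__(self):
        if self.backend not in ("sequential", "parallel"):
            raise CapabilityError(f"unknown backend {self.backend!r}")
        if self.n_workers < 1:
            raise CapabilityError("n_workers must be >= 1")
        if self.scheduler_address is not None:
            raise CapabilityError(
                "attaching to an external scheduler is not supported in this build; "
                "use backend='parallel' with a local pool"
            )


# pids of the currently running pool, for the memory sampler
_CURRENT_WORKER_PIDS: set = set()


def _eval_kernel(kernel: TrialKernel, trial: np.ndarray, params: dict, other=None,
                 channel_block: Optional[int] = None) -> np.ndarray:
    """Apply a kernel to one trial, optionally channel-block by block."""
    if channel_block is not None and kernel.channel_separable and trial.ndim >= 2:
        nch = trial.shape[-1]
        blocks = []
        for lo in range(0, nch, channel_block):
            sl = (Ellipsis, slice(lo, min(lo + channel_block, nch)))
            o = other[sl] if other is not None else None
            blocks.append(_call_apply(kernel, trial[sl], params, o))
        return np.concatenate(blocks, axis=-1)
    return _call_apply(kernel, trial, params, other)


def _call_apply(kernel, trial, params, other):
    if other is not None:
        return kernel.apply(trial, params, other)
    return kernel.apply(trial, params)


def _worker_task(path, other_path, bounds, other_bounds, apply_fn, params, index):
    """Executed in a worker process: read one trial, apply, return result."""
    import h5py  # local import keeps the task self-contained

    with h5py.File(path, "r", locking=False) as f:
        trial = f["data"][bounds[0]:bounds[1]]
    other = None
    if other_path is not None:
        with h5py.File(other_path, "r", locking=False) as f:
            other = f["data"][other_bounds[0]:other_bounds[1]]
    if other is not None:
        return index, apply_fn(trial, params, other)
    return index, apply_fn(trial, params)


def compute(
    data,
    kernel: TrialKernel,
    params: Optional[dict] = None,
    plan: Optional[ExecutionPlan] = None,
    other=None,
    channel_block: Optional[int] = None,
):
    """Apply ``kernel`` to every trial of ``data`` and return the new dataset.

    The output container is preallocated on disk from the summed per-trial
    output shapes before any trial runs; each task then fills exactly its
    own slot.  If any trial fails, the partial output file is removed and an
    :class:`EngineError` naming the trial is raised.
    """
    params = params or {}
    plan = plan or ExecutionPlan()
    data._require_trials()

    n_trials = data.n_trials
    shapes = []
    for i in range(n_trials):
        s = tuple(int(v) for v in kernel.output_shape(data.trial_shape(i), params))
        if len(shapes) and s[1:] != shapes[0][1:]:
            raise EngineError(
                f"kernel {kernel.name!r}: trailing output dimensions differ between "
                f"trials ({s[1:]} vs {shapes[0][1:]})"
            )
        shapes.append(s)

    total = sum(s[0] for s in shapes)
    out_shape = (total,) + shapes[0][1:]
    trl = []
    cursor = 0
    for i, s in enumerate(shapes):
        off = int(data._trialdefinition[i, 2]) if s[0] == data.trial_shape(i)[0] else 0
        trl.append([cursor, cursor + s[0], off])
        cursor += s[0]

    out_path = datamodel.new_payload_path(kernel.name.replace("/", "_"))
    import h5py

    fout = h5py.File(out_path, "w", locking=False)
    dset = fout.create_dataset(
        "data",
        shape=out_shape,
        dtype=kernel.output_dtype,
        chunks=datamodel._auto_chunks(
            out_shape, np.dtype(kernel.output_dtype).itemsize, trial_len=shapes[0][0]
        ),
    )

    def _write(i, arr):
        arr = np.asarray(arr, dtype=kernel.output_dtype)
        if tuple(arr.shape) != shapes[i]:
            raise EngineError(
                f"kernel {kernel.name!r} violated its shape contract on trial {i}: "
                f"declared {shapes[i]}, produced {tuple(arr.shape)}"
            )
        dset[trl[i][0]:trl[i][1]] = arr

    try:
        if plan.backend == "sequential" or n_trials == 1:
            for i in range(n_trials):
                try:
                    res = _eval_kernel(
                        kernel, data.trial(i), params,
                        other.trial(i) if other is not None else None,
                        channel_block,
                    )
                except EngineError:
                    raise
                except Exception as exc:
                    raise EngineError(
                        f"kernel {kernel.name!r} failed on trial {i}: {exc!r}"
                    ) from exc
                _write(i, res)
        else:
            data.flush()
            data.close()
            if other is not None:
                other.flush()
                other.close()
            ctx = get_context("spawn")
            with ProcessPoolExecutor(max_workers=plan.n_workers, mp_context=ctx) as pool:
                try:
                    _CURRENT_WORKER_PIDS.update(
                        p.pid for p in getattr(pool, "_processes", {}).values()
                    )
                except Exception:
                    pass
                futures = {}
                for i in range(n_trials):
                    b = tuple(int(v) for v in data._trialdefinition[i, :2])
                    ob = (
                        tuple(int(v) for v in other._trialdefinition[i, :2])
                        if other is not None
                        else None
                    )
                    fut = pool.submit(
                        _worker_task,
                        data._payload_path,
                        other._payload_path if other is not None else None,
                        b,
                        ob,
                        kernel.apply,
                        params,
                        i,
                    )
                    futures[fut] = i
                for fut in as_completed(futures):
                    i = futures[fut]
                    try:
                        idx, res = fut.result()
                    except EngineError:
                        raise
                    except Exception as exc:
                        raise EngineError(
                            f"kernel {kernel.name!r} failed on trial {i}: {exc!r}"
                        ) from exc
                    _write(idx, res)
                _CURRENT_WORKER_PIDS.clear()
    except Exception:
        fout.close()
        if os.path.exists(out_path):
            os.unlink(out_path)
        raise
    fout.close()

    result = kernel.result_factory(out_path, trl)
    return result


# --------------------------------------------------------------------------
# peak-memory benchmark harness
# --------------------------------------------------------------------------

@dataclass
class BenchmarkRecord:
    """One profiled run of one algorithm on one synthetic dataset size."""

    algorithm: str
    n_trials: int
    n_samples: int
    n_channels: int
    run: int
    peak_mb: float
    baseline_mb: float


def _rss_mb(pid: int) -> float:
    """Resident-set size of a process in MiB, via /proc (Linux)."""
    try:
        with open(f"/proc/{pid}/statm") as fh:
            pages = int(fh.read().split()[1])
        return pages * os.sysconf("SC_PAGE_SIZE") / 2**20
    except (OSError, ValueError):
        return 0.0


class _PeakSampler:
    """Background thread sampling RSS of the submitting process and any
    active pool workers at ~200 Hz; records the highest value seen."""

    def __init__(self, interval: float = 0.005):
        self.interval = interval
        self.peak = 0.0
        self._stop = threading.Event()
        self._thread = threading.Thread(target=self._run, daemon=True)

    def _run(self):
        me = os.getpid()
        while not self._stop.is_set():
            val = _rss_mb(me)
            for pid in list(_CURRENT_WORKER_PIDS):
                val = max(val, _rss_mb(pid))
            self.peak = max(self.peak, val)
            _time.sleep(self.interval)

    def __enter__(self):
        if not os.path.exists("/proc/self/statm"):
            raise CapabilityError("RSS profiling requires a /proc filesystem")
        self._thread.start()
        return self

    def __exit__(self, *exc):
        self._stop.set()
        self._thread.join()
        return False


def _pipeline_butterworth_hilbert(data, plan):
    from . import preprocessing

    filt = preprocessing.iir_filter(
        data, preprocessing.FilterSpec("lowpass", 100.0, order=4, direction="zerophase"),
        plan=plan,
    )
    return preprocessing.analytic_signal(filt, output="envelope", plan=plan)


def _pipeline_mtmfft(data, plan):
    from . import spectral

    return spectral.mtmfft(data, taper="dpss", tapsmofrq=2.0, plan=plan)


def _pipeline_mtmfft_ft(data, plan):
    from . import spectral

    return spectral.mtmfft(data, taper="hann", plan=plan)


def _pipeline_wavelet(data, plan):
    from . import spectral

    freqs = np.linspace(2, 80, 40)
    return spectral.wavelet_cwt(data, freqs=freqs, width=6.0, output="pow", plan=plan)


def _pipeline_coherence(data, plan):
    from . import connectivity

    return connectivity.coherence(data, plan=plan)


BENCHMARK_ALGORITHMS = {
    "butterworth_hilbert": _pipeline_butterworth_hilbert,
    "mtmfft": _pipeline_mtmfft,
    "mtmfft_ft": _pipeline_mtmfft_ft,
    "wavelet": _pipeline_wavelet,
    "coherence": _pipeline_coherence,
}


def memory_benchmark(
    algorithm: str,
    grid: Iterable[tuple],
    runs: int = 20,
    plan: Optional[ExecutionPlan] = None,
    samplerate: float = 1000.0,
    seed: int = 42,
    isolate: bool = True,
) -> list:
    """Profile peak memory consumption of a registered pipeline.

    For every ``(n_trials, n_samples, n_channels)`` grid point a fresh
    synthetic white-noise dataset is generated and the pipeline executed
    ``runs`` times; each run records the PMC (max RSS over submitting
    process and workers) and the pre-run baseline RSS.  The garbage
    collector is forced between runs so measurements are comparable.

    With ``isolate=True`` (default) every grid point is measured in a fresh
    Python subprocess, so heap pages left mapped by unrelated prior work
    cannot mask the pipeline's own footprint.
    """
    if algorithm not in BENCHMARK_ALGORITHMS:
        raise EngineError(
            f"unknown benchmark algorithm {algorithm!r}; "
            f"registered: {sorted(BENCHMARK_ALGORITHMS)}"
        )
    plan = plan or ExecutionPlan()
    if isolate:
        return _isolated_benchmark(algorithm, grid, runs, plan, samplerate, seed)
    from . import synthdata
    pipeline = BENCHMARK_ALGORITHMS[algorithm]
    records = []
    for (n_trials, n_samples, n_channels) in grid:
        spec = synthdata.GeneratorSpec(
            n_trials=int(n_trials),
            n_samples=int(n_samples),
            n_channels=int(n_channels),
            samplerate=samplerate,
            seed=seed,
        )
        data = synthdata.white_noise(spec)
        for run in range(runs):
            gc.collect()
            baseline = _rss_mb(os.getpid())
            with _PeakSampler() as sampler:
                out = pipeline(data, plan)
            out.close()
            del out
            gc.collect()
            records.append(
                BenchmarkRecord(
                    algorithm=algorithm,
                    n_trials=int(n_trials),
                    n_samples=int(n_samples),
                    n_channels=int(n_channels),
                    run=run,
                    peak_mb=sampler.peak,
                    baseline_mb=baseline,
                )
            )
        data.close()
        del data
        gc.collect()
    return records


_BENCH_DRIVER = """
import json, sys
from ephystream.engine import memory_benchmark
cfg = json.loads(sys.stdin.read())
from ephystream.engine import ExecutionPlan
plan = ExecutionPlan(**cfg["plan"])
recs = memory_benchmark(cfg["algorithm"], [tuple(cfg["point"])], runs=cfg["runs"],
                        plan=plan, samplerate=cfg["samplerate"], seed=cfg["seed"],
                        isolate=False)
print(json.dumps([vars(r) for r in recs]))
"""


def _isolated_benchmark(algorithm, grid, runs, plan, samplerate, seed):
    import json
    import subprocess
    import sys

    records = []
    for point in grid:
        cfg = {
            "algorithm": algorithm,
            "point": [int(v) for v in point],
            "runs": int(runs),
            "plan": {
                "backend": plan.backend,
                "n_workers": plan.n_workers,
                "scheduler_address": plan.scheduler_address,
            },
            "samplerate": float(samplerate),
            "seed": int(seed),
        }
        proc = subprocess.run(
            [sys.executable, "-c", _BENCH_DRIVER],
            input=json.dumps(cfg),
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise EngineError(
                f"isolated benchmark subprocess failed for {point}: "
                f"{proc.stderr.strip()[-500:]}"
            )
        for row in json.loads(proc.stdout.strip().splitlines()[-1]):
            records.append(BenchmarkRecord(**row))
    return records


def write_benchmark_csv(records: Sequence[BenchmarkRecord], path: str) -> None:
    cols = ["algorithm", "n_trials", "n_samples", "n_channels", "run", "peak_mb", "baseline_mb"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in records:
            writer.writerow([getattr(r, c) for c in cols])
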