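"""Trial-based, disk-backed data containers.

All containers in this module keep their numeric payload in an HDF5 file on
disk and only ever load single trials into memory.  A *trial definition* — an
integer array with one ``[start, stop, offset]`` row per trial — carves trials
out of the payload's first axis: trial ``i`` occupies the half-open row range
``[start_i, stop_i)`` and sample ``k`` of that trial sits at time
``(offset_i + k) / samplerate`` seconds, so ``offset`` places the trial's
``t = 0`` event (e.g. stimulus onset).  Rows may overlap: re-using payload
segments in several trials is legal.

Container classes
-----------------
``AnalogData``
    Regularly sampled multi-channel signal, payload ``(total_samples,
    n_channels)`` single-precision float.  The raw-data currency.
``TimeLockData``
    ``AnalogData`` whose trials all share one length and offset (identical
    time axes), as produced by a latency selection.
``SpectralData``
    Per-trial spectral estimates ``(n_time, n_tapers, n_freqs, n_channels)``,
    complex (``output="fourier"``) or real non-negative (``output="pow"``);
    trials are stacked along the time axis.
``CrossSpectralData``
    Channel-pair values ``(n_time, n_freqs, n_channels, n_channels)``;
    complex for cross-spectral densities, real for derived measures.  Also
    reused with a lag axis for cross-correlograms.
``SpikeData`` / ``EventData``
    Time-discrete tables ``(sample, channel, unit)`` / ``(sample, code)``
    sorted by sample index, with the same trial-definition semantics.

On-disk format
--------------
``save_dataset`` writes the payload to ``<name>.h5`` (one main HDF5 dataset
called ``"data"``, chunked for trialwise streaming) and all metadata to a
``<name>.json`` sidecar (format version ``"1.0"``).  The JSON header is the
single source of truth for metadata; the HDF5 file only carries a UUID
cross-reference attribute.  ``load_dataset`` reconstructs the container
without touching the payload.

Every public operation appends one entry to the container's processing log,
so any dataset carries the full provenance of the chain that produced it.
"""

from __future__ import annotations

import atexit
import datetime
import json
import numbers
import os
import shutil
import tempfile
import uuid as _uuid
import warnings
import weakref
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, Union

import h5py
import numpy as np

from .errors import (
    BoundsError,
    FormatError,
    IncompatibilityError,
    SelectionError,
    StateError,
    ValidationError,
    VersionError,
)

FORMAT_VERSION = "1.0"

__all__ = [
    "AnalogData",
    "TimeLockData",
    "SpectralData",
    "CrossSpectralData",
    "SpikeData",
    "EventData",
    "Selection",
    "apply_selection",
    "attach_trialdefinition",
    "dataset_arithmetic",
    "from_trial_source",
    "save_dataset",
    "load_dataset",
    "FORMAT_VERSION",
]


# --------------------------------------------------------------------------
# spool management: scratch payloads live in a per-process spool directory
# --------------------------------------------------------------------------

_SPOOL: Optional[str] = None


def spool_dir() -> str:
    """Directory where intermediate payload files are written.

    Defaults to a fresh temporary directory per process; override with the
    ``EPHYSTREAM_TMPDIR`` environment variable (e.g. to point at fast local
    storage on a cluster node).  The default spool is removed at exit.
    """
    global _SPOOL
    if _SPOOL is None:
        base = os.environ.get("EPHYSTREAM_TMPDIR")
        if base:
            os.makedirs(base, exist_ok=True)
            _SPOOL = tempfile.mkdtemp(prefix="ephystream-", dir=base)
        else:
            _SPOOL = tempfile.mkdtemp(prefix="ephystream-")
        atexit.register(shutil.rmtree, _SPOOL, True)
    return _SPOOL


def new_payload_path(tag: str = "data") -> str:
    return os.path.join(spool_dir(), f"{tag}-{_uuid.uuid4().hex}.h5")


_SLAB_BYTES = 4 * 2**20  # target chunk size within long trials


def _auto_chunks(shape, itemsize, trial_len=None):
    """One-trial (or <=4 MB slab) chunking along the stacking axis."""
    if len(shape) == 0 or shape[0] == 0 or any(s == 0 for s in shape):
        return None
    row_bytes = itemsize * int(np.prod(shape[1:], dtype=np.int64))
    rows = max(1, _SLAB_BYTES // max(row_bytes, 1))
    if trial_len is not None:
        rows = min(rows, max(1, int(trial_len)))
    rows = min(rows, shape[0])
    return (rows,) + tuple(shape[1:])


def _iter_slabs(n_rows: int, rows_per_slab: int) -> Iterator[slice]:
    for lo in range(0, n_rows, rows_per_slab):
        yield slice(lo, min(lo + rows_per_slab, n_rows))


def _copy_dataset(src: h5py.Dataset, dst: h5py.Dataset) -> None:
    """Stream ``src`` into ``dst`` slab by slab (never whole-payload)."""
    row_bytes = src.dtype.itemsize * int(np.prod(src.shape[1:], dtype=np.int64))
    rows = max(1, _SLAB_BYTES // max(row_bytes, 1))
    for sl in _iter_slabs(src.shape[0], rows):
        dst[sl] = src[sl]


def _h5open(path: str, mode: str) -> h5py.File:
    # locking off: the engine has multiple processes read disjoint regions
    return h5py.File(path, mode, locking=False)


# --------------------------------------------------------------------------
# trial definitions
# --------------------------------------------------------------------------

def validate_trialdefinition(trl, total_samples: int) -> np.ndarray:
    """Validate and canonicalize a ``[start, stop, offset]`` row array."""
    arr = np.asarray(trl)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValidationError(
            f"trial definition must be (n_trials, 3) [start, stop, offset]; got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("trial definition entries must be integers")
        arr = np.round(arr).astype(np.int64)
    arr = arr.astype(np.int64)
    for i, (start, stop, _off) in enumerate(arr):
        if start >= stop:
            raise ValidationError(
                f"trial definition row {i}: start ({start}) must be < stop ({stop})"
            )
        if start < 0 or stop > total_samples:
            raise BoundsError(
                f"trial definition row {i} ([{start}, {stop})) exceeds payload "
                f"bounds [0, {total_samples})"
            )
    return arr


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays so json.dumps accepts them."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.complexfloating,)):
        return [float(obj.real), float(obj.imag)]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# --------------------------------------------------------------------------
# base container
# --------------------------------------------------------------------------

class BaseData:
    """Common disk-backed container machinery (payload, log, trials)."""

    _dimord: tuple = ()
    _class_name: str = "BaseData"

    def __init__(
        self,
        payload_path: str,
        samplerate: float,
        channels: Sequence[str],
        trialdefinition=None,
        log: Optional[list] = None,
        dataset_uuid: Optional[str] = None,
        _owns_payload: bool = True,
    ):
        if samplerate is not None and not samplerate > 0:
            raise ValidationError(f"samplerate must be > 0 Hz, got {samplerate}")
        channels = [str(c) for c in channels]
        if len(set(channels)) != len(channels):
            raise ValidationError("channel labels must be unique")
        self._payload_path = payload_path
        self._file: Optional[h5py.File] = None
        self._mode = "r"
        self.samplerate = float(samplerate) if samplerate is not None else None
        self.channels = channels
        self.log: list = list(log) if log else []
        self.uuid = dataset_uuid or _uuid.uuid4().hex
        self._trialdefinition: Optional[np.ndarray] = None
        if trialdefinition is not None:
            self._set_trialdefinition(trialdefinition)
        if _owns_payload:
            self._finalizer = weakref.finalize(self, _maybe_unlink, payload_path)
        else:
            self._finalizer = None

    # -- payload access ---------------------------------------------------

    @property
    def filename(self) -> str:
        """Path of the HDF5 payload file backing this container."""
        return self._payload_path

    @property
    def data(self) -> h5py.Dataset:
        """The on-disk payload as an h5py dataset (lazy, never fully loaded)."""
        if self._file is None or not self._file.id.valid:
            self._file = _h5open(self._payload_path, self._mode)
        return self._file["data"]

    def close(self) -> None:
        if self._file is not None and self._file.id.valid:
            self._file.close()
        self._file = None

    def flush(self) -> None:
        if self._file is not None and self._file.id.valid:
            self._file.flush()

    @property
    def dtype(self) -> np.dtype:
        return self.data.dtype

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def dimord(self) -> tuple:
        return self._dimord

    # -- trials -----------------------------------------------------------

    def _payload_extent(self) -> int:
        return self.data.shape[0]

    def _set_trialdefinition(self, trl) -> None:
        self._trialdefinition = validate_trialdefinition(trl, self._payload_extent())

    @property
    def trialdefinition(self) -> Optional[np.ndarray]:
        return None if self._trialdefinition is None else self._trialdefinition.copy()

    @property
    def n_trials(self) -> int:
        self._require_trials()
        return len(self._trialdefinition)

    def _require_trials(self) -> None:
        if self._trialdefinition is None:
            raise StateError(
                f"{self._class_name} has no trial definition attached; "
                "use attach_trialdefinition() first"
            )

    def trial(self, i: int) -> np.ndarray:
        """Load trial ``i`` into memory as a NumPy array."""
        self._require_trials()
        start, stop, _ = self._trial_row(i)
        return self.data[start:stop]

    def _trial_row(self, i: int):
        n = self.n_trials
        if not -n <= i < n:
            raise BoundsError(f"trial index {i} out of range for {n} trials")
        return tuple(int(v) for v in self._trialdefinition[i])

    @property
    def trials(self) -> Iterator[np.ndarray]:
        for i in range(self.n_trials):
            yield self.trial(i)

    def trial_shape(self, i: int) -> tuple:
        start, stop, _ = self._trial_row(i)
        return (stop - start,) + tuple(self.data.shape[1:])

    def time(self, i: int = 0) -> np.ndarray:
        """Time axis (seconds) of trial ``i``: ``(offset + k) / samplerate``."""
        start, stop, off = self._trial_row(i)
        return (off + np.arange(stop - start)) / self.samplerate

    # -- provenance -------------------------------------------------------

    def log_entry(self, operation: str, **params) -> None:
        """Append one processing-history entry (never deleted)."""
        self.log.append(
            {
                "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
                "operation": operation,
                "params": _jsonable(params),
            }
        )

    # -- header / serialization ------------------------------------------

    def _extra_header(self) -> dict:
        return {}

    def header(self, payload_name: Optional[str] = None) -> dict:
        h = {
            "format_version": FORMAT_VERSION,
            "data_class": self._class_name,
            "dimord": list(self._dimord),
            "dtype": str(self.dtype),
            "shape": list(self.shape),
            "samplerate": self.samplerate,
            "channels": list(self.channels),
            "trialdefinition": _jsonable(self._trialdefinition)
            if self._trialdefinition is not None
            else None,
            "log": _jsonable(self.log),
            "uuid": self.uuid,
            "payload": payload_name or os.path.basename(self._payload_path),
        }
        h.update(_jsonable(self._extra_header()))
        return h

    # -- construction helpers --------------------------------------------

    @classmethod
    def _allocate(cls, shape, dtype, trial_len=None, tag=None) -> str:
        """Create an empty payload file of the given shape; return its path."""
        path = new_payload_path(tag or cls._class_name.lower())
        with _h5open(path, "w") as f:
            f.create_dataset(
                "data",
                shape=shape,
                dtype=dtype,
                chunks=_auto_chunks(shape, np.dtype(dtype).itemsize, trial_len),
            )
        return path

    def _writable(self) -> "BaseData":
        """Reopen the payload read-write (used internally while filling)."""
        self.close()
        self._mode = "r+"
        return self

    def _readonly(self) -> "BaseData":
        self.close()
        self._mode = "r"
        return self

    def __repr__(self) -> str:
        trl = len(self._trialdefinition) if self._trialdefinition is not None else 0
        return (
            f"<{self._class_name}: shape {tuple(self.shape)}, dtype {self.dtype}, "
            f"{trl} trials, fs={self.samplerate} Hz, {len(self.channels)} channels>"
        )

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        return dataset_arithmetic(self, other, "+")

    def __sub__(self, other):
        return dataset_arithmetic(self, other, "-")

    def __mul__(self, other):
        return dataset_arithmetic(self, other, "*")

    def __truediv__(self, other):
        return dataset_arithmetic(self, other, "/")

    __radd__ = __add__
    __rmul__ = __mul__


def _maybe_unlink(path: str) -> None:
    try:
        if path and os.path.dirname(path) == _SPOOL and os.path.exists(path):
            os.unlink(path)
    except OSError:
        pass


# --------------------------------------------------------------------------
# continuous containers
# --------------------------------------------------------------------------

class AnalogData(BaseData):
    """Disk-backed ``(total_samples, n_channels)`` regularly sampled signal."""

    _dimord = ("time", "channel")
    _class_name = "AnalogData"

    def __init__(self, payload_path, samplerate, channels, trialdefinition=None, **kw):
        super().__init__(payload_path, samplerate, channels, trialdefinition, **kw)
        if len(self.data.shape) != 2:
            raise ValidationError(
                f"AnalogData payload must be 2-D (samples, channels); got {self.data.shape}"
            )
        if self.data.shape[1] != len(self.channels):
            raise ValidationError(
                f"payload has {self.data.shape[1]} channels but "
                f"{len(self.channels)} labels were given"
            )

    @classmethod
    def from_array(cls, array, samplerate, channels=None, trialdefinition=None):
        """Build from one in-memory ``(samples, channels)`` array (one trial
        spanning everything unless a trial definition is given)."""
        array = np.atleast_2d(np.asarray(array))
        if array.ndim != 2:
            raise ValidationError("expected a 2-D (samples, channels) array")
        arr = array.astype(np.float32, copy=False)
        if channels is None:
            channels = [f"channel{i + 1}" for i in range(arr.shape[1])]
        path = cls._allocate(arr.shape, np.float32, trial_len=arr.shape[0])
        with _h5open(path, "r+") as f:
            f["data"][...] = arr
        if trialdefinition is None:
            trialdefinition = [[0, arr.shape[0], 0]]
        obj = cls(path, samplerate, channels, trialdefinition)
        obj.log_entry("from_array", samplerate=samplerate, shape=list(arr.shape))
        return obj

    @classmethod
    def from_trials(cls, trials, samplerate, channels=None, offsets=None):
        """See :func:`from_trial_source`."""
        return from_trial_source(trials, samplerate, channels=channels, offsets=offsets, cls=cls)

    def as_timelock(self) -> "TimeLockData":
        """Reinterpret as time-locked data (all trials must share one time axis)."""
        self._require_trials()
        trl = self._trialdefinition
        lengths = trl[:, 1] - trl[:, 0]
        if len(set(lengths.tolist())) != 1 or len(set(trl[:, 2].tolist())) != 1:
            raise ValidationError(
                "trials are not time-locked: unequal lengths or offsets "
                "(apply a latency selection first)"
            )
        out = TimeLockData(
            self._payload_path, self.samplerate, self.channels, trl,
            log=self.log, _owns_payload=False,
        )
        out.log_entry("as_timelock")
        return out


class TimeLockData(AnalogData):
    """AnalogData whose trials all share one length and one offset.

    Optionally caches the across-trial average and variance (computed on
    demand, streamed one trial at a time)."""

    _class_name = "TimeLockData"

    def __init__(self, *args, **kw):
        super().__init__(*args, **kw)
        if self._trialdefinition is not None:
            trl = self._trialdefinition
            lengths = set((trl[:, 1] - trl[:, 0]).tolist())
            offs = set(trl[:, 2].tolist())
            if len(lengths) != 1 or len(offs) != 1:
                raise ValidationError("TimeLockData trials must share length and offset")
        self._avg = None
        self._var = None

    @property
    def trial_length(self) -> int:
        return int(self._trialdefinition[0, 1] - self._trialdefinition[0, 0])

    def avg(self) -> np.ndarray:
        """Across-trial mean (samples × channels), cached."""
        if self._avg is None:
            acc = np.zeros(self.trial_shape(0), dtype=np.float64)
            for tr in self.trials:
                acc += tr
            self._avg = (acc / self.n_trials).astype(np.float32)
        return self._avg

    def var(self) -> np.ndarray:
        """Across-trial variance (unbiased), cached."""
        if self._var is None:
            n = self.n_trials
            mean = self.avg().astype(np.float64)
            acc = np.zeros_like(mean)
            for tr in self.trials:
                acc += (tr - mean) ** 2
            self._var = (acc / max(n - 1, 1)).astype(np.float32)
        return self._var


class SpectralData(BaseData):
    """Per-trial ``(time, taper, freq, channel)`` spectral estimates."""

    _dimord = ("time", "taper", "freq", "channel")
    _class_name = "SpectralData"

    def __init__(
        self,
        payload_path,
        samplerate,
        channels,
        trialdefinition=None,
        freqs=None,
        time_vector=None,
        taper=None,
        output="pow",
        **kw,
    ):
        super().__init__(payload_path, samplerate, channels, trialdefinition, **kw)
        if len(self.data.shape) != 4:
            raise ValidationError("SpectralData payload must be 4-D (time, taper, freq, channel)")
        self.freqs = np.asarray(freqs, dtype=float) if freqs is not None else None
        if self.freqs is not None:
            if np.any(np.diff(self.freqs) <= 0):
                raise ValidationError("frequency axis must be strictly ascending")
            if self.samplerate and (self.freqs[0] < 0 or self.freqs[-1] > self.samplerate / 2 + 1e-9):
                raise ValidationError("frequencies must lie in [0, samplerate/2]")
        self.time_vector = (
            np.asarray(time_vector, dtype=float) if time_vector is not None else None
        )
        self.taper = dict(taper) if taper else None
        self.output = output

    @property
    def n_tapers(self) -> int:
        return self.data.shape[1]

    def _extra_header(self) -> dict:
        return {
            "freqs": self.freqs,
            "time": self.time_vector,
            "taper": self.taper,
            "output": self.output,
        }


class CrossSpectralData(BaseData):
    """``(time, freq, channel, channel)`` channel-pair values.

    ``measure`` tags the quantity ("csd", "coherence", "ppc", "granger",
    "xcorr"); for cross-correlograms the frequency axis is reused as a lag
    axis in seconds (``lags`` is then set instead of ``freqs``).
    """

    _dimord = ("time", "freq", "channel", "channel")
    _class_name = "CrossSpectralData"

    def __init__(
        self,
        payload_path,
        samplerate,
        channels,
        trialdefinition=None,
        freqs=None,
        time_vector=None,
        measure="csd",
        trial_averaged=True,
        lags=None,
        **kw,
    ):
        super().__init__(payload_path, samplerate, channels, trialdefinition, **kw)
        if len(self.data.shape) != 4:
            raise ValidationError(
                "CrossSpectralData payload must be 4-D (time, freq, channel, channel)"
            )
        if self.data.shape[2] != self.data.shape[3] or self.data.shape[2] != len(self.channels):
            raise ValidationError("channel axes must be square and match the labels")
        self.freqs = np.asarray(freqs, dtype=float) if freqs is not None else None
        self.lags = np.asarray(lags, dtype=float) if lags is not None else None
        self.time_vector = (
            np.asarray(time_vector, dtype=float) if time_vector is not None else None
        )
        self.measure = measure
        self.trial_averaged = bool(trial_averaged)

    def _extra_header(self) -> dict:
        return {
            "freqs": self.freqs,
            "lags": self.lags,
            "time": self.time_vector,
            "measure": self.measure,
            "trial_averaged": self.trial_averaged,
        }


# --------------------------------------------------------------------------
# discrete containers
# --------------------------------------------------------------------------

class SpikeData(BaseData):
    """Ordered ``(sample, channel, unit)`` spike table, optional waveforms."""

    _dimord = ("spike", "field")
    _class_name = "SpikeData"

    def __init__(self, payload_path, samplerate, channels=None, trialdefinition=None, **kw):
        kw.setdefault("log", None)
        super().__init__(
            payload_path,
            samplerate,
            channels if channels is not None else [],
            None,
            **kw,
        )
        if len(self.data.shape) != 2 or self.data.shape[1] != 3:
            raise ValidationError("SpikeData payload must be (n_spikes, 3)")
        samples = self.data[:, 0]
        if np.any(np.diff(samples) < 0):
            raise ValidationError("spike samples must be non-decreasing")
        with _h5open(self._payload_path, "r") as f:
            if "waveforms" in f and f["waveforms"].shape[0] != self.data.shape[0]:
                raise ValidationError("waveform row count must equal spike count")
        if trialdefinition is not None:
            self._set_trialdefinition(trialdefinition)

    @classmethod
    def from_array(cls, spikes, samplerate, trialdefinition=None, waveforms=None):
        spikes = np.asarray(spikes, dtype=np.int64)
        if spikes.ndim != 2 or spikes.shape[1] != 3:
            raise ValidationError("expected an (n_spikes, 3) [sample, channel, unit] array")
        order = np.argsort(spikes[:, 0], kind="stable")
        spikes = spikes[order]
        path = new_payload_path("spikedata")
        with _h5open(path, "w") as f:
            f.create_dataset("data", data=spikes)
            if waveforms is not None:
                wf = np.asarray(waveforms, dtype=np.float32)[order]
                f.create_dataset("waveforms", data=wf)
        obj = cls(path, samplerate, trialdefinition=trialdefinition)
        obj.log_entry("from_array", n_spikes=int(spikes.shape[0]))
        return obj

    # trialdefinition indexes the recording timeline, not table rows
    def _payload_extent(self) -> int:
        if self.data.shape[0] == 0:
            return np.iinfo(np.int64).max
        return int(self.data[-1, 0]) + 1

    def _set_trialdefinition(self, trl) -> None:
        arr = np.asarray(trl)
        self._trialdefinition = validate_trialdefinition(arr, max(
            self._payload_extent(), int(np.asarray(arr)[:, 1].max()) if len(arr) else 0
        ))

    def trial(self, i: int) -> np.ndarray:
        """Spike rows of trial ``i`` (sample, channel, unit)."""
        start, stop, _ = self._trial_row(i)
        samples = self.data[:, 0]
        lo = np.searchsorted(samples, start, side="left")
        hi = np.searchsorted(samples, stop, side="left")
        return self.data[lo:hi]

    def trial_times(self, i: int) -> np.ndarray:
        """Spike times of trial ``i`` in seconds relative to the trial's t=0."""
        start, _stop, off = self._trial_row(i)
        rows = self.trial(i)
        return (rows[:, 0] - start + off) / self.samplerate

    def time_window(self, i: int) -> tuple:
        """(t_start, t_end) of trial ``i`` in seconds relative to its t=0."""
        start, stop, off = self._trial_row(i)
        return off / self.samplerate, (off + stop - start) / self.samplerate

    @property
    def waveforms(self) -> Optional[h5py.Dataset]:
        if self._file is None or not self._file.id.valid:
            self._file = _h5open(self._payload_path, self._mode)
        return self._file.get("waveforms")

    @property
    def units(self) -> np.ndarray:
        return np.unique(self.data[:, 2]) if self.data.shape[0] else np.array([], dtype=np.int64)

    def time(self, i: int = 0) -> np.ndarray:  # pragma: no cover - not meaningful
        raise StateError("SpikeData has no dense time axis; use trial_times()")


class EventData(BaseData):
    """Ordered ``(sample, code)`` event table."""

    _dimord = ("event", "field")
    _class_name = "EventData"

    def __init__(self, payload_path, samplerate, **kw):
        super().__init__(payload_path, samplerate, [], None, **kw)
        if len(self.data.shape) != 2 or self.data.shape[1] != 2:
            raise ValidationError("EventData payload must be (n_events, 2)")
        if np.any(np.diff(self.data[:, 0]) < 0):
            raise ValidationError("event samples must be non-decreasing")

    @classmethod
    def from_array(cls, events, samplerate):
        events = np.asarray(events, dtype=np.int64)
        order = np.argsort(events[:, 0], kind="stable")
        path = new_payload_path("eventdata")
        with _h5open(path, "w") as f:
            f.create_dataset("data", data=events[order])
        obj = cls(path, samplerate)
        obj.log_entry("from_array", n_events=int(events.shape[0]))
        return obj


_CLASSES = {
    c._class_name: c
    for c in (AnalogData, TimeLockData, SpectralData, CrossSpectralData, SpikeData, EventData)
}


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def attach_trialdefinition(data: BaseData, trialdefinition) -> BaseData:
    """Attach (or replace) the trial definition of ``data`` in place."""
    data._set_trialdefinition(trialdefinition)
    data.log_entry("attach_trialdefinition", n_trials=len(data._trialdefinition))
    return data


def from_trial_source(trials, samplerate, channels=None, offsets=None, cls=AnalogData):
    """Build an :class:`AnalogData` from a sequence *or generator* of
    per-trial ``(samples, channels)`` arrays.

    Trials are appended to disk one at a time, so peak memory stays
    proportional to a single trial regardless of how many trials the source
    yields.  Trial-definition rows are consecutive with offset 0 unless
    ``offsets`` (one int per trial) is given.
    """
    path = new_payload_path("analogdata")
    trl_rows = []
    n_channels = None
    cursor = 0
    f = _h5open(path, "w")
    try:
        dset = None
        for i, trial in enumerate(trials):
            arr = np.atleast_2d(np.asarray(trial, dtype=np.float32))
            if n_channels is None:
                n_channels = arr.shape[1]
                dset = f.create_dataset(
                    "data",
                    shape=(0, n_channels),
                    maxshape=(None, n_channels),
                    dtype=np.float32,
                    chunks=_auto_chunks(arr.shape, 4, trial_len=arr.shape[0]),
                )
            if arr.shape[1] != n_channels:
                raise ValidationError(
                    f"trial {i} has {arr.shape[1]} channels, expected {n_channels}"
                )
            dset.resize(cursor + arr.shape[0], axis=0)
            dset[cursor : cursor + arr.shape[0]] = arr
            off = int(offsets[i]) if offsets is not None else 0
            trl_rows.append([cursor, cursor + arr.shape[0], off])
            cursor += arr.shape[0]
        if dset is None:
            raise ValidationError("trial source yielded no trials")
    except Exception:
        f.close()
        if os.path.exists(path):
            os.unlink(path)
        raise
    f.close()
    if channels is None:
        channels = [f"channel{i + 1}" for i in range(n_channels)]
    obj = cls(path, samplerate, channels, trl_rows)
    obj.log_entry("from_trial_source", n_trials=len(trl_rows), samplerate=samplerate)
    return obj


# -- selections ------------------------------------------------------------

@dataclass
class Selection:
    """Subset specification: trials, channels, latency window, frequencies.

    ``None`` fields mean "keep everything".  ``latency`` is an inclusive
    ``[t_min, t_max]`` window in seconds relative to each trial's t=0;
    ``frequencies`` an inclusive ``[f_min, f_max]`` in Hz.
    """

    trials: Optional[Sequence[int]] = None
    channels: Optional[Sequence] = None
    latency: Optional[Sequence[float]] = None
    frequencies: Optional[Sequence[float]] = None

    def __post_init__(self):
        if self.latency is not None:
            lo, hi = self.latency
            if lo > hi:
                raise SelectionError(f"latency window reversed: [{lo}, {hi}]")
        if self.frequencies is not None:
            lo, hi = self.frequencies
            if lo > hi:
                raise SelectionError(f"frequency window reversed: [{lo}, {hi}]")


def _resolve_channels(sel_channels, labels):
    idx = []
    for c in sel_channels:
        if isinstance(c, numbers.Integral) and not isinstance(c, bool):
            if not 0 <= int(c) < len(labels):
                raise SelectionError(f"channel index {c} out of range (have {len(labels)})")
            idx.append(int(c))
        else:
            if str(c) not in labels:
                raise SelectionError(
                    f"channel label {c!r} not found; available: {labels}"
                )
            idx.append(labels.index(str(c)))
    if not idx:
        raise SelectionError("channel selection is empty")
    return idx


def apply_selection(data: BaseData, sel: Selection) -> BaseData:
    """Materialize a new disk-backed dataset holding only the selection.

    Time axes are preserved relative to each trial's t=0 (offsets are
    rewritten), and an empty intersection raises a :class:`SelectionError`
    naming the criterion that emptied it.
    """
    if isinstance(data, (AnalogData,)):
        return _select_continuous(data, sel)
    if isinstance(data, SpectralData):
        return _select_spectral(data, sel)
    if isinstance(data, SpikeData):
        return _select_spikes(data, sel)
    raise SelectionError(f"selections not supported for {type(data).__name__}")


def _sel_trials(data, sel):
    data._require_trials()
    if sel.trials is None:
        return list(range(data.n_trials))
    out = []
    for t in sel.trials:
        if not 0 <= int(t) < data.n_trials:
            raise SelectionError(f"trial index {t} out of range (have {data.n_trials})")
        out.append(int(t))
    if not out:
        raise SelectionError("trial selection is empty")
    return out


def _latency_rows(start, stop, off, fs, latency):
    """Row sub-range of one trial covered by an inclusive latency window."""
    n = stop - start
    k = np.arange(n)
    t = (off + k) / fs
    keep = np.flatnonzero((t >= latency[0] - 1e-12) & (t <= latency[1] + 1e-12))
    if keep.size == 0:
        return None
    return int(keep[0]), int(keep[-1]) + 1


def _select_continuous(data: AnalogData, sel: Selection) -> AnalogData:
    tr_idx = _sel_trials(data, sel)
    ch_idx = (
        _resolve_channels(sel.channels, data.channels)
        if sel.channels is not None
        else list(range(len(data.channels)))
    )
    pieces = []
    for t in tr_idx:
        start, stop, off = data._trial_row(t)
        lo, hi = 0, stop - start
        new_off = off
        if sel.latency is not None:
            rng = _latency_rows(start, stop, off, data.samplerate, sel.latency)
            if rng is None:
                raise SelectionError(
                    f"latency window {list(sel.latency)} empties trial {t}"
                )
            lo, hi = rng
            new_off = off + lo
        pieces.append((t, start + lo, start + hi, new_off))
    cls = AnalogData if not isinstance(data, TimeLockData) else TimeLockData
    total = sum(p[2] - p[1] for p in pieces)
    path = cls._allocate((total, len(ch_idx)), data.dtype, trial_len=pieces[0][2] - pieces[0][1])
    trl = []
    cursor = 0
    with _h5open(path, "r+") as f:
        dset = f["data"]
        for _t, lo, hi, off in pieces:
            block = data.data[lo:hi][:, ch_idx]
            dset[cursor : cursor + (hi - lo)] = block
            trl.append([cursor, cursor + (hi - lo), off])
            cursor += hi - lo
    try:
        out = cls(path, data.samplerate, [data.channels[i] for i in ch_idx], trl, log=data.log)
    except ValidationError:
        # a latency/trial subset may break time-locking; fall back to AnalogData
        out = AnalogData(path, data.samplerate, [data.channels[i] for i in ch_idx], trl,
                         log=data.log)
    out.log_entry(
        "apply_selection",
        trials=tr_idx if sel.trials is not None else "all",
        channels=[data.channels[i] for i in ch_idx] if sel.channels is not None else "all",
        latency=list(sel.latency) if sel.latency is not None else "all",
    )
    return out


def _select_spectral(data: SpectralData, sel: Selection) -> SpectralData:
    tr_idx = _sel_trials(data, sel)
    ch_idx = (
        _resolve_channels(sel.channels, data.channels)
        if sel.channels is not None
        else list(range(len(data.channels)))
    )
    f_idx = np.arange(len(data.freqs))
    if sel.frequencies is not None:
        f_idx = np.flatnonzero(
            (data.freqs >= sel.frequencies[0] - 1e-12)
            & (data.freqs <= sel.frequencies[1] + 1e-12)
        )
        if f_idx.size == 0:
            raise SelectionError(f"frequency window {list(sel.frequencies)} selects no bins")
    t_keep = None
    if sel.latency is not None and data.time_vector is not None:
        t_keep = np.flatnonzero(
            (data.time_vector >= sel.latency[0] - 1e-12)
            & (data.time_vector <= sel.latency[1] + 1e-12)
        )
        if t_keep.size == 0:
            raise SelectionError(f"latency window {list(sel.latency)} selects no time bins")
    rows_per_trial = None
    pieces = []
    for t in tr_idx:
        start, stop, off = data._trial_row(t)
        if t_keep is not None:
            rows = (start + int(t_keep[0]), start + int(t_keep[-1]) + 1, off)
        else:
            rows = (start, stop, off)
        pieces.append(rows)
        rows_per_trial = rows[1] - rows[0]
    total = sum(p[1] - p[0] for p in pieces)
    shape = (total, data.data.shape[1], len(f_idx), len(ch_idx))
    path = SpectralData._allocate(shape, data.dtype, trial_len=rows_per_trial)
    trl = []
    cursor = 0
    with _h5open(path, "r+") as f:
        dset = f["data"]
        for lo, hi, off in pieces:
            block = data.data[lo:hi][:, :, f_idx][..., ch_idx]
            dset[cursor : cursor + (hi - lo)] = block
            trl.append([cursor, cursor + (hi - lo), off])
            cursor += hi - lo
    out = SpectralData(
        path,
        data.samplerate,
        [data.channels[i] for i in ch_idx],
        trl,
        freqs=data.freqs[f_idx],
        time_vector=data.time_vector[t_keep] if t_keep is not None else data.time_vector,
        taper=data.taper,
        output=data.output,
        log=data.log,
    )
    out.log_entry("apply_selection", frequencies=_jsonable(sel.frequencies))
    return out


def _select_spikes(data: SpikeData, sel: Selection) -> SpikeData:
    tr_idx = _sel_trials(data, sel)
    rows = []
    trl = []
    cursor_guard = 0
    for t in tr_idx:
        start, stop, off = data._trial_row(t)
        block = data.trial(t)
        if sel.latency is not None:
            times = (block[:, 0] - start + off) / data.samplerate
            block = block[(times >= sel.latency[0] - 1e-12) & (times <= sel.latency[1] + 1e-12)]
        if sel.channels is not None:
            wanted = set(int(c) for c in sel.channels)
            block = block[np.isin(block[:, 1], list(wanted))]
        rows.append(block)
        trl.append([start, stop, off])
        cursor_guard += len(block)
    if cursor_guard == 0:
        raise SelectionError("selection removed every spike")
    table = np.vstack(rows) if rows else np.empty((0, 3), np.int64)
    out = SpikeData.from_array(table, data.samplerate, trialdefinition=trl)
    out.log = list(data.log) + out.log
    out.log_entry("apply_selection")
    return out


# -- arithmetic ------------------------------------------------------------

_OPS = {
    "+": np.add,
    "-": np.subtract,
    "*": np.multiply,
    "/": np.divide,
}


def dataset_arithmetic(a: BaseData, b, op: str):
    """Elementwise ``a op b`` computed trial by trial, never whole-payload.

    ``b`` may be a scalar or a dataset of identical class, shape and trial
    structure.  Division follows IEEE semantics (inf/nan) with a warning.
    """
    if op not in _OPS:
        raise ValueError(f"unknown operation {op!r}")
    if isinstance(a, (SpikeData, EventData)):
        raise IncompatibilityError("arithmetic is defined for continuous containers only")
    scalar = isinstance(b, numbers.Number)
    if not scalar:
        if type(b) is not type(a):
            raise IncompatibilityError(
                f"cannot combine {type(a).__name__} with {type(b).__name__}"
            )
        if tuple(a.shape) != tuple(b.shape) or not np.array_equal(
            a._trialdefinition, b._trialdefinition
        ):
            raise IncompatibilityError("operands differ in shape or trial structure")

    result_dtype = np.result_type(a.dtype, (np.float32 if scalar else b.dtype))
    if op == "/" and np.issubdtype(result_dtype, np.integer):
        result_dtype = np.float64

    from . import engine  # local import: engine depends on this module

    kernel = engine.TrialKernel(
        name=f"arithmetic[{op}]",
        apply=_arith_apply,
        output_shape=lambda shape, params: shape,
        output_dtype=result_dtype,
        result_factory=lambda path, trl: _clone_like(a, path, trl, f"arithmetic[{op}]"),
    )
    params = {"op": op, "_scalar": b if scalar else None, "_dtype": result_dtype}
    out = engine.compute(a, kernel, params=params, other=None if scalar else b)
    if op == "/":
        warnings.warn(
            "division follows floating-point semantics; zeros in the denominator "
            "produce inf/nan",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def _arith_apply(trial, params, other=None):
    """Per-trial elementwise kernel (module-level so it pickles to workers)."""
    func = _OPS[params["op"]]
    operand = params["_scalar"] if params["_scalar"] is not None else other
    with np.errstate(divide="ignore", invalid="ignore"):
        out = func(trial, operand)
    return np.asarray(out, dtype=params["_dtype"])


def _clone_like(template: BaseData, payload_path: str, trialdefinition, op_name: str):
    """Rebuild a container of the template's class around a new payload."""
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
    out = cls(
        payload_path,
        template.samplerate,
        template.channels,
        trialdefinition,
        log=template.log,
        **kw,
    )
    out.log_entry(op_name)
    return out


# -- save / load -----------------------------------------------------------

def _paths_for(path: str):
    base, ext = os.path.splitext(path)
    if ext == ".json":
        base = base
    elif ext != ".h5":
        base = path
    return base + ".h5", base + ".json"


def save_dataset(data: BaseData, path: str) -> dict:
    """Write ``data`` as ``<base>.h5`` payload + ``<base>.json`` header.

    The payload is streamed slab by slab, so saving never loads the full
    dataset into memory.  Returns the header dict (the manifest)."""
    h5path, jsonpath = _paths_for(path)
    data.flush()
    with _h5open(h5path, "w") as dst, _h5open(data._payload_path, "r") as src:
        out = dst.create_dataset(
            "data",
            shape=src["data"].shape,
            dtype=src["data"].dtype,
            chunks=src["data"].chunks,
        )
        _copy_dataset(src["data"], out)
        if "waveforms" in src:
            wf = dst.create_dataset(
                "waveforms", shape=src["waveforms"].shape, dtype=src["waveforms"].dtype
            )
            _copy_dataset(src["waveforms"], wf)
        dst.attrs["uuid"] = data.uuid
    header = data.header(payload_name=os.path.basename(h5path))
    with open(jsonpath, "w") as fh:
        json.dump(header, fh, indent=2)
    data.log_entry("save_dataset", path=os.path.abspath(h5path))
    return header


def load_dataset(path: str) -> BaseData:
    """Reconstruct a container from ``<base>.h5`` + ``<base>.json``.

    Only the header and the payload *shape* are read; trial data stay on
    disk until accessed."""
    h5path, jsonpath = _paths_for(path)
    if not os.path.exists(jsonpath):
        raise FormatError(f"missing JSON header {jsonpath}")
    if not os.path.exists(h5path):
        raise FormatError(f"missing HDF5 payload {h5path}")
    with open(jsonpath) as fh:
        header = json.load(fh)
    version = header.get("format_version")
    if version != FORMAT_VERSION:
        raise VersionError(f"unknown format version {version!r} (supported: {FORMAT_VERSION})")
    cls = _CLASSES.get(header.get("data_class"))
    if cls is None:
        raise FormatError(f"unknown data class {header.get('data_class')!r}")
    with _h5open(h5path, "r") as f:
        if "data" not in f:
            raise FormatError("payload file lacks the main 'data' dataset")
        shape = list(f["data"].shape)
    if shape != header.get("shape"):
        raise FormatError(
            f"header/payload shape mismatch: header says {header.get('shape')}, "
            f"payload is {shape}"
        )
    kw = {}
    if cls is SpectralData:
        kw = dict(
            freqs=header.get("freqs"),
            time_vector=header.get("time"),
            taper=header.get("taper"),
            output=header.get("output", "pow"),
        )
    elif cls is CrossSpectralData:
        kw = dict(
            freqs=header.get("freqs"),
            lags=header.get("lags"),
            time_vector=header.get("time"),
            measure=header.get("measure", "csd"),
            trial_averaged=header.get("trial_averaged", True),
        )
    common = dict(log=header.get("log"), dataset_uuid=header.get("uuid"), _owns_payload=False)
    if cls is SpikeData:
        obj = cls(
            h5path,
            header["samplerate"],
            trialdefinition=header.get("trialdefinition"),
            **common,
        )
    elif cls is EventData:
        obj = cls(h5path, header["samplerate"], **common)
    else:
        obj = cls(
            h5path,
            header["samplerate"],
            header["channels"],
            header.get("trialdefinition"),
            **common,
            **kw,
        )
    return obj
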