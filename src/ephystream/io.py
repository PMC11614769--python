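"""Foreign-format interoperability: NWB files, plain HDF5, dense arrays.

The NWB reader/writer targets the Neurodata Without Borders 2.x HDF5
layout directly through h5py and covers the subset this package's
containers map onto:

* regularly sampled acquisition series (``/acquisition/<name>`` with a
  ``data`` dataset and ``starting_time`` carrying the ``rate`` attribute)
  <-> :class:`~ephystream.datamodel.AnalogData`;
* the ``/units`` table (``spike_times`` + ``spike_times_index`` ragged
  columns, optional per-spike waveforms) <->
  :class:`~ephystream.datamodel.SpikeData`;
* the ``/intervals/trials`` table (``start_time`` / ``stop_time``) <->
  trial definitions.

Spike times are converted to sample indices with round-half-to-even
(unbiased).  Files with only irregular timestamps are rejected unless the
timestamps are uniform to within ``1e-6 * dt``.
"""

from __future__ import annotations

import datetime
import os
import uuid as _uuid
from typing import List, Optional

import h5py
import numpy as np

from .datamodel import AnalogData, BaseData, SpikeData, _h5open, new_payload_path
from .errors import ImportFormatError

__all__ = ["import_nwb", "export_nwb", "to_arrays", "from_hdf5"]

_NWB_VERSION = "2.5.0"


# --------------------------------------------------------------------------
# NWB export
# --------------------------------------------------------------------------

def _set_type(obj, neurodata_type: str) -> None:
    obj.attrs["neurodata_type"] = neurodata_type
    obj.attrs["namespace"] = "core"
    obj.attrs["object_id"] = str(_uuid.uuid4())


def export_nwb(data, path: str) -> str:
    """Write an AnalogData or SpikeData to an NWB-2.x-layout HDF5 file.

    The continuous payload becomes an acquisition electrical series with a
    sampling rate; spikes become a units table with per-unit spike times in
    seconds (and waveforms when present); the trial definition becomes the
    trials interval table.
    """
    if not isinstance(data, (AnalogData, SpikeData)):
        raise ImportFormatError(
            f"NWB export supports AnalogData and SpikeData, not {type(data).__name__}"
        )
    with h5py.File(path, "w") as f:
        f.attrs["nwb_version"] = _NWB_VERSION
        _set_type(f, "NWBFile")
        now = datetime.datetime.now().astimezone().isoformat()
        f.create_dataset("session_description", data="ephystream export")
        f.create_dataset("identifier", data=data.uuid)
        f.create_dataset("session_start_time", data=now)
        f.create_dataset("timestamps_reference_time", data=now)
        f.create_group("acquisition")
        f.create_group("processing")
        f.create_group("analysis")

        if isinstance(data, AnalogData):
            series = f["acquisition"].create_group("ElectricalSeries")
            _set_type(series, "ElectricalSeries")
            series.attrs["description"] = "ephystream AnalogData payload"
            series.attrs["comments"] = "channels: " + ",".join(data.channels)
            d = series.create_dataset("data", data=data.data[...])
            d.attrs["unit"] = "volts"
            d.attrs["conversion"] = 1.0
            d.attrs["resolution"] = -1.0
            st = series.create_dataset("starting_time", data=0.0)
            st.attrs["rate"] = float(data.samplerate)
            st.attrs["unit"] = "seconds"
        else:
            units = f.create_group("units")
            _set_type(units, "Units")
            units.attrs["description"] = "ephystream SpikeData"
            # spike times are stored in seconds; keep the acquisition clock so
            # a re-import reproduces the original sample indices
            units.attrs["sampling_rate"] = float(data.samplerate)
            table = np.asarray(data.data[...])
            unit_ids = np.unique(table[:, 2]) if table.size else np.array([], np.int64)
            times: List[np.ndarray] = []
            index = []
            wf_rows = []
            wf = data.waveforms
            cursor = 0
            for u in unit_ids:
                mask = table[:, 2] == u
                t = table[mask, 0] / data.samplerate
                times.append(t)
                cursor += len(t)
                index.append(cursor)
                if wf is not None:
                    wf_rows.append(np.asarray(wf)[mask])
            flat = np.concatenate(times) if times else np.empty(0)
            units.create_dataset("id", data=unit_ids.astype(np.int64))
            ds_t = units.create_dataset("spike_times", data=flat)
            ds_t.attrs["description"] = "spike times in seconds"
            ds_i = units.create_dataset("spike_times_index", data=np.asarray(index, np.int64))
            ds_i.attrs["target"] = "spike_times"
            if wf_rows:
                units.create_dataset("waveforms", data=np.vstack(wf_rows))

        if data.trialdefinition is not None:
            iv = f.create_group("intervals")
            trials = iv.create_group("trials")
            _set_type(trials, "TimeIntervals")
            trl = data.trialdefinition
            trials.create_dataset("id", data=np.arange(len(trl), dtype=np.int64))
            trials.create_dataset("start_time", data=trl[:, 0] / data.samplerate)
            trials.create_dataset("stop_time", data=trl[:, 1] / data.samplerate)
            trials.create_dataset("offset", data=trl[:, 2] / data.samplerate)
    data.log_entry("export_nwb", path=os.path.abspath(path))
    return path


# --------------------------------------------------------------------------
# NWB import
# --------------------------------------------------------------------------

def _series_rate(grp: h5py.Group) -> Optional[float]:
    if "starting_time" in grp and "rate" in grp["starting_time"].attrs:
        return float(grp["starting_time"].attrs["rate"])
    if "timestamps" in grp:
        ts = np.asarray(grp["timestamps"])
        if len(ts) < 2:
            return None
        dt = np.diff(ts)
        if np.ptp(dt) > 1e-6 * dt.mean():
            raise ImportFormatError(
                f"series {grp.name!r} has irregular timestamps "
                "(beyond 1e-6 * dt tolerance); cannot map to a regular container"
            )
        return 1.0 / dt.mean()
    return None


def _read_trials(f: h5py.File, samplerate: float):
    if "intervals" not in f or "trials" not in f["intervals"]:
        return None
    t = f["intervals/trials"]
    start = np.asarray(t["start_time"]) * samplerate
    stop = np.asarray(t["stop_time"]) * samplerate
    if "offset" in t:
        off = np.asarray(t["offset"]) * samplerate
    else:
        off = np.zeros_like(start)
    return np.column_stack(
        [np.round(start), np.round(stop), np.round(off)]
    ).astype(np.int64)


def import_nwb(path: str) -> dict:
    """Read an NWB file into native containers.

    Returns a dict with any of the keys ``"analog"`` (AnalogData from the
    first regularly sampled acquisition series) and ``"spikes"``
    (SpikeData from the units table); an epoch/trials table is attached as
    the trial definition of both.  A file with neither convertible part
    raises :class:`~ephystream.errors.ImportFormatError`.
    """
    if not os.path.exists(path):
        raise ImportFormatError(f"no such file: {path}")
    out = {}
    with h5py.File(path, "r") as f:
        analog = None
        if "acquisition" in f:
            for name, grp in f["acquisition"].items():
                if not isinstance(grp, h5py.Group) or "data" not in grp:
                    continue
                rate = _series_rate(grp)
                if rate is None:
                    continue
                arr = np.asarray(grp["data"])
                if arr.ndim == 1:
                    arr = arr[:, None]
                labels = None
                comments = grp.attrs.get("comments", "")
                if isinstance(comments, bytes):
                    comments = comments.decode()
                if isinstance(comments, str) and comments.startswith("channels: "):
                    labels = comments[len("channels: "):].split(",")
                    if len(labels) != arr.shape[1]:
                        labels = None
                analog = AnalogData.from_array(arr, rate, channels=labels)
                analog.log_entry("import_nwb", path=os.path.abspath(path), series=name)
                break
        spikes = None
        if "units" in f and "spike_times" in f["units"]:
            units = f["units"]
            flat = np.asarray(units["spike_times"], dtype=float)
            index = np.asarray(units["spike_times_index"], dtype=np.int64)
            ids = (
                np.asarray(units["id"], dtype=np.int64)
                if "id" in units
                else np.arange(len(index), dtype=np.int64)
            )
            if "sampling_rate" in units.attrs:
                rate = float(units.attrs["sampling_rate"])
            elif analog is not None:
                rate = float(analog.samplerate)
            else:
                rate = _guess_spike_rate(f)
            rows = []
            wf_all = units["waveforms"][...] if "waveforms" in units else None
            wf_rows = []
            lo = 0
            for k, hi in enumerate(index):
                t = flat[lo:hi]
                samples = np.round(t * rate).astype(np.int64)  # round-half-to-even
                rows.append(
                    np.column_stack(
                        [samples,
                         np.full(len(t), ids[k], np.int64),
                         np.full(len(t), ids[k], np.int64)]
                    )
                )
                if wf_all is not None:
                    wf_rows.append(wf_all[lo:hi])
                lo = hi
            table = np.vstack(rows) if rows else np.empty((0, 3), np.int64)
            order = np.argsort(table[:, 0], kind="stable")
            wf = np.vstack(wf_rows)[order] if wf_rows else None
            spikes = SpikeData.from_array(table, rate, waveforms=wf)
            spikes.log_entry("import_nwb", path=os.path.abspath(path))
        if analog is None and spikes is None:
            raise ImportFormatError(
                f"{path!r} holds neither a regularly sampled acquisition series "
                "nor a units table"
            )
        if analog is not None:
            trl = _read_trials(f, analog.samplerate)
            if trl is not None:
                analog._set_trialdefinition(trl)
            out["analog"] = analog
        if spikes is not None:
            trl = _read_trials(f, spikes.samplerate)
            if trl is not None:
                spikes._set_trialdefinition(trl)
            out["spikes"] = spikes
    return out


def _guess_spike_rate(f: h5py.File) -> float:
    # no series to infer from: fall back to a 30 kHz acquisition clock
    return 30000.0


# --------------------------------------------------------------------------
# dense arrays and plain HDF5
# --------------------------------------------------------------------------

def to_arrays(data: BaseData) -> List[np.ndarray]:
    """Extract all trials as in-memory arrays (trial-definition order)."""
    return [np.asarray(tr) for tr in data.trials]


def from_hdf5(path: str, dataset: str = "data", samplerate: float = 1000.0,
              channels=None) -> AnalogData:
    """Import a plain 2-D HDF5 dataset as a single-trial AnalogData."""
    with h5py.File(path, "r") as f:
        if dataset not in f:
            raise ImportFormatError(f"dataset {dataset!r} not found in {path!r}")
        arr = np.asarray(f[dataset])
    if arr.ndim != 2:
        raise ImportFormatError(
            f"expected a 2-D (samples, channels) dataset, got {arr.ndim}-D "
            f"{arr.shape}; reshape or split the file first"
        )
    out = AnalogData.from_array(arr, samplerate, channels=channels)
    out.log_entry("from_hdf5", path=os.path.abspath(path), dataset=dataset)
    return out
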