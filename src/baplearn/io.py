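"""Result serialization.

Rasters travel as two-column plain text (``unit_id time_ms``) or HDF5 event
tables, always sorted by time then unit; presentation schedules as CSV
sidecars (``start,end,label``); state snapshots and weight matrices as HDF5
groups, with a MatrixMarket export for sparse recurrent weights.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np
from scipy import io as spio
from scipy import sparse

from . import spikegen

__all__ = [
    "write_raster_text", "read_raster_text", "write_raster_hdf5",
    "read_raster_hdf5", "write_schedule_csv", "read_schedule_csv",
    "write_snapshots_hdf5", "write_weight_matrix", "export_metrics_json",
]


def _sorted_events(units, times):
    units = np.asarray(units, dtype=np.int64)
    times = np.asarray(times, dtype=np.float64)
    order = np.lexsort((units, times))
    return units[order], times[order]


def write_raster_text(path, units, times) -> None:
    """Two-column ``unit_id time_ms`` raster, sorted by (time, unit)."""
    units, times = _sorted_events(units, times)
    with open(path, "w") as fh:
        fh.write("# unit_id\ttime_ms\n")
        for u, t in zip(units, times):
            fh.write(f"{u}\t{t:.4f}\n")


def read_raster_text(path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    return data[:, 0].astype(np.int64), data[:, 1].astype(np.float64)


def write_raster_hdf5(path, units, times, group: str = "raster") -> None:
    units, times = _sorted_events(units, times)
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("unit_id", data=units)
        g.create_dataset("time_ms", data=times)


def read_raster_hdf5(path, group: str = "raster") -> tuple[np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        return g["unit_id"][...], g["time_ms"][...]


def write_schedule_csv(path, schedule: spikegen.PresentationSchedule) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["start", "end", "label"])
        for s, e, lab in zip(schedule.start, schedule.end, schedule.label):
            wr.writerow([f"{s:.4f}", f"{e:.4f}", lab])


def read_schedule_csv(path) -> spikegen.PresentationSchedule:
    starts, ends, labels = [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            starts.append(float(row["start"]))
            ends.append(float(row["end"]))
            labels.append(row["label"])
    return spikegen.PresentationSchedule(
        np.asarray(starts), np.asarray(ends), np.asarray(labels, dtype=object))


def write_snapshots_hdf5(path, result, stride_ms: float | None = None) -> None:
    """Membrane/gate/conductance/weight snapshots of a TrialResult."""
    with h5py.File(path, "a") as fh:
        for name in ("membrane", "weights"):
            if name in fh:
                del fh[name]
        g = fh.create_group("membrane")
        for key, arr in result.recordings.items():
            g.create_dataset(key, data=arr)
        w = fh.create_group("weights")
        w.create_dataset("snapshot_times_ms", data=result.snapshot_times)
        w.create_dataset("snapshots", data=result.weight_snapshots)
        w.create_dataset("final", data=result.weights)
        w.create_dataset("initial", data=result.weights0)
        fh.attrs["seed"] = result.config.seed
        fh.attrs["variant"] = result.config.neuron.variant


def write_weight_matrix(path_h5, w: np.ndarray, name: str = "w_rec",
                        path_mtx=None) -> None:
    """Dense HDF5 export; optionally MatrixMarket for the sparse structure."""
    with h5py.File(path_h5, "a") as fh:
        if name in fh:
            del fh[name]
        fh.create_dataset(name, data=w)
    if path_mtx is not None:
        spio.mmwrite(str(path_mtx), sparse.csr_matrix(w))


def export_metrics_json(path, payload: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not serializable: {type(o)}")
    Path(path).write_text(json.dumps(payload, indent=2, default=default))
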