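"""File formats: HDF5 recordings/epoch sets, delimited accelerometer traces,
JSON designs and summaries.

HDF5 is the canonical on-disk layout (datasets ``data``, ``channel_kind``,
``channel_unit``, ``channel_pos``, ``planar_pair``, attr ``sample_rate``);
:func:`to_mne_raw` converts a recording to an MNE ``RawArray`` for FIF
export when the ``mne`` package is available.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .design import Condition, StimulusDesign
from .epoching import EpochSet
from .forward import SensorArray
from .simulate import GroundTruth, KinematicSignal, SensorRecording


def _write_array_meta(g: h5py.Group, array: SensorArray) -> None:
    g.create_dataset("channel_kind", data=np.array(array.kind, dtype="S"))
    g.create_dataset("channel_unit", data=np.array(array.units, dtype="S"))
    g.create_dataset("channel_name", data=np.array(array.names, dtype="S"))
    g.create_dataset("channel_pos", data=array.pos)
    g.create_dataset("channel_normal", data=array.normal)
    g.create_dataset("grad_direction", data=array.grad_direction)
    g.create_dataset("planar_pair", data=array.pair_index)
    g.attrs["baseline_m"] = array.baseline_m


def _read_array_meta(g: h5py.Group) -> SensorArray:
    return SensorArray(
        pos=g["channel_pos"][()],
        normal=g["channel_normal"][()],
        grad_direction=g["grad_direction"][()],
        kind=tuple(s.decode() for s in g["channel_kind"][()]),
        pair_index=g["planar_pair"][()],
        names=tuple(s.decode() for s in g["channel_name"][()]),
        baseline_m=float(g.attrs["baseline_m"]),
    )


def write_recording(path, rec: SensorRecording) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("data", data=rec.data)
        h.attrs["sample_rate"] = rec.sample_rate
        _write_array_meta(h, rec.array)


def read_recording(path) -> SensorRecording:
    with h5py.File(path, "r") as h:
        return SensorRecording(data=h["data"][()], array=_read_array_meta(h),
                               sample_rate=float(h.attrs["sample_rate"]))


def write_epochs(path, es: EpochSet) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("meg", data=es.meg)
        h.create_dataset("ref", data=es.ref)
        h.create_dataset("starts", data=es.starts)
        h.attrs["sample_rate"] = es.sample_rate
        h.attrs["provenance"] = json.dumps(es.provenance, default=int)
        _write_array_meta(h, es.array)


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as h:
        return EpochSet(meg=h["meg"][()], ref=h["ref"][()],
                        starts=h["starts"][()],
                        sample_rate=float(h.attrs["sample_rate"]),
                        array=_read_array_meta(h),
                        provenance=json.loads(h.attrs["provenance"]))


def write_acceleration(path, kin: KinematicSignal) -> None:
    """Delimited text: time_ms, x, y, z."""
    t = np.arange(kin.n_samples) * 1000.0 / kin.sample_rate
    df = pd.DataFrame({"time_ms": t, "x": kin.axes[0], "y": kin.axes[1],
                       "z": kin.axes[2]})
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_acceleration(path, finger: str = "D2") -> KinematicSignal:
    df = pd.read_csv(path, sep="\t")
    dt = np.diff(df["time_ms"].to_numpy()[:2])[0]
    return KinematicSignal(finger=finger,
                           axes=df[["x", "y", "z"]].to_numpy().T,
                           sample_rate=1000.0 / dt)


def design_to_dict(design: StimulusDesign) -> dict:
    return {
        "condition": Condition(design.condition).value,
        "fingers": list(design.fingers),
        "freq_per_finger": dict(design.freq_per_finger),
        "burst_schedule": [list(b) for b in design.burst_schedule],
        "total_duration": design.total_duration,
        "sample_rate": design.sample_rate,
    }


def design_from_dict(d: dict) -> StimulusDesign:
    return StimulusDesign(
        condition=Condition(d["condition"]), fingers=tuple(d["fingers"]),
        freq_per_finger={k: float(v) for k, v in d["freq_per_finger"].items()},
        burst_schedule=tuple(tuple(b) for b in d["burst_schedule"]),
        total_duration=float(d["total_duration"]),
        sample_rate=float(d.get("sample_rate", 1000.0)))


def truth_to_dict(truth: GroundTruth) -> dict:
    d = dataclasses.asdict(truth)
    d["source_nodes"] = {k: int(v) for k, v in truth.source_nodes.items()}
    d["coupling_gain"] = {k: float(v) for k, v in truth.coupling_gain.items()}
    return d


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_source_map(path, cmap) -> None:
    """Delimited text: node x, y, z (mm) and coherence."""
    df = pd.DataFrame(np.column_stack([cmap.grid.nodes, cmap.values]),
                      columns=["x", "y", "z", "coherence"])
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def to_mne_raw(rec: SensorRecording):
    """Convert a recording to an MNE RawArray (for FIF export).

    Gradiometer data (fT/cm) and magnetometer data (fT) are converted to SI
    (T/m, T).  Requires the optional ``mne`` dependency.
    """
    import mne  # local import: optional dependency

    kinds = ["grad" if k == "gradiometer" else "mag" for k in rec.array.kind]
    info = mne.create_info(list(rec.array.names), rec.sample_rate, ch_types=kinds)
    scale = np.array([1e-13 if k == "grad" else 1e-15 for k in kinds])
    return mne.io.RawArray(rec.data * scale[:, None], info, verbose="error")
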