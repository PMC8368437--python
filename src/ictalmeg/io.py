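"""HDF5 recording container and JSON ground-truth round-tripping.

Layout of a recording file:

    /data          float64, (n_channels, n_samples), attribute ``unit`` = "T"
    /channel_ids   variable-length UTF-8 strings
    root attrs     ``rate_hz`` (float), ``t0`` (float)
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .exceptions import FormatError
from .preprocess import SensorRecording
from .simulate import GroundTruth

__all__ = ["write_recording", "read_recording", "ground_truth_to_json",
           "ground_truth_from_json"]


def write_recording(rec: SensorRecording, path, sidecar: dict | None = None) -> None:
    """Write a recording; an optional dict is stored as a JSON sidecar."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=rec.data)
        d.attrs["unit"] = "T"
        f.create_dataset(
            "channel_ids",
            data=np.array(rec.channel_ids, dtype=h5py.string_dtype("utf-8")),
        )
        f.attrs["rate_hz"] = float(rec.rate_hz)
        f.attrs["t0"] = float(rec.t0)
    if sidecar is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True, default=str)


def read_recording(path) -> SensorRecording:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise FormatError("missing dataset 'data'")
        if "rate_hz" not in f.attrs:
            raise FormatError("missing attribute 'rate_hz'")
        unit = f["data"].attrs.get("unit")
        if unit is None:
            raise FormatError("missing 'unit' attribute on data")
        if isinstance(unit, bytes):
            unit = unit.decode()
        if unit != "T":
            raise FormatError(f"unit mismatch: expected tesla ('T'), got {unit!r}")
        if "channel_ids" not in f:
            raise FormatError("missing dataset 'channel_ids'")
        ids = tuple(
            c.decode() if isinstance(c, bytes) else str(c) for c in f["channel_ids"][()]
        )
        return SensorRecording(
            data=f["data"][()],
            rate_hz=float(f.attrs["rate_hz"]),
            channel_ids=ids,
            t0=float(f.attrs.get("t0", 0.0)),
        )


def ground_truth_to_json(gt: GroundTruth, path) -> None:
    payload = {
        "source_locations_mm": np.asarray(gt.source_locations_mm).tolist(),
        "segment_boundaries": [list(map(int, b)) for b in gt.segment_boundaries],
        "source_bands": [list(b) for b in gt.source_bands],
        "true_source_voxels": gt.true_source_voxels,
        "true_correlated_pairs": [list(p) for p in gt.true_correlated_pairs],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def ground_truth_from_json(path) -> GroundTruth:
    with open(path) as fh:
        p = json.load(fh)
    return GroundTruth(
        source_locations_mm=np.asarray(p["source_locations_mm"], dtype=float),
        segment_boundaries=[tuple(b) for b in p["segment_boundaries"]],
        source_timecourses=np.zeros((0, 0)),
        source_bands=[tuple(b) for b in p["source_bands"]],
        true_source_voxels=p.get("true_source_voxels"),
        true_correlated_pairs=[tuple(q) for q in p.get("true_correlated_pairs", [])],
    )
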