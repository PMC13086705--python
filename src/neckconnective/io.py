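"""File I/O glue: raw recordings with JSON sidecars, label masks, tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .probes import ProbeGeometry
from .synth import Recording

__all__ = [
    "write_recording",
    "read_recording",
    "write_mask",
    "read_mask",
    "write_json",
    "read_json",
]


def write_recording(rec: Recording, stem: Path | str) -> tuple[Path, Path]:
    """Write raw int16 samples (channel-major frames) + JSON sidecar.

    Produces ``<stem>.bin`` (little-endian int16, sample-major layout:
    frame 0's channels, frame 1's channels, ...) and ``<stem>.json``.
    """
    stem = Path(stem)
    bin_path = stem.with_suffix(".bin")
    json_path = stem.with_suffix(".json")
    data = np.ascontiguousarray(rec.data.astype("<i2"))
    data.tofile(bin_path)
    sidecar = dict(rec.sidecar)
    sidecar["n_samples"] = int(rec.data.shape[0])
    sidecar["n_channels"] = int(rec.data.shape[1])
    sidecar["spike_times_s"] = [t.tolist() for t in rec.spike_times_s]
    json_path.write_text(json.dumps(sidecar, indent=1))
    return bin_path, json_path


def read_recording(stem: Path | str) -> Recording:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".bin"), dtype="<i2").reshape(
        sidecar["n_samples"], sidecar["n_channels"]
    )
    spikes = [np.asarray(t, float) for t in sidecar.pop("spike_times_s", [])]
    return Recording(data=data, sidecar=sidecar, spike_times_s=spikes)


def write_mask(mask: np.ndarray, path: Path | str) -> Path:
    """Write a label/binary mask as TIFF (16-bit when labels allow)."""
    path = Path(path)
    arr = np.asarray(mask)
    if arr.max() < 2**16:
        arr = arr.astype(np.uint16)
    tifffile.imwrite(path, arr)
    return path


def read_mask(path: Path | str) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_json(obj: dict, path: Path | str) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, default=_jsonify))
    return path


def read_json(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, ProbeGeometry):
        return x.to_dict()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="list")
    raise TypeError(f"not JSON serializable: {type(x)}")
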