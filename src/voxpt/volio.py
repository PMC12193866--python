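"""Volume file I/O: RAW + JSON sidecar, plus NIfTI reading via nibabel.

The native on-disk format is a flat binary RAW file of voxel values in C
(x-major) order together with a JSON sidecar declaring geometry and typing:

    {"dims": [nx, ny, nz], "spacing": [...], "origin": [...],
     "dtype": "float32", "value_kind": "continuous", "labels": null,
     "channels": 1}

A write-then-read round trip reproduces dims, spacing, origin, value_kind and
voxel values exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .volume import ProxyVolumeSet, Volume

__all__ = ["read_volume", "write_volume", "write_proxy_set", "read_proxy_set"]

_DTYPES = {"float32": np.float32, "float64": np.float64, "uint8": np.uint8,
           "uint16": np.uint16, "int16": np.int16, "int32": np.int32}


def _paths(path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in (".raw", ".json"):
        base = base.with_suffix("")
    return base.with_suffix(".raw"), base.with_suffix(".json")


def write_volume(vol: Volume, path) -> tuple[Path, Path]:
    """Write a volume as ``<path>.raw`` + ``<path>.json``; returns the paths."""
    raw_path, json_path = _paths(path)
    data = vol.values
    dtype = data.dtype.name
    if dtype not in _DTYPES:
        data = data.astype(np.float32)
        dtype = "float32"
    sidecar = {
        "dims": [int(d) for d in vol.dims],
        "spacing": [float(s) for s in vol.spacing],
        "origin": [float(o) for o in vol.origin],
        "dtype": dtype,
        "value_kind": vol.value_kind,
        "labels": list(vol.labels) if vol.labels is not None else None,
        "channels": vol.n_channels,
    }
    raw_path.parent.mkdir(parents=True, exist_ok=True)
    data.astype(_DTYPES[dtype]).tofile(raw_path)
    json_path.write_text(json.dumps(sidecar, indent=1))
    return raw_path, json_path


def _read_raw(raw_path: Path, sidecar: dict) -> Volume:
    dims = [int(d) for d in sidecar["dims"]]
    channels = int(sidecar.get("channels", 1))
    dtype_name = sidecar["dtype"]
    if dtype_name not in _DTYPES:
        raise ValueError(f"unknown element type {dtype_name!r}")
    dtype = _DTYPES[dtype_name]
    expected = int(np.prod(dims)) * channels
    data = np.fromfile(raw_path, dtype=dtype)
    if data.size != expected:
        raise ValueError(
            f"size mismatch: sidecar declares {expected} elements "
            f"({dims} x {channels} channels) but {raw_path} holds {data.size}")
    shape = tuple(dims) if channels == 1 else tuple(dims) + (channels,)
    labels = sidecar.get("labels")
    return Volume(data.reshape(shape),
                  spacing=np.asarray(sidecar["spacing"], dtype=float),
                  origin=np.asarray(sidecar["origin"], dtype=float),
                  value_kind=sidecar.get("value_kind", "continuous"),
                  labels=labels)


def read_volume(path, sidecar=None) -> Volume:
    """Read a volume from RAW+JSON (or a NIfTI file).

    ``path`` may point at the .raw, the .json, or the common base name; a
    ``sidecar`` dict can be passed explicitly to override the .json file.
    NIfTI files (.nii / .nii.gz) are read through nibabel and treated as
    continuous unless ``sidecar["value_kind"]`` says otherwise.
    """
    p = Path(path)
    if p.suffix == ".nii" or str(p).endswith(".nii.gz"):
        import nibabel as nib
        img = nib.load(str(p))
        data = np.asanyarray(img.dataobj).astype(np.float32)
        zooms = img.header.get_zooms()[:3]
        kind = (sidecar or {}).get("value_kind", "continuous")
        return Volume(data, spacing=np.asarray(zooms, dtype=float),
                      origin=np.zeros(3), value_kind=kind)
    raw_path, json_path = _paths(p)
    if sidecar is None:
        sidecar = json.loads(json_path.read_text())
    return _read_raw(raw_path, sidecar)


def write_proxy_set(pvs: ProxyVolumeSet, directory) -> dict:
    """Write every member of a proxy set under ``directory/<role>.raw/json``."""
    directory = Path(directory)
    out = {}
    for role in pvs.roles:
        raw, _ = write_volume(pvs[role], directory / role)
        out[role] = str(raw)
    return out


def read_proxy_set(paths: dict) -> ProxyVolumeSet:
    """Read a proxy set from a role -> path mapping."""
    return ProxyVolumeSet({role: read_volume(p) for role, p in paths.items()})
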