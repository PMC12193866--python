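"""Scalar-volume container, interpolation and gradients.

A :class:`Volume` is a 3D grid of voxel values with world-space placement
(spacing + origin).  Voxel ``(i, j, k)`` is centred at
``origin + (i, j, k) * spacing`` (0-based indices); the world-space support is
the box ``[origin - spacing/2, origin + (dims - 1/2) * spacing]``.

Volumes are either *continuous* (CT intensities, gradient magnitudes,
opacities) and sampled with trilinear interpolation, or *discrete* (label /
segmentation masks) and sampled with nearest-neighbour lookup so that no
undefined intermediate label values can appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["Volume", "ProxyVolumeSet", "sample_volume", "compute_gradient",
           "PROXY_ROLES"]

#: Recognized proxy-volume roles, in their fixed slot order.
PROXY_ROLES = ("primary", "gradient_magnitude", "opacity", "mask")


@dataclass
class Volume:
    """A 3D scalar (or small-vector) voxel grid with world placement.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz) or (nx, ny, nz, C) with C in {1, 3}
        Voxel data.  Stored as float32 (continuous) or as given (discrete).
    spacing : 3 positive floats, world units per voxel along each axis.
    origin : 3 floats, world position of the centre of voxel (0, 0, 0).
    value_kind : "continuous" or "discrete".
    labels : finite label set, required for discrete volumes.
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    value_kind: str = "continuous"
    labels: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (3, 4):
            raise ValueError("values must be a 3D grid, optionally with a "
                             "trailing channel axis")
        if self.values.ndim == 4 and self.values.shape[3] not in (1, 3):
            raise ValueError("channel count must be 1 or 3")
        if self.values.size == 0 or min(self.values.shape[:3]) < 1:
            raise ValueError("empty volume")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        if self.value_kind not in ("continuous", "discrete"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == "discrete":
            if self.values.ndim != 3:
                raise ValueError("discrete volumes must be single channel")
            present = np.unique(self.values)
            if self.labels is None:
                self.labels = tuple(int(v) for v in present)
            else:
                self.labels = tuple(int(v) for v in self.labels)
                missing = set(np.round(present).astype(int)) - set(self.labels)
                if missing:
                    raise ValueError(
                        f"voxel values {sorted(missing)} not in declared "
                        f"label set {self.labels}")
        else:
            self.values = np.ascontiguousarray(self.values, dtype=np.float32)

    # -- geometry -----------------------------------------------------------

    @property
    def dims(self) -> np.ndarray:
        return np.asarray(self.values.shape[:3], dtype=np.int64)

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 3 else self.values.shape[3]

    @property
    def world_min(self) -> np.ndarray:
        """Lower corner of the world-space support box."""
        return self.origin - 0.5 * self.spacing

    @property
    def world_max(self) -> np.ndarray:
        """Upper corner of the world-space support box."""
        return self.origin + (self.dims - 0.5) * self.spacing

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (nx, ny, nz, 3)."""
        axes = [self.origin[a] + np.arange(self.dims[a]) * self.spacing[a]
                for a in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack(g, axis=-1)

    def scalar_values(self) -> np.ndarray:
        """Values as a 3D array (channel 0 for multi-channel volumes)."""
        return self.values if self.values.ndim == 3 else self.values[..., 0]


@dataclass
class ProxyVolumeSet:
    """Up to four co-registered volumes indexed by role.

    All members must share the same world-space bounding box; the ``primary``
    member is mandatory and defines the renderer's domain.
    """

    members: dict

    def __post_init__(self) -> None:
        if "primary" not in self.members:
            raise ValueError("a ProxyVolumeSet requires a 'primary' member")
        if len(self.members) > 4:
            raise ValueError("at most 4 proxy volumes are supported")
        for role, vol in self.members.items():
            if role not in PROXY_ROLES:
                raise ValueError(f"unknown proxy role {role!r}")
            if not isinstance(vol, Volume):
                raise TypeError("proxy members must be Volume instances")
        ref = self.members["primary"]
        for role, vol in self.members.items():
            if (not np.allclose(vol.world_min, ref.world_min, atol=1e-9) or
                    not np.allclose(vol.world_max, ref.world_max, atol=1e-9)):
                raise ValueError(
                    f"proxy {role!r} does not share the primary volume's "
                    "world bounding box")

    def __getitem__(self, role: str) -> Volume:
        return self.members[role]

    def __contains__(self, role: str) -> bool:
        return role in self.members

    @property
    def primary(self) -> Volume:
        return self.members["primary"]

    @property
    def roles(self):
        return tuple(r for r in PROXY_ROLES if r in self.members)


# -- sampling ---------------------------------------------------------------

def _check_points(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite sample point")
    return p


def sample_volume(vol: Volume, p) -> np.ndarray:
    """Sample ``vol`` at world point(s) ``p``.

    Continuous volumes use trilinear interpolation of the eight surrounding
    voxel centres; discrete volumes return the value of the nearest voxel
    centre (never an interpolated label).  Points outside the world support
    return 0 (continuous) or label 0 (discrete).

    ``p`` may be a single 3-vector or an (N, 3) array; the result is a scalar,
    (C,), (N,) or (N, C) array accordingly.
    """
    p = _check_points(p)
    single = p.ndim == 1
    pts = p.reshape(-1, 3)
    dims = vol.dims
    rel = (pts - vol.origin) / vol.spacing  # continuous voxel coords
    inside = np.all((rel >= -0.5) & (rel <= dims - 0.5), axis=1)

    if vol.value_kind == "discrete":
        idx = np.clip(np.rint(rel).astype(np.int64), 0, dims - 1)
        out = vol.values[idx[:, 0], idx[:, 1], idx[:, 2]].astype(np.float64)
        out[~inside] = 0.0
        return out[0] if single else out

    i0 = np.clip(np.floor(rel).astype(np.int64), 0, dims - 1)
    i1 = np.minimum(i0 + 1, dims - 1)
    f = np.clip(rel - i0, 0.0, 1.0)
    v = vol.values.astype(np.float64)
    if v.ndim == 3:
        v = v[..., None]
    c = 0.0
    for dx in (0, 1):
        wx = (1 - f[:, 0]) if dx == 0 else f[:, 0]
        ix = i0[:, 0] if dx == 0 else i1[:, 0]
        for dy in (0, 1):
            wy = (1 - f[:, 1]) if dy == 0 else f[:, 1]
            iy = i0[:, 1] if dy == 0 else i1[:, 1]
            for dz in (0, 1):
                wz = (1 - f[:, 2]) if dz == 0 else f[:, 2]
                iz = i0[:, 2] if dz == 0 else i1[:, 2]
                c = c + (wx * wy * wz)[:, None] * v[ix, iy, iz]
    c[~inside] = 0.0
    if vol.n_channels == 1:
        c = c[:, 0]
    return c[0] if single else c


def compute_gradient(vol: Volume, p) -> np.ndarray:
    """Central-difference gradient of a continuous volume, per world unit.

    The stencil step is one voxel spacing per axis; within half a voxel of the
    support boundary the difference degrades to one-sided automatically (the
    off-support stencil point is clamped onto the boundary).
    """
    if vol.value_kind != "continuous":
        raise ValueError("gradients of discrete label volumes are undefined")
    p = _check_points(p)
    single = p.ndim == 1
    pts = p.reshape(-1, 3)
    lo = vol.world_min + 1e-9
    hi = vol.world_max - 1e-9
    grad = np.empty_like(pts)
    for a in range(3):
        h = vol.spacing[a]
        pp = pts.copy()
        pm = pts.copy()
        pp[:, a] = np.minimum(pts[:, a] + h, hi[a])
        pm[:, a] = np.maximum(pts[:, a] - h, lo[a])
        denom = pp[:, a] - pm[:, a]
        denom[denom <= 0] = 1.0
        fp = np.atleast_1d(sample_volume(vol, pp))
        fm = np.atleast_1d(sample_volume(vol, pm))
        if fp.ndim > 1:  # multi-channel: gradient of channel 0
            fp, fm = fp[:, 0], fm[:, 0]
        grad[:, a] = (fp - fm) / denom
    return grad[0] if single else grad
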