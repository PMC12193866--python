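"""Synthetic phantom generator.

Every other part of the renderer is testable without external data through
these phantoms: each family produces a continuous primary volume, its
gradient-magnitude proxy and a discrete segmentation mask, packaged as a
:class:`~voxpt.volume.ProxyVolumeSet` over the world box [-0.5, 0.5]^3.

Generation is a pure function of (spec, seed): all randomness comes from a
counter-based Philox generator keyed by the seed, so identical inputs give
bit-identical volumes on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .volume import ProxyVolumeSet, Volume

__all__ = ["PhantomSpec", "make_phantom", "PHANTOM_FAMILIES"]

PHANTOM_FAMILIES = ("nested_shells", "gaussian_blobs", "engine_like_block")


@dataclass
class PhantomSpec:
    """Description of a phantom: family, grid resolution and layout knobs."""

    family: str
    resolution: int = 64
    #: nested_shells: shell radii as fractions of the half-width (0.5 world).
    shell_radii: Tuple[float, float, float] = (0.2, 0.35, 0.45)
    #: gaussian_blobs: number of blobs.
    n_blobs: int = 6
    #: amplitude of the smooth texture perturbation added to the primary.
    noise: float = 0.01

    def __post_init__(self) -> None:
        if self.family not in PHANTOM_FAMILIES:
            raise ValueError(f"unknown phantom family {self.family!r}; "
                             f"choose one of {PHANTOM_FAMILIES}")
        if self.resolution < 4:
            raise ValueError("resolution must be at least 4")


def _grid(res: int):
    """Voxel-centre coordinates for an res^3 grid over [-0.5, 0.5]^3."""
    sp = 1.0 / res
    axis = -0.5 + (np.arange(res) + 0.5) * sp
    x, y, z = np.meshgrid(axis, axis, axis, indexing="ij")
    return x, y, z, sp


def _smoothstep(e0: float, e1: float, x: np.ndarray) -> np.ndarray:
    t = np.clip((x - e0) / (e1 - e0), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _texture(rng: np.random.Generator, x, y, z, amplitude: float):
    """Smooth band-limited perturbation: a few random-phase cosines."""
    if amplitude <= 0:
        return 0.0
    out = np.zeros_like(x)
    for _ in range(4):
        k = rng.uniform(4.0, 12.0, size=3)
        phase = rng.uniform(0.0, 2 * np.pi)
        out += np.cos(2 * np.pi * (k[0] * x + k[1] * y + k[2] * z) + phase)
    return amplitude * out / 4.0


def _assemble(field_vals: np.ndarray, mask: np.ndarray, labels, sp: float
              ) -> ProxyVolumeSet:
    origin = np.full(3, -0.5 + 0.5 * sp)
    spacing = np.full(3, sp)
    primary = Volume(np.clip(field_vals, 0.0, None).astype(np.float32),
                     spacing, origin, "continuous")
    gx, gy, gz = np.gradient(primary.values.astype(np.float64),
                             sp, sp, sp, edge_order=1)
    gmag = np.sqrt(gx * gx + gy * gy + gz * gz).astype(np.float32)
    grad_vol = Volume(gmag, spacing, origin, "continuous")
    mask_vol = Volume(mask.astype(np.int32), spacing, origin, "discrete",
                      labels=labels)
    return ProxyVolumeSet({"primary": primary,
                           "gradient_magnitude": grad_vol,
                           "mask": mask_vol})


def _nested_shells(spec: PhantomSpec, rng) -> ProxyVolumeSet:
    x, y, z, sp = _grid(spec.resolution)
    r = np.sqrt(x * x + y * y + z * z)
    r1, r2, r3 = (f * 0.5 for f in spec.shell_radii)
    edge = 1.5 * sp  # smooth transition width at each interface
    # value rises in steps toward the core: 0 outside, up to 1 in the centre
    vals = (0.3 * (1 - _smoothstep(r3 - edge, r3 + edge, r))
            + 0.3 * (1 - _smoothstep(r2 - edge, r2 + edge, r))
            + 0.4 * (1 - _smoothstep(r1 - edge, r1 + edge, r)))
    vals = vals + _texture(rng, x, y, z, spec.noise) * (r < r3 + 2 * edge)
    mask = np.zeros(x.shape, dtype=np.int32)
    mask[r <= r3] = 1
    mask[r <= r2] = 2
    mask[r <= r1] = 3
    return _assemble(vals, mask, (0, 1, 2, 3), sp)


def _gaussian_blobs(spec: PhantomSpec, rng) -> ProxyVolumeSet:
    x, y, z, sp = _grid(spec.resolution)
    n = spec.n_blobs
    centers = rng.uniform(-0.32, 0.32, size=(n, 3))
    sigmas = rng.uniform(0.05, 0.14, size=n)
    amps = rng.uniform(0.5, 1.0, size=n)
    contrib = np.zeros((n,) + x.shape)
    for k in range(n):
        d2 = ((x - centers[k, 0]) ** 2 + (y - centers[k, 1]) ** 2
              + (z - centers[k, 2]) ** 2)
        contrib[k] = amps[k] * np.exp(-0.5 * d2 / sigmas[k] ** 2)
    vals = contrib.sum(axis=0) + _texture(rng, x, y, z, spec.noise)
    strongest = np.argmax(contrib, axis=0)
    peak = np.max(contrib, axis=0)
    mask = np.where(peak > 0.15, strongest + 1, 0).astype(np.int32)
    return _assemble(vals, mask, tuple(range(n + 1)), sp)


def _engine_like_block(spec: PhantomSpec, rng) -> ProxyVolumeSet:
    x, y, z, sp = _grid(spec.resolution)
    edge = 1.5 * sp
    # rectangular housing
    dbox = np.maximum.reduce([np.abs(x) - 0.33, np.abs(y) - 0.33,
                              np.abs(z) - 0.42])
    housing = 1 - _smoothstep(-edge, edge, dbox)
    # two denser cylindrical bores along z, positions jittered by the seed
    offs = 0.17 + rng.uniform(-0.02, 0.02, size=2)
    vals = 0.45 * housing
    mask = np.zeros(x.shape, dtype=np.int32)
    mask[dbox <= 0] = 1
    for s, off in zip((-1.0, 1.0), offs):
        dcyl = np.sqrt((x - s * off) ** 2 + y * y) - 0.11
        inside = np.maximum(dcyl, np.abs(z) - 0.40)
        vals += 0.5 * (1 - _smoothstep(-edge, edge, inside))
        mask[inside <= 0] = 2
    vals = vals + _texture(rng, x, y, z, spec.noise) * housing
    return _assemble(vals, mask, (0, 1, 2), sp)


def make_phantom(spec, seed: int) -> ProxyVolumeSet:
    """Generate a phantom ProxyVolumeSet from a spec (or family name)."""
    if isinstance(spec, str):
        spec = PhantomSpec(spec)
    elif isinstance(spec, dict):
        spec = PhantomSpec(**spec)
    rng = np.random.Generator(np.random.Philox(key=int(seed)))
    if spec.family == "nested_shells":
        return _nested_shells(spec, rng)
    if spec.family == "gaussian_blobs":
        return _gaussian_blobs(spec, rng)
    return _engine_like_block(spec, rng)
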