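"""Scene assembly: camera, lights, volumes, manager, accelerator, integrator.

A scene is described by a JSON document::

    {"volumes": {"primary": "ct.raw", "mask": "seg.raw"}
       -- or -- {"phantom": {"family": "nested_shells", "resolution": 64,
                             "seed": 1}},
     "tf": {...transfer-function document...}  (or a path),
     "accelerator": {"leaf_level": 6, "hd": 0.2, "hu": 0.6,
                     "normalized_thresholds": true},
     "integrator": {"spp": 64, "seed": 1, "max_bounces": 32, "rr_start": 3,
                    "shadow_factor_a": 0.8, "channels": "single",
                    "density_scale": 100.0},
     "camera": {"position": [...], "look_at": [...], "up": [0,1,0],
                "fov": 45, "width": 256, "height": 256},
     "lights": [{"kind": "uniform_environment", "radiance": [1,1,1]},
                {"kind": "point", "position": [...], "intensity": [...]},
                {"kind": "latlong_environment", "radiance": [1,1,1],
                 "map": "env.pfm"}]}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np

from .octree import Octree
from .phantoms import make_phantom
from .tf import TFManager, tf_from_json
from .volio import read_volume
from .volume import ProxyVolumeSet

__all__ = ["Camera", "Light", "Scene", "generate_ray", "load_scene"]

_LIGHT_CODES = {"uniform_environment": 0, "latlong_environment": 1,
                "point": 2}


@dataclass
class Camera:
    """Pinhole camera; ``fov`` is the vertical field of view in degrees."""

    position: np.ndarray
    look_at: np.ndarray
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    fov: float = 45.0
    width: int = 256
    height: int = 256

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=np.float64).reshape(3)
        self.look_at = np.asarray(self.look_at, dtype=np.float64).reshape(3)
        self.up = np.asarray(self.up, dtype=np.float64).reshape(3)
        if not 0 < self.fov < 180:
            raise ValueError("fov must lie in (0, 180) degrees")
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        fwd = self.look_at - self.position
        n = np.linalg.norm(fwd)
        if n == 0:
            raise ValueError("camera position and look-at coincide")
        fwd = fwd / n
        if np.linalg.norm(np.cross(fwd, self.up)) < 1e-9:
            raise ValueError("up vector is parallel to the view direction")

    def basis(self):
        fwd = self.look_at - self.position
        fwd = fwd / np.linalg.norm(fwd)
        right = np.cross(fwd, self.up)
        right = right / np.linalg.norm(right)
        up = np.cross(right, fwd)
        tanf = np.tan(np.radians(self.fov) / 2.0)
        return fwd, right, up, tanf


def generate_ray(cam: Camera, i: int, j: int, u: float = 0.5, v: float = 0.5):
    """Pinhole ray through pixel (i, j) at sub-pixel jitter (u, v) in [0,1)."""
    if not (0 <= i < cam.width and 0 <= j < cam.height):
        raise ValueError("pixel index out of range")
    fwd, right, up, tanf = cam.basis()
    aspect = cam.width / cam.height
    px = (2.0 * (i + u) / cam.width - 1.0) * tanf * aspect
    py = (1.0 - 2.0 * (j + v) / cam.height) * tanf
    d = fwd + px * right + py * up
    return cam.position.copy(), d / np.linalg.norm(d)


@dataclass
class Light:
    """uniform_environment / latlong_environment / point light."""

    kind: str
    radiance: np.ndarray = field(default_factory=lambda: np.ones(3))
    position: Optional[np.ndarray] = None
    envmap: Optional[np.ndarray] = None  # (H, W, 3) lat-long float image

    def __post_init__(self):
        if self.kind not in _LIGHT_CODES:
            raise ValueError(f"unknown light kind {self.kind!r}")
        self.radiance = np.broadcast_to(
            np.asarray(self.radiance, dtype=np.float64), (3,)).copy()
        if np.any(self.radiance < 0):
            raise ValueError("light radiance must be non-negative")
        if self.kind == "point":
            if self.position is None:
                raise ValueError("point lights need a position")
            self.position = np.asarray(self.position,
                                       dtype=np.float64).reshape(3)
        if self.kind == "latlong_environment":
            if self.envmap is None:
                raise ValueError("lat-long environment lights need a map")
            self.envmap = np.ascontiguousarray(self.envmap, dtype=np.float32)
            if self.envmap.ndim != 3 or self.envmap.shape[2] != 3 or \
                    min(self.envmap.shape[:2]) < 1:
                raise ValueError("environment map must be (H, W, 3)")

    def lookup(self, direction) -> np.ndarray:
        """Radiance arriving from a direction (environment lights)."""
        if self.kind == "uniform_environment":
            return self.radiance.copy()
        if self.kind == "point":
            return np.zeros(3)
        from . import _kernels as K
        d = np.asarray(direction, dtype=np.float64)
        r, g, b = K._env_radiance(self.envmap, self.radiance[0],
                                  self.radiance[1], self.radiance[2],
                                  d[0], d[1], d[2])
        return np.array([r, g, b])


class Scene:
    """Everything the renderer needs, with octree kept in sync with the TF."""

    def __init__(self, proxies: ProxyVolumeSet, mgr: TFManager,
                 camera: Camera, lights: List[Light],
                 leaf_level: int = 4, hd: float = 0.2, hu: float = 0.6,
                 normalized_thresholds: bool = True, spp: int = 16,
                 seed: int = 0, max_bounces: int = 32, rr_start: int = 3,
                 shadow_factor_a: float = 0.8):
        if mgr.proxies is not proxies:
            raise ValueError("manager must be bound to the scene's proxies")
        if not lights:
            raise ValueError("a scene needs at least one light")
        if not 0 < shadow_factor_a <= 1:
            raise ValueError("shadow_factor_a must lie in (0, 1]")
        self.proxies = proxies
        self.mgr = mgr
        self.camera = camera
        self.lights = list(lights)
        self.octree = Octree(proxies.primary, leaf_level=leaf_level, hd=hd,
                             hu=hu, normalized_thresholds=normalized_thresholds)
        self.spp = int(spp)
        self.seed = int(seed)
        self.max_bounces = int(max_bounces)
        self.rr_start = int(rr_start)
        self.shadow_factor_a = float(shadow_factor_a)
        self._prepared = False
        self._light_arrays = None

    # -- preparation --------------------------------------------------------

    def prepare(self) -> "Scene":
        """Flatten the manager and run the bottom-up octree update."""
        if not self._prepared:
            self.octree.update(self.mgr)
            self._prepared = True
        return self

    def invalidate(self) -> None:
        """Mark the octree stale after a transfer-function edit."""
        self.mgr.invalidate()
        self._prepared = False

    def light_arrays(self):
        if self._light_arrays is None:
            nl = len(self.lights)
            ltype = np.empty(nl, dtype=np.int64)
            lrgb = np.zeros((nl, 3))
            lpos = np.zeros((nl, 3))
            envmap = np.ones((1, 1, 3), dtype=np.float32)
            for i, li in enumerate(self.lights):
                ltype[i] = _LIGHT_CODES[li.kind]
                lrgb[i] = li.radiance
                if li.position is not None:
                    lpos[i] = li.position
                if li.envmap is not None:
                    envmap = li.envmap
            self._light_arrays = (ltype, lrgb, lpos, envmap)
        return self._light_arrays

    def flat_args(self, global_majorant: bool = False) -> tuple:
        """Kernel argument pack (TF + octree + lights); prepares if needed."""
        self.prepare()
        return (*self.mgr.flatten().tf_args,
                *self.octree.traversal_args(global_majorant),
                *self.light_arrays())


# -- JSON loading -----------------------------------------------------------

def _load_volumes(doc: dict, base: Path) -> ProxyVolumeSet:
    if "phantom" in doc:
        ph = dict(doc["phantom"])
        seed = ph.pop("seed", 0)
        return make_phantom(ph, seed)
    members = {role: read_volume(base / p if not Path(p).is_absolute()
                                 else p)
               for role, p in doc.items()}
    return ProxyVolumeSet(members)


def load_scene(doc, base_dir=None) -> Scene:
    """Build a Scene from a JSON document (path or dict)."""
    if not isinstance(doc, dict):
        path = Path(doc)
        base = path.parent if base_dir is None else Path(base_dir)
        doc = json.loads(path.read_text())
    else:
        base = Path(base_dir) if base_dir is not None else Path(".")
    for key in ("volumes", "tf", "camera", "lights"):
        if key not in doc:
            raise ValueError(f"scene document is missing the {key!r} key")
    proxies = _load_volumes(doc["volumes"], base)
    integ = dict(doc.get("integrator", {}))
    tf_doc = doc["tf"]
    if isinstance(tf_doc, str):
        tf_doc = base / tf_doc
    overrides = {}
    if "channels" in integ:
        overrides["channels"] = integ["channels"]
    if "density_scale" in integ:
        overrides["density_scale"] = integ["density_scale"]
    mgr = tf_from_json(tf_doc, proxies, **overrides)
    cam_doc = dict(doc["camera"])
    camera = Camera(position=cam_doc["position"], look_at=cam_doc["look_at"],
                    up=cam_doc.get("up", [0.0, 1.0, 0.0]),
                    fov=cam_doc.get("fov", 45.0),
                    width=cam_doc.get("width", 256),
                    height=cam_doc.get("height", 256))
    lights = []
    for ld in doc["lights"]:
        envmap = None
        if ld.get("map"):
            from .images import read_pfm
            mp = base / ld["map"] if not Path(ld["map"]).is_absolute() \
                else Path(ld["map"])
            if mp.suffix == ".pfm":
                envmap = read_pfm(mp)
            else:
                import imageio.v3 as iio
                envmap = np.asarray(iio.imread(mp), dtype=np.float32)
                if envmap.ndim == 2:
                    envmap = np.repeat(envmap[:, :, None], 3, axis=2)
                envmap = envmap[:, :, :3]
        lights.append(Light(kind=ld["kind"],
                            radiance=ld.get("radiance",
                                            ld.get("intensity", [1, 1, 1])),
                            position=ld.get("position"), envmap=envmap))
    acc = dict(doc.get("accelerator", {}))
    return Scene(proxies, mgr, camera, lights,
                 leaf_level=acc.get("leaf_level", 4),
                 hd=acc.get("hd", 0.2), hu=acc.get("hu", 0.6),
                 normalized_thresholds=acc.get("normalized_thresholds", True),
                 spp=integ.get("spp", 16), seed=integ.get("seed", 0),
                 max_bounces=integ.get("max_bounces", 32),
                 rr_start=integ.get("rr_start", 3),
                 shadow_factor_a=integ.get("shadow_factor_a", 0.8))
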