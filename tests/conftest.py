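"""Shared fixtures: small phantoms, managers and helper scenes."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from voxpt import (Camera, Light, Scene, TFManager, build_octree,
                   make_phantom, update_octree)
from voxpt.tf import CoefficientVector, Material, TFBinding, TransferFunction
from voxpt.volume import ProxyVolumeSet, Volume

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def unit_cube_volume(values, value_kind="continuous", labels=None):
    """Volume whose world support is exactly [-0.5, 0.5]^3."""
    n = np.asarray(values.shape[:3])
    sp = 1.0 / n
    return Volume(values, spacing=sp, origin=-0.5 + 0.5 * sp,
                  value_kind=value_kind, labels=labels)


def constant_volume(n, value=1.0):
    return unit_cube_volume(np.full((n, n, n), value, dtype=np.float32))


def ramp_x_volume(n=16, length=1.0):
    """f(x, y, z) = x on a support box of the given x-length starting at 0."""
    sp = length / n
    vals = np.empty((n, n, n), dtype=np.float32)
    xs = (np.arange(n) + 0.5) * sp
    vals[:] = xs[:, None, None]
    return Volume(vals, spacing=[sp, sp, sp], origin=[0.5 * sp] * 3)


def opacity_cctf(points, **kw):
    return TransferFunction(
        "CCTF", points=[(v, CoefficientVector(opacity=o, **kw))
                        for v, o in points])


def absorber_manager(pvs, density_scale=1.0):
    """Pure absorber: opacity follows the primary value, no scattering."""
    tf = TransferFunction("CCTF", points=[
        (0.0, CoefficientVector(opacity=0.0, albedo=0.0,
                                volumetric_albedo=0.0)),
        (1.0, CoefficientVector(opacity=1.0, albedo=0.0,
                                volumetric_albedo=0.0))])
    return TFManager(pvs, [TFBinding("primary", tf)],
                     density_scale=density_scale)


@pytest.fixture(scope="session")
def shells32():
    return make_phantom({"family": "nested_shells", "resolution": 32}, seed=1)


@pytest.fixture(scope="session")
def blobs32():
    return make_phantom({"family": "gaussian_blobs", "resolution": 32},
                        seed=2)


@pytest.fixture(scope="session")
def shells_manager(shells32):
    """Priority-mode manager: CCTF on the primary + MDPTF on the mask."""
    cc = TransferFunction("CCTF", points=[
        (0.05, CoefficientVector(opacity=0.0)),
        (0.9, CoefficientVector(opacity=0.8, albedo=[0.8, 0.7, 0.5],
                                volumetric_albedo=[0.6, 0.6, 0.8]))])
    md = TransferFunction("MDPTF", mapping={3: 1})
    mats = [Material(id=1, kind="metal",
                     defaults=CoefficientVector(opacity=1.0,
                                                albedo=[0.9, 0.7, 0.4],
                                                roughness=0.2))]
    return TFManager(shells32, [TFBinding("primary", cc, priority=0),
                                TFBinding("mask", md, priority=1)],
                     mode="priority", materials=mats, density_scale=6.0)


@pytest.fixture(scope="session")
def blob_scene(blobs32):
    """Scattering blob scene under a uniform environment."""
    tf = TransferFunction("CCTF", points=[
        (0.1, CoefficientVector(opacity=0.0)),
        (0.8, CoefficientVector(opacity=1.0, albedo=[0.8, 0.6, 0.4],
                                volumetric_albedo=[0.7, 0.7, 0.9]))])
    mgr = TFManager(blobs32, [TFBinding("primary", tf)], density_scale=8.0)
    cam = Camera(position=[0.0, 0.2, -1.6], look_at=[0.0, 0.0, 0.0],
                 fov=35.0, width=32, height=32)
    lights = [Light("uniform_environment", radiance=[1.0, 1.0, 1.0])]
    return Scene(blobs32, mgr, cam, lights, leaf_level=3, spp=16, seed=3)


def homogeneous_setup(n=16, sigma_t=1.0, leaf_level=2):
    """Homogeneous unit cube with extinction sigma_t; returns (pvs, mgr, oct)."""
    vol = constant_volume(n)
    pvs = ProxyVolumeSet({"primary": vol})
    mgr = absorber_manager(pvs, density_scale=sigma_t)
    octree = build_octree(vol, leaf_level=leaf_level)
    update_octree(octree, mgr)
    return pvs, mgr, octree
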