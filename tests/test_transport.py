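"""Collision sampling, transmittance estimation and next-event estimation."""

import numpy as np
import pytest

from voxpt import (Light, build_octree, direct_light, estimate_transmittance,
                   sample_collision, update_octree)
from voxpt.octree import TraversalSegment
from voxpt.optics import OpticalProperties
from voxpt.tf import CoefficientVector, TFBinding, TFManager, TransferFunction
from voxpt.volume import ProxyVolumeSet

from conftest import homogeneous_setup, ramp_x_volume


def _count_events(props, majorant=1.0, n=10 ** 5, seed=0, length=1e9):
    rng = np.random.default_rng(seed)
    seg = TraversalSegment(0.0, length, 0, majorant)
    counts = {}
    for _ in range(n):
        ev = sample_collision(seg, lambda t: props, rng)
        counts[ev.kind] = counts.get(ev.kind, 0) + 1
    return counts


def test_pure_absorber_only_absorbs():
    props = OpticalProperties(sigma_a=1.0, sigma_s=0.0)
    counts = _count_events(props, majorant=1.0, n=2000)
    assert set(counts) == {"absorb"}


def test_no_surface_particles_means_no_surface_events():
    props = OpticalProperties(sigma_a=0.2, sigma_s=0.3, p_surface=0.0)
    counts = _count_events(props, majorant=1.0, n=5000)
    assert "surface_scatter" not in counts
    assert counts.get("null", 0) > 0


def test_event_frequencies_match_coefficient_ratios():
    """sigma_t = 0.5 under majorant 1: (absorb+scatter):null is 1:1."""
    props = OpticalProperties(sigma_a=0.25, sigma_s=0.25, p_surface=0.4,
                              gradient=[0, 0, 1])
    n = 10 ** 5
    counts = _count_events(props, majorant=1.0, n=n, seed=1)
    real = counts.get("absorb", 0) + counts.get("volume_scatter", 0) \
        + counts.get("surface_scatter", 0)
    null = counts.get("null", 0)
    se = np.sqrt(n * 0.5 * 0.5)
    assert abs(real - null) <= 3 * np.sqrt(2) * se
    # within real events: absorb vs scatter 1:1, surface fraction 0.4
    sc = counts["volume_scatter"] + counts["surface_scatter"]
    assert abs(counts["absorb"] - sc) <= 3 * np.sqrt(real)
    frac = counts["surface_scatter"] / sc
    assert abs(frac - 0.4) <= 3 * np.sqrt(0.4 * 0.6 / sc)


def test_event_probabilities_sum_to_one_for_random_media():
    """The four branch weights always total sigma_maj."""
    rng = np.random.default_rng(5)
    for _ in range(100):
        sa, ss = rng.random(2)
        pr = OpticalProperties(sigma_a=sa, sigma_s=ss,
                               p_surface=rng.random(),
                               gradient=rng.normal(size=3))
        M = sa + ss + rng.random()
        total = (pr.sigma_a + pr.sigma_vs + pr.sigma_fs + (M - pr.sigma_t))
        assert np.allclose(total, M, atol=1e-12)


def test_majorant_violation_raises_with_node_index():
    props = OpticalProperties(sigma_a=2.0, sigma_s=0.0)
    seg = TraversalSegment(0.0, 10.0, 42, 1.0)
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError, match="node 42"):
        for _ in range(50):
            sample_collision(seg, lambda t: props, rng)


def test_transmittance_vacuum_is_exactly_one():
    pvs, mgr, octree = homogeneous_setup(n=8, sigma_t=1.0)
    # ray that misses the volume entirely
    est = estimate_transmittance([0, 2.0, 0], [1, 0, 0], 5.0, 1.0, octree,
                                 mgr, 3, n=10)
    assert np.all(est == 1.0)
    assert np.all(estimate_transmittance([0, 0, 0], [1, 0, 0], 0.0, 1.0,
                                         octree, mgr, 3) == 1.0)


def test_transmittance_homogeneous_beer_lambert():
    pvs, mgr, octree = homogeneous_setup(n=16, sigma_t=1.0)
    n = 10 ** 5
    est = estimate_transmittance([-1, 0.01, 0.02], [1, 0, 0], 3.0, 1.0,
                                 octree, mgr, 17, n=n)[:, 0]
    mean, se = est.mean(), est.std(ddof=1) / np.sqrt(n)
    assert abs(mean - np.exp(-1.0)) <= 3 * se


def test_transmittance_linear_medium_with_shadow_factor():
    """sigma_t(t) = t over [0, 2]; a = 0.8 -> exp(-0.8 * 2)."""
    vol = ramp_x_volume(n=32, length=2.0)
    pvs = ProxyVolumeSet({"primary": vol})
    tf = TransferFunction("CCTF", points=[
        (0.0, CoefficientVector(opacity=0.0, albedo=0.0,
                                volumetric_albedo=0.0)),
        (2.0, CoefficientVector(opacity=2.0, albedo=0.0,
                                volumetric_albedo=0.0))])
    mgr = TFManager(pvs, [TFBinding("primary", tf)], density_scale=1.0)
    octree = build_octree(vol, leaf_level=3)
    update_octree(octree, mgr)
    y = float(vol.origin[1] + 7 * vol.spacing[1])  # along a voxel-centre row
    n = 10 ** 5
    est = estimate_transmittance([0.0, y, y], [1, 0, 0], 2.0, 0.8, octree,
                                 mgr, 23, n=n)[:, 0]
    mean, se = est.mean(), est.std(ddof=1) / np.sqrt(n)
    assert abs(mean - np.exp(-1.6)) <= 3 * se


@pytest.mark.parametrize("seed", range(4))
def test_transmittance_random_piecewise_constant_media(seed):
    """Ratio tracking is unbiased on random piecewise-constant extinction.

    A CPCTF over a linear ramp produces exactly piecewise-constant sigma_t
    along x, so the closed form is a finite product of exponentials.
    """
    rng = np.random.default_rng(100 + seed)
    vol = ramp_x_volume(n=32, length=2.0)
    pvs = ProxyVolumeSet({"primary": vol})
    for _ in range(5):
        nb = rng.integers(1, 4)
        bps = np.sort(rng.uniform(0.1, 1.9, nb))
        levels = rng.uniform(0.0, 2.0, nb + 1)
        tf = TransferFunction("CPCTF", breakpoints=list(bps), intervals=[
            CoefficientVector(opacity=float(o), albedo=0.0,
                              volumetric_albedo=0.0) for o in levels])
        mgr = TFManager(pvs, [TFBinding("primary", tf)], density_scale=1.0)
        octree = build_octree(vol, leaf_level=3)
        update_octree(octree, mgr)
        y = float(vol.origin[1] + 9 * vol.spacing[1])
        # quadrature of the optical depth over the step function
        edges = np.concatenate([[0.0], bps, [2.0]])
        tau = np.sum(np.diff(edges) * levels)
        n = 10 ** 5
        est = estimate_transmittance([0.0, y, y], [1, 0, 0], 2.0, 1.0,
                                     octree, mgr, int(rng.integers(2 ** 31)),
                                     n=n)[:, 0]
        mean, se = est.mean(), est.std(ddof=1) / np.sqrt(n)
        assert abs(mean - np.exp(-tau)) <= 3 * se + 1e-4


def test_shadow_factor_monotonicity():
    """Decreasing a never decreases the expected shadow transmittance."""
    pvs, mgr, octree = homogeneous_setup(n=16, sigma_t=2.0)
    n = 2 * 10 ** 4
    means = []
    for a in (1.0, 0.85, 0.8, 0.75, 0.5):
        est = estimate_transmittance([-1, 0.0, 0.0], [1, 0, 0], 3.0, a,
                                     octree, mgr, 5, n=n)[:, 0]
        means.append(est.mean())
    assert all(b >= a - 3e-3 for a, b in zip(means, means[1:]))
    # and the analytic ordering exp(-a*tau) is reproduced
    for a, m in zip((1.0, 0.85, 0.8, 0.75, 0.5), means):
        assert m == pytest.approx(np.exp(-2.0 * a), abs=0.01)


def test_direct_light_opaque_slab_blocks_point_light():
    pvs, mgr, octree = homogeneous_setup(n=16, sigma_t=500.0)
    props = OpticalProperties(sigma_a=0.0, sigma_s=1.0, p_surface=0.0)
    light = Light("point", radiance=[10.0, 10.0, 10.0],
                  position=[0.0, 0.0, 5.0])
    rng = np.random.default_rng(8)
    out = direct_light([0.0, 0.0, 0.0], [0.0, 0.0, 1.0], "volume_scatter",
                       props, [light], octree, mgr, rng)
    assert np.all(out < 1e-6)


def test_direct_light_vacuum_uniform_environment_returns_radiance():
    """Isotropic phase + perfectly importance-sampled uniform environment:
    the estimator returns exactly E at every volume event."""
    pvs, mgr, octree = homogeneous_setup(n=8, sigma_t=1.0)
    # empty the medium: all-zero TF, octree update marks everything invalid
    from conftest import absorber_manager, constant_volume
    vol0 = constant_volume(8, value=0.0)
    pvs0 = ProxyVolumeSet({"primary": vol0})
    mgr0 = absorber_manager(pvs0)
    octree0 = build_octree(vol0, leaf_level=2)
    update_octree(octree0, mgr0)
    props = OpticalProperties(sigma_a=0.0, sigma_s=1.0, p_surface=0.0,
                              phase_g=0.0)
    E = np.array([2.0, 1.0, 0.5])
    light = Light("uniform_environment", radiance=E)
    rng = np.random.default_rng(9)
    for _ in range(20):
        out = direct_light([0.0, 0.0, 0.0], [0.0, 0.0, 1.0],
                           "volume_scatter", props, [light], octree0, mgr0,
                           rng)
        assert np.allclose(out, E)


def test_direct_light_back_hemisphere_surface_gets_nothing():
    pvs, mgr, octree = homogeneous_setup(n=8, sigma_t=0.0 + 1e-9)
    props = OpticalProperties(sigma_a=0.0, sigma_s=1.0, p_surface=1.0,
                              gradient=[0.0, 0.0, -1.0])  # normal +z
    light = Light("point", radiance=[5.0, 5.0, 5.0],
                  position=[0.0, 0.0, -4.0])  # behind the surface
    rng = np.random.default_rng(10)
    out = direct_light([0.0, 0.0, 0.0], [0.0, 0.0, 1.0], "surface_scatter",
                       props, [light], octree, mgr, rng)
    assert np.all(out == 0.0)
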