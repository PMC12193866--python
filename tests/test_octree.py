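"""Octree structure, bottom-up update against a brute-force oracle, and
multi-level traversal against a dense ray-marching oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from voxpt import (TFManager, build_octree, node_index_at, traverse,
                   update_octree)
from voxpt.tf import CoefficientVector, TFBinding, TransferFunction
from voxpt.volume import ProxyVolumeSet, sample_volume

from conftest import absorber_manager, homogeneous_setup, unit_cube_volume


def _random_setup(seed, n=16, leaf_level=2):
    """Random continuous volume + random CCTF; returns (pvs, mgr, octree)."""
    rng = np.random.default_rng(seed)
    vol = unit_cube_volume(rng.random((n, n, n), dtype=np.float32))
    pvs = ProxyVolumeSet({"primary": vol})
    vals = np.sort(rng.random(4))
    ops = rng.random(4) * rng.integers(0, 2, size=4)  # some zero stretches
    tf = TransferFunction("CCTF", points=[
        (float(v), CoefficientVector(opacity=float(o)))
        for v, o in zip(vals, ops)])
    mgr = TFManager(pvs, [TFBinding("primary", tf)], density_scale=3.0)
    octree = build_octree(vol, leaf_level=leaf_level)
    update_octree(octree, mgr)
    return pvs, mgr, octree, (vals, ops)


def _sigma_oracle(vol, vals, ops, density_scale):
    """Pure-python extinction: trilinear sample -> np.interp opacity."""
    def sigma(points):
        v = np.atleast_1d(sample_volume(vol, points))
        return np.interp(v, vals, ops) * density_scale
    return sigma


def test_node_counts_and_structure():
    pvs, mgr, octree = homogeneous_setup(n=16, leaf_level=2)
    assert len(octree) == 1 + 8 + 64
    for idx in range(len(octree)):
        node = octree.node(idx)
        if node.level > 0:
            parent = octree.node(node.parent_index)
            assert np.sum(parent.child_indices == idx) == 1
            assert np.all(parent.bounds_min <= node.bounds_min + 1e-12)
            assert np.all(node.bounds_max <= parent.bounds_max + 1e-12)
        if node.level < octree.leaf_level:
            kids = [octree.node(c) for c in node.child_indices]
            assert max(k.max_extinction for k in kids) <= node.max_extinction


def test_leaf_core_ranges_partition_voxels():
    vol = unit_cube_volume(np.ones((64, 64, 64), dtype=np.float32))
    octree = build_octree(vol, leaf_level=3)
    spans = octree.leaf_core_hi - octree.leaf_core_lo + 1
    assert np.all(spans == 8)  # 64 / 2**3 voxels per axis before margin
    # core ranges tile the index space exactly once
    cover = np.zeros((64, 64, 64), dtype=np.int32)
    for lo, hi in zip(octree.leaf_core_lo, octree.leaf_core_hi):
        cover[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += 1
    assert np.all(cover == 1)


def test_too_deep_leaf_level_errors():
    vol = unit_cube_volume(np.ones((8, 8, 8), dtype=np.float32))
    with pytest.raises(ValueError, match="less than one voxel"):
        build_octree(vol, leaf_level=4)


def test_node_index_at_octants_and_root():
    pvs, mgr, octree = homogeneous_setup(n=16, leaf_level=2)
    # enumerate the 8 octants at level 1 and verify containment
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                p = 0.2 * np.array([sx, sy, sz])
                idx = node_index_at(octree, p, 1)
                node = octree.node(idx)
                assert node.level == 1
                assert np.all(node.bounds_min <= p)
                assert np.all(p <= node.bounds_max)
    # the (+x, -y, -z) octant is row-major cell (1, 0, 0) -> index 1 + 4
    assert node_index_at(octree, [0.4, -0.4, -0.4], 1) == 5
    assert node_index_at(octree, [0.31, -0.17, 0.42], 0) == 0
    assert node_index_at(octree, [0.9, 0.0, 0.0], 1) == -1  # outside


@given(st.lists(st.floats(-0.49, 0.49), min_size=3, max_size=3),
       st.integers(0, 2))
def test_node_index_containment_property(point, level):
    pvs, mgr, octree = homogeneous_setup(n=16, leaf_level=2)
    idx = node_index_at(octree, point, level)
    node = octree.node(idx)
    assert node.level == level
    assert np.all(node.bounds_min <= np.asarray(point) + 1e-12)
    assert np.all(np.asarray(point) <= node.bounds_max + 1e-12)


def test_update_zero_tf_invalidates_everything(shells32):
    tf = TransferFunction("CCTF", points=[
        (0.0, CoefficientVector(opacity=0.0)),
        (1.0, CoefficientVector(opacity=0.0))])
    mgr = TFManager(shells32, [TFBinding("primary", tf)])
    octree = build_octree(shells32.primary, leaf_level=3)
    update_octree(octree, mgr)
    assert octree.max_ext[0] == 0.0
    assert not octree.node(0).valid
    assert np.all(octree.max_ext == 0.0)


def test_single_hot_voxel_propagates_to_root():
    vals = np.zeros((16, 16, 16), dtype=np.float32)
    vals[5, 9, 3] = 1.0
    vol = unit_cube_volume(vals)
    pvs = ProxyVolumeSet({"primary": vol})
    mgr = absorber_manager(pvs, density_scale=2.0)
    octree = build_octree(vol, leaf_level=2)
    update_octree(octree, mgr)
    assert octree.max_ext[0] == pytest.approx(2.0)
    # every ancestor of the hot voxel's leaf carries the max
    p = vol.origin + np.array([5, 9, 3]) * vol.spacing
    for lev in range(octree.leaf_level + 1):
        assert octree.max_ext[node_index_at(octree, p, lev)] == \
            pytest.approx(2.0)


def _sup_oracle(vol, octree, vals, ops, density_scale):
    """Independent per-leaf supremum: numpy range reduction + curve extrema."""
    grid = vol.scalar_values().astype(np.float64)
    sups = np.empty(len(octree.leaf_lo))
    for q in range(len(octree.leaf_lo)):
        lo, hi = octree.leaf_lo[q], octree.leaf_hi[q]
        block = grid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        vmin, vmax = float(block.min()), float(block.max())
        sup = max(np.interp(vmin, vals, ops), np.interp(vmax, vals, ops))
        for cv, cop in zip(vals, ops):
            if vmin < cv < vmax:
                sup = max(sup, cop)
        sups[q] = sup * density_scale
    return sups


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_update_matches_brute_force_per_node_oracle(seed):
    """Stored leaf majorants equal an independent per-leaf supremum of the
    post-classification extinction (and bound the per-voxel-centre max);
    interior nodes equal the recursive max of their children."""
    pvs, mgr, octree, (vals, ops) = _random_setup(seed, n=16, leaf_level=2)
    vol = pvs.primary
    sigma = _sigma_oracle(vol, vals, ops, mgr.density_scale)
    centres = vol.voxel_centers()
    sig = sigma(centres.reshape(-1, 3)).reshape(centres.shape[:3])
    sups = _sup_oracle(vol, octree, vals, ops, mgr.density_scale)
    off = int(octree.level_off[octree.leaf_level])
    for q in range(len(octree.leaf_lo)):
        lo, hi = octree.leaf_lo[q], octree.leaf_hi[q]
        voxmax = sig[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1].max()
        stored = octree.max_ext[off + q]
        assert stored == pytest.approx(sups[q], abs=1e-9)
        assert stored >= voxmax - 1e-9
    # soundness against dense interpolated samples inside each leaf
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-0.499, 0.499, size=(5000, 3))
    sig_pts = sigma(pts)
    for p, s in zip(pts, sig_pts):
        idx = node_index_at(octree, p, octree.leaf_level)
        assert s <= octree.max_ext[idx] * (1 + 1e-6) + 1e-12
    # interiors: recursive max of children
    for lev in range(octree.leaf_level - 1, -1, -1):
        for idx in range(int(octree.level_off[lev]),
                         int(octree.level_off[lev + 1])):
            node = octree.node(idx)
            expect = max(octree.max_ext[c] for c in node.child_indices)
            assert octree.max_ext[idx] == pytest.approx(expect, abs=1e-12)


def test_traverse_all_invalid_emits_nothing(shells32):
    tf = TransferFunction("CCTF", points=[
        (0.0, CoefficientVector(opacity=0.0)),
        (1.0, CoefficientVector(opacity=0.0))])
    mgr = TFManager(shells32, [TFBinding("primary", tf)])
    octree = build_octree(shells32.primary, leaf_level=3)
    update_octree(octree, mgr)
    assert traverse(octree, [-1, 0.01, 0.02], [1, 0, 0]) == []


def test_traverse_dense_homogeneous_descends_to_leaves():
    """max extinction above hu everywhere -> sampling happens at leaf level."""
    pvs, mgr, octree = homogeneous_setup(n=16, sigma_t=1.0, leaf_level=2)
    segs = traverse(octree, [-1.0, 0.01, 0.02], [1.0, 0.0, 0.0])
    assert segs
    for s in segs:
        assert octree.level_of(s.node_index) == octree.leaf_level
        assert s.majorant == pytest.approx(1.0)
    # segments are ordered, disjoint and cover the full chord
    t = segs[0].t_enter
    assert t == pytest.approx(0.5, abs=1e-3)
    for s in segs:
        assert s.t_exit > s.t_enter
        assert s.t_enter >= t - 1e-9
        t = s.t_exit
    assert t == pytest.approx(1.5, abs=1e-3)


def test_degenerate_ray_direction_errors():
    pvs, mgr, octree = homogeneous_setup()
    with pytest.raises(ValueError):
        traverse(octree, [0, 0, 0], [0, 0, 0])


@pytest.mark.parametrize("seed", [3, 4])
def test_traversal_covers_dense_marcher_intervals(seed):
    """Union of segments covers every sigma_t > 0 point a dense marcher
    finds, and each segment's majorant bounds sigma_t along it."""
    pvs, mgr, octree, (vals, ops) = _random_setup(seed, n=32, leaf_level=3)
    vol = pvs.primary
    sigma = _sigma_oracle(vol, vals, ops, mgr.density_scale)
    step = float(vol.spacing[0]) / 2.0
    rng = np.random.default_rng(seed)
    tol = 1e-3 * float(vol.spacing[0])
    for _ in range(100):
        o = rng.uniform(-0.49, 0.49, 3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        segs = traverse(octree, o, d)
        ts = np.arange(0.0, 2.0, step)
        pts = o[None, :] + ts[:, None] * d[None, :]
        sig = sigma(pts)
        for t, s in zip(ts, sig):
            if s <= 1e-9:
                continue
            inside = [g for g in segs
                      if g.t_enter - tol <= t <= g.t_exit + tol]
            assert inside, f"uncovered sigma_t>0 point at t={t}"
            assert max(g.majorant for g in inside) >= s * (1 - 1e-6)


def test_traversal_never_emits_invalid_nodes(blob_scene):
    blob_scene.prepare()
    octree = blob_scene.octree
    rng = np.random.default_rng(0)
    for _ in range(50):
        o = rng.uniform(-0.6, 0.6, 3)
        d = rng.normal(size=3)
        for s in traverse(octree, o, d):
            assert octree.max_ext[s.node_index] > 0
            assert s.t_exit > s.t_enter
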