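"""Hierarchical volume-grid accelerator (octree stored as a flat list).

The octree is complete and level-major: level ``l`` holds ``8**l`` nodes at
offset ``sum(8**k for k < l)``, so the node covering any point at any level
is direct arithmetic — no pointer walk.  Each node stores only its maximum
post-classification extinction; bounds, parent and children follow from the
index.  Leaves store an index range into the primary volume, dilated by a
one-voxel margin so trilinear interpolation near node faces can never exceed
the stored majorant.

When the transfer function changes, :func:`update_octree` re-derives every
leaf's maximum from exact per-voxel manager evaluations (not a min/max
value-range bound) and propagates maxima bottom-up, so the stored majorants
stay tight for arbitrary multi-dimensional transfer functions.

Ray traversal applies three rules per step: invalid (zero-extinction) nodes
are climbed to the highest invalid ancestor and skipped whole; a node whose
maximum is below ``hd`` climbs (unless its parent exceeds ``hu``) while one
above ``hu`` descends toward the leaves; otherwise the node is emitted as a
sampling segment with its own majorant.  ``hd``/``hu`` default to 0.2/0.6 as
fractions of the root maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from . import _kernels as K
from .volume import Volume

__all__ = ["Octree", "OctreeNode", "TraversalSegment", "build_octree",
           "update_octree", "node_index_at", "traverse"]

_MAX_LEAF_LEVEL = 7


@dataclass
class TraversalSegment:
    """A ray interval inside one octree node, with that node's majorant."""

    t_enter: float
    t_exit: float
    node_index: int
    majorant: float


@dataclass
class OctreeNode:
    """Read-only view of one node of the flat octree."""

    index: int
    level: int
    bounds_min: np.ndarray
    bounds_max: np.ndarray
    parent_index: int
    child_indices: np.ndarray
    max_extinction: float
    voxel_range: Optional[tuple] = None  # (lo, hi) inclusive, leaves only

    @property
    def valid(self) -> bool:
        return self.max_extinction > 0.0


class Octree:
    def __init__(self, volume: Volume, leaf_level: int = 6, hd: float = 0.2,
                 hu: float = 0.6, normalized_thresholds: bool = True):
        if not 1 <= leaf_level <= _MAX_LEAF_LEVEL:
            raise ValueError(f"leaf_level must lie in [1, {_MAX_LEAF_LEVEL}]")
        n = 1 << leaf_level
        dims = volume.dims
        if int(dims.min()) < n:
            raise ValueError(
                f"leaf_level {leaf_level} gives {n} cells per axis but the "
                f"volume has only {dims.tolist()} voxels: a leaf would cover "
                "less than one voxel")
        if not 0 < hd < hu:
            raise ValueError("thresholds must satisfy 0 < hd < hu")
        self.leaf_level = leaf_level
        self.hd = float(hd)
        self.hu = float(hu)
        self.normalized_thresholds = bool(normalized_thresholds)
        self.bounds_min = volume.world_min.copy()
        self.bounds_max = volume.world_max.copy()
        self.dims = dims.copy()
        self.level_off = np.zeros(leaf_level + 2, dtype=np.int64)
        for lev in range(leaf_level + 1):
            self.level_off[lev + 1] = self.level_off[lev] + 8 ** lev
        self.max_ext = np.zeros(int(self.level_off[-1]))
        # proportional voxel split per axis, then a 1-voxel margin per side
        edges = [np.floor(np.arange(n + 1) * dims[a] / n).astype(np.int64)
                 for a in range(3)]
        nleaf = n ** 3
        self.leaf_core_lo = np.empty((nleaf, 3), dtype=np.int64)
        self.leaf_core_hi = np.empty((nleaf, 3), dtype=np.int64)
        cells = np.arange(n)
        cx, cy, cz = np.meshgrid(cells, cells, cells, indexing="ij")
        cell = np.stack([cx.ravel(), cy.ravel(), cz.ravel()], axis=1)
        for a in range(3):
            self.leaf_core_lo[:, a] = edges[a][cell[:, a]]
            self.leaf_core_hi[:, a] = edges[a][cell[:, a] + 1] - 1
        self.leaf_lo = np.maximum(self.leaf_core_lo - 1, 0)
        self.leaf_hi = np.minimum(self.leaf_core_hi + 1, dims - 1)

    # -- structure ----------------------------------------------------------

    def __len__(self) -> int:
        return int(self.level_off[-1])

    @property
    def size(self) -> np.ndarray:
        return self.bounds_max - self.bounds_min

    def level_of(self, index: int) -> int:
        lev = int(np.searchsorted(self.level_off, index, side="right")) - 1
        if not 0 <= index < len(self):
            raise IndexError("node index out of range")
        return lev

    def _cell_of(self, index: int, level: int) -> np.ndarray:
        n = 1 << level
        q = index - int(self.level_off[level])
        return np.array([q // (n * n), (q // n) % n, q % n], dtype=np.int64)

    def _index_of(self, cell: np.ndarray, level: int) -> int:
        n = 1 << level
        return int(self.level_off[level]
                   + (cell[0] * n + cell[1]) * n + cell[2])

    def node(self, index: int) -> OctreeNode:
        lev = self.level_of(index)
        cell = self._cell_of(index, lev)
        edge = self.size / (1 << lev)
        bmin = self.bounds_min + cell * edge
        if lev == 0:
            parent = -1
        else:
            parent = self._index_of(cell // 2, lev - 1)
        if lev < self.leaf_level:
            children = np.empty(8, dtype=np.int64)
            q = 0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        children[q] = self._index_of(
                            cell * 2 + np.array([dx, dy, dz]), lev + 1)
                        q += 1
        else:
            children = np.full(8, -1, dtype=np.int64)
        vr = None
        if lev == self.leaf_level:
            q = index - int(self.level_off[lev])
            vr = (self.leaf_lo[q].copy(), self.leaf_hi[q].copy())
        return OctreeNode(index=index, level=lev, bounds_min=bmin,
                          bounds_max=bmin + edge, parent_index=parent,
                          child_indices=children,
                          max_extinction=float(self.max_ext[index]),
                          voxel_range=vr)

    # -- thresholds ---------------------------------------------------------

    def thresholds_abs(self) -> tuple:
        """(hd, hu) on the absolute extinction scale used by traversal."""
        scale = float(self.max_ext[0]) if self.normalized_thresholds else 1.0
        return self.hd * scale, self.hu * scale

    # -- update -------------------------------------------------------------

    def update(self, mgr) -> "Octree":
        return update_octree(self, mgr)

    def traversal_args(self, global_majorant: bool = False) -> tuple:
        hd_abs, hu_abs = self.thresholds_abs()
        return (self.max_ext, self.level_off, self.leaf_level,
                self.bounds_min, self.size, hd_abs, hu_abs,
                1 if global_majorant else 0)


def build_octree(volume: Volume, leaf_level: int = 6, **kw) -> Octree:
    """Construct a complete octree over a volume; all majorants start at 0."""
    return Octree(volume, leaf_level=leaf_level, **kw)


def _proxy_leaf_ranges(octree: Octree, vol: Volume):
    """Inclusive voxel-index boxes of ``vol`` covering each leaf's margin-
    dilated region (the proxy may be gridded differently from the primary)."""
    if np.array_equal(vol.dims, octree.dims):
        return octree.leaf_lo, octree.leaf_hi
    # world box of the dilated leaf region, mapped into the proxy's grid
    prim_sp = (octree.bounds_max - octree.bounds_min) / octree.dims
    lo_w = octree.bounds_min + (octree.leaf_lo - 0.5) * prim_sp
    hi_w = octree.bounds_min + (octree.leaf_hi + 1.5) * prim_sp
    lo = np.floor((lo_w - vol.origin) / vol.spacing).astype(np.int64)
    hi = np.ceil((hi_w - vol.origin) / vol.spacing).astype(np.int64)
    return (np.clip(lo, 0, vol.dims - 1), np.clip(hi, 0, vol.dims - 1))


def _binding_leaf_sup(octree: Octree, mgr, binding) -> np.ndarray:
    """Per-leaf supremum of one binding's opacity over the leaf region.

    Continuous forms: the opacity curve's supremum over the value interval
    spanned by the leaf's (margin-dilated) voxels — the curve evaluated at
    the interval endpoints plus its own critical values strictly inside.
    Trilinear interpolation cannot leave that interval, and attains every
    value in it, so for a single binding this is the exact supremum of the
    post-classification extinction over the leaf.  Discrete forms have no
    intermediate values: an exact per-voxel-label maximum.
    """
    from .tf import label_opacities, opacity_curve

    vol = mgr.proxies[binding.proxy]
    lo, hi = _proxy_leaf_ranges(octree, vol)
    nleaf = lo.shape[0]
    if binding.tf.is_discrete_form:
        ops = label_opacities(binding.tf, mgr)
        grid = vol.scalar_values().astype(np.float64)
        opgrid = np.zeros_like(grid)
        for lab, op in ops.items():
            opgrid[grid == lab] = op
        mn = np.empty(nleaf)
        mx = np.empty(nleaf)
        K.leaf_range_reduce(opgrid, lo, hi, mn, mx)
        return mx
    op_of, criticals = opacity_curve(binding.tf, mgr)
    grid = np.ascontiguousarray(vol.scalar_values(), dtype=np.float64)
    vmin = np.empty(nleaf)
    vmax = np.empty(nleaf)
    K.leaf_range_reduce(grid, lo, hi, vmin, vmax)
    sup = np.maximum(op_of(vmin), op_of(vmax))
    for cv, cop in criticals:
        if cop > 0:
            inside = (vmin < cv) & (cv < vmax)
            sup = np.where(inside, np.maximum(sup, cop), sup)
    return sup


def update_octree(octree: Octree, mgr) -> Octree:
    """Bottom-up majorant refresh after a transfer-function change.

    Each leaf's majorant is the supremum of the post-classification
    extinction over the leaf's margin-dilated region (see
    :func:`_binding_leaf_sup`; bindings combine by product in multiply mode
    and by maximum in priority mode, both sound upper bounds of the combined
    opacity).  Interior nodes take the max of their children.
    """
    vol = mgr.proxies.primary
    if (not np.allclose(vol.world_min, octree.bounds_min) or
            not np.allclose(vol.world_max, octree.bounds_max) or
            not np.array_equal(vol.dims, octree.dims)):
        raise ValueError("manager volume geometry does not match the octree")
    mgr.flatten()  # validates + caches the kernel tables
    sups = [_binding_leaf_sup(octree, mgr, b) for b in mgr.bindings]
    if mgr.mode == "multiply":
        comb = np.prod(sups, axis=0)
    else:
        comb = np.max(sups, axis=0)
    K.octree_fill_up(comb * mgr.density_scale, octree.max_ext,
                     octree.level_off, octree.leaf_level)
    return octree


def node_index_at(octree: Octree, p, level: int) -> int:
    """Direct arithmetic node lookup; -1 signals a point outside the root."""
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < octree.bounds_min) or np.any(p > octree.bounds_max):
        return -1
    if not 0 <= level <= octree.leaf_level:
        raise ValueError("level out of range")
    n = 1 << level
    cell = np.floor((p - octree.bounds_min) / (octree.size / n)).astype(
        np.int64)
    cell = np.clip(cell, 0, n - 1)
    return octree._index_of(cell, level)


def traverse(octree: Octree, origin, direction,
             global_majorant: bool = False) -> List[TraversalSegment]:
    """Emit the ordered majorant segments of a ray through the octree."""
    o = np.asarray(origin, dtype=np.float64)
    d = np.asarray(direction, dtype=np.float64)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("degenerate ray direction")
    d = d / nrm
    hit, t0, t1 = K._ray_box(o[0], o[1], o[2], d[0], d[1], d[2],
                             *octree.bounds_min, *octree.bounds_max)
    if not hit:
        return []
    t0 = max(t0, 0.0)
    if t1 <= t0:
        return []
    st0 = np.empty(K._MAX_SEG)
    st1 = np.empty(K._MAX_SEG)
    smaj = np.empty(K._MAX_SEG)
    snode = np.empty(K._MAX_SEG, dtype=np.int64)
    n = K.traverse(o[0], o[1], o[2], d[0], d[1], d[2], t0, t1,
                   *octree.traversal_args(global_majorant),
                   st0, st1, smaj, snode)
    return [TraversalSegment(float(st0[i]), float(st1[i]), int(snode[i]),
                             float(smaj[i])) for i in range(n)]
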