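"""Light transport: collision sampling, transmittance and path tracing.

The medium is treated as a mixture of four particle populations — absorbing,
volumetric-scattering, surface-scattering and fictitious (null) particles —
against a per-node majorant.  Free flights are sampled from the majorant
exponential; at a tentative collision the event type is chosen with
probabilities sigma_a/sigma_maj, P_vol*sigma_s/sigma_maj,
P_surf*sigma_s/sigma_maj and sigma_n/sigma_maj (which sum to one because
sigma_n = sigma_maj - sigma_t).  Null collisions leave the path unchanged,
making the estimator exact for heterogeneous media under any valid majorant.

Transmittance uses ratio tracking: an unbiased product estimate of
``exp(-int a * sigma_t dt)``; the self-occlusion factor ``a`` scales the
extinction on shadow rays only (default 0.8, sensible range (0.75, 0.85))
to keep implicit surfaces from darkening their own illumination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import _kernels as K
from ._layout import NOUT
from .octree import Octree, TraversalSegment
from .optics import (OpticalProperties, eval_phase, eval_psf, sample_phase,
                     sample_psf)

__all__ = ["CollisionEvent", "sample_collision", "estimate_transmittance",
           "direct_light", "trace_path"]

_EVENT_KINDS = ("absorb", "volume_scatter", "surface_scatter", "null",
                "escaped")


@dataclass
class CollisionEvent:
    """Outcome of one tentative collision inside a majorant segment."""

    kind: str
    t: float
    weight: np.ndarray = field(default_factory=lambda: np.ones(3))
    props: Optional[OpticalProperties] = None

    def __post_init__(self):
        assert self.kind in _EVENT_KINDS
        self.weight = np.asarray(self.weight, dtype=np.float64).reshape(3)


def _as_seed(rng) -> int:
    if isinstance(rng, (int, np.integer)):
        return int(rng) & 0x7FFFFFFF
    return int(rng.integers(2 ** 31))


def sample_collision(segment: TraversalSegment,
                     props_at: Callable[[float], OpticalProperties],
                     rng: np.random.Generator) -> CollisionEvent:
    """Sample the next tentative collision along a majorant segment.

    ``props_at`` maps the ray parameter t to optical properties.  Returns the
    first event — including null collisions, which the caller simply steps
    past — or ``escaped`` when the free flight leaves the segment.  The event
    ``weight`` carries the per-channel ratio ``sigma_x / (sigma_maj * p_x)``
    of the chosen branch (history-aware single-path spectral tracking).
    """
    M = segment.majorant
    if M <= 0:
        raise ValueError("collision sampling requires a positive majorant")
    t = segment.t_enter - np.log(1.0 - rng.random()) / M
    if t >= segment.t_exit:
        return CollisionEvent("escaped", segment.t_exit)
    pr = props_at(t)
    sig_t = pr.sigma_t
    sig_n = M - sig_t
    if np.min(sig_n) < -(M * 1e-6 + 1e-12):
        raise ValueError(
            f"majorant violation in node {segment.node_index}: extinction "
            f"{float(np.max(sig_t)):.6g} exceeds the stored bound {M:.6g}")
    sig_n = np.maximum(sig_n, 0.0)
    w = np.ones(3)
    ca = float(np.sum(w * pr.sigma_a))
    cn = float(np.sum(w * sig_n))
    cvs = float(np.sum(w * pr.sigma_vs))
    cfs = float(np.sum(w * pr.sigma_fs))
    ctot = ca + cn + cvs + cfs
    pick = rng.random() * ctot
    if pick < ca:
        p = ca / ctot
        return CollisionEvent("absorb", t, pr.sigma_a / (M * p), pr)
    if pick < ca + cn:
        p = cn / ctot
        return CollisionEvent("null", t, sig_n / (M * p), pr)
    if pick < ca + cn + cvs:
        p = cvs / ctot
        return CollisionEvent("volume_scatter", t, pr.sigma_vs / (M * p), pr)
    p = cfs / ctot
    return CollisionEvent("surface_scatter", t, pr.sigma_fs / (M * p), pr)


def estimate_transmittance(origin, direction, length, shadow_a: float,
                           octree: Octree, mgr, rng, n: int = 1) -> np.ndarray:
    """Ratio-tracking estimate(s) of exp(-int a*sigma_t) along a segment.

    Unbiased: the mean over replicates converges to the closed-form
    transmittance.  ``rng`` may be a seed or a numpy Generator; ``n``>1
    returns an (n, 3) array of independent estimates.
    """
    if not 0 < shadow_a <= 1:
        raise ValueError("the extinction scaling factor must lie in (0, 1]")
    o = np.asarray(origin, dtype=np.float64)
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    if length <= 0:
        out = np.ones((n, 3))
        return out[0] if n == 1 else out
    f = mgr.flatten()
    est = np.empty(n)
    K.transmittance_batch(o[0], o[1], o[2], d[0], d[1], d[2], float(length),
                          float(shadow_a), *f.tf_args,
                          *octree.traversal_args(), _as_seed(rng), est)
    out = np.repeat(est[:, None], 3, axis=1)
    return out[0] if n == 1 else out


def direct_light(position, d_in, event_kind: str, props: OpticalProperties,
                 lights, octree: Octree, mgr, rng: np.random.Generator,
                 shadow_a: float = 0.8) -> np.ndarray:
    """Next-event estimation at a real scattering event (reference path).

    Samples each light, weights by the phase function (volume events) or the
    proxy scattering function (surface events) and by a shadow-ray
    transmittance with the self-occlusion factor ``a``.  The event albedo is
    already folded into the path throughput by the caller and therefore does
    not appear here.  Fully occluded lights contribute 0.
    """
    if event_kind not in ("volume_scatter", "surface_scatter"):
        raise ValueError("direct lighting applies to real scattering events")
    q = np.asarray(position, dtype=np.float64)
    d_in = np.asarray(d_in, dtype=np.float64)
    surface = event_kind == "surface_scatter"
    if surface:
        G = -props.gradient  # outward normal of dense structures
        n_hat = G / np.linalg.norm(G)
    total = np.zeros(3)
    for light in lights:
        rad = np.asarray(light.radiance, dtype=np.float64)
        if light.kind == "point":
            to_l = np.asarray(light.position, float) - q
            r = np.linalg.norm(to_l)
            wl = to_l / r
            if surface:
                fval = float(eval_psf(props, G, props.albedo, d_in, wl))
            else:
                fval = float(eval_phase(props.phase_g, d_in, wl))
            if fval <= 0:
                continue
            T = estimate_transmittance(q, wl, r, shadow_a, octree, mgr, rng)
            total += fval * rad / r ** 2 * T
        elif light.kind == "uniform_environment":
            if surface:
                wl, fac = sample_psf(props, G, props.albedo, d_in, rng)
            else:
                wl, fac = sample_phase(props.phase_g, d_in, rng), 1.0
            if fac <= 0:
                continue
            T = estimate_transmittance(q, wl, 1e30, shadow_a, octree, mgr,
                                       rng)
            total += fac * rad * T
        else:  # lat-long environment: uniform-sphere sampling
            u1, u2 = rng.random(2)
            ct = 1 - 2 * u1
            st = np.sqrt(max(0.0, 1 - ct * ct))
            phi = 2 * np.pi * u2
            wl = np.array([st * np.cos(phi), ct, st * np.sin(phi)])
            if surface:
                fval = float(eval_psf(props, G, props.albedo, d_in, wl))
            else:
                fval = float(eval_phase(props.phase_g, d_in, wl))
            if fval <= 0:
                continue
            T = estimate_transmittance(q, wl, 1e30, shadow_a, octree, mgr,
                                       rng)
            total += fval * 4 * np.pi * light.lookup(wl) * T
    return total


def trace_path(origin, direction, scene, rng, max_bounces: Optional[int] = None
               ) -> np.ndarray:
    """One radiance sample for a ray through a prepared scene."""
    o = np.asarray(origin, dtype=np.float64)
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    fa = scene.flat_args()
    bufs = [np.empty(K._MAX_SEG), np.empty(K._MAX_SEG), np.empty(K._MAX_SEG),
            np.empty(K._MAX_SEG, dtype=np.int64),
            np.empty(K._MAX_SEG), np.empty(K._MAX_SEG), np.empty(K._MAX_SEG),
            np.empty(K._MAX_SEG, dtype=np.int64),
            np.empty(NOUT), np.empty(NOUT)]
    mb = scene.max_bounces if max_bounces is None else max_bounces
    state = np.uint64(K.rng_init(_as_seed(rng), 0, 0))
    _, lr, lg, lb = K.trace_path(o[0], o[1], o[2], d[0], d[1], d[2], *fa,
                                 scene.shadow_factor_a, mb, scene.rr_start,
                                 *bufs, state)
    return np.array([lr, lg, lb])
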