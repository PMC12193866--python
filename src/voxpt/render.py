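"""Progressive Monte Carlo render loop."""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import _kernels as K
from .scene import Scene

__all__ = ["render", "RenderStats"]


class RenderStats:
    """Per-pixel accumulation: running mean and standard-error estimate."""

    def __init__(self, image: np.ndarray, m2: np.ndarray, spp: int):
        self.image = image
        self.spp = spp
        self._m2 = m2

    @property
    def pixel_variance(self) -> np.ndarray:
        """Variance of the per-pixel mean estimate."""
        var = np.maximum(self._m2 - self.image ** 2, 0.0)
        return var / max(self.spp - 1, 1)

    def mean_se(self):
        """(mean, SE) of the whole-image per-channel mean radiance."""
        npix = self.image.shape[0] * self.image.shape[1]
        mean = self.image.mean(axis=(0, 1))
        se = np.sqrt(self.pixel_variance.sum(axis=(0, 1))) / npix
        return mean, se


def render(scene: Scene, spp: Optional[int] = None,
           seed: Optional[int] = None, base_sample: int = 0,
           global_majorant: bool = False, return_stats: bool = False):
    """Render the scene: per-pixel mean of spp path-traced samples.

    Samples use stratified sub-pixel jitter (when spp is a perfect square)
    and a counter-based RNG keyed by (seed, pixel, sample index), so results
    are bit-identical for identical (scene, spp, seed) and an accumulation
    over sample ranges [0, N) and [N, 2N) (via ``base_sample``) reproduces a
    single 2N-sample render exactly.

    With ``global_majorant=True`` traversal degenerates to a single
    root-majorant segment per ray (delta tracking stays unbiased under any
    valid majorant; the octree only sharpens it).
    """
    spp = scene.spp if spp is None else int(spp)
    seed = scene.seed if seed is None else int(seed)
    if spp < 1:
        raise ValueError("spp must be >= 1")
    cam = scene.camera
    fwd, right, up, tanf = cam.basis()
    h, w = cam.height, cam.width
    out_sum = np.zeros((h, w, 3))
    out_sumsq = np.zeros((h, w, 3))
    fa = scene.flat_args(global_majorant)
    try:
        K.render_kernel(cam.position, fwd, right, up, tanf, w, h, spp,
                        base_sample, seed, *fa, scene.shadow_factor_a,
                        scene.max_bounces, scene.rr_start, out_sum, out_sumsq)
    except FloatingPointError as err:
        raise FloatingPointError(
            f"non-finite radiance while rendering {w}x{h} at {spp} spp "
            f"(seed {seed})") from err
    image = out_sum / spp
    if return_stats:
        return RenderStats(image, out_sumsq / spp, spp)
    return image
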