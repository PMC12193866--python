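"""Phase function, proxy scattering function and optical properties.

Two angular distributions drive scattering in the model:

* the Henyey-Greenstein phase function for volumetric scattering particles,
  normalized to 1 over the sphere;
* the *proxy scattering function* (PSF) for surface-scattering particles: a
  BSDF ``f`` renormalized by the geometric cosine and the albedo,
  ``fs = f(wi, wo) * (G_hat . wo) / A`` on the front hemisphere and 0 behind
  it (light arriving from the back of the implicit surface is absorbed).  For
  the diffuse BSDF ``f = A / pi`` the PSF integrates to exactly 1 over the
  sphere, which lets surface scattering live inside the volumetric collision
  framework like a phase function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._layout import (KIND_CODES, NOUT, O_A, O_G, O_GRAD, O_KIND, O_LE,
                      O_METAL, O_PFS, O_ROUGH, O_S, O_SFS, O_SIGA, O_SIGS,
                      O_SVS)

__all__ = ["eval_phase", "sample_phase", "eval_psf", "sample_psf",
           "lobe_exponent", "OpticalProperties"]

_KIND_NAMES = {v: k for k, v in KIND_CODES.items()}


def _unit(v, name):
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v, axis=-1)
    if np.any(np.abs(n - 1.0) > 1e-4):
        raise ValueError(f"{name} must be a unit vector")
    return v


def eval_phase(g: float, wi, wo):
    """Henyey-Greenstein density (per steradian) for scattering wi -> wo.

    ``wi`` is the propagation direction of the incident light; ``wo`` may be a
    single direction or an (N, 3) batch.  ``g = 0`` gives the isotropic value
    1 / (4 pi).
    """
    if not -1.0 < g < 1.0:
        raise ValueError("asymmetry g must lie in (-1, 1)")
    wi = _unit(wi, "wi")
    wo = _unit(wo, "wo")
    mu = np.sum(wi * wo, axis=-1)
    g2 = g * g
    return (1.0 - g2) / (4.0 * np.pi * (1.0 + g2 - 2.0 * g * mu) ** 1.5)


def _onb(w: np.ndarray):
    """Build two tangents orthogonal to unit vector w."""
    a = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t = np.cross(w, a)
    t /= np.linalg.norm(t)
    return t, np.cross(w, t)


def sample_phase(g: float, wi, rng: np.random.Generator, n: Optional[int] = None):
    """Draw direction(s) exactly from the Henyey-Greenstein density around wi."""
    if not -1.0 < g < 1.0:
        raise ValueError("asymmetry g must lie in (-1, 1)")
    wi = _unit(wi, "wi")
    m = 1 if n is None else n
    u1 = rng.random(m)
    u2 = rng.random(m)
    if abs(g) < 1e-6:
        mu = 1.0 - 2.0 * u1
    else:
        s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
        mu = (1.0 + g * g - s * s) / (2.0 * g)
    mu = np.clip(mu, -1.0, 1.0)
    phi = 2.0 * np.pi * u2
    st = np.sqrt(np.maximum(0.0, 1.0 - mu * mu))
    t1, t2 = _onb(wi)
    wo = (mu[:, None] * wi[None, :]
          + (st * np.cos(phi))[:, None] * t1[None, :]
          + (st * np.sin(phi))[:, None] * t2[None, :])
    wo /= np.linalg.norm(wo, axis=1, keepdims=True)
    return wo[0] if n is None else wo


def lobe_exponent(roughness: float) -> float:
    """Powered-cosine lobe exponent used by the metal/dielectric BSDFs."""
    r = max(float(roughness), 1e-3)
    return max(1.0, 2.0 / (r * r) - 2.0)


def _kind_name(material) -> tuple[str, float]:
    """Accept a Material object, kind string or kind code; -> (kind, rough)."""
    if isinstance(material, str):
        return material, 0.3
    if isinstance(material, (int, np.integer, float)):
        return _KIND_NAMES[int(material)], 0.3
    rough = getattr(material, "roughness", None)
    if rough is None:  # a Material carries its roughness in the defaults
        defaults = getattr(material, "defaults", None)
        rough = getattr(defaults, "roughness", None)
    return material.kind, 0.3 if rough is None else float(rough)


def eval_psf(material, G, A, wi, wo):
    """Proxy scattering function density (per steradian).

    ``G`` is the (unnormalized) gradient acting as the surface normal, ``A``
    the per-channel surface albedo, ``wi`` the propagation direction of the
    incident light and ``wo`` the outgoing direction (batched allowed).  The
    back hemisphere (``G_hat . wo <= 0``) is fully absorbed and returns 0.
    """
    G = np.asarray(G, dtype=np.float64)
    gn = np.linalg.norm(G)
    if gn <= 0:
        raise ValueError("PSF undefined at zero gradient; surface events "
                         "must not be classified there")
    n = G / gn
    A = np.broadcast_to(np.asarray(A, dtype=np.float64), (3,))
    wi = _unit(wi, "wi")
    wo = _unit(wo, "wo")
    cos_o = np.sum(n * wo, axis=-1)
    kind, rough = _kind_name(material)
    if kind in ("metal", "dielectric"):
        e = lobe_exponent(rough)
        r = wi - 2.0 * np.dot(wi, n) * n
        f_over_a = (e + 2.0) / (2.0 * np.pi) * np.maximum(
            0.0, np.sum(r * wo, axis=-1)) ** e
    else:  # diffuse-family BSDF f = A / pi
        f = A / np.pi
        if np.any((A <= 0) & (f > 0)):
            raise ValueError("albedo component is 0 where the BSDF is nonzero")
        f_over_a = 1.0 / np.pi
    return np.where(cos_o > 0.0, f_over_a * cos_o, 0.0)


def sample_psf(material, G, A, wi, rng: np.random.Generator):
    """Sample an outgoing direction for a surface-scattering event.

    Returns ``(wo, weight)`` where ``weight = fs(wo) / pdf(wo)``; a direction
    landing in the absorbing back hemisphere yields weight 0 (the energy is
    absorbed by the surface, consistent with treating sub-unit PSF integrals
    as surface absorption).
    """
    G = np.asarray(G, dtype=np.float64)
    gn = np.linalg.norm(G)
    if gn <= 0:
        raise ValueError("cannot sample a surface event at zero gradient")
    n = G / gn
    wi = _unit(wi, "wi")
    kind, rough = _kind_name(material)
    u1, u2 = rng.random(2)
    if kind in ("metal", "dielectric"):
        e = lobe_exponent(rough)
        r = wi - 2.0 * np.dot(wi, n) * n
        ct = u1 ** (1.0 / (e + 1.0))
        st = np.sqrt(max(0.0, 1.0 - ct * ct))
        phi = 2.0 * np.pi * u2
        t1, t2 = _onb(r)
        wo = ct * r + st * np.cos(phi) * t1 + st * np.sin(phi) * t2
        cos_o = float(np.dot(n, wo))
        if cos_o <= 0.0:
            return wo, 0.0
        # fs / pdf with pdf = (e+1)/(2 pi) (r.wo)^e
        return wo, (e + 2.0) / (e + 1.0) * cos_o
    # cosine-weighted hemisphere around the normal: fs/pdf = 1 exactly
    ct = np.sqrt(u1)
    st = np.sqrt(max(0.0, 1.0 - u1))
    phi = 2.0 * np.pi * u2
    t1, t2 = _onb(n)
    wo = ct * n + st * np.cos(phi) * t1 + st * np.sin(phi) * t2
    return wo, 1.0


def _vec3(x, default=0.0):
    if x is None:
        x = default
    return np.broadcast_to(np.asarray(x, dtype=np.float64), (3,)).copy()


@dataclass
class OpticalProperties:
    """Complete optical description of one point, as consumed by transport.

    The extinction decomposes per channel as
    ``sigma_t = sigma_a + sigma_vs + sigma_fs`` (absorption, volumetric
    scattering, surface scattering); ``sigma_s = sigma_vs + sigma_fs``.  The
    particle-type probabilities satisfy ``p_surface + p_volume == 1`` exactly.
    """

    sigma_a: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sigma_s: np.ndarray = field(default_factory=lambda: np.zeros(3))
    albedo: np.ndarray = field(default_factory=lambda: 0.8 * np.ones(3))
    volumetric_albedo: np.ndarray = field(default_factory=lambda: 0.8 * np.ones(3))
    emission: np.ndarray = field(default_factory=lambda: np.zeros(3))
    p_surface: float = 0.0
    gradient: np.ndarray = field(default_factory=lambda: np.zeros(3))
    roughness: float = 0.3
    metallic: float = 0.0
    phase_g: float = 0.0
    kind: str = "diffuse"
    sigma_vs: Optional[np.ndarray] = None
    sigma_fs: Optional[np.ndarray] = None

    def __post_init__(self):
        self.sigma_a = _vec3(self.sigma_a)
        self.sigma_s = _vec3(self.sigma_s)
        self.albedo = _vec3(self.albedo)
        self.volumetric_albedo = _vec3(self.volumetric_albedo)
        self.emission = _vec3(self.emission)
        self.gradient = np.asarray(self.gradient, dtype=np.float64).reshape(3)
        if np.any(self.sigma_a < 0) or np.any(self.sigma_s < 0):
            raise ValueError("extinction components must be non-negative")
        if not 0.0 <= self.p_surface <= 1.0:
            raise ValueError("p_surface must lie in [0, 1]")
        for nm in ("albedo", "volumetric_albedo"):
            v = getattr(self, nm)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{nm} must lie in [0, 1] per channel")
        if self.sigma_vs is None:
            self.sigma_vs = (1.0 - self.p_surface) * self.sigma_s
        else:
            self.sigma_vs = _vec3(self.sigma_vs)
        if self.sigma_fs is None:
            self.sigma_fs = self.p_surface * self.sigma_s
        else:
            self.sigma_fs = _vec3(self.sigma_fs)

    @property
    def sigma_t(self) -> np.ndarray:
        return self.sigma_a + self.sigma_s

    @property
    def p_volume(self) -> float:
        return 1.0 - self.p_surface

    @classmethod
    def from_row(cls, row: np.ndarray) -> "OpticalProperties":
        """Build from a manager-evaluation kernel output row."""
        assert row.shape[-1] == NOUT
        return cls(sigma_a=row[O_SIGA:O_SIGA + 3],
                   sigma_s=row[O_SIGS:O_SIGS + 3],
                   albedo=np.clip(row[O_A:O_A + 3], 0, 1),
                   volumetric_albedo=np.clip(row[O_S:O_S + 3], 0, 1),
                   emission=row[O_LE:O_LE + 3],
                   p_surface=float(row[O_PFS]),
                   gradient=row[O_GRAD:O_GRAD + 3],
                   roughness=float(row[O_ROUGH]),
                   metallic=float(row[O_METAL]),
                   phase_g=float(row[O_G]),
                   kind=_KIND_NAMES[int(row[O_KIND])],
                   sigma_vs=row[O_SVS:O_SVS + 3],
                   sigma_fs=row[O_SFS:O_SFS + 3])
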