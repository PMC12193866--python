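"""Transfer functions, materials and the transfer-function manager.

Five standardized transfer-function forms map proxy-volume values to optical
coefficients or material identities:

* ``CCTF``  - coefficient curve: sorted control points, linearly interpolated
  component-wise (continuous proxies only).
* ``CPCTF`` - coefficient piecewise constant: interior breakpoints with one
  coefficient vector per half-open interval ``[b_i, b_{i+1})``.
* ``CDPTF`` - coefficient discrete point: exact label -> coefficient vector.
* ``MPCTF`` - material piecewise constant: breakpoints with one material id
  per interval (materials are discrete; never interpolated).
* ``MDPTF`` - material discrete point: exact label -> material id.

The :class:`TFManager` binds transfer functions to the members of a proxy
volume set and is the single classification entry point of the renderer: it
maps a world position to complete :class:`~voxpt.optics.OpticalProperties`.
Bindings combine either by component-wise multiplication or by priority
(the highest-priority binding with nonzero opacity wins outright).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _layout as L
from .optics import OpticalProperties
from .volume import ProxyVolumeSet

__all__ = ["CoefficientVector", "Material", "TransferFunction", "TFBinding",
           "TFManager", "eval_tf", "tf_from_json", "tf_to_json",
           "UNCLASSIFIED"]

_COEF_KEYS = ("opacity", "albedo", "volumetric_albedo", "emission",
              "roughness", "metallic", "phase_g")

#: Field values used when neither a control point nor a material supplies one.
_GLOBAL_DEFAULT = np.zeros(L.NC)
_GLOBAL_DEFAULT[L.C_OP] = 1.0
_GLOBAL_DEFAULT[L.C_A:L.C_A + 3] = 0.8
_GLOBAL_DEFAULT[L.C_S:L.C_S + 3] = 0.8
_GLOBAL_DEFAULT[L.C_ROUGH] = 0.3
_GLOBAL_DEFAULT[L.C_SURF] = -1.0  # gradient-driven surface probability

#: Default surface-probability behaviour per material kind (None = auto).
_KIND_SURFACE = {"diffuse": None, "metal": 1.0, "dielectric": 1.0,
                 "highlight": 1.0, "emissive": 0.0}


class CoefficientVector:
    """Optical coefficients produced by a transfer function.

    Any field left ``None`` is *absent* and falls back to the bound
    material's default (and ultimately to the global defaults).
    """

    def __init__(self, opacity=None, albedo=None, volumetric_albedo=None,
                 emission=None, roughness=None, metallic=None, phase_g=None):
        self.opacity = opacity
        self.albedo = albedo
        self.volumetric_albedo = volumetric_albedo
        self.emission = emission
        self.roughness = roughness
        self.metallic = metallic
        self.phase_g = phase_g
        self._validate()

    def _validate(self):
        if self.opacity is not None and self.opacity < 0:
            raise ValueError("opacity scale must be >= 0")
        for nm in ("albedo", "volumetric_albedo"):
            v = getattr(self, nm)
            if v is not None:
                v = np.broadcast_to(np.asarray(v, float), (3,))
                if np.any(v < 0) or np.any(v > 1):
                    raise ValueError(f"{nm} must lie in [0, 1]")
        if self.emission is not None and np.any(np.asarray(self.emission) < 0):
            raise ValueError("emission must be >= 0")
        for nm in ("roughness", "metallic"):
            v = getattr(self, nm)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{nm} must lie in [0, 1]")
        if self.phase_g is not None and not -1 < self.phase_g < 1:
            raise ValueError("phase asymmetry must lie in (-1, 1)")

    def partial_row(self) -> np.ndarray:
        """Coefficient row with NaN marking absent entries (no kind/surf)."""
        row = np.full(L.NC, np.nan)
        if self.opacity is not None:
            row[L.C_OP] = self.opacity
        for key, col in (("albedo", L.C_A), ("volumetric_albedo", L.C_S),
                         ("emission", L.C_LE)):
            v = getattr(self, key)
            if v is not None:
                row[col:col + 3] = np.broadcast_to(np.asarray(v, float), (3,))
        for key, col in (("roughness", L.C_ROUGH), ("metallic", L.C_METAL),
                         ("phase_g", L.C_G)):
            v = getattr(self, key)
            if v is not None:
                row[col] = v
        return row

    def to_json(self) -> dict:
        doc = {}
        for key in _COEF_KEYS:
            v = getattr(self, key)
            if v is not None:
                doc[key] = (list(np.broadcast_to(np.asarray(v, float), (3,)))
                            if key in ("albedo", "volumetric_albedo",
                                       "emission") and np.ndim(v) > 0
                            else v)
        return doc

    @classmethod
    def from_json(cls, doc: dict) -> "CoefficientVector":
        unknown = set(doc) - set(_COEF_KEYS)
        if unknown:
            raise ValueError(f"unknown coefficient keys {sorted(unknown)}")
        return cls(**doc)


#: The entry returned for unmapped labels of discrete transfer functions.
UNCLASSIFIED = CoefficientVector(opacity=0.0)


@dataclass
class Material:
    """A named material: kind plus default coefficients.

    ``surface_probability`` fixes the surface-scattering particle probability
    Pfs for this material (1 = pure surface scatterer, 0 = purely volumetric);
    ``None`` leaves it gradient-driven.  Surface-like kinds (metal,
    dielectric, highlight) default to 1, emissive to 0, diffuse to auto.
    """

    id: int
    kind: str = "diffuse"
    defaults: CoefficientVector = field(default_factory=CoefficientVector)
    surface_probability: Optional[float] = None

    def __post_init__(self):
        if self.kind not in L.KIND_CODES:
            raise ValueError(f"unknown material kind {self.kind!r}")
        if self.surface_probability is None:
            self.surface_probability = _KIND_SURFACE[self.kind]
        if (self.surface_probability is not None
                and not 0 <= self.surface_probability <= 1):
            raise ValueError("surface_probability must lie in [0, 1]")

    def row(self) -> np.ndarray:
        """Fully resolved coefficient row including kind/surf columns."""
        row = self.defaults.partial_row()
        row = np.where(np.isnan(row), _GLOBAL_DEFAULT, row)
        row[L.C_KIND] = L.KIND_CODES[self.kind]
        row[L.C_SURF] = -1.0 if self.surface_probability is None \
            else float(self.surface_probability)
        return row


_DEFAULT_MATERIAL = Material(id=-1, kind="diffuse")


class TransferFunction:
    """One of the five standardized transfer-function forms.

    Parameters depend on the form:

    * CCTF: ``points`` — list of ``(value, CoefficientVector)``.
    * CPCTF: ``breakpoints`` (interior, sorted) and ``intervals`` — list of
      ``len(breakpoints) + 1`` CoefficientVectors.
    * CDPTF: ``mapping`` — ``{label: CoefficientVector}``.
    * MPCTF: ``breakpoints`` and ``materials`` — list of material ids.
    * MDPTF: ``mapping`` — ``{label: material id}``.

    ``material`` optionally names the material supplying defaults for the
    coefficient forms.
    """

    def __init__(self, form: str, points=None, breakpoints=None,
                 intervals=None, mapping=None, materials=None,
                 material: Optional[int] = None):
        if form not in L.FORM_CODES:
            raise ValueError(f"unknown transfer-function form {form!r}")
        self.form = form
        self.material = material
        self.points: List[Tuple[float, CoefficientVector]] = []
        self.breakpoints: List[float] = []
        self.intervals: List[CoefficientVector] = []
        self.mapping: Dict[int, Union[CoefficientVector, int]] = {}
        self.interval_materials: List[int] = []

        if form == "CCTF":
            if not points:
                raise ValueError("CCTF requires control points")
            vals = [float(v) for v, _ in points]
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError("CCTF control values must be strictly "
                                 "increasing")
            self.points = [(float(v), c) for v, c in points]
        elif form in ("CPCTF", "MPCTF"):
            self.breakpoints = [float(b) for b in (breakpoints or [])]
            if any(b <= a for a, b in
                   zip(self.breakpoints, self.breakpoints[1:])):
                raise ValueError(f"{form} breakpoints must be strictly "
                                 "increasing")
            if form == "CPCTF":
                self.intervals = list(intervals or [])
                if len(self.intervals) != len(self.breakpoints) + 1:
                    raise ValueError("CPCTF needs one coefficient vector per "
                                     "interval (len(breakpoints) + 1)")
            else:
                self.interval_materials = [int(m) for m in (materials or [])]
                if len(self.interval_materials) != len(self.breakpoints) + 1:
                    raise ValueError("MPCTF needs one material id per "
                                     "interval (len(breakpoints) + 1)")
        elif form in ("CDPTF", "MDPTF"):
            if not mapping:
                raise ValueError(f"{form} requires a label mapping")
            self.mapping = {int(k): v for k, v in mapping.items()}
        self.is_material_form = form in ("MPCTF", "MDPTF")
        self.is_discrete_form = form in ("CDPTF", "MDPTF")

    # -- evaluation ---------------------------------------------------------

    def __call__(self, v: float):
        return eval_tf(self, v)

    def labels(self) -> Sequence[int]:
        return tuple(self.mapping.keys())


def eval_tf(tf: TransferFunction, v: float):
    """Evaluate a transfer function at proxy value ``v``.

    Coefficient forms return a :class:`CoefficientVector` (absent entries
    resolved against global defaults for standalone evaluation); material
    forms return a material id.  Unmapped labels of discrete forms return the
    ``UNCLASSIFIED`` entry (opacity 0) / ``None`` — never an exception.
    Queries exactly at a breakpoint take the right interval; CCTF queries
    outside the control range clamp to the end values.
    """
    v = float(v)
    if tf.form == "CCTF":
        rows = _cctf_rows(tf, _DEFAULT_MATERIAL)
        xs = np.array([p[0] for p in tf.points])
        row = _interp_row(xs, rows, v)
        return _row_to_coeff(row)
    if tf.form == "CPCTF":
        idx = int(np.searchsorted(np.asarray(tf.breakpoints), v, side="right"))
        return tf.intervals[idx]
    if tf.form == "MPCTF":
        idx = int(np.searchsorted(np.asarray(tf.breakpoints), v, side="right"))
        return tf.interval_materials[idx]
    if tf.form == "CDPTF":
        return tf.mapping.get(int(round(v)), UNCLASSIFIED)
    # MDPTF
    out = tf.mapping.get(int(round(v)))
    return None if out is None else int(out)


def _cctf_rows(tf: TransferFunction, mat: Material) -> np.ndarray:
    base = mat.row()
    rows = np.empty((len(tf.points), L.NC))
    for i, (_, coeff) in enumerate(tf.points):
        pr = coeff.partial_row()
        rows[i] = np.where(np.isnan(pr), base, pr)
    return rows


def _interp_row(xs: np.ndarray, rows: np.ndarray, v: float) -> np.ndarray:
    if v <= xs[0]:
        return rows[0]
    if v >= xs[-1]:
        return rows[-1]
    j = int(np.searchsorted(xs, v, side="right"))
    t = (v - xs[j - 1]) / (xs[j] - xs[j - 1])
    row = (1 - t) * rows[j - 1] + t * rows[j]
    row[L.C_KIND] = rows[j - 1][L.C_KIND]   # material identity never lerps
    row[L.C_SURF] = rows[j - 1][L.C_SURF]
    return row


def _row_to_coeff(row: np.ndarray) -> CoefficientVector:
    return CoefficientVector(opacity=float(row[L.C_OP]),
                             albedo=row[L.C_A:L.C_A + 3].copy(),
                             volumetric_albedo=row[L.C_S:L.C_S + 3].copy(),
                             emission=row[L.C_LE:L.C_LE + 3].copy(),
                             roughness=float(np.clip(row[L.C_ROUGH], 0, 1)),
                             metallic=float(np.clip(row[L.C_METAL], 0, 1)),
                             phase_g=float(row[L.C_G]))


@dataclass
class TFBinding:
    """A transfer function attached to one member of the proxy set."""

    proxy: str
    tf: TransferFunction
    priority: int = 0


class TFManager:
    """Maps a world position to the optical properties of that position.

    Parameters
    ----------
    proxies : ProxyVolumeSet
    bindings : list of TFBinding
    mode : "multiply" or "priority"
        multiply: coefficient vectors combine by component-wise product
        (roughness/metallic/phase_g average weighted by opacity);
        priority: the highest-priority binding with opacity > 0 wins.
    materials : materials referenced by material-form TFs and bindings.
    density_scale : sigma_ref; extinction is opacity * density_scale per
        world unit (default 100).
    g_ref, grad_gamma : parameters of the gradient-driven surface
        probability Pfs = min(1, (|G| / g_ref) ** gamma); g_ref defaults to
        the 98th percentile of the gradient-magnitude proxy.
    channels : "single" (scalar sigma_t, albedo carries colour) or "multi"
        (per-channel coefficients with single-path spectral tracking).
    """

    def __init__(self, proxies: ProxyVolumeSet, bindings: List[TFBinding],
                 mode: str = "multiply",
                 materials: Optional[Sequence[Material]] = None,
                 density_scale: float = 100.0,
                 g_ref: Optional[float] = None, grad_gamma: float = 1.0,
                 channels: str = "single"):
        if mode not in L.MODE_CODES:
            raise ValueError(f"unknown combine mode {mode!r}")
        if channels not in L.CHAN_CODES:
            raise ValueError(f"unknown channel mode {channels!r}")
        if density_scale <= 0:
            raise ValueError("density_scale must be positive")
        self.proxies = proxies
        self.bindings = list(bindings)
        self.mode = mode
        self.materials = {m.id: m for m in (materials or [])}
        self.density_scale = float(density_scale)
        self.grad_gamma = float(grad_gamma)
        self.channels = channels
        self._g_ref = g_ref
        self._flat = None
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if not self.bindings:
            raise ValueError("a TFManager requires at least one binding")
        for k, b in enumerate(self.bindings):
            name = f"binding {k} ({b.tf.form} on {b.proxy!r})"
            if b.proxy not in self.proxies:
                raise ValueError(f"{name}: proxy volume not loaded")
            vol = self.proxies[b.proxy]
            if b.tf.is_discrete_form:
                if vol.value_kind != "discrete":
                    raise ValueError(
                        f"{name}: discrete transfer-function forms bind only "
                        "to discrete (label) volumes")
                extra = set(b.tf.labels()) - set(vol.labels or ())
                if extra:
                    raise ValueError(
                        f"{name}: labels {sorted(extra)} are not in the "
                        f"volume's label set {vol.labels}")
            else:
                if vol.value_kind != "continuous":
                    raise ValueError(
                        f"{name}: form {b.tf.form} requires a continuous "
                        "volume (discrete labels must not be interpolated)")
            for mid in self._referenced_materials(b.tf):
                if mid not in self.materials:
                    raise ValueError(f"{name}: material id {mid} is not "
                                     "registered")

    @staticmethod
    def _referenced_materials(tf: TransferFunction):
        if tf.form == "MPCTF":
            return list(tf.interval_materials)
        if tf.form == "MDPTF":
            return [int(v) for v in tf.mapping.values()]
        return [] if tf.material is None else [tf.material]

    # -- derived parameters -------------------------------------------------

    @property
    def g_ref(self) -> float:
        if self._g_ref is None:
            if "gradient_magnitude" in self.proxies:
                g = self.proxies["gradient_magnitude"].values
            else:
                vol = self.proxies.primary
                gs = np.gradient(vol.scalar_values().astype(np.float64),
                                 *vol.spacing, edge_order=1)
                g = np.sqrt(sum(a * a for a in gs))
            ref = float(np.percentile(g, 98.0))
            self._g_ref = ref if ref > 0 else 1.0
        return self._g_ref

    def invalidate(self) -> None:
        """Drop cached flattened tables after editing bindings in place."""
        self._flat = None

    # -- flattening for the kernels -----------------------------------------

    def flatten(self):
        if self._flat is not None:
            return self._flat
        from . import _flat
        self._flat = _flat.flatten_manager(self)
        return self._flat

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, p) -> OpticalProperties:
        """Optical properties at world point ``p`` (pure in ``p``)."""
        row = self.evaluate_raw(np.asarray(p, float).reshape(1, 3))[0]
        return OpticalProperties.from_row(row)

    def evaluate_raw(self, points: np.ndarray) -> np.ndarray:
        """Kernel-layout property rows for an (N, 3) batch of points."""
        from . import _kernels as K
        f = self.flatten()
        pts = np.ascontiguousarray(points, dtype=np.float64)
        out = np.empty((len(pts), L.NOUT))
        K.eval_props_many(pts, *f.tf_args, out)
        return out


def manager_evaluate(mgr: TFManager, p) -> OpticalProperties:
    """Functional alias for :meth:`TFManager.evaluate`."""
    return mgr.evaluate(p)


def _resolve_row(cv: CoefficientVector, mat: Material) -> np.ndarray:
    pr = cv.partial_row()
    return np.where(np.isnan(pr), mat.row(), pr)


def opacity_curve(tf: TransferFunction, mgr: "TFManager"):
    """Opacity as a function of proxy value, for continuous TF forms.

    Returns ``(op_of, criticals)`` where ``op_of`` maps a value array to
    opacity scales and ``criticals`` lists ``(value, opacity)`` pairs at
    which the curve attains local extrema (control points; breakpoint
    levels).  Used by the accelerator to bound the extinction over a value
    interval exactly.
    """
    mat = (_DEFAULT_MATERIAL if tf.material is None
           else mgr.materials[tf.material])
    if tf.form == "CCTF":
        xs = np.array([v for v, _ in tf.points])
        ops = np.array([_resolve_row(c, mat)[L.C_OP] for _, c in tf.points])
        return (lambda v: np.interp(v, xs, ops)), list(zip(xs, ops))
    if tf.form == "CPCTF":
        bps = np.asarray(tf.breakpoints, dtype=float)
        ops = np.array([_resolve_row(c, mat)[L.C_OP] for c in tf.intervals])
    elif tf.form == "MPCTF":
        bps = np.asarray(tf.breakpoints, dtype=float)
        ops = np.array([mgr.materials[m].row()[L.C_OP]
                        for m in tf.interval_materials])
    else:
        raise ValueError(f"{tf.form} has no continuous opacity curve")
    criticals = [(b, max(ops[i], ops[i + 1])) for i, b in enumerate(bps)]

    def op_of(v):
        return ops[np.searchsorted(bps, np.asarray(v), side="right")]

    return op_of, criticals


def label_opacities(tf: TransferFunction, mgr: "TFManager") -> dict:
    """label -> opacity scale for the discrete TF forms."""
    mat = (_DEFAULT_MATERIAL if tf.material is None
           else mgr.materials[tf.material])
    if tf.form == "CDPTF":
        return {lab: float(_resolve_row(c, mat)[L.C_OP])
                for lab, c in tf.mapping.items()}
    if tf.form == "MDPTF":
        return {lab: float(mgr.materials[int(m)].row()[L.C_OP])
                for lab, m in tf.mapping.items()}
    raise ValueError(f"{tf.form} is not a discrete form")


def validate_tf_doc(doc: dict) -> list:
    """Schema-level validation of a transfer-function document.

    Returns a list of problem strings (empty when valid).  Role conventions
    stand in for the volumes: the ``mask`` proxy is discrete, all other
    roles are continuous.
    """
    problems = []
    if doc.get("mode", "multiply") not in L.MODE_CODES:
        problems.append(f"unknown combine mode {doc.get('mode')!r}")
    ids = {int(m["id"]) for m in doc.get("materials", [])}
    for m in doc.get("materials", []):
        if m.get("kind", "diffuse") not in L.KIND_CODES:
            problems.append(f"material {m.get('id')}: unknown kind "
                            f"{m.get('kind')!r}")
    for k, b in enumerate(doc.get("bindings", [])):
        name = f"binding {k} ({b.get('form')} on {b.get('proxy')!r})"
        form = b.get("form")
        proxy = b.get("proxy")
        if form not in L.FORM_CODES:
            problems.append(f"{name}: unknown form")
            continue
        if proxy not in ("primary", "gradient_magnitude", "opacity", "mask"):
            problems.append(f"{name}: unknown proxy role")
            continue
        discrete_form = form in ("CDPTF", "MDPTF")
        if discrete_form and proxy != "mask":
            problems.append(f"{name}: discrete form bound to the continuous "
                            f"proxy {proxy!r}")
        if not discrete_form and proxy == "mask":
            problems.append(f"{name}: form {form} interpolates values and "
                            "cannot bind to the discrete 'mask' proxy")
        try:
            tf = _tf_payload_from_json(dict(b))
        except (KeyError, ValueError) as err:
            problems.append(f"{name}: {err}")
            continue
        for mid in TFManager._referenced_materials(tf):
            if mid not in ids:
                problems.append(f"{name}: material id {mid} is not declared")
    if not doc.get("bindings"):
        problems.append("document declares no bindings")
    return problems


# -- JSON (de)serialization -------------------------------------------------

def _tf_payload_to_json(tf: TransferFunction) -> dict:
    doc = {"form": tf.form}
    if tf.material is not None:
        doc["material"] = tf.material
    if tf.form == "CCTF":
        doc["points"] = [dict(value=v, **c.to_json()) for v, c in tf.points]
    elif tf.form == "CPCTF":
        doc["breakpoints"] = tf.breakpoints
        doc["intervals"] = [c.to_json() for c in tf.intervals]
    elif tf.form == "MPCTF":
        doc["breakpoints"] = tf.breakpoints
        doc["materials"] = tf.interval_materials
    elif tf.form == "CDPTF":
        doc["map"] = {str(k): v.to_json() for k, v in tf.mapping.items()}
    else:
        doc["map"] = {str(k): int(v) for k, v in tf.mapping.items()}
    return doc


def _tf_payload_from_json(doc: dict) -> TransferFunction:
    form = doc["form"]
    material = doc.get("material")
    if form == "CCTF":
        pts = []
        for p in doc["points"]:
            p = dict(p)
            v = p.pop("value")
            pts.append((v, CoefficientVector.from_json(p)))
        return TransferFunction("CCTF", points=pts, material=material)
    if form == "CPCTF":
        return TransferFunction(
            "CPCTF", breakpoints=doc.get("breakpoints", []),
            intervals=[CoefficientVector.from_json(c)
                       for c in doc["intervals"]], material=material)
    if form == "MPCTF":
        return TransferFunction("MPCTF", breakpoints=doc.get("breakpoints", []),
                                materials=doc["materials"])
    if form == "CDPTF":
        return TransferFunction(
            "CDPTF", mapping={int(k): CoefficientVector.from_json(c)
                              for k, c in doc["map"].items()},
            material=material)
    if form == "MDPTF":
        return TransferFunction("MDPTF", mapping={int(k): int(v)
                                                  for k, v in
                                                  doc["map"].items()})
    raise ValueError(f"unknown transfer-function form {form!r}")


def tf_to_json(mgr: TFManager) -> dict:
    """Serialize a manager (without the volumes) to a JSON document."""
    return {
        "proxies": list(mgr.proxies.roles),
        "mode": mgr.mode,
        "channels": mgr.channels,
        "density_scale": mgr.density_scale,
        "bindings": [dict(proxy=b.proxy, priority=b.priority,
                          **_tf_payload_to_json(b.tf))
                     for b in mgr.bindings],
        "materials": [{"id": m.id, "kind": m.kind,
                       "defaults": m.defaults.to_json(),
                       "surface_probability": m.surface_probability}
                      for m in mgr.materials.values()],
    }


def tf_from_json(doc, proxies: ProxyVolumeSet, **overrides) -> TFManager:
    """Build a manager from a JSON document (path, string or dict)."""
    if isinstance(doc, (str,)) and doc.strip().startswith("{"):
        doc = json.loads(doc)
    elif not isinstance(doc, dict):
        with open(doc) as fh:
            doc = json.load(fh)
    materials = [Material(id=int(m["id"]), kind=m.get("kind", "diffuse"),
                          defaults=CoefficientVector.from_json(
                              m.get("defaults", {})),
                          surface_probability=m.get("surface_probability"))
                 for m in doc.get("materials", [])]
    bindings = []
    for b in doc["bindings"]:
        b = dict(b)
        proxy = b.pop("proxy")
        priority = b.pop("priority", 0)
        bindings.append(TFBinding(proxy=proxy, tf=_tf_payload_from_json(b),
                                  priority=priority))
    kwargs = dict(mode=doc.get("mode", "multiply"),
                  materials=materials,
                  density_scale=doc.get("density_scale", 100.0),
                  channels=doc.get("channels", "single"),
                  g_ref=doc.get("g_ref"),
                  grad_gamma=doc.get("grad_gamma", 1.0))
    kwargs.update(overrides)
    return TFManager(proxies, bindings, **kwargs)
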