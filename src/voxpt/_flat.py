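"""Flattening of the object model into kernel-ready arrays."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _layout as L
from .volume import PROXY_ROLES, ProxyVolumeSet

_DUMMY = np.zeros((1, 1, 1), dtype=np.float32)


@dataclass
class FlatTF:
    """Volumes + transfer-function tables in the kernels' argument order."""

    v0: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    v3: np.ndarray
    vmeta: np.ndarray
    bproxy: np.ndarray
    bform: np.ndarray
    bxs_off: np.ndarray
    bcf_off: np.ndarray
    xs: np.ndarray
    coef: np.ndarray
    tfp: np.ndarray

    @property
    def tf_args(self) -> tuple:
        return (self.v0, self.v1, self.v2, self.v3, self.vmeta, self.bproxy,
                self.bform, self.bxs_off, self.bcf_off, self.xs, self.coef,
                self.tfp)


def flatten_volumes(proxies: ProxyVolumeSet):
    vols = [_DUMMY, _DUMMY, _DUMMY, _DUMMY]
    vmeta = np.zeros((4, L.NVM))
    vmeta[:, L.VM_DIMS:L.VM_DIMS + 3] = 1
    vmeta[:, L.VM_SPACING:L.VM_SPACING + 3] = 1
    for slot, role in enumerate(PROXY_ROLES):
        if role not in proxies:
            continue
        vol = proxies[role]
        vols[slot] = np.ascontiguousarray(vol.scalar_values(),
                                          dtype=np.float32)
        vmeta[slot, L.VM_USED] = 1
        vmeta[slot, L.VM_DISCRETE] = 1 if vol.value_kind == "discrete" else 0
        vmeta[slot, L.VM_DIMS:L.VM_DIMS + 3] = vol.dims
        vmeta[slot, L.VM_SPACING:L.VM_SPACING + 3] = vol.spacing
        vmeta[slot, L.VM_ORIGIN:L.VM_ORIGIN + 3] = vol.origin
    return vols, vmeta


def _binding_tables(mgr):
    """Per-binding control tables with materials resolved into dense rows."""
    from .tf import _cctf_rows, _DEFAULT_MATERIAL

    order = sorted(range(len(mgr.bindings)),
                   key=lambda k: (-mgr.bindings[k].priority, k))
    bform = []
    bproxy = []
    xs_parts = []
    coef_parts = []
    bxs_off = [0]
    bcf_off = [0]
    for k in order:
        b = mgr.bindings[k]
        tf = b.tf
        bform.append(L.FORM_CODES[tf.form])
        bproxy.append(PROXY_ROLES.index(b.proxy))
        mat = (_DEFAULT_MATERIAL if tf.material is None
               else mgr.materials[tf.material])
        if tf.form == "CCTF":
            xs_b = np.array([v for v, _ in tf.points])
            rows = _cctf_rows(tf, mat)
        elif tf.form == "CPCTF":
            xs_b = np.asarray(tf.breakpoints, dtype=float)
            base = mat.row()
            rows = np.empty((len(tf.intervals), L.NC))
            for i, cv in enumerate(tf.intervals):
                pr = cv.partial_row()
                rows[i] = np.where(np.isnan(pr), base, pr)
        elif tf.form == "MPCTF":
            xs_b = np.asarray(tf.breakpoints, dtype=float)
            rows = np.stack([mgr.materials[m].row()
                             for m in tf.interval_materials])
        elif tf.form == "CDPTF":
            labels = sorted(tf.mapping)
            xs_b = np.asarray(labels, dtype=float)
            base = mat.row()
            rows = np.empty((len(labels), L.NC))
            for i, lab in enumerate(labels):
                pr = tf.mapping[lab].partial_row()
                rows[i] = np.where(np.isnan(pr), base, pr)
        else:  # MDPTF
            labels = sorted(tf.mapping)
            xs_b = np.asarray(labels, dtype=float)
            rows = np.stack([mgr.materials[int(tf.mapping[lab])].row()
                             for lab in labels])
        xs_parts.append(xs_b)
        coef_parts.append(rows)
        bxs_off.append(bxs_off[-1] + len(xs_b))
        bcf_off.append(bcf_off[-1] + len(rows))
    xs = (np.concatenate(xs_parts) if xs_parts else np.zeros(0))
    coef = (np.concatenate(coef_parts, axis=0) if coef_parts
            else np.zeros((0, L.NC)))
    return (np.asarray(bproxy, dtype=np.int64),
            np.asarray(bform, dtype=np.int64),
            np.asarray(bxs_off, dtype=np.int64),
            np.asarray(bcf_off, dtype=np.int64),
            np.ascontiguousarray(xs, dtype=np.float64),
            np.ascontiguousarray(coef, dtype=np.float64))


def flatten_manager(mgr) -> FlatTF:
    vols, vmeta = flatten_volumes(mgr.proxies)
    bproxy, bform, bxs_off, bcf_off, xs, coef = _binding_tables(mgr)
    tfp = np.array([float(L.MODE_CODES[mgr.mode]), mgr.density_scale,
                    mgr.g_ref, mgr.grad_gamma,
                    float(L.CHAN_CODES[mgr.channels])])
    return FlatTF(vols[0], vols[1], vols[2], vols[3], vmeta, bproxy, bform,
                  bxs_off, bcf_off, xs, coef, tfp)
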