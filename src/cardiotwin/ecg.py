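"""Pseudo-ECG computation and lead algebra.

The extracellular pseudo-potential at an electrode x_e is the infinite
homogeneous-conductor integral

    Phi_e(x_e) = - int_Omega grad(Phi) . grad(1/||x - x_e||) dV,

evaluated with the constant P1 gradient per tet and midpoint (centroid)
quadrature for the smooth 1/r kernel (electrodes sit >= 10 mm off the
mesh).  Because the integral is linear in the nodal potentials, each
electrode reduces to a fixed lead-field row; the 9 electrode traces
(V1-V6, LA, RA, F) are then expanded into the standard 12-lead ECG via the
bipolar limb leads I = LA-RA, II = F-RA, III = F-LA and the augmented
leads aVL = (I-III)/2, aVR = -(I+II)/2, aVF = (II+III)/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from cardiotwin.anatomy import ElectrodeSet, Mesh, p1_gradients

LEAD9 = ("V1", "V2", "V3", "V4", "V5", "V6", "LA", "RA", "F")
LEAD12 = ("V1", "V2", "V3", "V4", "V5", "V6", "I", "II", "III", "aVL", "aVR", "aVF")

# 12-lead reconstruction as a fixed linear map of the 9 electrode traces
_M12 = np.zeros((12, 9))
for _i in range(6):
    _M12[_i, _i] = 1.0
_LA, _RA, _F = 6, 7, 8
_M12[6, _LA], _M12[6, _RA] = 1.0, -1.0          # I
_M12[7, _F], _M12[7, _RA] = 1.0, -1.0           # II
_M12[8, _F], _M12[8, _LA] = 1.0, -1.0           # III
_M12[9] = (_M12[6] - _M12[8]) / 2.0             # aVL
_M12[10] = -(_M12[6] + _M12[7]) / 2.0           # aVR
_M12[11] = (_M12[7] + _M12[8]) / 2.0            # aVF


@dataclass
class LeadTraces:
    """Nine raw electrode traces on a common time grid."""

    t: np.ndarray              # (T,) ms
    traces: np.ndarray         # (9, T) in LEAD9 order

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.traces = np.asarray(self.traces, float)
        if self.traces.shape != (9, len(self.t)):
            raise ValueError("traces must be (9, len(t))")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("non-finite trace values")

    def to_csv(self, path):
        import pandas as pd

        df = pd.DataFrame({"t_ms": self.t, **{l: self.traces[i] for i, l in enumerate(LEAD9)}})
        df.to_csv(path, index=False)


@dataclass
class ECG12:
    """Twelve-lead ECG; the lead identities I + III = II and
    aVL + aVR + aVF = 0 hold by construction for every reconstructed ECG.
    Observational traces (e.g. with independent per-lead measurement
    noise) may carry validate=False, since noise on derived leads breaks
    the exact algebra."""

    t: np.ndarray
    traces: np.ndarray         # (12, T) in LEAD12 order
    validate: bool = True

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.traces = np.asarray(self.traces, float)
        if self.traces.shape != (12, len(self.t)):
            raise ValueError("traces must be (12, len(t))")
        if self.validate:
            scale = max(1.0, float(np.abs(self.traces).max()))
            if np.abs(self.traces[6] + self.traces[8] - self.traces[7]).max() > 1e-12 * scale:
                raise ValueError("lead identity I + III = II violated")
            if np.abs(self.traces[9] + self.traces[10] + self.traces[11]).max() > 1e-12 * scale:
                raise ValueError("lead identity aVL + aVR + aVF = 0 violated")

    def lead(self, name: str) -> np.ndarray:
        return self.traces[LEAD12.index(name)]

    def to_csv(self, path):
        import pandas as pd

        df = pd.DataFrame({"t_ms": self.t, **{l: self.traces[i] for i, l in enumerate(LEAD12)}})
        df.to_csv(path, index=False)


def lead_field_matrix(mesh: Mesh, electrodes: ElectrodeSet) -> np.ndarray:
    """(9, n_vertices) matrix L with Phi_e(t) = L @ V(t).

    Raises if any electrode touches or enters the mesh (kernel singular)."""
    G, vol = p1_gradients(mesh)          # (m,4,3), (m,)
    cent = mesh.tet_centroids()
    pos = electrodes.array()             # (9,3)

    # crude inside test: an electrode closer to a centroid than the local
    # element size is treated as inside/on the mesh
    from scipy.spatial import cKDTree

    d, _ = cKDTree(cent).query(pos)
    if np.any(d < mesh.h):
        bad = ElectrodeSet.LABELS[int(np.argmin(d))]
        raise ValueError(f"electrode {bad} is inside or on the mesh")

    L = np.zeros((9, mesh.n_vertices))
    for e in range(9):
        r = cent - pos[e]                # (m,3)
        g_kernel = -r / np.linalg.norm(r, axis=1, keepdims=True) ** 3  # grad(1/r) at centroid
        # contribution of node a of tet m: -vol_m * (G[m,a] . g_kernel[m])
        contrib = -vol[:, None] * np.einsum("mad,md->ma", G, g_kernel)
        np.add.at(L[e], mesh.tets.ravel(), contrib.ravel())
    return L


def pseudo_potential(mesh: Mesh, V: np.ndarray, electrodes: ElectrodeSet) -> np.ndarray:
    """Pseudo-potential of one snapshot V (n_vertices,) at each electrode."""
    return lead_field_matrix(mesh, electrodes) @ np.asarray(V, float)


def reconstruct_12lead(traces: LeadTraces) -> ECG12:
    """Exact lead algebra: precordial leads pass through, limb and
    augmented leads from the linear combinations above."""
    return ECG12(traces.t, _M12 @ traces.traces)


def ecg12_from_9(t: np.ndarray, leads9: np.ndarray) -> ECG12:
    """12-lead ECG from a (9, T) array in LEAD9 order (any common scale:
    the identities are scale-free)."""
    return ECG12(t, _M12 @ np.asarray(leads9, float))


@dataclass
class Normalizer:
    """Per-lead affine map onto [-1, 1], fitted as the min-max envelope of
    a training ensemble; time maps to t / T_HB."""

    lo: np.ndarray             # (9,)
    hi: np.ndarray             # (9,)
    t_hb: float = 600.0

    def __post_init__(self):
        self.lo = np.asarray(self.lo, float)
        self.hi = np.asarray(self.hi, float)

    @property
    def scale(self) -> np.ndarray:
        return 0.5 * (self.hi - self.lo)

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.hi + self.lo)

    def apply(self, traces: np.ndarray) -> np.ndarray:
        """(9, T) raw -> (9, T) in [-1, 1] (on the training envelope)."""
        return (np.asarray(traces, float) - self.center[:, None]) / self.scale[:, None]

    def invert(self, traces: np.ndarray) -> np.ndarray:
        return np.asarray(traces, float) * self.scale[:, None] + self.center[:, None]

    def normalize_time(self, t_ms: np.ndarray) -> np.ndarray:
        return np.asarray(t_ms, float) / self.t_hb

    def to_json(self, path):
        with open(path, "w") as f:
            json.dump({"lo": self.lo.tolist(), "hi": self.hi.tolist(), "t_hb": self.t_hb}, f, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as f:
            d = json.load(f)
        return cls(np.array(d["lo"]), np.array(d["hi"]), d["t_hb"])


def fit_normalizer(ensemble: list[LeadTraces] | np.ndarray, t_hb: float = 600.0) -> Normalizer:
    """Min-max fit over an ensemble: per lead, the ensemble extremes map to
    exactly -1 and +1.  A constant lead degenerates to a unit-scale map
    (with a warning)."""
    import warnings

    if isinstance(ensemble, np.ndarray):
        stacked = ensemble  # (n_samples, 9, T)
    else:
        if len(ensemble) == 0:
            raise ValueError("ensemble must be nonempty")
        stacked = np.stack([tr.traces for tr in ensemble])
    lo = stacked.min(axis=(0, 2))
    hi = stacked.max(axis=(0, 2))
    flat = hi - lo < 1e-14
    if flat.any():
        warnings.warn("constant lead(s) in ensemble; using unit scale")
        hi = np.where(flat, lo + 1.0, hi)
        lo = np.where(flat, lo - 1.0, lo)
    return Normalizer(lo, hi, t_hb)
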