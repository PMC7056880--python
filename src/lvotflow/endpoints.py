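"""Hemodynamic endpoints: WSS metrics, turbulence fields and comparisons.

Wall shear stress here is the fixed-frame Cartesian 1-2 viscous component

    tau_12 = mu * (du1/dx2 + du2/dx1)

evaluated from one-sided (wall-adjacent element) gradients and area-averaged
over each 2 mm site window.  Cycle metrics:

* TSM = (1/T) int |tau_12| dt          (temporal shear magnitude, Pa)
* TSG = (1/T) int |d tau_12 / dt| dt   (temporal shear gradient, Pa/s)
* OSI = 0.5 [1 - |int tau_12 dt| / int |tau_12| dt]

Turbulence kinetic energy is reported as the transported model variable k
(the printed mean-velocity form is dimensionally a mean kinetic energy and is
not what the closure transports); the Reynolds shear stress uses the
Boussinesq eddy-viscosity form -rho<u1'u2'> = rho nu_t (du1/dx2 + du2/dx1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import shapely

from . import _fem
from .geometry import LVGeometry, SiteWindow, TAG_SEPTAL
from .meshing import TriMesh

__all__ = [
    "WSSRecord", "EndpointSummary", "compute_vorticity", "compute_tke",
    "compute_rss", "extract_wall_shear", "compute_tsm", "compute_tsg",
    "compute_osi", "effective_jet_diameter", "compare_models",
    "WallShearSampler",
]


class RecordError(ValueError):
    """WSS record does not span a proper uniform cycle."""


@dataclass
class WSSRecord:
    """Site-averaged tau_12 time series over one analyzed cycle."""

    site_id: int
    times: np.ndarray
    tau: np.ndarray                   # Pa

    def validate(self) -> None:
        if len(self.times) != len(self.tau):
            raise RecordError("times/tau length mismatch")
        if len(self.times) < 4:
            raise RecordError("record too short")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise RecordError("times must increase")
        if np.max(np.abs(dt - dt.mean())) > 1e-6 * dt.mean() + 1e-12:
            raise RecordError("record must be uniformly sampled")

    @property
    def period(self) -> float:
        dt = float(np.mean(np.diff(self.times)))
        return float(self.times[-1] - self.times[0]) + dt

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"time_s": self.times,
                      "tau12_pa": self.tau}).to_csv(path, index=False)


@dataclass
class EndpointSummary:
    """Per-model endpoint collection."""

    model_id: str = ""
    tsm: dict = field(default_factory=dict)       # site_id -> Pa
    tsg: dict = field(default_factory=dict)       # site_id -> Pa/s
    osi: dict = field(default_factory=dict)       # site_id -> [0, 0.5]
    max_tke: float = 0.0                          # m^2/s^2
    peak_rss: float = 0.0                         # Pa
    lvot_mean_abs_vorticity: float = 0.0          # 1/s, time averaged
    peak_lvot_velocity: float = 0.0               # m/s, systole
    effective_jet_diameter: float = 0.0           # m, at peak systole
    peak_systole_time: float = 0.0

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=float)

    @classmethod
    def from_json(cls, path) -> "EndpointSummary":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("tsm", "tsg", "osi"):
            d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# field operators
# ---------------------------------------------------------------------------

def compute_vorticity(mesh: TriMesh, u: np.ndarray) -> np.ndarray:
    """Out-of-plane vorticity du2/dx1 - du1/dx2 at nodes (area-weighted
    recovery of element P1 gradients)."""
    area, grads = _fem.tri_geometry(mesh.points, mesh.tris)
    g1 = _fem.node_gradient(mesh.points, mesh.tris, u[:, 0], area, grads)
    g2 = _fem.node_gradient(mesh.points, mesh.tris, u[:, 1], area, grads)
    return g2[:, 0] - g1[:, 1]


def compute_tke(k: np.ndarray, closure_active: bool = True) -> np.ndarray:
    """Turbulence kinetic energy field: the transported k (zero if laminar)."""
    if not closure_active:
        return np.zeros_like(k)
    return np.asarray(k, float)


def compute_rss(mesh: TriMesh, u: np.ndarray, nut: np.ndarray, rho: float
                ) -> np.ndarray:
    """Modeled Reynolds shear stress -rho<u1'u2'> = rho nu_t (du1/dx2+du2/dx1)."""
    area, grads = _fem.tri_geometry(mesh.points, mesh.tris)
    g1 = _fem.node_gradient(mesh.points, mesh.tris, u[:, 0], area, grads)
    g2 = _fem.node_gradient(mesh.points, mesh.tris, u[:, 1], area, grads)
    return rho * nut * (g1[:, 1] + g2[:, 0])


class WallShearSampler:
    """Per-site tau_12 extraction from wall-adjacent element gradients.

    Site windows live in septal arc-length coordinates; boundary edges are
    matched to sites through the arc coordinates frozen into the mesh at
    build time, so the association survives wall motion and interior
    remeshing.
    """

    def __init__(self, mesh: TriMesh, geometry: LVGeometry, mu: float,
                 sites: Optional[list] = None):
        self.mu = mu
        self.sites = geometry.sites if sites is None else sites
        # septal arc coordinate of each boundary edge midpoint: walking the
        # loop from point 0 (septal outlet end) toward the foot *decreases*
        # septal s, so  septal_s = ref_septal_s + (ref_loop_s - loop_s)
        # anchored at the foot (minimum septal s, below any lesion detour).
        la = geometry.loop_arc()
        sep = geometry.septal_s
        i_ref = int(np.nanargmin(sep))
        ref_loop_s, ref_sep_s = la[i_ref], sep[i_ref]
        mids = np.full(len(mesh.bedges), np.nan)
        for e, (i, j) in enumerate(mesh.bedges):
            if mesh.btags[e] != TAG_SEPTAL:
                continue
            si = mesh.bnode_s.get(int(i))
            sj = mesh.bnode_s.get(int(j))
            if si is None or sj is None:
                continue
            mids[e] = 0.5 * (si + sj)
        self.edge_septal_s = ref_sep_s + (ref_loop_s - mids)
        self._site_edges = {}
        for sw in self.sites:
            sel = np.where((self.edge_septal_s >= sw.arc_start - 1e-9)
                           & (self.edge_septal_s <= sw.arc_end + 1e-9))[0]
            if len(sel) == 0:
                raise RecordError(
                    f"no boundary edges found for site {sw.site_id}; refine "
                    "the boundary near the crest")
            self._site_edges[sw.site_id] = sel
        # wall-adjacent element of each boundary edge
        edge_to_tri = {}
        for it, t in enumerate(mesh.tris):
            for kk in range(3):
                e = (min(t[kk], t[(kk + 1) % 3]), max(t[kk], t[(kk + 1) % 3]))
                edge_to_tri.setdefault(e, []).append(it)
        self._edge_tri = np.full(len(mesh.bedges), -1)
        for e, (i, j) in enumerate(mesh.bedges):
            owner = edge_to_tri.get((min(i, j), max(i, j)), [])
            if owner:
                self._edge_tri[e] = owner[0]
        self.mesh = mesh

    def sample(self, points: np.ndarray, u: np.ndarray) -> dict:
        """tau_12 per site (edge-length weighted mean over the window)."""
        area, grads = _fem.tri_geometry(points, self.mesh.tris)
        out = {}
        for sid, edges in self._site_edges.items():
            tris = self._edge_tri[edges]
            ok = tris >= 0
            tr = tris[ok]
            gu = np.einsum("ejd,ej->ed", grads[tr],
                           u[self.mesh.tris[tr], 0])
            gv = np.einsum("ejd,ej->ed", grads[tr],
                           u[self.mesh.tris[tr], 1])
            tau_e = self.mu * (gu[:, 1] + gv[:, 0])
            i, j = self.mesh.bedges[edges[ok], 0], self.mesh.bedges[edges[ok], 1]
            w = np.linalg.norm(points[j] - points[i], axis=1)
            out[sid] = float(np.sum(tau_e * w) / np.sum(w))
        return out


def extract_wall_shear(mesh: TriMesh, geometry: LVGeometry, site: SiteWindow,
                       u: np.ndarray, mu: float) -> float:
    """One-off tau_12 sample for a single site window (Pa)."""
    sampler = WallShearSampler(mesh, geometry, mu, sites=[site])
    return sampler.sample(mesh.points, u)[site.site_id]


# ---------------------------------------------------------------------------
# cycle metrics
# ---------------------------------------------------------------------------

def _check(record: WSSRecord) -> tuple:
    record.validate()
    t = record.times
    dt = float(np.mean(np.diff(t)))
    # close the cycle: the sample at t0 + T equals the first sample
    tau = np.concatenate([record.tau, record.tau[:1]])
    tt = np.concatenate([t, [t[-1] + dt]])
    return tt, tau, record.period


def compute_tsm(record: WSSRecord) -> float:
    """Cycle average of |tau_12| (Pa), trapezoidal in time."""
    tt, tau, T = _check(record)
    return float(np.trapezoid(np.abs(tau), tt) / T)


def compute_tsg(record: WSSRecord) -> float:
    """Cycle average of |d tau_12/dt| (Pa/s): centred periodic differences
    then a trapezoidal average of the absolute value."""
    record.validate()
    tau = record.tau
    t = record.times
    dt = float(np.mean(np.diff(t)))
    dtau = (np.roll(tau, -1) - np.roll(tau, 1)) / (2.0 * dt)
    dd = np.concatenate([dtau, dtau[:1]])
    tt = np.concatenate([t, [t[-1] + dt]])
    return float(np.trapezoid(np.abs(dd), tt) / record.period)


def compute_osi(record: WSSRecord) -> float:
    """Oscillatory shear index in [0, 0.5]."""
    tt, tau, T = _check(record)
    denom = float(np.trapezoid(np.abs(tau), tt))
    if denom <= 0.0:
        warnings.warn("identically zero WSS signal; OSI defined as 0",
                      stacklevel=2)
        return 0.0
    num = abs(float(np.trapezoid(tau, tt)))
    return float(np.clip(0.5 * (1.0 - num / denom), 0.0, 0.5))


# ---------------------------------------------------------------------------
# jet diameter and comparisons
# ---------------------------------------------------------------------------

def effective_jet_diameter(mesh: TriMesh, u: np.ndarray,
                           cross_section: np.ndarray, axis: np.ndarray,
                           threshold: float = 0.1, n_samples: int = 200
                           ) -> float:
    """Width (m) of the contiguous forward-flow jet core on a cross-section.

    The jet is the longest contiguous run of sample stations whose axial
    velocity exceeds ``threshold`` times the instantaneous cross-sectional
    maximum.  ``cross_section`` is a (2, 2) segment in metres; ``axis`` the
    downstream unit vector.
    """
    from scipy.interpolate import LinearNDInterpolator
    a, b = np.asarray(cross_section, float)
    f = np.linspace(0.0, 1.0, n_samples)
    pts = a[None, :] + f[:, None] * (b - a)[None, :]
    interp = LinearNDInterpolator(mesh.points, u @ np.asarray(axis, float))
    ua = interp(pts)
    ua = np.where(np.isfinite(ua), ua, 0.0)
    umax = float(ua.max())
    if umax <= 0:
        warnings.warn("no forward flow on the cross-section", stacklevel=2)
        return 0.0
    mask = ua > threshold * umax
    ds = np.linalg.norm(b - a) / (n_samples - 1)
    best = run = 0
    for mk in mask:
        run = run + 1 if mk else 0
        best = max(best, run)
    return float(best * ds)


def compare_models(summary_a: EndpointSummary, summary_b: EndpointSummary,
                   phase_tol: float = 0.05) -> dict:
    """Fold changes and percent differences of B relative to A.

    Peak-velocity and vorticity ratios, jet-diameter percent reduction, and
    site-wise percent differences in TSM/TSG plus OSI differences; matches
    the reporting convention (1.00 vs 1.23 Pa -> +23 %).
    """
    if abs(summary_a.peak_systole_time - summary_b.peak_systole_time) \
            > phase_tol:
        raise ValueError("summaries sampled at different phase instants")

    def ratio(b, a):
        return float(b / a) if a != 0 else float("nan")

    out = {
        "peak_velocity_fold": ratio(summary_b.peak_lvot_velocity,
                                    summary_a.peak_lvot_velocity),
        "vorticity_fold": ratio(summary_b.lvot_mean_abs_vorticity,
                                summary_a.lvot_mean_abs_vorticity),
        "jet_diameter_reduction_pct":
            100.0 * (1.0 - ratio(summary_b.effective_jet_diameter,
                                 summary_a.effective_jet_diameter)),
        "tsm_pct_diff": {}, "tsg_pct_diff": {}, "osi_diff": {},
    }
    for sid in summary_a.tsm:
        if sid in summary_b.tsm:
            out["tsm_pct_diff"][sid] = 100.0 * (
                ratio(summary_b.tsm[sid], summary_a.tsm[sid]) - 1.0)
    for sid in summary_a.tsg:
        if sid in summary_b.tsg:
            out["tsg_pct_diff"][sid] = 100.0 * (
                ratio(summary_b.tsg[sid], summary_a.tsg[sid]) - 1.0)
    for sid in summary_a.osi:
        if sid in summary_b.osi:
            out["osi_diff"][sid] = float(summary_b.osi[sid]
                                         - summary_a.osi[sid])
    return out
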