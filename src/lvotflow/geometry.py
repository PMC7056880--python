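"""Parametric 2D left-ventricle / LVOT geometries.

Three models are supported:

* ``N-LV``  — idealized chamber with a normal (130 deg) aortoseptal angle,
* ``S-LV``  — the same chamber with a steep (110 deg) aortoseptal angle,
* ``DSS-LV`` — the S-LV geometry with a subaortic lesion tab attached to the
  septal side of the outflow tract, obstructing 25 % of the lumen by default.

All geometric quantities are expressed in millimetres.  ``x1`` is horizontal,
``x2`` vertical; the chamber hangs below the base plane ``x2 = 0`` and the
outflow tract leaves the septal crest toward the upper right.  The boundary is
stored as a single closed, counter-clockwise polyline with one tag per edge;
the mitral inlet and aortic outlet are open gaps tagged ``inlet`` / ``outlet``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "GeometryError",
    "StenosisError",
    "CrestNotFoundError",
    "SiteError",
    "LesionSpec",
    "SiteWindow",
    "GeometryParams",
    "LVGeometry",
    "build_geometry",
    "locate_septal_crest",
    "define_sites",
    "measure_aosa",
]

MODEL_IDS = ("N-LV", "S-LV", "DSS-LV")

TAG_SEPTAL = "septal_wall"
TAG_LV = "lv_wall"
TAG_INLET = "inlet"
TAG_OUTLET = "outlet"
TAG_LESION = "lesion"
WALL_TAGS = (TAG_SEPTAL, TAG_LV, TAG_LESION)
OPEN_TAGS = (TAG_INLET, TAG_OUTLET)


class GeometryError(ValueError):
    """Invalid or self-intersecting geometry."""


class StenosisError(GeometryError):
    """Lesion protrusion incompatible with the lumen."""


class CrestNotFoundError(GeometryError):
    """Septal wall has no curvature maximum above threshold."""


class SiteError(GeometryError):
    """Septal wall cannot host the requested site windows."""


@dataclass
class LesionSpec:
    """Subaortic lesion tab, realized as a rounded rectangular protrusion.

    ``length`` is the out-of-plane crescent span reported for the lesion and
    is carried as metadata for the solid model; the in-plane cross section is
    ``thickness`` (along the wall) by ``protrusion_depth`` (into the lumen).
    ``attachment_arc_position`` is the arc-length coordinate of the tab centre
    on the septal wall, measured LVOT-ward from the septal crest.
    """

    length: float = 10.0
    thickness: float = 1.0
    protrusion_depth: float = 4.65
    attachment_arc_position: float = 8.0
    root_fillet_radius: float = 0.25


@dataclass
class SiteWindow:
    """A 2 mm wall-shear characterization window on the septal wall."""

    site_id: int
    arc_start: float
    arc_end: float

    @property
    def width(self) -> float:
        return self.arc_end - self.arc_start

    @property
    def center(self) -> float:
        return 0.5 * (self.arc_start + self.arc_end)


@dataclass
class GeometryParams:
    """Parameters of the idealized chamber shared by all three models.

    The chamber leans apex-left so that both the normal and the steep
    aortoseptal angle leave the outflow axis pointing upward, with the mitral
    inlet immediately to the right of the aortic outlet across a sharp
    Mi-Ao junction wedge.
    """

    aosa_deg: float = 130.0
    outlet_width: float = 18.6
    outlet_ext_length: float = 10.0
    inlet_width: float = 24.4
    inlet_ext_length: float = 2.0
    lvot_length: float = 15.0          # crest -> start of outlet extension
    lvot_base_width: Optional[float] = None  # funnel entrance width;
                                       # None: set by the Mi-Ao junction
    lvot_taper_length: float = 5.0     # funnel converges to outlet_width here
    crest: tuple = (-20.0, 0.0)
    septal_tilt_deg: float = 52.0      # septal-wall lean from vertical
    septal_length: float = 22.0        # crest -> septal foot
    chamber_depth: float = 35.0        # ellipse semi-axis below the foot chord
    right_foot: tuple = (22.0, -10.0)  # chamber arc endpoint on the right
    inlet_left_x: float = 6.0          # Mi-Ao junction x (junction at x2 = 0)
    crest_fillet_radius: float = 2.0   # apexward blend arc; 0 = sharp corner
    crest_fillet_out_radius: float = 7.0   # LVOT-ward continuation arc
    crest_fillet_turn_fraction: float = 0.4  # share of the turn in arc 1
    crest_fillet_turn_angle_deg: float = 13.0  # absolute arc-1 turn (overrides)
    crest_bulge_height: float = 0.0    # optional prominence at the crest (mm)
    crest_bulge_halfwidth: float = 4.0  # arc half-width of the prominence
    septal_bow_height: float = 3.0     # chamber septal wall bows away (mm)
    site_width: float = 2.0
    arc_step_deg: float = 3.0          # ellipse discretization
    stenosis_fraction: float = 0.25
    lesion: Optional[LesionSpec] = None

    def apexward(self) -> np.ndarray:
        a = math.radians(self.septal_tilt_deg)
        return np.array([-math.sin(a), -math.cos(a)])

    def septal_foot(self) -> np.ndarray:
        return np.asarray(self.crest, float) + self.septal_length * self.apexward()

    def validate(self) -> None:
        if not (90.0 <= self.aosa_deg <= 160.0):
            raise GeometryError(f"aosa_deg={self.aosa_deg} outside [90, 160]")
        if not (0.0 <= self.stenosis_fraction < 0.6):
            raise StenosisError(
                f"stenosis_fraction={self.stenosis_fraction} outside [0, 0.6)")
        for name in ("outlet_width", "inlet_width", "lvot_length",
                     "septal_length", "chamber_depth"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")


@dataclass
class LVGeometry:
    """A built LV/LVOT boundary.

    Attributes
    ----------
    points : (P, 2) float array
        Closed CCW polyline (last point connects back to the first), mm.
    edge_tags : (P,) object array
        Tag of the edge from ``points[i]`` to ``points[i+1]`` (wrapping).
    septal_s : (P,) float array
        Septal-wall arc coordinate of each point (NaN off the septal wall,
        including lesion points).  Increases LVOT-ward; the septal foot is 0.
    """

    model_id: str
    params: GeometryParams
    points: np.ndarray
    edge_tags: np.ndarray
    septal_s: np.ndarray
    aosa: float
    crest_s: float
    crest_xy: np.ndarray
    d_hat: np.ndarray          # outflow-axis unit vector
    n_hat: np.ndarray          # cross-lumen unit vector (septal -> anterior)
    anchor_s_range: tuple      # loop arc range (mm) of the movable chamber wall
    lesion: Optional[LesionSpec] = None
    sites: list = field(default_factory=list)
    lesion_root_s: Optional[float] = None   # septal s of the lesion root

    # ------------------------------------------------------------------ utils
    @property
    def n_points(self) -> int:
        return len(self.points)

    def loop_arc(self) -> np.ndarray:
        """Cumulative arc length (mm) at each point, starting at 0."""
        seg = np.linalg.norm(
            np.diff(self.points, axis=0, append=self.points[:1]), axis=1)
        return np.concatenate(([0.0], np.cumsum(seg)[:-1]))

    def loop_length(self) -> float:
        seg = np.linalg.norm(
            np.diff(self.points, axis=0, append=self.points[:1]), axis=1)
        return float(seg.sum())

    def polygon(self) -> Polygon:
        return Polygon(self.points)

    def area(self) -> float:
        return float(self.polygon().area)

    def is_simple(self) -> bool:
        return self.polygon().is_valid

    def septal_point_of_s(self, s: float) -> np.ndarray:
        """Position (mm) at septal arc coordinate ``s``, by piecewise-linear
        interpolation along the built septal chain (the lesion footprint is
        crossed in a straight line)."""
        ss, xy = septal_polyline(self)
        return np.array([np.interp(s, ss, xy[:, 0]),
                         np.interp(s, ss, xy[:, 1])])

    def min_lumen_width(self) -> float:
        """Minimum LVOT lumen width (mm) across the lesion section.

        Distance from the lesion outline to the anterior LVOT wall line; for
        an unobstructed model this is the full outlet width.
        """
        emask = self.edge_tags == TAG_LESION
        if not emask.any():
            return self.params.outlet_width
        pmask = emask | np.roll(emask, 1)
        les_pts = self.points[pmask]
        b0 = self.crest_xy + self.params.outlet_width * self.n_hat
        dist = np.abs((les_pts - b0) @ self.n_hat)
        return float(dist.min())

    def lvot_region_polygon(self, s_from: float = 0.0,
                            s_to: Optional[float] = None) -> Polygon:
        """Quadrilateral covering the outflow tract between axial stations."""
        p = self.params
        if s_to is None:
            s_to = p.lvot_length + p.outlet_ext_length
        c, d, n = self.crest_xy, self.d_hat, self.n_hat
        w = p.outlet_width
        quad = [c + s_from * d, c + s_to * d,
                c + s_to * d + w * n, c + s_from * d + w * n]
        return Polygon(np.asarray(quad))

    def cross_section_line(self, s_axial: float) -> np.ndarray:
        """Endpoints (2, 2) of the lumen chord at axial station ``s_axial``."""
        a = self.crest_xy + s_axial * self.d_hat
        b = a + self.params.outlet_width * self.n_hat
        return np.vstack([a, b])

    # ------------------------------------------------------------------- I/O
    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "s_mm": self.loop_arc(),
            "x1_mm": self.points[:, 0],
            "x2_mm": self.points[:, 1],
            "tag": self.edge_tags,
        }).to_csv(path, index=False)

    def params_json(self) -> str:
        d = asdict(self.params)
        d["model_id"] = self.model_id
        return json.dumps(d, indent=2)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.params_json())


def geometry_from_json(path) -> LVGeometry:
    """Rebuild a geometry from its JSON parameter form."""
    with open(path) as fh:
        d = json.load(fh)
    model_id = d.pop("model_id")
    lesion = d.pop("lesion", None)
    params = GeometryParams(**d)
    if lesion is not None:
        params.lesion = LesionSpec(**lesion)
    return build_geometry(model_id, params)


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def _rot(v: np.ndarray, ang_deg: float) -> np.ndarray:
    a = math.radians(ang_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _arc_points(center, radius, a0, a1, step_deg=15.0):
    """Sampled circular arc from angle ``a0`` to ``a1`` (radians), inclusive."""
    n = max(2, int(math.ceil(abs(a1 - a0) / math.radians(step_deg))) + 1)
    ang = np.linspace(a0, a1, n)
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])


def _lesion_outline(crest, d, n, spec: LesionSpec, depth: float):
    """Lesion tab outline walked from high septal-s to low septal-s.

    The first and last returned points lie on the septal wall line (the fillet
    tangent points, or the root corners when the fillet radius is zero).
    """
    t = spec.thickness
    rf = min(spec.root_fillet_radius, 0.45 * t)
    r_tip = 0.5 * t
    s_c = spec.attachment_arc_position
    a1 = crest + (s_c + 0.5 * t) * d     # root corner, outlet side
    b1 = crest + (s_c - 0.5 * t) * d     # root corner, crest side
    tipc = crest + s_c * d + (depth - r_tip) * n
    angd = math.atan2(d[1], d[0])

    pts = []
    if rf > 1e-9:
        o = a1 + rf * (d + n)
        pts.append(_arc_points(o, rf, angd + 0.5 * math.pi, angd + math.pi))
    else:
        pts.append(a1[None, :])
    pts.append((a1 + (depth - r_tip) * n)[None, :])
    # rounded tip: semicircle through the +n apex
    pts.append(_arc_points(tipc, r_tip, angd, angd - math.pi, 10.0))
    pts.append((b1 + (depth - r_tip) * n)[None, :])
    if rf > 1e-9:
        o = b1 + rf * (n - d)
        pts.append(_arc_points(o, rf, angd, angd + 0.5 * math.pi))
    else:
        pts.append(b1[None, :])
    return np.vstack(pts)


def build_geometry(model_id: str, params: Optional[GeometryParams] = None,
                   ) -> LVGeometry:
    """Construct one of the three LV models.

    Parameters
    ----------
    model_id : {"N-LV", "S-LV", "DSS-LV"}
        ``N-LV`` defaults to a 130 deg aortoseptal angle, ``S-LV`` and
        ``DSS-LV`` to 110 deg.
    params : GeometryParams, optional
        Chamber parameters; the defaults give a plausible adult 2D section.
        When omitted, model-appropriate defaults are used.
    """
    if model_id not in MODEL_IDS:
        raise GeometryError(f"unknown model_id {model_id!r}")
    if params is None:
        params = GeometryParams()
        if model_id in ("S-LV", "DSS-LV"):
            params.aosa_deg = 110.0
    params.validate()

    p = params
    crest = np.asarray(p.crest, float)
    foot = p.septal_foot()
    apexward = (foot - crest) / np.linalg.norm(foot - crest)
    d = _rot(apexward, -p.aosa_deg)      # outflow axis (clockwise from septum)
    if d[1] <= 0:
        raise GeometryError("aortoseptal angle leaves the outflow axis "
                            "pointing downward; adjust aosa_deg")
    n = np.array([d[1], -d[0]])          # septal -> anterior across the lumen
    W = p.outlet_width
    lvot_total = p.lvot_length + p.outlet_ext_length

    lesion = None
    depth = 0.0
    if model_id == "DSS-LV":
        lesion = p.lesion if p.lesion is not None else LesionSpec()
        depth = p.stenosis_fraction * W
        lesion.protrusion_depth = depth
        if depth >= W:
            raise StenosisError("lesion protrusion >= lumen width")
        sc = lesion.attachment_arc_position
        if depth > 0 and not (0.5 * lesion.thickness < sc <
                              lvot_total - 0.5 * lesion.thickness):
            raise StenosisError("lesion attachment outside the LVOT wall")

    pts: list = []
    arrive: list = []   # tag of the edge arriving at each point

    def add(points, tag):
        for q in np.atleast_2d(points):
            if pts and np.allclose(q, pts[-1], atol=1e-12):
                continue
            pts.append(np.asarray(q, float))
            arrive.append(tag)

    # crest blend: a tight arc on the chamber side (whose midpoint is the
    # septal crest) continued by a wider arc that completes the turn onto the
    # septal-side LVOT wall; tangent-continuous throughout
    rf = p.crest_fillet_radius
    theta = math.pi - math.radians(p.aosa_deg)   # turning angle at the crest
    blend_pts_up = None
    td_ch = 0.0      # crest -> blend start along the chamber wall
    td = 0.0         # crest -> blend end along the LVOT wall
    arc1_len = 0.0
    blend_lo = 0.0   # wall-arc below the crest covered by the blend
    blend_hi = 0.0   # wall-arc above the crest covered by the blend
    if rf > 0:
        r2 = p.crest_fillet_out_radius if p.crest_fillet_out_radius > 0 \
            else rf
        if p.crest_fillet_turn_angle_deg > 0:
            th1 = min(math.radians(p.crest_fillet_turn_angle_deg),
                      0.95 * theta)
        else:
            th1 = min(max(p.crest_fillet_turn_fraction, 0.05), 1.0) * theta
        th2 = theta - th1
        u0 = -apexward                          # walking-up tangent at start

        def _rotv(v, ang):
            c, s_ = math.cos(ang), math.sin(ang)
            return np.array([c * v[0] - s_ * v[1], s_ * v[0] + c * v[1]])

        chord = 2 * rf * math.sin(0.5 * th1) * _rotv(u0, 0.5 * th1) \
            + 2 * r2 * math.sin(0.5 * th2) * _rotv(u0, th1 + 0.5 * th2)
        denom = float(apexward @ n)
        if abs(denom) < 1e-12:
            raise GeometryError("degenerate crest blend")
        td_ch = -float(chord @ n) / denom
        start = crest + td_ch * apexward
        end = start + chord
        td = float((end - crest) @ d)
        if td_ch <= 0 or td <= 0:
            raise GeometryError("crest blend arcs do not fit the corner")
        up = [start[None, :]]
        pt, tan = start, u0
        for r_a, th_a in ((rf, th1), (r2, th2)):
            o = pt + r_a * _rotv(tan, 0.5 * math.pi)
            a0 = math.atan2(*(pt - o)[::-1])
            nseg = max(3, int(math.ceil(math.degrees(th_a) / 4.0)))
            ang = a0 + np.linspace(0.0, th_a, nseg + 1)[1:]
            up.append(np.column_stack([o[0] + r_a * np.cos(ang),
                                       o[1] + r_a * np.sin(ang)]))
            pt = up[-1][-1]
            tan = _rotv(tan, th_a)
        blend_pts_up = np.vstack(up)
        arc1_len = rf * th1
        blend_lo = 0.5 * arc1_len
        blend_hi = 0.5 * arc1_len + r2 * th2
    ls_straight = float(np.linalg.norm(crest - foot))
    if rf > 0 and (td > 0.6 * lvot_total or td_ch > 0.6 * ls_straight):
        raise GeometryError("crest blend too large for the wall")

    # septal prominence ("crest of the septum"): the wall bulges into the
    # outflow tract around the blended corner, as the basal septum does
    bump = p.crest_bulge_height
    bump_w = p.crest_bulge_halfwidth
    dense = 0.4                         # sampling step inside sculpted spans
    reach_lvot = bump_w if bump > 0 else 0.0
    reach_chamber = bump_w if bump > 0 else 0.0
    if p.septal_bow_height > 0:
        # the bow spans the whole straight chamber wall: sample it densely
        reach_chamber = max(reach_chamber,
                            blend_lo + (ls_straight - td_ch) - 1.0)

    # 1. septal-side LVOT wall, walked from the outlet down to the crest
    add(crest + lvot_total * d, TAG_SEPTAL)
    if lesion is not None and depth > 1e-12:
        root_lo = lesion.attachment_arc_position - 0.5 * lesion.thickness \
            - lesion.root_fillet_radius
        if td >= root_lo:
            raise GeometryError("crest fillet reaches the lesion root")
        if bump > 0 and td + (bump_w - arc_half) >= root_lo:
            raise GeometryError("crest bulge reaches the lesion root")
        outline = _lesion_outline(crest, d, n, lesion, depth)
        add(outline[0], TAG_SEPTAL)
        add(outline[1:], TAG_LESION)
    if reach_lvot > blend_hi:
        # dense stations on the straight LVOT wall inside the sculpted span
        hi = td + (reach_lvot - blend_hi)
        for sta in np.arange(hi, td, -dense):
            add(crest + sta * d, TAG_SEPTAL)
    if blend_pts_up is not None:
        add(blend_pts_up[::-1], TAG_SEPTAL)      # walked downward
    else:
        add(crest, TAG_SEPTAL)
    if reach_chamber > blend_lo:
        # dense stations on the chamber septal wall inside the sculpted span
        hi = min(td_ch + (reach_chamber - blend_lo),
                 float(np.linalg.norm(foot - crest)) - 0.5)
        for sta in np.arange(td_ch + dense, hi + 0.5 * dense, dense):
            add(crest + sta * apexward, TAG_SEPTAL)

    # 2. chamber septal wall: crest (or blend end) -> septal foot
    add(foot, TAG_SEPTAL)

    # 3. chamber arc: rotated half-ellipse from the septal foot around the
    #    apex to the right foot
    rfoot = np.asarray(p.right_foot, float)
    mid = 0.5 * (foot + rfoot)
    u = (rfoot - foot) / np.linalg.norm(rfoot - foot)
    v = np.array([-u[1], u[0]])          # upward-ish normal of the foot chord
    a_el = 0.5 * float(np.linalg.norm(rfoot - foot))
    b_el = p.chamber_depth
    th = np.linspace(math.pi, 2 * math.pi,
                     max(9, int(180.0 / p.arc_step_deg) + 1))[1:-1]
    ell = mid[None, :] + a_el * np.cos(th)[:, None] * u[None, :] \
        + b_el * np.sin(th)[:, None] * v[None, :]
    add(ell, TAG_LV)
    add(rfoot, TAG_LV)

    # 4. right wall to the base, inlet extension walls and mitral gap
    inlet_l = np.array([p.inlet_left_x, 0.0])     # Mi-Ao junction
    inlet_r = inlet_l + [p.inlet_width, 0.0]
    hext = p.inlet_ext_length
    add(inlet_r, TAG_LV)
    add(inlet_r + [0, hext], TAG_LV)
    add(inlet_l + [0, hext], TAG_INLET)     # edge across the mitral gap
    add(inlet_l, TAG_LV)

    # 5. Mi-Ao wedge from the junction to the funnel base, the converging
    #    anterior funnel wall, then the straight anterior LVOT wall; the
    #    closing edge back to the start is the aortic outlet gap
    wb = p.lvot_base_width
    if wb is None:
        # anatomical funnel: the entrance spans from the crest to (just shy
        # of) the fixed Mi-Ao junction, so a steeper aorta means a tighter
        # outflow funnel
        wb = float((inlet_l - crest) @ n) - 1.5
    tl = p.lvot_taper_length
    if wb < W:
        raise GeometryError("lvot_base_width must be >= outlet_width")
    if lesion is not None and depth > 1e-12 and tl >= \
            lesion.attachment_arc_position - 0.5 * lesion.thickness \
            - lesion.root_fillet_radius:
        raise GeometryError("LVOT taper reaches the lesion root")
    if float((inlet_l - crest) @ n) < wb:
        raise GeometryError("Mi-Ao junction lies inside the outflow corridor; "
                            "increase inlet_left_x or reduce lvot_base_width")
    add(crest + wb * n, TAG_LV)                 # funnel base corner
    if wb > W:
        add(crest + W * n + tl * d, TAG_LV)     # funnel -> parallel channel
    add(crest + W * n + lvot_total * d, TAG_LV)

    points = np.vstack(pts)
    edge_tags = np.array(arrive[1:] + [TAG_OUTLET], dtype=object)

    def chain_septal_s(pp):
        """Cumulative septal arc length: points interior to the lesion
        outline are skipped (the footprint is crossed in a straight line);
        NaN off the septal chain.  The foot is 0, increasing LVOT-ward."""
        ss = np.full(len(pp), np.nan)
        i_foot = int(np.argmin(np.linalg.norm(pp - foot, axis=1)))
        on_sep = [i for i in range(i_foot + 1)
                  if not (arrive[i] == TAG_LESION
                          and edge_tags[i] == TAG_LESION)]
        chain = pp[on_sep]
        seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        ss[on_sep] = cum[-1] - cum
        return ss

    septal_s = chain_septal_s(points)

    # sculpt the basal septum: a prominence at the crest and/or a recessed
    # bay below it (sigmoid-septum analog); features are raised-cosine wall
    # displacements along the local inward normal
    l1 = ls_straight - td_ch            # foot -> blend start
    crest_s0 = l1 + blend_lo            # crest: midpoint of the tight arc
    features = []
    if bump > 0:
        features.append((crest_s0, bump, bump_w))
    if p.septal_bow_height > 0:
        # full-wall bow away from the lumen, vanishing smoothly at the foot
        # and at the fillet tangent point
        features.append((0.5 * l1, -p.septal_bow_height, 0.5 * l1))
    if features:
        sel = np.where(~np.isnan(septal_s))[0]
        order = sel[np.argsort(septal_s[sel])]
        P = points[order]
        tang = np.gradient(P, septal_s[order], axis=0)
        tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
        nrm = np.column_stack([tang[:, 1], -tang[:, 0]])   # into the lumen
        if np.mean(nrm @ n) < 0:
            nrm = -nrm
        total = np.zeros(len(order))
        for c_s, h, w in features:
            delta = np.abs(septal_s[order] - c_s)
            m = delta < w
            total[m] += h * 0.5 * (1.0 + np.cos(np.pi * delta[m] / w))
        points[order] = P + total[:, None] * nrm
        septal_s = chain_septal_s(points)

    poly = Polygon(points)
    if not poly.is_valid:
        raise GeometryError("constructed wall polyline self-intersects")
    if _signed_area(points) <= 0:  # pragma: no cover - construction is CCW
        raise GeometryError("wall polyline is not counter-clockwise")

    # the crest is the curvature maximum of the built wall (the prominence
    # apex, or the fillet/corner when the bulge is disabled)
    sep_idx = np.where(~np.isnan(septal_s))[0]
    sep_order = sep_idx[np.argsort(septal_s[sep_idx])]
    crest_s = locate_septal_crest(s=septal_s[sep_order],
                                  xy=points[sep_order])

    # loop-arc range of the movable chamber wall (crest -> inlet-right corner)
    la = _loop_arc(points)
    i_crest = int(np.argmin(np.linalg.norm(points - crest, axis=1)))
    i_anchor = int(np.argmin(np.linalg.norm(points - inlet_r, axis=1)))
    anchor_s_range = (float(la[i_crest]), float(la[i_anchor]))

    geom = LVGeometry(
        model_id=model_id, params=params, points=points, edge_tags=edge_tags,
        septal_s=septal_s, aosa=p.aosa_deg, crest_s=crest_s, crest_xy=crest,
        d_hat=d, n_hat=n, anchor_s_range=anchor_s_range, lesion=lesion,
    )
    if lesion is not None and depth > 1e-12:
        i_root = int(np.argmin(np.linalg.norm(points - outline[-1], axis=1)))
        geom.lesion_root_s = float(septal_s[i_root])
    geom.sites = define_sites(geom, locate_septal_crest(geom))

    meas = measure_aosa(geom)
    if abs(meas - p.aosa_deg) > 0.5:
        raise GeometryError(
            f"measured AoSA {meas:.2f} deviates from requested {p.aosa_deg}")
    return geom


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _loop_arc(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0, append=points[:1]), axis=1)
    return np.concatenate(([0.0], np.cumsum(seg)[:-1]))


def _on_segment(points, a, b, tol=1e-9):
    a, b = np.asarray(a, float), np.asarray(b, float)
    ab = b - a
    L = np.linalg.norm(ab)
    t = (points - a) @ ab / L**2
    proj = a + np.clip(t, 0, 1)[:, None] * ab
    return (np.linalg.norm(points - proj, axis=1) < tol) \
        & (t > -tol) & (t < 1 + tol)


def measure_aosa(geometry: LVGeometry) -> float:
    """Angle (deg) between the outflow axis and the apexward septal tangent,
    measured from the constructed polyline rather than the input parameters.

    Uses the wall points farthest from the crest on each side, so a crest
    fillet does not bias the measurement.
    """
    pts = geometry.points
    s = geometry.septal_s
    crest = geometry.crest_xy
    below = np.where((s < geometry.crest_s - 1e-9) & ~np.isnan(s))[0]
    above = np.where((s > geometry.crest_s + 1e-9) & ~np.isnan(s))[0]
    if len(below) == 0 or len(above) == 0:
        raise GeometryError("cannot measure AoSA: septal wall incomplete")
    v1 = pts[below[np.argmin(s[below])]] - crest
    v2 = pts[above[np.argmax(s[above])]] - crest
    v1 = v1 / np.linalg.norm(v1)
    v2 = v2 / np.linalg.norm(v2)
    return math.degrees(math.acos(float(np.clip(v1 @ v2, -1, 1))))


# ---------------------------------------------------------------------------
# crest location and site definition
# ---------------------------------------------------------------------------

def septal_polyline(geometry: LVGeometry):
    """Septal wall vertices ordered by increasing arc coordinate.

    Returns ``(s, xy)`` with the lesion outline (if any) excluded; the wall
    is continuous in ``s`` across the lesion footprint.
    """
    s = geometry.septal_s
    idx = np.where(~np.isnan(s))[0]
    order = idx[np.argsort(s[idx])]
    return s[order], geometry.points[order]


def locate_septal_crest(geometry=None, *, curvature_threshold: float = 0.05,
                        s=None, xy=None, resolution: float = 0.25) -> float:
    """Arc-length coordinate of the septal crest.

    The crest is the point of maximum discrete curvature (turning angle per
    unit arc length) along the septal wall — the corner where the septum turns
    into the outflow tract.  The wall is resampled at ``resolution`` mm
    (original vertices retained) before the scan.  A contiguous plateau of
    maximal curvature maps to its arc midpoint (a circular-arc crest), and
    multiple distinct maxima break the tie toward the LVOT (largest ``s``).

    Either a geometry or an explicit ``(s, xy)`` polyline may be given.

    Raises
    ------
    CrestNotFoundError
        If no curvature peak exceeds ``curvature_threshold`` (1/mm).
    """
    if s is None or xy is None:
        s, xy = septal_polyline(geometry)
    s = np.asarray(s, float)
    xy = np.asarray(xy, float)
    if len(s) < 3:
        raise CrestNotFoundError("septal wall too short")

    # uniform resampling keeps the discrete turning-angle/arc-length ratio
    # a consistent curvature estimate
    ss = np.arange(s[0], s[-1] + 0.5 * resolution, resolution)
    P = np.column_stack([np.interp(ss, s, xy[:, 0]), np.interp(ss, s, xy[:, 1])])

    t1 = P[1:-1] - P[:-2]
    t2 = P[2:] - P[1:-1]
    cross = t1[:, 0] * t2[:, 1] - t1[:, 1] * t2[:, 0]
    dot = np.einsum("ij,ij->i", t1, t2)
    with np.errstate(divide="ignore", invalid="ignore"):
        # signed curvature: positive at the corner where the septum turns
        # toward the outflow tract (left turn for a polyline walked
        # apexward -> LVOT-ward); receding bays score negative
        kappa = np.arctan2(cross, dot) / resolution
    kappa = np.where(np.isfinite(kappa), kappa, 0.0)
    kmax = kappa.max() if len(kappa) else 0.0
    if kmax < curvature_threshold:
        raise CrestNotFoundError(
            "no curvature maximum above threshold on the septal wall")

    # cluster near-maximal samples by arc-length gap: a rounded (constant
    # curvature) crest forms one cluster whose midpoint is the crest; two
    # distinct corners form two clusters and the tie breaks LVOT-ward
    s_inner = ss[1:-1]
    cand = s_inner[kappa >= 0.9 * kmax]
    gap = max(4.0 * resolution, 1.0)
    clusters = np.split(cand, np.flatnonzero(np.diff(cand) > gap) + 1)
    cl = clusters[-1]
    return float(0.5 * (cl[0] + cl[-1]))


def define_sites(geometry: LVGeometry, crest: float,
                 width: Optional[float] = None) -> list:
    """Three contiguous site windows around the crest.

    Site 2 is centred on the crest; site 1 sits immediately LVOT-ward and
    site 3 immediately apex-ward.  Septal ``s`` increases LVOT-ward.
    """
    w = geometry.params.site_width if width is None else width
    s = geometry.septal_s
    smin = float(np.nanmin(s))
    smax = float(np.nanmax(s))
    if geometry.lesion_root_s is not None:
        smax = min(smax, geometry.lesion_root_s)
    if crest - 1.5 * w < smin or crest + 1.5 * w > smax:
        raise SiteError("septal wall too short for three contiguous site "
                        "windows around the crest")
    return [
        SiteWindow(1, crest + 0.5 * w, crest + 1.5 * w),
        SiteWindow(2, crest - 0.5 * w, crest + 0.5 * w),
        SiteWindow(3, crest - 1.5 * w, crest - 0.5 * w),
    ]
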