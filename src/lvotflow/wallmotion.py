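"""Synthetic LV wall motion: contour sequences and their spline interpolation.

The study's wall motion came from cine-MRI segmentation (29 frames over a
0.772 s cycle, 80 nodes per contour) which is not deposited; this module
generates a deterministic stand-in with the same structure.  Motion is a
tapered radial scaling of the chamber wall about an interior centre, with an
area waveform shaped by raised-cosine E-wave, A-wave and ejection segments:
filling on (0, 0.480) s with two inflow peaks, monotone ejection afterwards.
Only the chamber wall below the outflow tract moves; the LVOT, Mi-Ao wedge
and inlet extension stay rigid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import Polygon

from .geometry import LVGeometry

__all__ = [
    "MotionError",
    "MotionParams",
    "ContourSequence",
    "VolumeWaveform",
    "generate_contours",
    "interpolate_contours",
    "compute_area_waveform",
    "write_contours",
    "read_contours",
]

PERIOD = 0.772
PHASE_SPLIT = 0.480


class MotionError(ValueError):
    """Motion parameters produce an invalid contour."""


@dataclass
class MotionParams:
    """Parameters of the synthetic chamber-wall motion."""

    ef_analog: float = 0.33        # (A_max - A_min) / A_max, 2D analog of EF
    ea_ratio: float = 1.7          # E-wave / A-wave filling-rate amplitude
    period: float = PERIOD
    phase_split: float = PHASE_SPLIT
    e_window: tuple = (0.02, 0.26)
    a_window: tuple = (0.30, 0.46)
    ejection_window: tuple = (0.50, 0.76)
    blend_mm: float = 8.0          # taper length at the rigid anchors
    noise_amp: float = 0.0         # optional smooth nodal perturbation (mm)

    def validate(self) -> None:
        if not (0.0 <= self.ef_analog < 0.8):
            raise MotionError(f"ef_analog={self.ef_analog} outside [0, 0.8)")
        for w in (self.e_window, self.a_window):
            if not (0.0 <= w[0] < w[1] <= self.phase_split):
                raise MotionError(f"filling window {w} outside diastole")
        w = self.ejection_window
        if not (self.phase_split <= w[0] < w[1] <= self.period):
            raise MotionError(f"ejection window {w} outside systole")


@dataclass
class ContourSequence:
    """Time-stamped cyclic wall contours with material node correspondence.

    ``nodes`` has shape (F, N, 2) in mm; frame ``F`` wraps to frame 0 after
    one ``period``.  ``node_s`` holds each node's arc-length coordinate on the
    t=0 boundary loop, which downstream consumers use to map contour motion
    onto mesh boundary nodes.
    """

    times: np.ndarray
    nodes: np.ndarray
    period: float = PERIOD
    phase_split: float = PHASE_SPLIT
    node_s: Optional[np.ndarray] = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[1]

    def validate(self) -> None:
        if self.nodes.ndim != 3 or self.nodes.shape[2] != 2:
            raise MotionError("nodes must have shape (F, N, 2)")
        if len(self.times) != len(self.nodes):
            raise MotionError("times/nodes length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise MotionError("times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] >= self.period:
            raise MotionError("times must lie in [0, period)")

    def displacements(self) -> np.ndarray:
        """Nodal displacement of every frame relative to frame 0."""
        return self.nodes - self.nodes[0]

    def frame_polygon_area(self, i: int) -> float:
        x, y = self.nodes[i, :, 0], self.nodes[i, :, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class VolumeWaveform:
    """Chamber area waveform, the 2D analog of the LV volume curve."""

    times: np.ndarray
    area: np.ndarray               # mm^2
    dA_dt: np.ndarray              # mm^2/s
    period: float = PERIOD
    phase_split: float = PHASE_SPLIT

    def cyclic_closure(self) -> float:
        """| integral of dA/dt over one period |, should vanish for a cycle."""
        t = np.concatenate([self.times, [self.times[0] + self.period]])
        r = np.concatenate([self.dA_dt, [self.dA_dt[0]]])
        return abs(float(np.trapezoid(r, t)))


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _bump(t, t0, t1):
    """Raised cosine on [t0, t1]: zero value and slope at both ends."""
    t = np.asarray(t, float)
    w = t1 - t0
    y = np.zeros_like(t)
    m = (t >= t0) & (t <= t1)
    y[m] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[m] - t0) / w))
    return y


def _bump_integral(t, t0, t1):
    """Running integral of ``_bump``; total over the window is (t1-t0)/2."""
    t = np.asarray(t, float)
    w = t1 - t0
    x = np.clip(t - t0, 0.0, w)
    return 0.5 * (x - (w / (2.0 * np.pi)) * np.sin(2.0 * np.pi * x / w))


def _loop_resample(points: np.ndarray, n: int):
    """Sample a closed polyline at n equal arc-length stations."""
    seg = np.linalg.norm(np.diff(points, axis=0, append=points[:1]), axis=1)
    s_cum = np.concatenate([[0.0], np.cumsum(seg)])
    L = s_cum[-1]
    s = np.arange(n) * L / n
    pts_ext = np.vstack([points, points[:1]])
    x = np.interp(s, s_cum, pts_ext[:, 0])
    y = np.interp(s, s_cum, pts_ext[:, 1])
    return np.column_stack([x, y]), s


def _area_of(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class _MotionField:
    """Tapered radial scaling of the movable chamber boundary."""

    def __init__(self, geometry: LVGeometry, params: MotionParams,
                 points: np.ndarray, s: np.ndarray):
        s0, s1 = geometry.anchor_s_range
        blend = params.blend_mm
        g = _smoothstep((s - s0) / blend) * _smoothstep((s1 - s) / blend)
        g[(s < s0) | (s > s1)] = 0.0
        self.g = g
        movable = g > 0
        if movable.any():
            self.center = points[movable].mean(axis=0)
        else:  # pragma: no cover - degenerate taper
            self.center = points.mean(axis=0)
        self.base = points
        self.radial = points - self.center

    def displace(self, amp: float) -> np.ndarray:
        return self.base + amp * self.g[:, None] * self.radial


def _amp_waveform(params: MotionParams, times: np.ndarray):
    """Normalized scaling amplitude: 0 at t=0 and t=T, rising over diastole."""
    aE = params.ea_ratio
    aA = 1.0
    iE = 0.5 * (params.e_window[1] - params.e_window[0])
    iA = 0.5 * (params.a_window[1] - params.a_window[0])
    iS = 0.5 * (params.ejection_window[1] - params.ejection_window[0])
    aS = (aE * iE + aA * iA) / iS       # closes the cycle exactly
    amp = (aE * _bump_integral(times, *params.e_window)
           + aA * _bump_integral(times, *params.a_window)
           - aS * _bump_integral(times, *params.ejection_window))
    peak = aE * iE + aA * iA
    return amp / peak                   # max value 1 at end-diastole


def generate_contours(geometry: LVGeometry, motion_params: Optional[MotionParams]
                      = None, n_frames: int = 29, seed: int = 0,
                      n_nodes: int = 80) -> ContourSequence:
    """Generate a cyclic synthetic contour sequence for one cardiac cycle.

    Frame 0 is the end-systolic outline of ``geometry`` sampled at ``n_nodes``
    equal arc-length stations; the chamber wall expands over diastole with an
    E-wave and an A-wave filling peak and contracts monotonically over
    systole.  The scaling amplitude is calibrated so that the enclosed-area
    waveform attains exactly the requested ejection-fraction analog.
    """
    params = motion_params if motion_params is not None else MotionParams()
    params.validate()
    if n_frames < 8:
        raise MotionError("n_frames must be at least 8")

    base, s = _loop_resample(geometry.points, n_nodes)
    field = _MotionField(geometry, params, base, s)
    times = np.arange(n_frames) * params.period / n_frames
    amp = _amp_waveform(params, times)

    scale = 0.0
    if params.ef_analog > 0:
        # area is quadratic in the scaling amplitude: fit and solve for the
        # scale that achieves (A_max - A_min)/A_max = ef_analog
        a0 = _area_of(field.displace(0.0))
        a1 = _area_of(field.displace(0.5))
        a2 = _area_of(field.displace(1.0))
        c2 = 2.0 * (a2 - 2.0 * a1 + a0)
        c1 = a2 - a0 - c2
        target = a0 / (1.0 - params.ef_analog)   # required A_max (A_min = a0)
        disc = c1 * c1 + 4.0 * c2 * (target - a0)
        if disc < 0 or c2 == 0 and c1 <= 0:
            raise MotionError("cannot reach requested ef_analog")
        scale = (2.0 * (target - a0) / (c1 + np.sqrt(disc)) if c2 != 0
                 else (target - a0) / c1)
        if not np.isfinite(scale) or scale <= 0:
            raise MotionError("cannot reach requested ef_analog")

    nodes = np.stack([field.displace(scale * a) for a in amp])

    if params.noise_amp > 0:
        rng = np.random.default_rng(seed)
        phase = rng.uniform(0, 2 * np.pi, size=n_nodes)
        rhat = field.radial / np.maximum(
            np.linalg.norm(field.radial, axis=1, keepdims=True), 1e-12)
        wig = np.sin(2 * np.pi * times[:, None] / params.period + phase[None, :])
        nodes = nodes + params.noise_amp * (field.g[None, :] * wig)[:, :, None] \
            * rhat[None, :, :]

    cs = ContourSequence(times=times, nodes=nodes, period=params.period,
                         phase_split=params.phase_split, node_s=s)
    cs.validate()
    for i in (0, int(np.argmax(amp))):
        if cs.frame_polygon_area(i) <= 0 or not Polygon(cs.nodes[i]).is_valid:
            raise MotionError(f"frame {i} contour is degenerate")
    return cs


def interpolate_contours(cs: ContourSequence, n_intermediate: int
                         ) -> ContourSequence:
    """Refine a contour sequence in time with periodic cubic splines.

    Each node's trajectory is fit with a periodic cubic spline through all
    frames; ``n_intermediate`` uniformly spaced samples are inserted in every
    inter-frame interval (including the wrap back to frame 0).  Original
    frame positions are reproduced exactly.
    """
    cs.validate()
    if n_intermediate < 0:
        raise MotionError("n_intermediate must be >= 0")
    if n_intermediate == 0:
        return ContourSequence(times=cs.times.copy(), nodes=cs.nodes.copy(),
                               period=cs.period, phase_split=cs.phase_split,
                               node_s=None if cs.node_s is None
                               else cs.node_s.copy())

    t_ext = np.concatenate([cs.times, [cs.times[0] + cs.period]])
    y_ext = np.concatenate([cs.nodes, cs.nodes[:1]], axis=0)
    spline = CubicSpline(t_ext, y_ext, axis=0, bc_type="periodic")

    k = n_intermediate + 1
    fine = []
    for i in range(cs.n_frames):
        t0, t1 = t_ext[i], t_ext[i + 1]
        fine.append(t0 + (t1 - t0) * np.arange(k) / k)
    fine_t = np.concatenate(fine)
    fine_nodes = spline(fine_t)
    # snap original frames to their exact input values
    fine_nodes[::k] = cs.nodes
    return ContourSequence(times=fine_t, nodes=fine_nodes, period=cs.period,
                           phase_split=cs.phase_split,
                           node_s=None if cs.node_s is None
                           else cs.node_s.copy())


def compute_area_waveform(cs: ContourSequence, inlet_width: float = None,
                          outlet_width: float = None, validate: str = "auto",
                          ) -> VolumeWaveform:
    """Enclosed area and its time derivative for a contour sequence.

    Area comes from the shoelace formula on each closed contour (the inlet
    and outlet gaps are spanned by the contour loop itself, so the widths are
    accepted for interface compatibility but not needed); dA/dt uses centred
    differences with periodic wrap.
    """
    cs.validate()
    x = cs.nodes[..., 0]
    y = cs.nodes[..., 1]
    area = 0.5 * np.sum(x * np.roll(y, -1, axis=1)
                        - np.roll(x, -1, axis=1) * y, axis=1)

    check = validate == "all" or (validate == "auto" and cs.n_frames <= 200)
    frames = range(cs.n_frames) if check else \
        np.linspace(0, cs.n_frames - 1, 20).astype(int)
    for i in frames:
        if area[i] <= 0:
            raise MotionError(f"frame {i} has non-positive area")
        if not Polygon(cs.nodes[i]).is_valid:
            raise MotionError(f"frame {i} contour is not a simple polygon")

    t = cs.times
    T = cs.period
    tp = np.roll(t, 1).copy()
    tp[0] -= T
    tn = np.roll(t, -1).copy()
    tn[-1] += T
    dA = (np.roll(area, -1) - np.roll(area, 1)) / (tn - tp)
    return VolumeWaveform(times=t.copy(), area=area, dA_dt=dA,
                          period=cs.period, phase_split=cs.phase_split)


# ---------------------------------------------------------------------------
# I/O: CSV of (frame, time_s, node_id, x1_mm, x2_mm) + JSON sidecar
# ---------------------------------------------------------------------------

def write_contours(cs: ContourSequence, csv_path, sidecar_path=None) -> None:
    import pandas as pd
    F, N, _ = cs.nodes.shape
    frame = np.repeat(np.arange(F), N)
    df = pd.DataFrame({
        "frame": frame,
        "time_s": np.repeat(cs.times, N),
        "node_id": np.tile(np.arange(N), F),
        "x1_mm": cs.nodes[..., 0].ravel(),
        "x2_mm": cs.nodes[..., 1].ravel(),
    })
    df.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        meta = {"period_s": cs.period, "phase_split_s": cs.phase_split,
                "n_nodes": int(N), "n_frames": int(F),
                "node_s_mm": None if cs.node_s is None
                else [float(v) for v in cs.node_s]}
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def read_contours(csv_path, sidecar_path=None) -> ContourSequence:
    import pandas as pd
    df = pd.read_csv(csv_path)
    frames = np.sort(df["frame"].unique())
    F = len(frames)
    N = int((df["frame"] == frames[0]).sum())
    nodes = np.empty((F, N, 2))
    times = np.empty(F)
    for i, f in enumerate(frames):
        sub = df[df["frame"] == f].sort_values("node_id")
        nodes[i, :, 0] = sub["x1_mm"].to_numpy()
        nodes[i, :, 1] = sub["x2_mm"].to_numpy()
        times[i] = sub["time_s"].iloc[0]
    period, split, node_s = PERIOD, PHASE_SPLIT, None
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        period = meta["period_s"]
        split = meta["phase_split_s"]
        if meta.get("node_s_mm") is not None:
            node_s = np.asarray(meta["node_s_mm"], float)
    cs = ContourSequence(times=times, nodes=nodes, period=period,
                         phase_split=split, node_s=node_s)
    cs.validate()
    return cs
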