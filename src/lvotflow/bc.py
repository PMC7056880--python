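"""Phase-switched inlet/outlet velocity schedules.

During diastolic filling (t < 0.480 s) the aortic outlet is a closed wall
(zero velocity) and the mitral inlet carries a spatially uniform velocity
whose magnitude equals the rate of change of chamber area divided by the
inlet width; during systolic ejection the roles swap.  A short smooth ramp
(default 5 ms) regularizes the valve switch; the synthetic area waveform has
zero rate at the transitions so the ramp matters little by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .wallmotion import VolumeWaveform

__all__ = ["BCSchedule", "derive_bc_schedule"]

log = logging.getLogger(__name__)

MM_PER_M = 1000.0


@dataclass
class BCSchedule:
    """Open-boundary mean-velocity time series over one cycle.

    Velocities are in m/s: ``inlet_mean_velocity`` is positive into the
    domain, ``outlet_mean_velocity`` positive out of it.  ``phase`` is
    ``"diastole"`` or ``"systole"`` per sample.  The spatial profile is a
    uniform plug (``uniform_profile``).
    """

    times: np.ndarray
    inlet_mean_velocity: np.ndarray
    outlet_mean_velocity: np.ndarray
    phase: np.ndarray
    period: float
    phase_split: float
    inlet_width_mm: float
    outlet_width_mm: float
    ramp_eps: float
    uniform_profile: bool = True

    def interp(self, t: float):
        """(inlet, outlet) mean velocities at an arbitrary cyclic time."""
        tc = t % self.period
        ui = np.interp(tc, self.times, self.inlet_mean_velocity,
                       period=self.period)
        uo = np.interp(tc, self.times, self.outlet_mean_velocity,
                       period=self.period)
        return float(ui), float(uo)

    def phase_at(self, t: float) -> str:
        return "diastole" if (t % self.period) < self.phase_split else "systole"

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "time_s": self.times,
            "phase": self.phase,
            "u_in_m_s": self.inlet_mean_velocity,
            "u_out_m_s": self.outlet_mean_velocity,
        }).to_csv(path, index=False)


def _ramp(t, lo, hi, eps):
    """Smoothstep window equal to 1 on [lo+eps, hi-eps], 0 outside [lo, hi]."""
    if eps <= 0:
        return ((t >= lo) & (t < hi)).astype(float)
    a = np.clip((t - lo) / eps, 0.0, 1.0)
    b = np.clip((hi - t) / eps, 0.0, 1.0)
    sm = lambda u: u * u * (3 - 2 * u)  # noqa: E731
    return sm(a) * sm(b)


def derive_bc_schedule(wave: VolumeWaveform, inlet_width: float,
                       outlet_width: float, phase_split: float = None,
                       ramp_eps: float = 0.005,
                       sign_tolerance: float = 0.02) -> BCSchedule:
    """Build the valve schedule from an area waveform.

    Parameters
    ----------
    wave : VolumeWaveform
        Chamber area waveform (mm^2, mm^2/s) over one cycle.
    inlet_width, outlet_width : float
        Open-boundary widths in mm.
    phase_split : float, optional
        Diastole -> systole transition time; defaults to the waveform's.
    ramp_eps : float
        Half-width (s) of the smooth valve-switch ramp; 0 disables it.
    sign_tolerance : float
        Fraction of the peak |dA/dt| beyond which a phase-inconsistent rate
        sign triggers a warning before clipping.
    """
    if inlet_width <= 0 or outlet_width <= 0:
        raise ValueError("widths must be positive")
    split = wave.phase_split if phase_split is None else phase_split
    if not (0.0 < split < wave.period):
        raise ValueError("phase_split must lie inside the period")

    t = wave.times
    rate = wave.dA_dt / MM_PER_M    # mm^2/s -> (mm^2/s)/1000 = mm*m/s
    peak = np.abs(wave.dA_dt).max()
    dia = t < split

    bad_dia = dia & (wave.dA_dt < -sign_tolerance * peak)
    bad_sys = ~dia & (wave.dA_dt > sign_tolerance * peak)
    if bad_dia.any() or bad_sys.any():
        log.warning("dA/dt sign inconsistent with phase at %d samples; "
                    "clipping", int(bad_dia.sum() + bad_sys.sum()))

    u_in = np.where(dia, np.maximum(rate, 0.0) / inlet_width, 0.0)
    u_out = np.where(~dia, np.maximum(-rate, 0.0) / outlet_width, 0.0)
    u_in = u_in * _ramp(t, 0.0, split, ramp_eps)
    u_out = u_out * _ramp(t, split, wave.period, ramp_eps)

    phase = np.where(dia, "diastole", "systole")
    return BCSchedule(times=t.copy(), inlet_mean_velocity=u_in,
                      outlet_mean_velocity=u_out, phase=phase,
                      period=wave.period, phase_split=split,
                      inlet_width_mm=inlet_width, outlet_width_mm=outlet_width,
                      ramp_eps=ramp_eps)
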