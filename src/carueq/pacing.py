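"""Periodic voltage-clamp waveform used to pace the lattice.

The membrane potential is not a dynamical variable in this model: the cell is
driven by an imposed periodic action potential of period ``T`` and duration
``APD``.  The waveform is a smoothed rectangular pulse — a short linear
upstroke to ``V_peak``, a plateau with an optional linear droop, and a linear
repolarization back to ``V_rest`` — which is all the analysis needs, since the
beat-to-beat flux balances are insensitive to the fine clamp shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["APClamp", "ap_waveform"]


@dataclass(frozen=True)
class APClamp:
    """Clamped action-potential waveform, evaluable as V(t).

    Parameters
    ----------
    period : float
        Pacing period T, ms.
    apd : float
        Action potential duration, ms (time from stimulus onset to the end of
        repolarization).
    v_rest, v_peak : float
        Diastolic and peak potentials, mV.
    rise_ms : float
        Upstroke duration, ms.
    repol_ms : float
        Repolarization ramp duration, ms (contained within ``apd``).
    plateau_droop : float
        Linear drop of the plateau over its span, mV (0 gives a flat plateau).
    """

    period: float = 500.0
    apd: float = 200.0
    v_rest: float = -85.0
    v_peak: float = 20.0
    rise_ms: float = 2.0
    repol_ms: float = 10.0
    plateau_droop: float = 30.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("pacing.period must be positive")
        if not (0 < self.apd < self.period):
            raise ValueError("pacing.apd must lie in (0, period)")
        if self.rise_ms < 0 or self.repol_ms < 0:
            raise ValueError("pacing ramp durations must be nonnegative")
        if self.rise_ms + self.repol_ms > self.apd:
            raise ValueError("pacing ramps must fit inside apd")
        if self.v_peak <= self.v_rest:
            raise ValueError("pacing.v_peak must exceed v_rest")

    def __call__(self, t):
        return ap_waveform(t, self)


def ap_waveform(t, clamp: APClamp):
    """Evaluate the clamped potential V(t) in mV.  Periodic and deterministic.

    Accepts scalars or arrays; vectorized via numpy.
    """
    tm = np.mod(np.asarray(t, dtype=float), clamp.period)
    v = np.full_like(tm, clamp.v_rest)

    rise_end = clamp.rise_ms
    repol_start = clamp.apd - clamp.repol_ms
    v_plat_end = clamp.v_peak - clamp.plateau_droop

    if clamp.rise_ms > 0:
        m = tm < rise_end
        v = np.where(
            m, clamp.v_rest + (clamp.v_peak - clamp.v_rest) * tm / clamp.rise_ms, v
        )
    plat = (tm >= rise_end) & (tm < repol_start)
    if repol_start > rise_end:
        frac = (tm - rise_end) / max(repol_start - rise_end, 1e-12)
        v = np.where(plat, clamp.v_peak + (v_plat_end - clamp.v_peak) * frac, v)
    rep = (tm >= repol_start) & (tm < clamp.apd)
    if clamp.repol_ms > 0:
        frac = (tm - repol_start) / clamp.repol_ms
        v = np.where(rep, v_plat_end + (clamp.v_rest - v_plat_end) * frac, v)
    if np.ndim(t) == 0:
        return float(v)
    return v
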