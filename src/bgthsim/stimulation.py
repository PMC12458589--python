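"""Open-loop deep-brain-stimulation (DBS) current waveform.

The DBS current is a periodic rectangular pulse train written with
Heaviside step functions of sinusoids:

    I_DBS(t) = i_D * H(sin(2 pi t / rho_D)) * (1 - H(sin(2 pi (t + delta_D) / rho_D)))

with amplitude ``i_D = 200`` uA/cm^2, impulse length ``delta_D = 0.6`` ms
and stimulation period ``rho_D = 6`` ms by default (an inter-pulse
frequency of ~167 Hz, a typical clinical high-frequency setting).  The
two Heaviside factors carve, out of the positive half-wave of the sine,
a window of width exactly ``delta_D`` at the end of each half-period, so
the waveform is "on" for ``delta_D`` ms out of every ``rho_D`` ms.

The stimulus is open loop — a fixed schedule with no feedback from the
ongoing network state — and is added only to the STN and/or GPi membrane
equations, the usual clinical targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ResolutionError

DBS_TARGETS = ("STN", "GPi")


@dataclass
class DBSParams:
    """Open-loop DBS waveform parameters and routing."""

    amplitude: float = 200.0  # i_D, uA/cm^2
    pulse_width: float = 0.6  # delta_D, ms
    period: float = 6.0  # rho_D, ms
    targets: tuple = ("STN", "GPi")
    enabled: bool = False

    def __post_init__(self):
        self.targets = tuple(self.targets)
        # pulse_width == 0 is admitted as the degenerate always-off limit
        if not 0 <= self.pulse_width < self.period:
            raise ParameterError(
                f"need 0 <= pulse_width < period, got "
                f"({self.pulse_width}, {self.period})"
            )
        if self.amplitude < 0:
            raise ParameterError("DBS amplitude must be >= 0")
        for t in self.targets:
            if t not in DBS_TARGETS:
                raise ParameterError(
                    f"DBS target {t!r} not allowed; choose from {DBS_TARGETS}"
                )
        if self.enabled and not self.targets:
            raise ParameterError("enabled DBS needs a nonempty target set")


def _heaviside(x) -> float:
    """H(x) = 1 for x > 0, else 0 (the boundary set has measure zero)."""
    return np.where(np.asarray(x) > 0.0, 1.0, 0.0)


def dbs_current(t, params: DBSParams):
    """DBS current at time t (ms); vectorized over t.

    Returns ``amplitude`` when sin(2 pi t / period) > 0 and
    sin(2 pi (t + pulse_width) / period) <= 0, else 0.  Periodic with
    ``period``; within each period the on-set has total measure
    ``pulse_width``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be >= 0")
    two_pi = 2.0 * math.pi
    on = _heaviside(np.sin(two_pi * t / params.period)) * (
        1.0 - _heaviside(np.sin(two_pi * (t + params.pulse_width) / params.period))
    )
    out = params.amplitude * on
    return float(out) if out.ndim == 0 else out


def pulse_geometry(params: DBSParams, dt: float = 0.001,
                   n_periods: int = 5) -> dict:
    """Measure the waveform on a fine grid: max, min, period, on-duration.

    Evaluates ``n_periods`` (>= 3) nominal periods at spacing ``dt`` and
    reports the observed maximum and minimum, the mean rising-edge
    spacing (detected period) and the mean on-duration per period, each
    accurate to one grid step.
    """
    if dt >= params.pulse_width:
        raise ResolutionError(
            f"grid step {dt} cannot resolve a {params.pulse_width} ms pulse"
        )
    n_periods = max(int(n_periods), 3)
    t = np.arange(0.0, n_periods * params.period, dt)
    y = dbs_current(t, params)
    on = y > 0
    rising = np.flatnonzero(~on[:-1] & on[1:]) + 1
    detected_period = float(np.mean(np.diff(t[rising]))) if len(rising) > 1 else math.nan
    on_per_period = float(np.sum(on) * dt / n_periods)
    return {
        "max": float(np.max(y)),
        "min": float(np.min(y)),
        "period": detected_period,
        "on_duration_per_period": on_per_period,
    }


def stage_stimulus(region: str, t: float, dbs: DBSParams) -> float:
    """Additive DBS current for one region at time t.

    Returns ``dbs_current(t)`` iff stimulation is enabled and the region
    is in the target set; GPe and TH always receive 0.  When both STN
    and GPi are targeted they share the identical waveform.
    """
    if region not in ("STN", "GPi", "GPe", "TH"):
        raise ParameterError(f"unknown region {region!r}")
    if not dbs.enabled or region not in dbs.targets:
        return 0.0
    return float(dbs_current(t, dbs))
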