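"""Environmental forcing: PAR and temperature as functions of time.

All shipped experiments run at a constant 1 °C; PAR is either constant
or a linear ramp (the autumn scenario ramps 20 → 0 W m⁻² over the run).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Forcing:
    """Piecewise-linear PAR trajectory and constant temperature.

    Parameters
    ----------
    par_start, par_end : float
        PAR (W m⁻²) at t = 0 and at ``ramp_end``; equal values give a
        constant light field.
    ramp_end : float
        Day at which the linear ramp finishes; PAR is held at ``par_end``
        afterwards.  Ignored when the trajectory is constant.
    temperature : float
        Water temperature, °C (constant).
    """

    par_start: float
    par_end: float | None = None
    ramp_end: float = 35.0
    temperature: float = 1.0

    def __post_init__(self) -> None:
        end = self.par_start if self.par_end is None else self.par_end
        if np.any(np.asarray(self.par_start) < 0.0) or np.any(np.asarray(end) < 0.0):
            raise ValueError("PAR must be nonnegative")
        if self.ramp_end <= 0.0:
            raise ValueError("ramp_end must be positive")

    @classmethod
    def constant(cls, par: float, temperature: float = 1.0) -> "Forcing":
        return cls(par_start=par, par_end=par, temperature=temperature)

    @classmethod
    def ramp(cls, par_start: float, par_end: float, ramp_end: float = 35.0,
             temperature: float = 1.0) -> "Forcing":
        return cls(par_start=par_start, par_end=par_end, ramp_end=ramp_end,
                   temperature=temperature)

    def par(self, t: float | np.ndarray) -> np.ndarray:
        """PAR (W m⁻²) at time t (days)."""
        end = self.par_start if self.par_end is None else self.par_end
        frac = np.clip(np.asarray(t, dtype=float) / self.ramp_end, 0.0, 1.0)
        return self.par_start + (end - self.par_start) * frac

    def temp(self, t: float | np.ndarray) -> np.ndarray:
        """Temperature (°C) at time t (days)."""
        return np.full_like(np.asarray(t, dtype=float), self.temperature)
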