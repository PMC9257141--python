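"""Flux-controlled memristor: memristance law, flux dynamics, hysteresis loops.

The leak element of the MC neuron circuit is a flux-controlled memristor:
its resistance (memristance) M is a function of the flux state
``phi = ∫ v dt``, not of the instantaneous voltage.  Two memristance laws
are provided:

``verbatim``
    The published three-branch piecewise law: M = 20000 Ω for
    phi < phi_low, a steep linear segment ``slope·phi + intercept``
    (defaults −3.98e8 Ω per flux-unit and 1e8 Ω) in between, and
    M = 100 Ω for phi ≥ phi_high.

``reconciled``
    A linearization consistent with the operating range quoted for the
    membrane experiments: M(0) = 10^4 Ω, linear in phi and clamped to
    [M_on, M_off] = [100, 20000] Ω, nonincreasing in phi.  The slope is
    fixed so that M(phi_high) = M_on, i.e. (10^4 − 100)/0.25 = 39600 Ω
    per flux-unit.

Units.  Voltages are millivolts and times milliseconds throughout the
package.  The internal flux unit is mV·s: ``flux_scale`` converts
volt·seconds of applied flux into internal flux-units and defaults to
10^3 (so 100 mV applied for 2.5 ms crosses the phi_high = 0.25 threshold,
putting the switching thresholds on the millisecond time base of the
membrane experiments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError

VERBATIM = "verbatim"
RECONCILED = "reconciled"

#: Columns of the exported hysteresis trace.
HYSTERESIS_COLUMNS = ("t_ms", "v_mV", "i_uA", "phi", "M_ohm")


@dataclass(frozen=True)
class MemristorParams:
    """Parameters of the flux-controlled memristance law.

    Parameters
    ----------
    mode
        ``"verbatim"`` or ``"reconciled"`` (see module docstring).
    M_on, M_off
        Low- and high-resistance states in Ω.
    slope, intercept
        Middle-branch coefficients of the verbatim law (Ω per flux-unit, Ω).
    phi_low, phi_high
        Flux thresholds of the piecewise law (internal flux-units).
    flux_scale
        Internal flux-units per volt·second; 10^3 makes the internal
        unit mV·s.
    M_init
        Reconciled-mode memristance at phi = 0 (Ω).
    """

    mode: str = RECONCILED
    M_on: float = 100.0
    M_off: float = 20_000.0
    slope: float = -3.98e8
    intercept: float = 1.0e8
    phi_low: float = -0.75
    phi_high: float = 0.25
    flux_scale: float = 1.0e3
    M_init: float = 10_000.0

    def __post_init__(self) -> None:
        if self.mode not in (VERBATIM, RECONCILED):
            raise ParameterError(f"unknown memristor mode {self.mode!r}")
        if not self.M_on < self.M_off:
            raise ParameterError("require M_on < M_off")
        if not self.phi_low < self.phi_high:
            raise ParameterError("require phi_low < phi_high")
        if not self.flux_scale >= 0:
            raise ParameterError("require flux_scale >= 0")

    @property
    def reconciled_slope(self) -> float:
        """Ω per flux-unit such that M falls from M_init at 0 to M_on at phi_high."""
        return (self.M_init - self.M_on) / self.phi_high

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "M_on": self.M_on,
            "M_off": self.M_off,
            "slope": self.slope,
            "intercept": self.intercept,
            "phi_low": self.phi_low,
            "phi_high": self.phi_high,
            "flux_scale": self.flux_scale,
            "M_init": self.M_init,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MemristorParams":
        return cls(**d)


def memristance(phi, params: MemristorParams = MemristorParams()):
    """Memristance M(phi) in Ω.

    Accepts a scalar or array ``phi``; returns the same shape.  Depends on
    the flux state only, never on the instantaneous voltage.
    """
    arr = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("phi must be finite")
    if params.mode == VERBATIM:
        mid = params.slope * arr + params.intercept
        out = np.where(
            arr < params.phi_low,
            params.M_off,
            np.where(arr >= params.phi_high, params.M_on, mid),
        )
    else:
        out = np.clip(
            params.M_init - params.reconciled_slope * arr,
            params.M_on,
            params.M_off,
        )
    if np.isscalar(phi) or arr.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class MemristorState:
    """Flux state and cached memristance of one memristor."""

    phi: float = 0.0
    M: float = 10_000.0

    @classmethod
    def initial(
        cls, params: MemristorParams = MemristorParams(), phi: float = 0.0
    ) -> "MemristorState":
        return cls(phi=phi, M=memristance(phi, params))


def flux_increment(v_mV, dt_ms: float, params: MemristorParams) -> float:
    """Flux gained over one step of piecewise-constant voltage, in flux-units.

    ``v·dt`` is formed in volt·seconds and then scaled by ``flux_scale``;
    exact for piecewise-constant drive and linear in dt.
    """
    return params.flux_scale * (np.asarray(v_mV) * 1e-3) * (dt_ms * 1e-3)


def update_flux(
    state: MemristorState,
    v: float,
    dt: float,
    params: MemristorParams = MemristorParams(),
) -> MemristorState:
    """Advance the flux state under voltage ``v`` (mV) for ``dt`` (ms)."""
    if not dt > 0:
        raise ParameterError("dt must be positive")
    if not math.isfinite(v):
        raise DomainError("v must be finite")
    phi = state.phi + float(flux_increment(v, dt, params))
    return MemristorState(phi=phi, M=memristance(phi, params))


def iv_hysteresis(
    amplitude: float,
    frequency: float,
    cycles: int = 1,
    params: MemristorParams = MemristorParams(),
    dt: float | None = None,
) -> pd.DataFrame:
    """Current–voltage loop under sinusoidal drive v(t) = A·sin(2πft).

    Returns a DataFrame with columns ``t_ms, v_mV, i_uA, phi, M_ohm``.
    The loop is pinched: i = v / M(phi), so i = 0 wherever v = 0, and the
    trace lies in the first and third quadrants.  Loop area shrinks as the
    drive frequency rises because the flux excursion scales as 1/f.

    Parameters
    ----------
    amplitude : drive amplitude in mV (must be ≥ 0; 0 gives i ≡ 0).
    frequency : drive frequency in Hz (> 0).
    cycles : number of full periods to simulate.
    dt : time step in ms; defaults to period/1000.
    """
    if amplitude < 0:
        raise ParameterError("amplitude must be >= 0")
    if not frequency > 0:
        raise ParameterError("frequency must be positive")
    if cycles < 1:
        raise ParameterError("cycles must be >= 1")
    period_ms = 1e3 / frequency
    if dt is None:
        dt = period_ms / 1000.0
    n = int(round(cycles * period_ms / dt)) + 1
    t = np.arange(n) * dt
    v = amplitude * np.sin(2 * np.pi * frequency * t * 1e-3)
    # flux integrated with the same sample-and-hold rule as update_flux
    dphi = flux_increment(v[:-1], dt, params)
    phi = np.concatenate(([0.0], np.cumsum(dphi)))
    M = memristance(phi, params)
    i = v * 1e3 / M  # mV/Ω → μA
    return pd.DataFrame(
        {"t_ms": t, "v_mV": v, "i_uA": i, "phi": phi, "M_ohm": M}
    )


def loop_area(trace: pd.DataFrame) -> float:
    """Area enclosed by the (v, i) trajectory, |∮ i dv|, in mV·μA.

    Taken over the whole trace; compare loops simulated with the same
    number of cycles.
    """
    v = trace["v_mV"].to_numpy()
    i = trace["i_uA"].to_numpy()
    return float(abs(np.trapezoid(i, v)))
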