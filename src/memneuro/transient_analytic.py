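"""Closed-form and finite-difference transients of RC and MC series circuits.

A first-order series loop — supply E, capacitor C, and a leak that is
either a fixed resistor R or a flux-controlled memristor M(φ) — charges as

    V_C(t) = E (1 − e^{−t/τ}),   V_leak = E e^{−t/τ},   τ = R·C (or M·C)

and discharges from V_C0 as

    V_C(t) = V_C0 e^{−t/τ},      V_leak = −V_C.

The memristor circuit is handled in two submodes: ``frozen``, in which the
memristance is held at its current state and the RC closed forms apply with
R → M (this is what the published exponential formulas describe), and
``coupled``, in which φ evolves with the leak voltage and the trace is
integrated numerically by :func:`euler_transient`.

Units: mV, ms, μA, Ω, F; charge in coulomb; power in watt.  With these
units τ[ms] = R[Ω]·C[F]·10^3 and I[μA] = V[mV]·10^3/R[Ω].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NumericalError, ParameterError
from .memristor import MemristorParams, flux_increment, memristance

#: Fixed header of the exported trace CSV.
TRACE_COLUMNS = (
    "t_ms",
    "V_C_mV",
    "V_leak_mV",
    "I_uA",
    "Q_C",
    "P_E_W",
    "P_C_W",
    "P_leak_W",
)

#: "Fully charged/discharged" operationalized as the 5τ criterion.
FULL_FRACTION = 1.0 - math.exp(-5.0)


@dataclass(frozen=True)
class SeriesCircuitParams:
    """Series charge/discharge loop: supply, capacitor, and leak element.

    ``R`` selects a fixed resistor leak; ``memristor`` (with initial flux
    ``phi0``) selects a memristive leak.  Exactly one must be given.
    ``E`` is ignored for discharge runs, where the capacitor starts at
    ``V_C0`` and relaxes to zero.
    """

    E: float = 100.0  # mV
    C: float = 1.0e-6  # F
    R: float | None = 1.0e3  # Ω
    memristor: MemristorParams | None = None
    phi0: float = 0.0
    V_C0: float = 0.0  # mV

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ParameterError("C must be positive")
        if (self.R is None) == (self.memristor is None):
            raise ParameterError("specify exactly one of R or memristor")
        if self.R is not None and not self.R > 0:
            raise ParameterError("R must be positive")

    def leak_resistance(self, phi: float | None = None) -> float:
        """Leak resistance in Ω at flux ``phi`` (defaults to phi0)."""
        if self.R is not None:
            return self.R
        return memristance(self.phi0 if phi is None else phi, self.memristor)

    @property
    def tau(self) -> float:
        """Time constant R·C (or M(phi0)·C) in ms."""
        return self.leak_resistance() * self.C * 1e3


@dataclass
class TransientTrace:
    """Time-indexed record of one charge or discharge transient."""

    t: np.ndarray
    V_C: np.ndarray
    V_leak: np.ndarray
    I: np.ndarray
    Q: np.ndarray
    P_E: np.ndarray
    P_C: np.ndarray
    P_leak: np.ndarray
    direction: str = "charge"
    phi: np.ndarray | None = None
    M: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                zip(
                    TRACE_COLUMNS,
                    (
                        self.t,
                        self.V_C,
                        self.V_leak,
                        self.I,
                        self.Q,
                        self.P_E,
                        self.P_C,
                        self.P_leak,
                    ),
                )
            )
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def _assemble(t, V_C, V_leak, I, C, E_mV, direction, phi=None, M=None):
    Q = C * V_C * 1e-3  # coulomb
    P_E = (E_mV * 1e-3) * (I * 1e-6) if direction == "charge" else np.zeros_like(I)
    P_C = (V_C * 1e-3) * (I * 1e-6)
    P_leak = (V_leak * 1e-3) * (I * 1e-6)
    return TransientTrace(
        t=np.asarray(t, float),
        V_C=V_C,
        V_leak=V_leak,
        I=I,
        Q=Q,
        P_E=P_E,
        P_C=P_C,
        P_leak=P_leak,
        direction=direction,
        phi=phi,
        M=M,
    )


def rc_charge(params: SeriesCircuitParams, t_grid) -> TransientTrace:
    """Closed-form charging transient of the fixed-resistor circuit."""
    if params.R is None:
        raise ParameterError("rc_charge requires a resistor leak")
    if params.V_C0 != 0:
        raise ParameterError("charging starts from an uncharged capacitor (V_C0 = 0)")
    t = np.asarray(t_grid, dtype=float)
    decay = np.exp(-t / params.tau)
    V_C = params.E * (1.0 - decay)
    V_leak = params.E * decay
    I = params.E * 1e3 / params.R * decay  # μA
    return _assemble(t, V_C, V_leak, I, params.C, params.E, "charge")


def rc_discharge(params: SeriesCircuitParams, t_grid) -> TransientTrace:
    """Closed-form discharge of a charged capacitor through the resistor."""
    if params.R is None:
        raise ParameterError("rc_discharge requires a resistor leak")
    if not params.V_C0 > 0:
        raise ParameterError("discharge requires V_C0 > 0")
    t = np.asarray(t_grid, dtype=float)
    decay = np.exp(-t / params.tau)
    V_C = params.V_C0 * decay
    V_leak = -V_C
    I = -params.V_C0 * 1e3 / params.R * decay  # μA
    return _assemble(t, V_C, V_leak, I, params.C, params.E, "discharge")


def _frozen_equivalent(params: SeriesCircuitParams) -> SeriesCircuitParams:
    """RC circuit with R pinned at the memristor's current memristance."""
    return SeriesCircuitParams(
        E=params.E,
        C=params.C,
        R=params.leak_resistance(),
        V_C0=params.V_C0,
    )


def mc_charge(
    params: SeriesCircuitParams, t_grid, mode: str = "frozen"
) -> TransientTrace:
    """Charging transient of the memristor-capacitor circuit.

    ``frozen`` holds M at M(phi0) and evaluates the RC closed forms with
    R → M (the published exponential description); ``coupled`` lets φ
    evolve with the memristor voltage and integrates numerically on the
    (uniform) grid.
    """
    if params.memristor is None:
        raise ParameterError("mc_charge requires a memristor leak")
    if mode == "frozen":
        tr = rc_charge(_frozen_equivalent(params), t_grid)
        tr.M = np.full_like(tr.t, params.leak_resistance())
        tr.phi = np.full_like(tr.t, params.phi0)
        return tr
    if mode != "coupled":
        raise ParameterError(f"unknown mc mode {mode!r}")
    t = np.asarray(t_grid, dtype=float)
    dt = _uniform_dt(t)
    return euler_transient(params, dt=dt, T=t[-1], direction="charge")


def mc_discharge(
    params: SeriesCircuitParams, t_grid, mode: str = "frozen"
) -> TransientTrace:
    """Discharge transient of the memristor-capacitor circuit (see mc_charge)."""
    if params.memristor is None:
        raise ParameterError("mc_discharge requires a memristor leak")
    if mode == "frozen":
        tr = rc_discharge(_frozen_equivalent(params), t_grid)
        tr.M = np.full_like(tr.t, params.leak_resistance())
        tr.phi = np.full_like(tr.t, params.phi0)
        return tr
    if mode != "coupled":
        raise ParameterError(f"unknown mc mode {mode!r}")
    t = np.asarray(t_grid, dtype=float)
    dt = _uniform_dt(t)
    return euler_transient(params, dt=dt, T=t[-1], direction="discharge")


def _uniform_dt(t: np.ndarray) -> float:
    if t.size < 2:
        raise ParameterError("coupled mode needs a grid with >= 2 points")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=0):
        raise ParameterError("coupled mode needs a uniform grid")
    return float(steps[0])


def powers(trace: TransientTrace, E: float | None = None) -> TransientTrace:
    """Recompute the power bookkeeping P_E = E·I, P_C = V_C·I, P_leak = V_leak·I.

    During charging P_E = P_C + P_leak pointwise; during discharge
    P_C + P_leak = 0 (the capacitor sources what the leak dissipates).
    """
    I_A = trace.I * 1e-6
    if trace.direction == "charge":
        if E is None:
            E = trace.V_C + trace.V_leak  # KVL: E is the loop sum
        trace.P_E = np.asarray(E, float) * 1e-3 * I_A
    else:
        trace.P_E = np.zeros_like(trace.I)
    trace.P_C = trace.V_C * 1e-3 * I_A
    trace.P_leak = trace.V_leak * 1e-3 * I_A
    return trace


def euler_transient(
    params: SeriesCircuitParams,
    dt: float,
    T: float,
    direction: str = "charge",
    verbatim_sign: bool = False,
) -> TransientTrace:
    """Forward-Euler integration of the series-loop ODE.

    The recurrence is V(t+Δt) = V(t) + (Δt/τ)(E − V(t)) for charging
    (E = 0 for discharge).  ``verbatim_sign=True`` flips the update to the
    sign-flawed published finite-difference form, which diverges from E;
    it exists for documentation only.  For a memristive leak the flux is
    advanced each step from the leak voltage and τ is state-dependent.

    Raises a hard error when dt ≥ 2τ_min (unconditionally unstable) and
    warns when dt exceeds the τ/10 accuracy guard.
    """
    if direction not in ("charge", "discharge"):
        raise ParameterError(f"unknown direction {direction!r}")
    if not dt > 0:
        raise ParameterError("dt must be positive")
    if not T > dt:
        raise ParameterError("T must exceed dt")
    if direction == "charge" and params.V_C0 != 0:
        raise ParameterError("charging starts from V_C0 = 0")
    if direction == "discharge" and not params.V_C0 > 0:
        raise ParameterError("discharge requires V_C0 > 0")

    memr = params.memristor
    tau_min = (
        params.tau
        if memr is None
        else min(params.tau, memr.M_on * params.C * 1e3)
    )
    if dt >= 2 * tau_min:
        raise ParameterError(
            f"dt = {dt} ms >= 2·tau_min = {2 * tau_min} ms: forward Euler unstable"
        )
    if dt > tau_min / 10 * (1 + 1e-9):
        warnings.warn(
            f"dt = {dt} ms exceeds tau_min/10 = {tau_min / 10} ms; accuracy degraded",
            stacklevel=2,
        )

    n = int(round(T / dt)) + 1
    t = np.arange(n) * dt
    target = params.E if direction == "charge" else 0.0

    V = np.empty(n)
    phi = np.empty(n)
    M = np.empty(n)
    V[0] = params.V_C0
    phi[0] = params.phi0
    for k in range(n - 1):
        R_k = params.R if memr is None else memristance(phi[k], memr)
        M[k] = R_k
        tau_k = R_k * params.C * 1e3
        step = (dt / tau_k) * (target - V[k])
        V[k + 1] = V[k] - step if verbatim_sign else V[k] + step
        v_leak = target - V[k]  # charge: E−V_C; discharge: −V_C
        if memr is not None:
            phi[k + 1] = phi[k] + float(flux_increment(v_leak, dt, memr))
        else:
            phi[k + 1] = phi[k]
        if not math.isfinite(V[k + 1]):
            raise NumericalError(f"membrane voltage blew up at step {k + 1}")
    M[-1] = params.R if memr is None else memristance(phi[-1], memr)

    V_leak = (params.E - V) if direction == "charge" else -V
    I = V_leak * 1e3 / M  # μA
    tr = _assemble(
        t, V, V_leak, I, params.C, params.E, direction, phi=phi, M=M
    )
    return tr


def full_charge_time(
    params: SeriesCircuitParams, threshold: float = FULL_FRACTION
) -> float:
    """Time (ms) for V_C to reach ``threshold``·E, i.e. τ·ln(1/(1−threshold)).

    The default threshold 1 − e⁻⁵ ≈ 99.33% is the 5τ "fully charged"
    criterion; the memristance is taken frozen at phi0.
    """
    if not 0 < threshold < 1:
        raise ParameterError("threshold must be in (0, 1)")
    return params.tau * math.log(1.0 / (1.0 - threshold))


def first_crossing(t, y, level: float, rising: bool = True) -> float:
    """First time (linear interpolation) at which y crosses ``level``.

    Raises if the trace never crosses.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    hit = y >= level if rising else y <= level
    if hit[0]:
        return float(t[0])
    idx = np.argmax(hit)
    if not hit[idx]:
        raise ParameterError("trace never crosses the requested level")
    t0, t1, y0, y1 = t[idx - 1], t[idx], y[idx - 1], y[idx]
    if y1 == y0:
        return float(t1)
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))
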