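"""Parallel membrane circuit under arbitrary stimulus, with response labeling.

The membrane model is the parallel leaky integrator

    dV/dt = I_ext/C − V/(R·C)          (RC leak)
    dV/dt = I_ext/C − V/(M(φ)·C)       (memristive leak, dφ/dt = V)

with I_ext the injected current, C the membrane capacitance and the leak
either a fixed resistor or a flux-controlled memristor.  Kirchhoff's
current law splits the drive into the capacitive and leak branch currents,
I_ext = I_C + I_leak, with I_leak = V/R (or V/M).

Units as elsewhere in the package: mV, ms, μA, Ω, F.  With these units the
drive term I[μA]·10⁻⁶/C[F] is numerically mV/ms and the leak term is
V/τ[ms] with τ = R·C·10³.

Response labeling.  The driven charge/discharge oscillations are labeled
descriptively — there is no threshold-and-reset spike mechanism here:

``quiescent``
    max|V| below 1% of the I·R drive scale.
``oscillatory_potentials``
    at least two local maxima, every one preceded by a trough below 50%
    of that peak — i.e. the membrane recharges from near-baseline on each
    pulse (full charge/discharge cycling).
``subthreshold_superposition``
    everything else: successive pulses ride on an incompletely decayed
    baseline (temporal summation without full discharge).

The 1% and 50% thresholds are configurable; requiring *every* peak to rise
from a deep trough is what separates a summating staircase (whose later
troughs stay high) from sustained full-depth oscillation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import NumericalError, ParameterError
from .memristor import MemristorParams, flux_increment, memristance
from .stimuli import StimulusSpec, sample

MEMBRANE_COLUMNS = ("t_ms", "V_mV", "I_ext_uA", "I_C_uA", "I_leak_uA", "Q_C")

LABELS = ("quiescent", "subthreshold_superposition", "oscillatory_potentials")


@dataclass(frozen=True)
class MembraneParams:
    """Parallel membrane circuit and solver settings.

    Defaults are the membrane-experiment values: C = 10⁻⁶ F and a 10⁴ Ω
    leak (for the memristive leak, the reconciled law with M(0) = 10⁴ Ω).
    """

    C: float = 1.0e-6  # F
    R: float | None = 1.0e4  # Ω
    memristor: MemristorParams | None = None
    phi0: float = 0.0
    V0: float = 0.0  # mV
    dt: float = 0.01  # ms
    T: float = 100.0  # ms
    method: str = "euler"

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ParameterError("C must be positive")
        if (self.R is None) == (self.memristor is None):
            raise ParameterError("specify exactly one of R or memristor")
        if self.R is not None and not self.R > 0:
            raise ParameterError("R must be positive")
        if not self.dt > 0:
            raise ParameterError("dt must be positive")
        if not self.T > self.dt:
            raise ParameterError("T must exceed dt")
        if self.method not in ("euler", "rk4"):
            raise ParameterError(f"unknown method {self.method!r}")

    def leak_resistance(self, phi: float | None = None):
        if self.R is not None:
            return self.R
        return memristance(self.phi0 if phi is None else phi, self.memristor)

    @property
    def tau(self) -> float:
        """Leak time constant at the initial state, ms."""
        return self.leak_resistance() * self.C * 1e3


@dataclass
class MembraneTrace:
    """Solved membrane trajectory with branch-current decomposition."""

    t: np.ndarray
    V: np.ndarray
    I_ext: np.ndarray
    I_C: np.ndarray
    I_leak: np.ndarray
    Q: np.ndarray
    phi: np.ndarray | None = None
    M: np.ndarray | None = None
    label: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                zip(
                    MEMBRANE_COLUMNS,
                    (self.t, self.V, self.I_ext, self.I_C, self.I_leak, self.Q),
                )
            )
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def integrate_membrane(
    params: MembraneParams, spec: StimulusSpec
) -> MembraneTrace:
    """Integrate the membrane ODE under the given stimulus.

    Forward Euler by default (dt defaults to τ/1000 for the canonical
    τ = 10 ms experiments); RK4 available for convergence testing with a
    fixed-R leak.  The stimulus is held piecewise-constant over each step.
    """
    memr = params.memristor
    tau_min = (
        params.tau if memr is None else min(params.tau, memr.M_on * params.C * 1e3)
    )
    if params.dt >= 2 * tau_min:
        raise ParameterError(
            f"dt = {params.dt} ms >= 2·tau_min = {2 * tau_min} ms: unstable"
        )
    if params.dt > tau_min / 10 * (1 + 1e-9):
        warnings.warn(
            f"dt = {params.dt} ms exceeds tau_min/10; accuracy degraded",
            stacklevel=2,
        )

    n = int(round(params.T / params.dt)) + 1
    t = np.arange(n) * params.dt
    I_ext = sample(spec, t)
    dt = params.dt
    C = params.C

    V = np.empty(n)
    V[0] = params.V0
    phi = np.empty(n) if memr is not None else None
    if phi is not None:
        phi[0] = params.phi0

    drive = I_ext * 1e-6 / C  # mV/ms

    if params.method == "rk4" and memr is None:
        tau = params.tau
        for k in range(n - 1):
            f = lambda v: drive[k] - v / tau  # noqa: E731 — stimulus held over the step
            k1 = f(V[k])
            k2 = f(V[k] + 0.5 * dt * k1)
            k3 = f(V[k] + 0.5 * dt * k2)
            k4 = f(V[k] + dt * k3)
            V[k + 1] = V[k] + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    else:
        if params.method == "rk4":
            raise ParameterError("rk4 supports the fixed-R leak only")
        for k in range(n - 1):
            if memr is None:
                tau_k = params.tau
            else:
                tau_k = memristance(phi[k], memr) * C * 1e3
            V[k + 1] = V[k] + dt * (drive[k] - V[k] / tau_k)
            if memr is not None:
                phi[k + 1] = phi[k] + float(flux_increment(V[k], dt, memr))
            if not math.isfinite(V[k + 1]):
                raise NumericalError(f"membrane voltage blew up at step {k + 1}")

    trace = MembraneTrace(
        t=t,
        V=V,
        I_ext=I_ext,
        I_C=np.empty(n),
        I_leak=np.empty(n),
        Q=C * V * 1e-3,
        phi=phi,
        M=None if memr is None else memristance(phi, memr),
    )
    return branch_currents(trace, params)


def branch_currents(trace: MembraneTrace, params: MembraneParams) -> MembraneTrace:
    """Fill I_leak = V/R (or V/M(φ)) and I_C = I_ext − I_leak, in μA."""
    if params.memristor is None:
        R = params.R
        trace.I_leak = trace.V * 1e3 / R
    else:
        M = trace.M if trace.M is not None else memristance(trace.phi, params.memristor)
        trace.I_leak = trace.V * 1e3 / M
    trace.I_C = trace.I_ext - trace.I_leak
    return trace


def classify_response(
    trace: MembraneTrace,
    params: MembraneParams,
    quiescent_frac: float = 0.01,
    trough_frac: float = 0.5,
) -> str:
    """Label the trace morphology (see module docstring for the rule).

    The drive scale is max|I_ext|·R (the steady-state voltage a sustained
    drive would reach); peaks smaller than ``quiescent_frac`` of it are
    ignored as numerical ripple.
    """
    I_max = float(np.max(np.abs(trace.I_ext), initial=0.0))
    scale = I_max * params.leak_resistance() * 1e-3  # mV
    v_max = float(np.max(np.abs(trace.V), initial=0.0))
    if scale == 0.0 or v_max < quiescent_frac * scale:
        trace.label = "quiescent"
        return trace.label

    peaks, _ = find_peaks(trace.V, prominence=quiescent_frac * scale)
    if len(peaks) < 2:
        trace.label = "subthreshold_superposition"
        return trace.label

    deep = True
    prev = 0
    for p in peaks:
        trough = float(np.min(trace.V[prev : p + 1]))
        if trough >= trough_frac * trace.V[p]:
            deep = False
            break
        prev = p
    trace.label = "oscillatory_potentials" if deep else "subthreshold_superposition"
    return trace.label


def count_peaks(
    trace: MembraneTrace, params: MembraneParams, quiescent_frac: float = 0.01
) -> int:
    """Number of prominent local maxima (same prominence floor as the classifier)."""
    I_max = float(np.max(np.abs(trace.I_ext), initial=0.0))
    scale = I_max * params.leak_resistance() * 1e-3
    if scale == 0:
        return 0
    peaks, _ = find_peaks(trace.V, prominence=quiescent_frac * scale)
    return int(len(peaks))
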