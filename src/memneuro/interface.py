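"""Run configuration, per-figure presets, serialization and orchestration.

A :class:`RunConfig` bundles one experiment (charge, discharge,
step_response, pulse_train, single_pulse, hysteresis, membrane, network)
with its circuit, stimulus and solver settings.  :func:`run_experiment`
executes it, writes CSV traces plus a JSON summary and a provenance record
(config hash, package version), and returns a manifest of the files
written with their checksums.

``PRESETS`` holds the canonical configurations reproducing the published
figures (3–15): RC/MC charge and discharge transients, the 10 μA step,
the 4/16/38-pulse trains, the single pulses, the pinched hysteresis loop,
and the asynchronous/synchronous network runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ConfigError
from .membrane_sim import (
    MembraneParams,
    classify_response,
    count_peaks,
    integrate_membrane,
)
from .memristor import MemristorParams, iv_hysteresis
from .network_sim import NetworkParams, simulate_network, synchrony_index
from .stimuli import StimulusSpec, pulse_train
from .transient_analytic import (
    SeriesCircuitParams,
    euler_transient,
    mc_charge,
    mc_discharge,
    rc_charge,
    rc_discharge,
)

log = logging.getLogger("memneuro")

EXPERIMENTS = (
    "charge",
    "discharge",
    "step_response",
    "pulse_train",
    "single_pulse",
    "hysteresis",
    "membrane",
    "network",
)


@dataclass(frozen=True)
class RunConfig:
    """One reproducible experiment: kind, circuit, stimulus, solver, seed."""

    experiment: str
    circuit: dict = field(default_factory=dict)
    stimulus: dict | None = None
    solver: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(f"unknown experiment {self.experiment!r}")
        if not isinstance(self.circuit, dict):
            raise ConfigError("circuit must be a mapping")
        if self.stimulus is not None and not isinstance(self.stimulus, dict):
            raise ConfigError("stimulus must be a mapping or null")
        needs_stim = self.experiment in (
            "step_response",
            "pulse_train",
            "single_pulse",
            "membrane",
        )
        if needs_stim and self.stimulus is None:
            raise ConfigError(f"experiment {self.experiment!r} requires a stimulus")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _memristor_from(d: dict | None) -> MemristorParams | None:
    if d is None:
        return None
    try:
        return MemristorParams.from_dict(d)
    except TypeError as exc:
        raise ConfigError(f"bad memristor parameters: {exc}") from exc


def _series_params(circuit: dict) -> SeriesCircuitParams:
    c = dict(circuit)
    c["memristor"] = _memristor_from(c.get("memristor"))
    if c["memristor"] is not None:
        c.setdefault("R", None)
    try:
        return SeriesCircuitParams(**c)
    except TypeError as exc:
        raise ConfigError(f"bad circuit parameters: {exc}") from exc


def _membrane_params(circuit: dict, solver: dict) -> MembraneParams:
    c = dict(circuit)
    c["memristor"] = _memristor_from(c.get("memristor"))
    if c["memristor"] is not None:
        c.setdefault("R", None)
    c.update({k: v for k, v in solver.items() if k in ("dt", "T", "method")})
    try:
        return MembraneParams(**c)
    except TypeError as exc:
        raise ConfigError(f"bad membrane parameters: {exc}") from exc


def _grid(params: SeriesCircuitParams, solver: dict) -> np.ndarray:
    T = solver.get("T", 10 * params.tau)
    dt = solver.get("dt", params.tau / 1000)
    return np.arange(0.0, T + dt / 2, dt)


def run_experiment(config: RunConfig, outdir) -> dict:
    """Execute one configuration; write outputs; return the file manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info(
        "run_experiment experiment=%s hash=%s seed=%d",
        config.experiment,
        config.config_hash,
        config.seed,
    )
    files: list[Path] = []
    summary: dict = {"experiment": config.experiment}
    exp = config.experiment

    if exp in ("charge", "discharge"):
        params = _series_params(config.circuit)
        mode = config.solver.get("mode", "frozen")
        grid = _grid(params, config.solver)
        if params.memristor is not None:
            fn = mc_charge if exp == "charge" else mc_discharge
            trace = fn(params, grid, mode=mode)
        elif config.solver.get("method") == "euler":
            trace = euler_transient(
                params,
                dt=float(grid[1] - grid[0]),
                T=float(grid[-1]),
                direction=exp,
            )
        else:
            trace = (rc_charge if exp == "charge" else rc_discharge)(params, grid)
        path = outdir / f"{exp}_trace.csv"
        trace.to_csv(path)
        files.append(path)
        summary.update(
            tau_ms=params.tau,
            V_C_final_mV=float(trace.V_C[-1]),
            V_C_at_tau_mV=float(np.interp(params.tau, trace.t, trace.V_C)),
        )

    elif exp in ("step_response", "pulse_train", "single_pulse", "membrane"):
        params = _membrane_params(config.circuit, config.solver)
        try:
            spec = StimulusSpec.from_dict(config.stimulus)
        except TypeError as exc:
            raise ConfigError(f"bad stimulus: {exc}") from exc
        trace = integrate_membrane(params, spec)
        label = classify_response(trace, params)
        path = outdir / f"{exp}_trace.csv"
        trace.to_csv(path)
        files.append(path)
        summary.update(
            label=label,
            n_peaks=count_peaks(trace, params),
            V_max=float(np.max(np.abs(trace.V))),
        )

    elif exp == "hysteresis":
        c = dict(config.circuit)
        params = _memristor_from(c.get("memristor")) or MemristorParams()
        frame = iv_hysteresis(
            amplitude=c.get("amplitude", 100.0),
            frequency=c.get("frequency", 50.0),
            cycles=int(c.get("cycles", 2)),
            params=params,
            dt=config.solver.get("dt"),
        )
        path = outdir / "hysteresis_trace.csv"
        frame.to_csv(path, index=False, float_format="%.12g")
        files.append(path)
        summary.update(
            n_samples=int(len(frame)),
            M_min_ohm=float(frame["M_ohm"].min()),
            M_max_ohm=float(frame["M_ohm"].max()),
        )

    else:  # network
        c = dict(config.circuit)
        c["memristor"] = _memristor_from(c.get("memristor")) or MemristorParams()
        c.setdefault("seed", config.seed)
        try:
            params = NetworkParams(**c)
        except TypeError as exc:
            raise ConfigError(f"bad network parameters: {exc}") from exc
        raster = simulate_network(params)
        path = outdir / "raster.csv"
        raster.to_csv(path)
        files.append(path)
        summary.update(
            n_spikes=raster.n_spikes,
            synchrony_index=synchrony_index(raster, params),
            max_v=raster.v_max_recorded,
        )

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, sort_keys=True, indent=1))
    files.append(summary_path)

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "version": __version__,
    }
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, sort_keys=True, indent=1))
    files.append(prov_path)

    manifest = {
        "config_hash": config.config_hash,
        "version": __version__,
        "files": [
            {
                "path": str(p),
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            }
            for p in files
        ],
        "summary": summary,
    }
    log.info("run_experiment wrote %d files to %s", len(files), outdir)
    return manifest


# --- canonical per-figure presets -----------------------------------------

_RC_SERIES = {"E": 100.0, "C": 1e-6, "R": 1e3}
_MC_LOW = {
    "E": 100.0,
    "C": 1e-6,
    "memristor": MemristorParams(mode="verbatim").to_dict(),
    "phi0": 0.3,  # low-resistance branch: M = 100 Ω
}
_MEMBRANE = {"C": 1e-6, "R": 1e4}


def _train_stim(count: int, duration: float) -> dict:
    return pulse_train(count=count, duration=duration, amplitude=10.0).to_dict()


PRESETS: dict[str, RunConfig] = {
    "fig3": RunConfig(
        experiment="charge", circuit=_RC_SERIES, solver={"T": 10.0, "dt": 0.001}
    ),
    "fig4": RunConfig(
        experiment="charge", circuit=_MC_LOW, solver={"T": 1.0, "dt": 0.0001}
    ),
    "fig5": RunConfig(
        experiment="discharge",
        circuit={**_RC_SERIES, "V_C0": 100.0},
        solver={"T": 10.0, "dt": 0.001},
    ),
    "fig6": RunConfig(
        experiment="discharge",
        circuit={**_MC_LOW, "V_C0": 100.0},
        solver={"T": 1.0, "dt": 0.0001},
    ),
    "fig7": RunConfig(
        experiment="step_response",
        circuit=_MEMBRANE,
        stimulus={
            "kind": "step",
            "amplitude": 10.0,
            "onset": 3.0,
            "width": 30.0,
            "duration": 40.0,
        },
        solver={"T": 40.0, "dt": 0.01},
    ),
    "fig8": RunConfig(
        experiment="pulse_train",
        circuit=_MEMBRANE,
        stimulus=_train_stim(16, 100.0),
        solver={"T": 100.0, "dt": 0.01},
    ),
    "fig9": RunConfig(
        experiment="pulse_train",
        circuit=_MEMBRANE,
        stimulus=_train_stim(16, 1000.0),
        solver={"T": 1000.0, "dt": 0.01},
    ),
    "fig10": RunConfig(
        experiment="pulse_train",
        circuit=_MEMBRANE,
        stimulus=_train_stim(38, 1000.0),
        solver={"T": 1000.0, "dt": 0.01},
    ),
    "fig11": RunConfig(
        experiment="pulse_train",
        circuit=_MEMBRANE,
        stimulus=_train_stim(4, 20.0),
        solver={"T": 20.0, "dt": 0.01},
    ),
    "fig12": RunConfig(
        experiment="pulse_train",
        circuit=_MEMBRANE,
        stimulus=_train_stim(4, 1000.0),
        solver={"T": 1000.0, "dt": 0.01},
    ),
    "fig13": RunConfig(
        experiment="single_pulse",
        circuit=_MEMBRANE,
        stimulus={
            "kind": "single_pulse",
            "amplitude": 10.0,
            "onset": 0.0,
            "width": 10.0,
            "duration": 20.0,
        },
        solver={"T": 20.0, "dt": 0.01},
    ),
    "fig14": RunConfig(
        experiment="single_pulse",
        circuit=_MEMBRANE,
        stimulus={
            "kind": "single_pulse",
            "amplitude": 10.0,
            "onset": 0.0,
            "width": 500.0,
            "duration": 1000.0,
        },
        solver={"T": 1000.0, "dt": 0.01},
    ),
    "fig1d": RunConfig(
        experiment="hysteresis",
        circuit={
            "amplitude": 100.0,
            "frequency": 50.0,
            "cycles": 2,
            "memristor": MemristorParams(mode="reconciled").to_dict(),
        },
    ),
    "fig15a": RunConfig(
        experiment="network", circuit={"inhibitory_scale": 1.0}, seed=0
    ),
    "fig15c": RunConfig(
        experiment="network", circuit={"inhibitory_scale": 0.01}, seed=0
    ),
}


def generate_fixtures(seed: int, outdir) -> list[Path]:
    """Write the per-figure preset configs plus three randomized configs.

    Byte-stable for a fixed seed (sorted-key JSON, deterministic draws).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, cfg in sorted(PRESETS.items()):
        p = outdir / f"{name}.json"
        p.write_text(cfg.to_json())
        paths.append(p)
    rng = np.random.default_rng(seed)
    for k in range(3):
        count = int(rng.integers(2, 20))
        duration = float(np.round(rng.uniform(50, 500), 3))
        cfg = RunConfig(
            experiment="pulse_train",
            circuit={"C": 1e-6, "R": float(np.round(rng.uniform(1e3, 2e4), 3))},
            stimulus=pulse_train(
                count=count,
                duration=duration,
                amplitude=float(np.round(rng.uniform(1, 20), 3)),
            ).to_dict(),
            solver={"T": duration, "dt": 0.01},
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        p = outdir / f"random{k}.json"
        p.write_text(cfg.to_json())
        paths.append(p)
    log.info("generate_fixtures wrote %d configs to %s", len(paths), outdir)
    return paths
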