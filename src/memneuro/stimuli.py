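"""Parametric external-drive generators for the membrane experiments.

Five kinds of drive are supported: ``none``, a ``step`` current, a
``single_pulse``, a ``pulse_train`` of ``count`` rectangular pulses, and
Gaussian ``random_drive``.  The published pulse protocols state only the
pulse count and the total action time (e.g. 16 pulses over 100 ms); the
on/off split within a period is the configurable ``duty`` (default 0.5,
a symmetric square alternation matching the plotted waveforms).

Convention: the sampled value at a grid point holds over [t, t+Δt)
(left-continuous steps), and stimuli are zero outside their active
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

KINDS = ("none", "step", "single_pulse", "pulse_train", "random_drive")


@dataclass(frozen=True)
class StimulusSpec:
    """Description of one external drive I_ext(t).

    Fields (units): amplitude μA, onset/width/period/duration ms,
    sigma_exc/sigma_inh μA (random_drive noise scales), seed for
    random_drive reproducibility.
    """

    kind: str = "none"
    amplitude: float = 0.0
    onset: float = 0.0
    width: float | None = None
    period: float | None = None
    count: int = 1
    duration: float = 1.0
    sigma_exc: float = 5.0
    sigma_inh: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"unknown stimulus kind {self.kind!r}")
        if not np.isfinite(self.amplitude):
            raise ParameterError("amplitude must be finite")
        if not self.duration > 0:
            raise ParameterError("duration must be positive")
        if self.kind in ("single_pulse", "pulse_train"):
            if self.width is None or not self.width > 0:
                raise ParameterError(f"{self.kind} requires width > 0")
        if self.kind == "pulse_train":
            if self.count < 1:
                raise ParameterError("pulse_train requires count >= 1")
            if self.period is None or not self.period > 0:
                raise ParameterError("pulse_train requires period > 0")
            if self.width > self.period:
                raise ParameterError("require width <= period")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "amplitude": self.amplitude,
            "onset": self.onset,
            "width": self.width,
            "period": self.period,
            "count": self.count,
            "duration": self.duration,
            "sigma_exc": self.sigma_exc,
            "sigma_inh": self.sigma_inh,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        return cls(**d)


def train_layout(count: int, duration: float, duty: float = 0.5) -> tuple[float, float]:
    """(width, period) of a ``count``-pulse train filling ``duration`` ms.

    period = duration/count and width = duty·period, so the total on-time
    is duty·duration.
    """
    if not 0 < duty < 1:
        raise ParameterError("duty must be in (0, 1)")
    if count < 1:
        raise ParameterError("count must be >= 1")
    if count * 1e-9 >= duration:
        raise ParameterError("duration too short for this pulse count")
    period = duration / count
    return duty * period, period


def pulse_train(
    count: int,
    duration: float,
    amplitude: float,
    duty: float = 0.5,
    onset: float = 0.0,
) -> StimulusSpec:
    """Convenience constructor: a train laid out by :func:`train_layout`."""
    width, period = train_layout(count, duration, duty)
    return StimulusSpec(
        kind="pulse_train",
        amplitude=amplitude,
        onset=onset,
        width=width,
        period=period,
        count=count,
        duration=onset + duration,
    )


def sample(spec: StimulusSpec, t_grid) -> np.ndarray:
    """Evaluate the drive on a strictly increasing time grid (ms → μA).

    Deterministic for the non-random kinds; ``random_drive`` is
    reproducible under a fixed ``spec.seed``.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ParameterError("t_grid must be a non-empty 1-D array")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ParameterError("t_grid must be strictly increasing")

    out = np.zeros_like(t)
    if spec.kind == "none":
        return out
    if spec.kind == "step":
        end = spec.onset + spec.width if spec.width is not None else np.inf
        out[(t >= spec.onset) & (t < end)] = spec.amplitude
        return out
    if spec.kind == "single_pulse":
        out[(t >= spec.onset) & (t < spec.onset + spec.width)] = spec.amplitude
        return out
    if spec.kind == "pulse_train":
        rel = t - spec.onset
        k = np.floor(rel / spec.period)
        in_pulse = (
            (rel >= 0)
            & (k < spec.count)
            & (rel - k * spec.period < spec.width)
        )
        out[in_pulse] = spec.amplitude
        return out
    # random_drive: zero-mean Gaussian current at every grid point
    rng = np.random.default_rng(spec.seed)
    active = (t >= spec.onset) & (t < spec.onset + spec.duration)
    out[active] = spec.amplitude + rng.normal(
        0.0, spec.sigma_exc, int(active.sum())
    )
    return out


def rising_edges(i: np.ndarray) -> int:
    """Number of off→on transitions in a sampled drive (counts pulses)."""
    on = np.abs(np.asarray(i)) > 0
    return int(np.sum(on[1:] & ~on[:-1]) + (1 if on.size and on[0] else 0))
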