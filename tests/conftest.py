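import numpy as np
import pytest

from memneuro import MemristorParams, SeriesCircuitParams


@pytest.fixture
def verbatim() -> MemristorParams:
    return MemristorParams(mode="verbatim")


@pytest.fixture
def reconciled() -> MemristorParams:
    return MemristorParams(mode="reconciled")


@pytest.fixture
def rc_circuit() -> SeriesCircuitParams:
    """The canonical series circuit: E=100 mV, R=10³ Ω, C=10⁻⁶ F, τ=1 ms."""
    return SeriesCircuitParams(E=100.0, C=1e-6, R=1e3)


@pytest.fixture
def fine_grid(rc_circuit) -> np.ndarray:
    """10τ at τ/1000 resolution."""
    tau = rc_circuit.tau
    return np.arange(0.0, 10 * tau + tau / 2000, tau / 1000)
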