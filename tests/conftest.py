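import numpy as np
import pytest

from lambdahop import SurrogateSystem, calibrate_system


@pytest.fixture(scope="session")
def calibrated_system() -> SurrogateSystem:
    """Surrogate calibrated to the printed gas/solution gaps and barrier."""
    return calibrate_system(gas_delta_g_ez=-3.0, solution_delta_g_ez=0.51, barrier=40.0)


@pytest.fixture(scope="session")
def gas_system(calibrated_system) -> SurrogateSystem:
    """Calibrated system without solvent coordinates (phi marginal unchanged)."""
    from dataclasses import replace
    return replace(calibrated_system, N_s=0)


@pytest.fixture(scope="session")
def small_system() -> SurrogateSystem:
    """Low-barrier system for fast mixing in statistical unit tests."""
    return SurrogateSystem(K_b=2.0, a=0.5, d_eps=1.0, N_s=4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
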