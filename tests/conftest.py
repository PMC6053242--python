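import numpy as np
import pytest

from cortexflow.grid import Grid
from cortexflow.phasefield import PhaseFieldState


def equilibrium_circle(grid: Grid, R: float, epsilon: float) -> PhaseFieldState:
    """Circle with the equilibrium tanh(3 d / eps) cross-section."""
    X, Y = grid.meshgrid()
    r = np.hypot(X, Y)
    phi = 0.5 * (1.0 + np.tanh(3.0 * (R - r) / epsilon))
    return PhaseFieldState(grid, phi, epsilon)


def equilibrium_stripe(grid: Grid, half_width: float,
                       epsilon: float) -> PhaseFieldState:
    """Flat (1-D) interface pair: phi = 1 inside |x| < half_width."""
    X, _ = grid.meshgrid()
    phi = 0.5 * (1.0 + np.tanh(3.0 * (half_width - np.abs(X)) / epsilon))
    return PhaseFieldState(grid, phi, epsilon)


@pytest.fixture
def grid64():
    return Grid(64, 64, 32.0, 32.0)


@pytest.fixture
def grid128():
    return Grid(128, 128, 64.0, 64.0)
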