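"""Phase-field geometry: cell and eggshell indicator fields, the double-well
potential, and curvature.

The membrane/cortex is represented implicitly by a phase field ``phi`` that is
1 inside the cell, 0 outside, and transitions smoothly across a diffuse
interface of width set by ``epsilon``; the membrane itself is the 0.5-level
set.  The double-well potential

    G(phi) = 18 phi^2 (phi - 1)^2

is nonzero only on the interface band and is used both in the interface free
energy and to restrict cortical protein dynamics to the membrane
neighbourhood.

The rigid eggshell is a *fixed* field ``phi_s`` that vanishes inside the shell
ellipse and rises to 1 outside; the product ``phi * phi_s**2`` is then nonzero
exactly where the cell attempts to cross the shell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid

__all__ = [
    "PhaseFieldState",
    "EggshellField",
    "double_well",
    "double_well_prime",
    "double_well_second",
    "init_ellipse_phase_field",
    "init_eggshell",
    "curvature",
    "grad_norm",
    "interface_weight",
]

#: Regularization added under the square root of |grad phi| wherever a unit
#: normal is formed, so that normals decay harmlessly to zero away from the
#: interface instead of dividing by zero.
GRAD_EPS = 1.0e-8

#: Stronger regularization used only inside :func:`curvature`.  The unit
#: normal there is *differentiated* spectrally, so its off-band transition
#: must stay smooth on the grid scale; 1e-2 is ~1% of the equilibrium
#: interface gradient 3/(2 eps) and biases on-band curvature by O(1e-4).
CURV_EPS = 1.0e-2

#: Floor added to G(phi) when it is used as the weight of the diffuse-domain
#: surface transport operator (see :mod:`cortexflow.species`).  The floor
#: keeps the weighted operator uniformly parabolic; it cannot be made
#: arbitrarily small because the division by the weight amplifies spectral
#: discretization error of the fluxes by 1/floor off the band.
WEIGHT_FLOOR = 0.05


def double_well(phi: np.ndarray) -> np.ndarray:
    """G(phi) = 18 phi^2 (phi-1)^2, maximal (9/8) at phi = 1/2."""
    return 18.0 * phi**2 * (phi - 1.0) ** 2


def double_well_prime(phi: np.ndarray) -> np.ndarray:
    """G'(phi) = 36 phi (phi-1) (2 phi-1)."""
    return 36.0 * phi * (phi - 1.0) * (2.0 * phi - 1.0)


def double_well_second(phi: np.ndarray) -> np.ndarray:
    """G''(phi) = 36 (6 phi^2 - 6 phi + 1)."""
    return 36.0 * (6.0 * phi**2 - 6.0 * phi + 1.0)


@dataclass
class PhaseFieldState:
    """The cell indicator field plus its interface-width parameter."""

    grid: Grid
    phi: np.ndarray
    epsilon: float = 2.0

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != self.grid.shape:
            raise ValueError("phi shape must match grid")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    def area(self) -> float:
        """Enclosed area proxy: the domain integral of phi."""
        return self.grid.integrate(self.phi)

    def copy(self) -> "PhaseFieldState":
        return PhaseFieldState(self.grid, self.phi.copy(), self.epsilon)


@dataclass
class EggshellField:
    """Fixed shell indicator: 0 inside the shell ellipse, -> 1 outside."""

    grid: Grid
    phi_s: np.ndarray
    e_d: float
    rx: float
    ry: float

    def __post_init__(self) -> None:
        self.phi_s = np.asarray(self.phi_s, dtype=float)
        if self.phi_s.shape != self.grid.shape:
            raise ValueError("phi_s shape must match grid")


def _ellipse_level(grid: Grid, rx: float, ry: float) -> np.ndarray:
    """rho(x, y) = sqrt((x/rx)^2 + (y/ry)^2); 1 on the ellipse."""
    X, Y = grid.meshgrid()
    return np.sqrt((X / rx) ** 2 + (Y / ry) ** 2)


def init_ellipse_phase_field(
    grid: Grid, rx: float = 15.0, ry: float = 25.0, epsilon: float = 2.0
) -> PhaseFieldState:
    """Elliptical initial cell.

    phi(x, y) = 0.5 (tanh((1 - rho)/(0.025 eps)) + 1) with rho the normalized
    ellipse level function, so phi = 0.5 exactly on the ellipse.  The default
    radii (15, 25) approximate a 30 um x 50 um embryo cross-section with the
    long (anterior-posterior) axis along y.
    """
    if rx >= grid.Lx / 2 or ry >= grid.Ly / 2:
        raise ValueError(
            "ellipse must fit strictly inside the periodic box "
            f"(rx={rx}, ry={ry}, box {grid.Lx} x {grid.Ly})"
        )
    rho = _ellipse_level(grid, rx, ry)
    phi = 0.5 * (np.tanh((1.0 - rho) / (0.025 * epsilon)) + 1.0)
    return PhaseFieldState(grid, phi, epsilon)


def init_eggshell(
    grid: Grid,
    rx: float = 15.0,
    ry: float = 25.0,
    e_d: float = 5.5,
    ramp_width: float | None = None,
) -> EggshellField:
    """Eggshell at distance ``e_d`` from the initial membrane ellipse.

    The shell ellipse is the membrane ellipse with both radii inflated by
    ``e_d``; phi_s is 0 strictly inside and rises smoothly to 1 outside over
    roughly one grid cell (tanh ramp in the normalized level function).
    """
    if e_d < 0:
        raise ValueError("e_d must be nonnegative")
    srx, sry = rx + e_d, ry + e_d
    if srx >= grid.Lx / 2 or sry >= grid.Ly / 2:
        raise ValueError("eggshell ellipse must fit inside the periodic box")
    if ramp_width is None:
        ramp_width = max(grid.dx, grid.dy)
    # normalized ramp width: a physical length / local radius scale
    w = ramp_width / min(srx, sry)
    rho = _ellipse_level(grid, srx, sry)
    phi_s = 0.5 * (np.tanh((rho - 1.0) / w) + 1.0)
    # clip the residual interior tail so phi_s is exactly 0 well inside
    phi_s[rho < 1.0 - 4.0 * w] = 0.0
    return EggshellField(grid, phi_s, e_d=e_d, rx=srx, ry=sry)


def grad_norm(grid: Grid, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(d phi/dx, d phi/dy, regularized |grad phi|)."""
    gx, gy = grid.grad(phi)
    mag = np.sqrt(gx**2 + gy**2 + GRAD_EPS**2)
    return gx, gy, mag


def curvature(grid: Grid, phi: np.ndarray) -> np.ndarray:
    """Local interface curvature c = div(n_out), n_out the outward unit normal.

    With phi = 1 inside the cell, grad phi points inward, so the outward
    normal is -grad phi / |grad phi| and a circle of radius R has c = +1/R on
    its 0.5-level set (positive for a convex cell).  This orientation makes
    the stabilization term ``c * eps * |grad phi|`` in the interface equation
    cancel curvature-driven shrinkage of closed interfaces.
    """
    gx, gy = grid.grad(phi)
    mag = np.sqrt(gx**2 + gy**2 + CURV_EPS**2)
    return grid.div(-gx / mag, -gy / mag)


def interface_weight(phi: np.ndarray) -> np.ndarray:
    """G(phi) floored at WEIGHT_FLOOR: the diffuse-domain surface weight.

    The floor keeps the weighted transport operator uniformly parabolic off
    the interface band, where field values act only as a smooth extension.
    """
    return double_well(phi) + WEIGHT_FLOOR
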