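"""Manufactured solutions and synthetic geometries for verification.

Every numerical operator in the package has an analytic oracle here:
manufactured forcings for the momentum solver (derived by hand once; the
derivations are reproduced in the package documentation), eigen-decay cases
for diffuse-domain surface diffusion on a circle, and parametric contours
with known furrow geometry for the observables.  None of these use the
solvers under test to construct their expected answers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .grid import Grid
from .observables import MembraneContour

__all__ = [
    "ManufacturedMomentumCase",
    "make_momentum_case",
    "make_variable_viscosity_case",
    "SurfaceDiffusionCase",
    "make_surface_diffusion_case",
    "make_synthetic_contour",
    "make_linear_interface_trajectory",
]


@dataclass
class ManufacturedMomentumCase:
    """Velocity field, viscosity and the forcing that makes it exact.

    The forcing F satisfies div[eta (grad u + grad u^T)] - xi u + F = 0
    identically for the given u, so a solver run with (eta, xi, F) must
    recover u up to its own tolerance.
    """

    grid: Grid
    eta: np.ndarray
    xi: float
    ux: np.ndarray
    uy: np.ndarray
    fx: np.ndarray
    fy: np.ndarray


def make_momentum_case(
    grid: Grid, eta0: float = 1.0, xi: float = 1.0, k_mode: int = 1, A: float = 1.0
) -> ManufacturedMomentumCase:
    """Constant-viscosity case u = (A sin(k x), 0).

    With eta constant, div[eta(grad u + grad u^T)] = (2 eta d^2u1/dx^2, 0)
    = (-2 eta k^2 A sin kx, 0), so F1 = A (2 eta0 k^2 + xi) sin(k x).
    """
    k = 2.0 * np.pi * k_mode / grid.Lx
    X, _ = grid.meshgrid()
    ux = A * np.sin(k * X)
    uy = np.zeros(grid.shape)
    fx = A * (2.0 * eta0 * k**2 + xi) * np.sin(k * X)
    fy = np.zeros(grid.shape)
    eta = np.full(grid.shape, eta0)
    return ManufacturedMomentumCase(grid, eta, xi, ux, uy, fx, fy)


def make_variable_viscosity_case(
    grid: Grid,
    eta0: float = 1.0,
    eta1: float = 0.5,
    xi: float = 1.0,
    k_mode: int = 1,
    A: float = 1.0,
) -> ManufacturedMomentumCase:
    """Variable-viscosity case: eta = eta0 + eta1 cos(q x), u = (A sin(k x), 0).

    Only the xx stress component is nonzero: s_xx = 2 eta A k cos(kx), and
      div_x s = d/dx [2 A k (eta0 + eta1 cos qx) cos kx]
              = -2 A k [ (eta0 + eta1 cos qx) k sin kx + eta1 q sin qx cos kx ]
    so F1 = xi A sin kx + 2 A k [ (eta0 + eta1 cos qx) k sin kx
                                  + eta1 q sin qx cos kx ],  F2 = 0.
    """
    if eta1 >= eta0:
        raise ValueError("need eta1 < eta0 so viscosity stays positive")
    k = 2.0 * np.pi * k_mode / grid.Lx
    q = 2.0 * np.pi / grid.Lx
    X, _ = grid.meshgrid()
    eta = eta0 + eta1 * np.cos(q * X)
    ux = A * np.sin(k * X)
    uy = np.zeros(grid.shape)
    fx = xi * ux + 2.0 * A * k * (
        eta * k * np.sin(k * X) + eta1 * q * np.sin(q * X) * np.cos(k * X)
    )
    fy = np.zeros(grid.shape)
    return ManufacturedMomentumCase(grid, eta, xi, ux, uy, fx, fy)


@dataclass
class SurfaceDiffusionCase:
    """Angular Fourier mode on a static circle with analytic eigen-decay.

    On a circle of radius R, the Laplace-Beltrami eigenfunction cos(n theta)
    decays under surface diffusion as exp(-D n^2 t / R^2).  The initial
    species field is constant along radii (the constant-normal extension of
    the surface profile), so the diffuse-domain operator should reproduce
    the surface decay rate.
    """

    R: float
    D: float
    n_mode: int
    mean: float
    amplitude: float

    def field(self, grid: Grid) -> np.ndarray:
        X, Y = grid.meshgrid()
        theta = np.arctan2(Y, X)
        return self.mean + self.amplitude * np.cos(self.n_mode * theta)

    def decay_rate(self) -> float:
        return self.D * self.n_mode**2 / self.R**2

    def amplitude_at(self, t: float) -> float:
        return self.amplitude * float(np.exp(-self.decay_rate() * t))


def make_surface_diffusion_case(
    R: float = 10.0, D: float = 1.0, n_mode: int = 1,
    mean: float = 1.0, amplitude: float = 0.5,
) -> SurfaceDiffusionCase:
    return SurfaceDiffusionCase(R, D, n_mode, mean, amplitude)


def make_synthetic_contour(
    rx: float = 15.0,
    ry: float = 25.0,
    dent_depth: float = 0.0,
    dent_width: float = 15.0,
    dent_angle: float = -0.5 * np.pi,
    n_points: int = 720,
    time: float = 0.0,
) -> MembraneContour:
    """Parametric ellipse with an optional radial Gaussian dent.

    The dent is an inward radial displacement depth * exp(-(dtheta/w)^2)
    centered at ``dent_angle`` (radians, measured from +x; -pi/2 is the
    posterior pole) with angular half-width ``dent_width`` degrees.  The
    radial depth equals ``dent_depth`` exactly at the dent center, which for
    dents narrow relative to the ellipse is the furrow depth to within the
    contour discretization.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r_ell = 1.0 / np.sqrt((np.cos(theta) / rx) ** 2 + (np.sin(theta) / ry) ** 2)
    dtheta = np.angle(np.exp(1j * (theta - dent_angle)))
    w = np.radians(dent_width)
    r = r_ell - dent_depth * np.exp(-((dtheta / w) ** 2))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return MembraneContour(pts, time)


def make_linear_interface_trajectory(
    y0: float = -20.0,
    speed: float = 0.005,
    t_end: float = 6000.0,
    cadence: float = 50.0,
    midpoint: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic interface-position series y(t) = y0 + speed * t.

    Returns (times, tracked_y, midpoint_y) in the shape expected by
    :func:`cortexflow.observables.time_to_polarization`.
    """
    times = np.arange(0.0, t_end + 0.5 * cadence, cadence)
    return times, y0 + speed * times, np.full_like(times, midpoint)
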