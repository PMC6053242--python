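"""Viscous momentum balance for the deformation velocity.

The membrane/cortex forces drive a creeping flow u that obeys a variable
viscosity Stokes-Brinkman balance without pressure (area conservation is
enforced separately, by the volume penalty force):

    div[ eta(phi, m) (grad u + grad u^T) ] - xi u + F_mem = 0

with eta = eta_m * m * 4 phi (1 - phi) + eta_c * phi (cortex more viscous
than cytoplasm, and viscosity proportional to actomyosin density there) and
xi > 0 the hydrodynamic drag that makes the operator invertible on the
periodic box.

The solver is a Fourier-preconditioned conjugate-gradient iteration: the
constant-coefficient part (mean viscosity, drag) is inverted exactly per
Fourier mode and used as the preconditioner for the full variable-viscosity
operator, which is applied spectrally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from .grid import Grid
from .params import ViscosityParams

__all__ = ["MomentumSolveError", "viscosity_field", "solve_momentum"]


class MomentumSolveError(RuntimeError):
    """Raised when the momentum solver fails to reach its tolerance."""

    def __init__(self, message: str, residuals: list[float]):
        super().__init__(message)
        self.residuals = residuals


def viscosity_field(
    phi: np.ndarray, m: np.ndarray, visc: ViscosityParams
) -> np.ndarray:
    """eta(phi, m) = eta_m m 4 phi (1-phi) + eta_c phi, floored at eta_min.

    The factor 4 phi (1-phi) is ~1 at the interface center and 0 in the bulk,
    so the cortical term lives on the membrane band only.  The floor
    (eta_min_frac * eta_c, applied outside the cell where eta would vanish)
    keeps the momentum operator uniformly elliptic; the exterior velocity is
    physically irrelevant since it only advects phi ~ 0.
    """
    eta = visc.eta_m * m * 4.0 * phi * (1.0 - phi) + visc.eta_c * phi
    return np.maximum(eta, visc.eta_min_frac * visc.eta_c)


def _apply_operator(
    grid: Grid, eta: np.ndarray, xi: float, ux: np.ndarray, uy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """B(u) = xi u - div[eta (grad u + grad u^T)]  (symmetric positive definite)."""
    uxx, uxy = grid.grad(ux)
    uyx, uyy = grid.grad(uy)
    sxx = eta * (2.0 * uxx)
    sxy = eta * (uxy + uyx)
    syy = eta * (2.0 * uyy)
    bx = xi * ux - grid.div(sxx, sxy)
    by = xi * uy - grid.div(sxy, syy)
    return bx, by


@dataclass
class _SpectralPreconditioner:
    """Exact per-mode inverse of the constant-coefficient operator.

    For mean viscosity eta0 the symbol of B is eta0 (|k|^2 I + k k^T) + xi I,
    inverted in closed form (Sherman-Morrison) as
    (1/a)(I - eta0 k k^T / (a + eta0 |k|^2)) with a = eta0 |k|^2 + xi.
    """

    grid: Grid
    eta0: float
    xi: float
    _sym: tuple[np.ndarray, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = self.grid
        ikx, iky = g._ik
        kx, ky = ikx.imag, iky.imag
        k2 = g.k2
        a = self.eta0 * k2 + self.xi
        c = self.eta0 / (a * (a + self.eta0 * k2))
        self._sym = (1.0 / a - c * kx * kx, -c * kx * ky, 1.0 / a - c * ky * ky)

    def apply(self, rx: np.ndarray, ry: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = self.grid
        rxh, ryh = g.fft(rx), g.fft(ry)
        mxx, mxy, myy = self._sym
        return (
            g.ifft(mxx * rxh + mxy * ryh),
            g.ifft(mxy * rxh + myy * ryh),
        )


def solve_momentum(
    grid: Grid,
    eta: np.ndarray,
    xi: float,
    fx: np.ndarray,
    fy: np.ndarray,
    rtol: float = 1.0e-8,
    maxiter: int = 500,
    u0: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve div[eta (grad u + grad u^T)] - xi u + F = 0 for u.

    Returns (ux, uy) satisfying the discrete equation with relative residual
    <= rtol.  Raises :class:`MomentumSolveError` (with the residual history)
    on non-convergence.
    """
    if np.min(eta) <= 0:
        raise ValueError("viscosity must be strictly positive (floor it)")
    if xi <= 0:
        raise ValueError("xi must be positive")
    fnorm = float(np.sqrt(np.sum(fx**2) + np.sum(fy**2)))
    if fnorm == 0.0:
        return np.zeros(grid.shape), np.zeros(grid.shape)

    n = grid.nx * grid.ny
    shape = grid.shape
    eta0 = 0.5 * (float(np.min(eta)) + float(np.max(eta)))
    precond = _SpectralPreconditioner(grid, eta0, xi)

    def matvec(v: np.ndarray) -> np.ndarray:
        ux = v[:n].reshape(shape)
        uy = v[n:].reshape(shape)
        bx, by = _apply_operator(grid, eta, xi, ux, uy)
        return np.concatenate([bx.ravel(), by.ravel()])

    def psolve(v: np.ndarray) -> np.ndarray:
        zx, zy = precond.apply(v[:n].reshape(shape), v[n:].reshape(shape))
        return np.concatenate([zx.ravel(), zy.ravel()])

    A = spla.LinearOperator((2 * n, 2 * n), matvec=matvec, dtype=float)
    M = spla.LinearOperator((2 * n, 2 * n), matvec=psolve, dtype=float)
    b = np.concatenate([fx.ravel(), fy.ravel()])

    residuals: list[float] = []

    def callback(vk: np.ndarray) -> None:
        residuals.append(float(np.linalg.norm(b - A @ vk)) / fnorm)

    x0 = None
    if u0 is not None:
        x0 = np.concatenate([u0[0].ravel(), u0[1].ravel()])
    sol, info = spla.cg(A, b, x0=x0, rtol=rtol, atol=0.0, maxiter=maxiter,
                        M=M, callback=callback)
    if info != 0:
        raise MomentumSolveError(
            f"momentum solver did not converge in {maxiter} iterations "
            f"(last relative residual "
            f"{residuals[-1] if residuals else float('nan'):.3e})",
            residuals,
        )
    return sol[:n].reshape(shape), sol[n:].reshape(shape)
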