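"""Uniform periodic grids and Fourier-spectral differential operators.

Every field in the simulation lives on a uniform, fully periodic 2-D grid
centered at the origin.  Periodicity is not a physical statement about the
embryo -- the cell never approaches the box boundary -- but it lets all
derivatives be taken spectrally with FFTs, which is both accurate for the
smooth diffuse-interface fields used here and cheap enough to run whole
polarization trajectories on a laptop.

Conventions
-----------
* Arrays are indexed ``[ix, iy]``; the first axis is x, the second y.
* The anterior pole of the embryo is at +y, the posterior at -y.
* Physical units are micrometres and seconds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

__all__ = ["Grid", "ScalarField", "VectorField"]


@dataclass(frozen=True)
class Grid:
    """Uniform periodic grid on ``[-Lx/2, Lx/2) x [-Ly/2, Ly/2)``.

    Parameters
    ----------
    nx, ny
        Number of cells in each direction.
    Lx, Ly
        Physical extents in micrometres.  The default 90 x 90 box leaves a
        comfortable margin around a 30 x 50 um embryo.
    """

    nx: int = 256
    ny: int = 256
    Lx: float = 90.0
    Ly: float = 90.0

    def __post_init__(self) -> None:
        if self.nx < 4 or self.ny < 4:
            raise ValueError("grid needs at least 4 cells per direction")

    # -- geometry -----------------------------------------------------------

    @property
    def dx(self) -> float:
        return self.Lx / self.nx

    @property
    def dy(self) -> float:
        return self.Ly / self.ny

    @property
    def x(self) -> np.ndarray:
        """Cell-center x coordinates (1-D)."""
        return -0.5 * self.Lx + self.dx * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        return -0.5 * self.Ly + self.dy * np.arange(self.ny)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Full coordinate arrays X, Y with shape (nx, ny)."""
        return np.meshgrid(self.x, self.y, indexing="ij")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    # -- spectral machinery -------------------------------------------------
    # Real-to-complex transforms along the last axis; wavenumber arrays are
    # cached per grid instance.

    @property
    def _ik(self) -> tuple[np.ndarray, np.ndarray]:
        cache = _spectral_cache(self)
        return cache["ikx"], cache["iky"]

    @property
    def k2(self) -> np.ndarray:
        """|k|^2 on the rfft2 layout (nx, ny//2 + 1)."""
        return _spectral_cache(self)["k2"]

    @property
    def dealias_mask(self) -> np.ndarray:
        """2/3-rule low-pass mask on the rfft2 layout."""
        return _spectral_cache(self)["mask"]

    def fft(self, f: np.ndarray) -> np.ndarray:
        return sfft.rfft2(f)

    def ifft(self, fh: np.ndarray) -> np.ndarray:
        return sfft.irfft2(fh, s=self.shape)

    def ddx(self, f: np.ndarray) -> np.ndarray:
        ikx, _ = self._ik
        return self.ifft(ikx * self.fft(f))

    def ddy(self, f: np.ndarray) -> np.ndarray:
        _, iky = self._ik
        return self.ifft(iky * self.fft(f))

    def grad(self, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fh = self.fft(f)
        ikx, iky = self._ik
        return self.ifft(ikx * fh), self.ifft(iky * fh)

    def div(self, fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
        ikx, iky = self._ik
        return self.ifft(ikx * self.fft(fx) + iky * self.fft(fy))

    def laplacian(self, f: np.ndarray) -> np.ndarray:
        return self.ifft(-self.k2 * self.fft(f))

    def dealias(self, f: np.ndarray) -> np.ndarray:
        """Remove the upper third of the spectrum (2/3 rule)."""
        return self.ifft(self.dealias_mask * self.fft(f))

    def integrate(self, f: np.ndarray) -> float:
        """Domain integral with the (spectrally exact) trapezoid rule."""
        return float(np.sum(f) * self.cell_area)


# Spectral arrays are cached keyed on the grid signature so that frozen Grid
# dataclasses stay hashable and cheap to copy around.
_CACHE: dict[tuple[int, int, float, float], dict[str, np.ndarray]] = {}


def _spectral_cache(grid: Grid) -> dict[str, np.ndarray]:
    key = (grid.nx, grid.ny, grid.Lx, grid.Ly)
    cache = _CACHE.get(key)
    if cache is None:
        kx = 2.0 * np.pi * sfft.fftfreq(grid.nx, d=grid.dx)
        ky = 2.0 * np.pi * sfft.rfftfreq(grid.ny, d=grid.dy)
        KX, KY = np.meshgrid(kx, ky, indexing="ij")
        mask = (np.abs(KX) < (2.0 / 3.0) * np.pi / grid.dx) & (
            np.abs(KY) < (2.0 / 3.0) * np.pi / grid.dy
        )
        cache = {
            "ikx": 1j * KX,
            "iky": 1j * KY,
            "k2": KX**2 + KY**2,
            "mask": mask,
        }
        _CACHE[key] = cache
    return cache


@dataclass
class ScalarField:
    """A scalar quantity sampled at the cell centers of a grid."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy())


@dataclass
class VectorField:
    """A 2-D vector quantity (x- and y-component planes) on a grid."""

    grid: Grid
    vx: np.ndarray
    vy: np.ndarray

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        if self.vx.shape != self.grid.shape or self.vy.shape != self.grid.shape:
            raise ValueError("vector component shapes must match the grid")

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)
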