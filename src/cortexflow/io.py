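"""Snapshot, checkpoint and table serialization.

Fields are stored as compressed NPZ with grid metadata; contours as CSV of
ordered (x, y) points in um; sweep results as CSV tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .grid import Grid
from .observables import MembraneContour
from .params import CytoplasmicPools
from .species import SPECIES_NAMES, SpeciesState

__all__ = ["save_checkpoint", "load_checkpoint", "save_contour_csv",
           "load_contour_csv"]


def save_checkpoint(
    path: str | Path,
    t: float,
    grid: Grid,
    phi: np.ndarray,
    species: SpeciesState,
    ux: np.ndarray | None = None,
    uy: np.ndarray | None = None,
) -> None:
    """Store (t, phi, species, u) with grid metadata for exact restart."""
    data = {
        "t": np.array(t),
        "nx": np.array(grid.nx),
        "ny": np.array(grid.ny),
        "Lx": np.array(grid.Lx),
        "Ly": np.array(grid.Ly),
        "phi": phi,
        "pools": np.array([species.pools.Ay, species.pools.A2y,
                           species.pools.Py, species.pools.My]),
    }
    for name in SPECIES_NAMES:
        data[name] = getattr(species, name)
    if ux is not None:
        data["ux"] = ux
        data["uy"] = uy
    np.savez_compressed(path, **data)


def load_checkpoint(path: str | Path):
    """Returns (t, grid, phi, species, ux, uy); ux/uy may be None."""
    with np.load(path) as z:
        grid = Grid(int(z["nx"]), int(z["ny"]), float(z["Lx"]), float(z["Ly"]))
        pools = CytoplasmicPools(*z["pools"].tolist())
        species = SpeciesState(
            grid, *(z[name] for name in SPECIES_NAMES), pools=pools
        )
        ux = z["ux"] if "ux" in z else None
        uy = z["uy"] if "uy" in z else None
        return float(z["t"]), grid, z["phi"], species, ux, uy


def save_contour_csv(path: str | Path, contour: MembraneContour) -> None:
    np.savetxt(
        path,
        contour.points,
        delimiter=",",
        header=f"x_um,y_um  (t={contour.time} s)",
        comments="# ",
    )


def load_contour_csv(path: str | Path, time: float = 0.0) -> MembraneContour:
    return MembraneContour(np.loadtxt(path, delimiter=","), time)
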