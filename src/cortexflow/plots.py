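"""Minimal figure helpers: contour montages of a trajectory."""

from __future__ import annotations

import numpy as np

from .phasefield import EggshellField
from .runner import Trajectory

__all__ = ["plot_contour_montage"]


def plot_contour_montage(traj: Trajectory, path: str, n_panels: int = 6,
                         shell: EggshellField | None = None) -> None:
    """Save a PNG montage of membrane contours at evenly spaced times.

    Panels are colored by time; the eggshell ellipse (if present in the run
    configuration) is drawn in each panel.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    contours = traj.contours
    if not contours:
        raise ValueError("trajectory holds no contours")
    idx = np.linspace(0, len(contours) - 1, min(n_panels, len(contours)))
    idx = np.unique(idx.astype(int))
    fig, axes = plt.subplots(1, len(idx), figsize=(3 * len(idx), 3.4),
                             sharex=True, sharey=True)
    axes = np.atleast_1d(axes)
    cfg = traj.config
    theta = np.linspace(0, 2 * np.pi, 256)
    for ax, i in zip(axes, idx):
        c = contours[i]
        ax.plot(np.append(c.x, c.x[0]), np.append(c.y, c.y[0]), "b-", lw=1)
        if cfg.mech.M_s > 0:
            ax.plot((cfg.rx + cfg.e_d) * np.cos(theta),
                    (cfg.ry + cfg.e_d) * np.sin(theta), color="violet", lw=1)
        ax.set_title(f"t = {c.time:.0f} s", fontsize=9)
        ax.set_aspect("equal")
        ax.set_xlim(-cfg.Lx / 2, cfg.Lx / 2)
        ax.set_ylim(-cfg.Ly / 2, cfg.Ly / 2)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
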