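"""Optional plotting conveniences (matplotlib).

These are thin wrappers for quick inspection; no analysis result depends
on a rendered figure.
"""

from __future__ import annotations

from .stability import StabilityRegion
from .walker import Trajectory


def plot_trajectory(traj: Trajectory, ax=None):
    """CoM position, contact point and relative position vs time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(traj.t, traj.x, label="x (CoM)", lw=1.5)
    ax.step(traj.t, traj.p, where="post", label="p (contact)", lw=1.0)
    ax.plot(traj.t, traj.q, label="q = x - p", lw=1.0, ls="--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("position (m)")
    ax.legend(frameon=False)
    return ax


def plot_region(region: StabilityRegion, ax=None):
    """Heatmap of the spectral radius over the gain plane with the triangle overlaid."""
    import matplotlib.pyplot as plt
    import numpy as np

    if region.rho is None:
        raise ValueError("region has no sampled grid; use region_grid()")
    if ax is None:
        _, ax = plt.subplots()
    rho = np.where(region.rho < 1.0, region.rho, np.nan)  # white = unstable
    mesh = ax.pcolormesh(
        region.bp, region.bd, rho, shading="auto", vmin=0.0, vmax=1.0
    )
    plt.colorbar(mesh, ax=ax, label=r"spectral radius $\rho(A)$")
    tri = np.vstack([region.vertices, region.vertices[:1]])
    ax.plot(tri[:, 0], tri[:, 1], "k-", lw=1.0)
    ax.set_xlabel(r"$b_p$")
    ax.set_ylabel(r"$b_d$ (s)")
    return ax
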