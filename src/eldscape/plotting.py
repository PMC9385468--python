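"""Surface and contour rendering of landscapes (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np

from .fpe2d import GridField

__all__ = ["plot_energy"]


def plot_energy(field: GridField, ax=None, kind: str = "contour", label: str = "U"):
    """Plot an energy field as a filled contour map (jet colormap, the usual
    styling for pluripotency landscapes) or a 3-D surface.

    Masked nodes are clipped to the largest unmasked value so the far-field
    plateau does not dominate the color range.  Returns the matplotlib Axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if field is None:
        raise ValueError("no grid field to plot (mean-field fit in dim > 2?)")
    X, Y = field.grid.meshgrid()
    Z = field.values.copy()
    if field.mask is not None and field.mask.any():
        cap = Z[field.mask].max()
        Z = np.where(field.mask, Z, cap)
    Z = np.nan_to_num(Z, nan=float(np.nanmax(Z)))
    if kind == "surface":
        if ax is None:
            fig = plt.figure()
            ax = fig.add_subplot(projection="3d")
        ax.plot_surface(X, Y, Z, cmap="jet", linewidth=0, antialiased=True)
        ax.set_zlabel(label)
    else:
        if ax is None:
            _, ax = plt.subplots()
        cs = ax.contourf(X, Y, Z, levels=40, cmap="jet")
        ax.figure.colorbar(cs, ax=ax, label=label)
    ax.set_xlabel("$x_1$")
    ax.set_ylabel("$x_2$")
    return ax
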