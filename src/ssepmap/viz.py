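"""Topographic map plots (radial projection) for reports."""

from __future__ import annotations

import numpy as np

from .montage import Montage

__all__ = ["plot_topography"]


def _radial_projection(positions: np.ndarray) -> np.ndarray:
    """Project unit-sphere electrode positions to the plane.

    Azimuthal equidistant projection about the vertex: radius equals the
    polar angle, so the whole cap (including below-equator sites) stays
    visible without overlap.
    """
    x, y, z = positions.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(x, y)
    return np.stack([theta * np.sin(phi), theta * np.cos(phi)], axis=1)


def plot_topography(values: np.ndarray, montage: Montage, ax=None,
                    levels: int = 24, show_labels: bool = False,
                    cmap: str = "RdBu_r"):
    """Contour plot of one average-referenced scalp map.

    Frontal points up, right points right.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib.tri import Triangulation

    values = np.asarray(values, float)
    if values.shape != (montage.n_electrodes,):
        raise ValueError("one value per montage electrode required")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    xy = _radial_projection(montage.positions)
    tri = Triangulation(xy[:, 0], xy[:, 1])
    vmax = np.abs(values).max() or 1.0
    ax.tricontourf(tri, values, levels=levels, cmap=cmap,
                   vmin=-vmax, vmax=vmax)
    ax.scatter(xy[:, 0], xy[:, 1], s=8, c="k", zorder=3)
    if show_labels:
        for lab, (px, py) in zip(montage.electrode_ids, xy):
            ax.annotate(lab, (px, py), fontsize=6,
                        textcoords="offset points", xytext=(2, 2))
    ax.set_aspect("equal")
    ax.set_axis_off()
    return ax
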