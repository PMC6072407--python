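"""Matplotlib helpers: DQI-HLD polygons and dose-quantity curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .dose_quantity import DoseQuantityCurve
from .ensemble import DqiHldPolygon

__all__ = ["plot_polygons", "plot_dose_quantity_curve"]


def plot_polygons(polygons: list[DqiHldPolygon], ax=None, show_centroid: bool = True, labels: bool = True):
    """Draw DQI (y) vs HLD (x) polygons with optional centroids."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for poly in polygons:
        verts = np.vstack([poly.vertices, poly.vertices[:1]])
        (line,) = ax.plot(verts[:, 0], verts[:, 1], lw=1.0, alpha=0.8,
                          label=poly.compound if labels else None)
        if show_centroid:
            ax.plot(poly.centroid_hld, poly.centroid_dqi, "o", ms=4, color=line.get_color())
    ax.set_xlabel("HLD  [log10(dose, mg)]")
    ax.set_ylabel("DQI  [log10(quantity) per log10(dose)]")
    if labels and polygons:
        ax.legend(fontsize=7, loc="best")
    return ax


def plot_dose_quantity_curve(curve: DoseQuantityCurve, ax=None):
    """Draw a log-log dose-quantity curve with its slope-1 line and plateau."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.log10_dose, curve.log10_quantity, "o-", ms=4, label=f"{curve.quantity_name} ({curve.level})")
    if curve.dqi is not None and curve.hld is not None:
        x = np.asarray([curve.log10_dose.min(), curve.hld])
        ax.plot(x, x + curve.dqi, "--", color="grey", lw=1, label="slope-1 line")
        ax.axhline(curve.log10_max_quantity, ls=":", color="grey", lw=1, label="max quantity")
        ax.axvline(curve.hld, ls=":", color="grey", lw=1)
    ax.set_xlabel("log10(dose, mg)")
    ax.set_ylabel("log10(quantity)")
    ax.legend(fontsize=8)
    return ax
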