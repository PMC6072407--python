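"""Input-error ensembles and DQI-HLD polygon analytics.

Prediction errors on the two disposition inputs (V_ss and Cl) are modelled
as independent Gaussians on the log10 scale: each error scenario replaces
the original value by ``10**N(log10(original), sd)``.  Fifty perturbed
scenarios plus the original give 51 input-data scenarios; combined with the
five distribution-kinetics scenarios each compound yields 255 (HLD, DQI)
coordinate pairs.

Each compound's coordinate cloud is represented by a non-self-intersecting
closed polygon in the DQI-HLD plane (vertices ordered by angle about their
mean, which yields a star-shaped, hence simple, polygon).  The polygon's
area, centroid and second moments of area summarise where the compound
lives in suitability space and how sensitive its parameters are to the
input errors.  The second moments are taken about the HLD (x) and DQI (y)
coordinate axes, i.e. ``I_x = integral of y^2 dA`` and
``I_y = integral of x^2 dA``; centroidal moments are also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compound_io import Compound, ModelSettings
from .distribution import PLASMA_VOLUME_L, make_scenarios
from .dose_quantity import run_dose_sweep
from .physchem import absorption_params
from .pk_engine import build_time_grid, dose_events

__all__ = [
    "DqiHldPolygon",
    "make_error_scenarios",
    "build_polygon",
    "dqi_hld_vertices",
    "summarize",
]

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class DqiHldPolygon:
    """A compound's DQI-HLD polygon and its geometric summary.

    ``vertices`` are (HLD, DQI) pairs in boundary order.  ``area`` and the
    centroid come from the shoelace/polygon-centroid formulas;
    ``second_moment_hld`` is the second moment of area about the HLD (x)
    axis and ``second_moment_dqi`` the one about the DQI (y) axis, both
    unnormalised; the ``centroidal_*`` variants are taken about axes through
    the centroid.  Collinear or coincident vertex sets degenerate to area 0
    with the centroid at the vertex mean.
    """

    compound: str
    quantity_name: str
    level: str
    vertices: np.ndarray
    area: float
    centroid_hld: float
    centroid_dqi: float
    second_moment_hld: float
    second_moment_dqi: float
    centroidal_second_moment_hld: float
    centroidal_second_moment_dqi: float
    vertex_mean_hld: float
    vertex_mean_dqi: float


def make_error_scenarios(
    compound: Compound,
    settings: ModelSettings,
    rng: np.random.Generator | int | None = None,
) -> list[Compound]:
    """The compound's input-data scenarios: the original followed by
    ``settings.n_error_scenarios`` perturbed copies.

    Each perturbed copy independently replaces ``vss_per_kg`` and
    ``cl_per_kg`` by ``10**N(log10(original), settings.error_sd_log10)``
    draws.  Draws that would make the model degenerate are redrawn (and
    logged): a clearance reaching hepatic blood flow (the first-pass
    fraction would be <= 0), or a V_ss at or below the plasma volume (the
    V_central = 3.0 L distribution scenarios would be degenerate).
    """
    if rng is None:
        rng = settings.rng_seed
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sd = settings.error_sd_log10
    max_cl = settings.q_h / settings.body_weight
    min_vss = PLASMA_VOLUME_L / settings.body_weight
    scenarios = [compound]
    for i in range(settings.n_error_scenarios):
        vss = _draw_log10(rng, compound.vss_per_kg, sd, lower=min_vss, name=f"{compound.name} Vss")
        cl = _draw_log10(rng, compound.cl_per_kg, sd, upper=max_cl, name=f"{compound.name} Cl")
        scenarios.append(compound.replace(vss_per_kg=vss, cl_per_kg=cl))
    return scenarios


def _draw_log10(rng, original, sd, lower=None, upper=None, name=""):
    mean = np.log10(original)
    for _ in range(_MAX_REDRAWS):
        # sd == 0 degenerates to the original value exactly (not 10**log10(x))
        value = 10.0 ** rng.normal(mean, sd) if sd > 0 else original
        if (lower is None or value > lower) and (upper is None or value < upper):
            return value
        logger.info("redrawing %s: draw %.4g outside the physical range", name, value)
    raise RuntimeError(f"could not draw a physical value for {name} after {_MAX_REDRAWS} tries")


def _order_vertices(vertices: np.ndarray, ordering: str) -> np.ndarray:
    if ordering == "angular":
        mean = vertices.mean(axis=0)
        angles = np.arctan2(vertices[:, 1] - mean[1], vertices[:, 0] - mean[0])
        return vertices[np.argsort(angles, kind="stable")]
    if ordering == "hull":
        from scipy.spatial import ConvexHull, QhullError

        try:
            hull = ConvexHull(vertices)
        except QhullError:  # collinear input
            return _order_vertices(vertices, "angular")
        return vertices[hull.vertices]
    raise ValueError(f"unknown vertex ordering {ordering!r}")


def build_polygon(
    vertices: np.ndarray,
    compound: str = "",
    quantity_name: str = "",
    level: str = "total",
    ordering: str = "angular",
) -> DqiHldPolygon:
    """Build the closed DQI-HLD polygon from (HLD, DQI) vertex pairs.

    ``ordering="angular"`` (default) sorts the vertices by angle about
    their arithmetic mean, producing a star-shaped simple polygon through
    every vertex; ``ordering="hull"`` uses the convex hull instead (which
    drops interior points and encloses the whole cloud).
    """
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or vertices.shape[0] < 3:
        raise ValueError("need at least three (HLD, DQI) vertex pairs")
    ordered = _order_vertices(vertices, ordering)
    x, y = ordered[:, 0], ordered[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    signed_area = 0.5 * cross.sum()
    mean_x, mean_y = float(x.mean()), float(y.mean())
    scale = float(max(np.abs(ordered).max(), 1.0))
    if abs(signed_area) < 1e-12 * scale**2:
        return DqiHldPolygon(
            compound, quantity_name, level, ordered,
            area=0.0, centroid_hld=mean_x, centroid_dqi=mean_y,
            second_moment_hld=0.0, second_moment_dqi=0.0,
            centroidal_second_moment_hld=0.0, centroidal_second_moment_dqi=0.0,
            vertex_mean_hld=mean_x, vertex_mean_dqi=mean_y,
        )
    sign = 1.0 if signed_area > 0 else -1.0
    area = abs(signed_area)
    cx = sign * ((x + xn) * cross).sum() / (6.0 * area)
    cy = sign * ((y + yn) * cross).sum() / (6.0 * area)
    # standard polygon moment sums; the explicit sign handles clockwise orderings
    ix = sign * ((y * y + y * yn + yn * yn) * cross).sum() / 12.0
    iy = sign * ((x * x + x * xn + xn * xn) * cross).sum() / 12.0
    return DqiHldPolygon(
        compound, quantity_name, level, ordered,
        area=float(area),
        centroid_hld=float(cx),
        centroid_dqi=float(cy),
        second_moment_hld=float(ix),
        second_moment_dqi=float(iy),
        centroidal_second_moment_hld=float(ix - area * cy * cy),
        centroidal_second_moment_dqi=float(iy - area * cx * cx),
        vertex_mean_hld=mean_x,
        vertex_mean_dqi=mean_y,
    )


def dqi_hld_vertices(
    compound: Compound,
    settings: ModelSettings,
    quantity: str = "css_central_max",
    level: str = "total",
    errors: bool = False,
    seed: int | None = None,
) -> np.ndarray:
    """(HLD, DQI) vertex cloud for one compound and one quantity.

    Without errors: the five distribution-kinetics scenarios give five
    vertices.  With errors: 51 input-data scenarios x 5 distribution
    scenarios give 255 vertices.  ``seed`` overrides the settings seed for
    the error draws (the time-grid seed is unchanged).
    """
    rng = np.random.default_rng(settings.rng_seed if seed is None else seed)
    variants = make_error_scenarios(compound, settings, rng) if errors else [compound]
    grid = build_time_grid(settings, dose_events(settings))
    vertices = []
    for variant in variants:
        absorption = absorption_params(variant, settings)
        for scenario in make_scenarios(variant, settings):
            curves = run_dose_sweep(variant, scenario, settings, absorption=absorption, grid=grid)
            key = (quantity, level)
            if key not in curves:
                raise ValueError(
                    f"{compound.name}: quantity {quantity!r} at level {level!r} unavailable "
                    "(free levels need plasma protein binding)"
                )
            curve = curves[key]
            if curve.dqi is None:
                raise ValueError(
                    f"{compound.name}, scenario {scenario.scenario_id}: no slope-1 region "
                    f"for {quantity} ({level}); non-linear PK at all tested doses"
                )
            vertices.append((curve.hld, curve.dqi))
    return np.asarray(vertices)


def summarize(
    compounds: list[Compound],
    settings: ModelSettings,
    quantity: str = "css_central_max",
    level: str = "total",
    errors: bool = True,
    seed: int | None = None,
    ordering: str = "angular",
) -> pd.DataFrame:
    """Polygon summary table (one row per compound).

    Columns mirror the standard presentation: polygon area, second moments
    of area about the HLD and DQI axes, and the centroid's HLD and DQI
    coordinates, for the requested quantity and level.
    """
    rows = []
    for compound in compounds:
        try:
            vertices = dqi_hld_vertices(compound, settings, quantity, level, errors=errors, seed=seed)
            poly = build_polygon(vertices, compound.name, quantity, level, ordering=ordering)
        except Exception as exc:
            raise RuntimeError(f"summary failed for {compound.name}: {exc}") from exc
        rows.append(
            {
                "compound": compound.name,
                "n_vertices": len(vertices),
                "area": poly.area,
                "second_moment_hld": poly.second_moment_hld,
                "second_moment_dqi": poly.second_moment_dqi,
                "centroid_hld": poly.centroid_hld,
                "centroid_dqi": poly.centroid_dqi,
            }
        )
    return pd.DataFrame(rows)
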