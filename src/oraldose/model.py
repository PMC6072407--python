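"""Model/Results front end for the oral-dose suitability workflow.

:class:`DoseQuantityModel` is constructed from a compound record (or a row
of a compound table) plus the protocol settings; :meth:`~DoseQuantityModel.fit`
runs the full simulation pipeline — distribution-kinetics scenarios,
optional input-error ensemble, 20-dose sweeps, DQI/HLD estimation and
polygon construction — and returns a :class:`DoseQuantityResults` carrying
the estimates, their scenario/error spread, and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compound_io import Compound, ModelSettings, load_settings
from .distribution import make_scenarios
from .dose_quantity import DoseQuantityCurve, quantity_at_dose, run_dose_sweep
from .ensemble import DqiHldPolygon, build_polygon, make_error_scenarios
from .physchem import absorption_params
from .pk_engine import build_time_grid, dose_events

__all__ = ["DoseQuantityModel", "DoseQuantityResults"]


class DoseQuantityModel:
    """Dose-quantity model for one compound under a simulation protocol.

    Parameters
    ----------
    compound : Compound
        The compound's input record.
    settings : ModelSettings, optional
        Protocol constants; defaults to the standard twice-daily 14-dose
        protocol.
    """

    def __init__(self, compound: Compound, settings: ModelSettings | None = None) -> None:
        self.compound = compound
        self.settings = settings if settings is not None else load_settings()

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        name: str | None = None,
        settings: ModelSettings | None = None,
    ) -> "DoseQuantityModel":
        """Build from one row of a compound table (see ``read_compounds``
        for the column contract).  ``name`` selects the row when the frame
        holds several compounds."""
        from .compound_io import _parse_optional  # column parsing shared with read_compounds

        if name is not None:
            frame = frame[frame["name"] == name]
        if len(frame) != 1:
            raise ValueError("from_dataframe needs exactly one compound row (use name= to select)")
        row = frame.iloc[0]
        compound = Compound(
            name=str(row["name"]),
            charge_type=str(row["charge_type"]).strip().lower(),
            pka=_parse_optional(row.get("pka")),
            solubility_ph74=float(row["solubility_ph74"]),
            papp_caco2_ph65=float(row["papp_caco2_ph65"]),
            vss_per_kg=float(row["vss_per_kg"]),
            cl_per_kg=float(row["cl_per_kg"]),
            ppb_percent_bound=_parse_optional(row.get("ppb_percent_bound")),
            mol_weight=float(row["mol_weight"]),
        )
        return cls(compound, settings)

    def fit(
        self,
        quantity: str = "css_central_max",
        level: str = "total",
        errors: bool = False,
        seed: int | None = None,
        ordering: str = "angular",
    ) -> "DoseQuantityResults":
        """Run the pipeline and estimate the compound's DQI and HLD.

        ``errors=True`` adds the 50 Gaussian input-error scenarios on V_ss
        and Cl (255 polygon vertices instead of 5); ``seed`` controls those
        draws.  Returns a :class:`DoseQuantityResults`.
        """
        settings = self.settings
        rng = np.random.default_rng(settings.rng_seed if seed is None else seed)
        variants = make_error_scenarios(self.compound, settings, rng) if errors else [self.compound]
        grid = build_time_grid(settings, dose_events(settings))
        key = (quantity, level)
        vertices = []
        rows = []
        baseline_curves: dict[tuple[str, str], DoseQuantityCurve] | None = None
        for variant_idx, variant in enumerate(variants):
            absorption = absorption_params(variant, settings)
            for scenario in make_scenarios(variant, settings):
                curves = run_dose_sweep(variant, scenario, settings, absorption=absorption, grid=grid)
                if key not in curves:
                    raise ValueError(
                        f"{self.compound.name}: {quantity!r} at level {level!r} unavailable "
                        "(free levels need plasma protein binding)"
                    )
                if variant_idx == 0 and baseline_curves is None and scenario.scenario_id == "v":
                    baseline_curves = curves
                curve = curves[key]
                if curve.dqi is None:
                    raise ValueError(
                        f"{self.compound.name}, scenario {scenario.scenario_id}: no slope-1 "
                        f"region for {quantity} ({level}); non-linear PK at all tested doses"
                    )
                vertices.append((curve.hld, curve.dqi))
                rows.append(
                    {
                        "error_scenario": variant_idx,
                        "distribution_scenario": scenario.scenario_id,
                        "vss_per_kg": variant.vss_per_kg,
                        "cl_per_kg": variant.cl_per_kg,
                        "dqi": curve.dqi,
                        "hld": curve.hld,
                        "log10_max_quantity": curve.log10_max_quantity,
                        "plateau_reached": curve.plateau_reached,
                        "n_linear_points": curve.n_linear_points,
                    }
                )
        vertices = np.asarray(vertices)
        polygon = build_polygon(vertices, self.compound.name, quantity, level, ordering=ordering)
        return DoseQuantityResults(
            model=self,
            quantity=quantity,
            level=level,
            errors=errors,
            polygon=polygon,
            scenario_table=pd.DataFrame(rows),
            baseline_curves=baseline_curves or {},
        )


@dataclass
class DoseQuantityResults:
    """Fitted DQI/HLD estimates and their scenario/error dispersion.

    ``params`` exposes the headline numbers (polygon-centroid HLD and DQI,
    their sum — the capped log10 maximum quantity — plus polygon area and
    second moments); ``scenario_table`` holds the per-scenario estimates
    behind them.
    """

    model: DoseQuantityModel
    quantity: str
    level: str
    errors: bool
    polygon: DqiHldPolygon
    scenario_table: pd.DataFrame
    baseline_curves: dict[tuple[str, str], DoseQuantityCurve] = field(default_factory=dict)

    @property
    def centroid_hld(self) -> float:
        return self.polygon.centroid_hld

    @property
    def centroid_dqi(self) -> float:
        return self.polygon.centroid_dqi

    @property
    def log10_max_quantity(self) -> float:
        """Capped log10 quantity reachable at the highest linear dose:
        centroid HLD + centroid DQI."""
        return self.polygon.centroid_hld + self.polygon.centroid_dqi

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {
                "centroid_hld": self.centroid_hld,
                "centroid_dqi": self.centroid_dqi,
                "log10_max_quantity": self.log10_max_quantity,
                "area": self.polygon.area,
                "second_moment_hld": self.polygon.second_moment_hld,
                "second_moment_dqi": self.polygon.second_moment_dqi,
            }
        )

    def predict(self, dose_mg) -> np.ndarray:
        """Predicted steady-state quantity at the given dose(s), linear in
        dose up to the centroid HLD and capped above it."""
        doses = np.atleast_1d(np.asarray(dose_mg, dtype=float))
        out = np.asarray(
            [quantity_at_dose(self.centroid_dqi, self.centroid_hld, d) for d in doses]
        )
        return out if np.ndim(dose_mg) else float(out[0])

    def summary(self) -> str:
        """Readable summary of the fit."""
        c = self.model.compound
        n_err = self.scenario_table["error_scenario"].nunique()
        lines = [
            "Dose-quantity suitability fit",
            "=" * 46,
            f"compound:            {c.name} ({c.charge_type})",
            f"quantity:            {self.quantity} [{self.level}]",
            f"distribution scenarios: 5; input-data scenarios: {n_err}",
            f"polygon vertices:    {len(self.polygon.vertices)}",
            "-" * 46,
            f"centroid HLD:        {self.centroid_hld:9.3f}  log10(mg)",
            f"centroid DQI:        {self.centroid_dqi:9.3f}  log10(quantity)/dose",
            f"log10 max quantity:  {self.log10_max_quantity:9.3f}  (HLD + DQI)",
            f"polygon area:        {self.polygon.area:9.3f}  (log10 units)^2",
            f"second moment (HLD axis): {self.polygon.second_moment_hld:9.3f}",
            f"second moment (DQI axis): {self.polygon.second_moment_dqi:9.3f}",
            "-" * 46,
            "per-scenario spread:",
            f"  HLD range: [{self.scenario_table['hld'].min():.3f}, "
            f"{self.scenario_table['hld'].max():.3f}]",
            f"  DQI range: [{self.scenario_table['dqi'].min():.3f}, "
            f"{self.scenario_table['dqi'].max():.3f}]",
        ]
        return "\n".join(lines)

    def plot_polygon(self, ax=None, **kwargs):
        """Draw the DQI (y) vs HLD (x) polygon with its centroid."""
        from .plotting import plot_polygons

        return plot_polygons([self.polygon], ax=ax, **kwargs)

    def plot_curve(self, ax=None, **kwargs):
        """Draw the mid-point-scenario dose-quantity curve when available."""
        from .plotting import plot_dose_quantity_curve

        key = (self.quantity, self.level)
        if key not in self.baseline_curves:
            raise ValueError("no baseline curve stored for this quantity/level")
        return plot_dose_quantity_curve(self.baseline_curves[key], ax=ax, **kwargs)
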