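"""Dose-quantity curves and the DQI / HLD suitability parameters.

A dose sweep simulates the full repeat-dose protocol at each dose of the
20-point grid and collates each steady-state quantity into a
log10(dose) vs log10(quantity) curve.  Below the solubility-limited region
the model is linear, so the curve has slope 1; as doses saturate the
intestinal fluid the curve bends over and plateaus.

* DQI (dose-quantity intercept): intercept of the ordinary least-squares
  line through the low-dose region where the fitted slope is 1 within a
  small tolerance.  ``quantity = dose * 10**DQI`` in the linear regime.
* HLD (highest linear dose): the log10(dose) at which that slope-1 line
  reaches the curve's maximum log10(quantity), i.e.
  ``HLD = log10(max_quantity) - DQI``.  It approximates the upper dose
  limit of linear pharmacokinetics.

An alternative estimator fits the whole curve to the smooth saturation form
``log10(quantity) = log10(max_quantity) - log10(1 + 10**(HLD - log10(dose)))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .compound_io import Compound, ModelSettings
from .distribution import DistributionScenario
from .physchem import AbsorptionParams, absorption_params
from .pk_engine import QUANTITY_NAMES, build_time_grid, dose_events, simulate_protocol, steady_state_quantities

__all__ = [
    "DoseQuantityCurve",
    "PowerCurveFit",
    "run_dose_sweep",
    "estimate_dqi_hld",
    "fit_power_curve",
    "quantity_at_dose",
    "PLATEAU_LOG10_TOLERANCE",
]

#: The curve is declared plateaued when the top two doses differ by less
#: than this in log10(quantity).
PLATEAU_LOG10_TOLERANCE = 1e-3


@dataclass
class DoseQuantityCurve:
    """One steady-state quantity as a function of dose, on log10-log10 axes.

    ``level`` is ``"total"`` or ``"free"``.  The fit fields (``dqi``,
    ``hld``, ``log10_max_quantity``, ``plateau_reached``,
    ``n_linear_points``) are populated by :func:`estimate_dqi_hld`.
    """

    quantity_name: str
    level: str
    log10_dose: np.ndarray
    log10_quantity: np.ndarray
    dqi: float | None = None
    hld: float | None = None
    log10_max_quantity: float | None = None
    plateau_reached: bool | None = None
    n_linear_points: int | None = None

    def __post_init__(self) -> None:
        self.log10_dose = np.asarray(self.log10_dose, dtype=float)
        self.log10_quantity = np.asarray(self.log10_quantity, dtype=float)
        if self.log10_dose.shape != self.log10_quantity.shape:
            raise ValueError("dose and quantity arrays must have the same length")
        if np.any(np.diff(self.log10_dose) <= 0):
            raise ValueError("curve points must be sorted by strictly increasing dose")


def run_dose_sweep(
    compound: Compound,
    scenario: DistributionScenario,
    settings: ModelSettings,
    absorption: AbsorptionParams | None = None,
    grid: np.ndarray | None = None,
    fit: bool = True,
) -> dict[tuple[str, str], DoseQuantityCurve]:
    """Simulate every dose of ``settings.dose_list`` for one distribution
    scenario and build fitted dose-quantity curves.

    Returns a mapping ``(quantity_name, level) -> DoseQuantityCurve`` for
    all central/peripheral quantities at total level, plus free level when
    the compound's plasma protein binding is known.
    """
    if absorption is None:
        absorption = absorption_params(compound, settings)
    if grid is None:
        grid = build_time_grid(settings, dose_events(settings))
    doses = np.asarray(sorted(settings.dose_list))
    if np.any(doses <= 0):
        raise ValueError("dose sweep requires strictly positive doses")
    results: dict[str, list[dict[str, float]]] = {"total": [], "free": []}
    for dose in doses:
        try:
            trace = simulate_protocol(dose, absorption, scenario, settings, grid=grid)
            qty = steady_state_quantities(trace, scenario, compound, settings)
        except Exception as exc:
            raise RuntimeError(
                f"{compound.name}, scenario {scenario.scenario_id}: simulation failed at dose "
                f"{dose:g} mg: {exc}"
            ) from exc
        results["total"].append(qty["total"])
        if qty["free"] is not None:
            results["free"].append(qty["free"])
    levels = ["total"] + (["free"] if results["free"] else [])
    log_dose = np.log10(doses)
    curves: dict[tuple[str, str], DoseQuantityCurve] = {}
    for level in levels:
        for name in QUANTITY_NAMES:
            values = np.asarray([q[name] for q in results[level]])
            with np.errstate(invalid="ignore", divide="ignore"):
                # non-positive values (cancellation noise in near-degenerate
                # peripheral quantities) become NaN and fail the fit below
                log_values = np.log10(values)
            curve = DoseQuantityCurve(name, level, log_dose, log_values)
            if fit:
                # Leave the fit fields unset when a quantity has no slope-1
                # region (possible for near-degenerate peripheral quantities
                # in perturbed-input scenarios); only a caller that needs
                # that specific curve should fail.
                try:
                    estimate_dqi_hld(curve, settings)
                except ValueError:
                    pass
            curves[(name, level)] = curve
    return curves


def estimate_dqi_hld(curve: DoseQuantityCurve, settings: ModelSettings) -> tuple[float, float]:
    """Estimate DQI and HLD by the slope-1 regression method.

    Grows a prefix from the lowest dose and keeps the longest prefix of at
    least two points whose ordinary least-squares slope is within
    ``settings.slope_tolerance`` of 1.  The DQI is that fit's intercept.
    The maximum quantity is the highest-dose value (which equals the
    plateau level when the curve has flattened); the HLD extrapolates the
    slope-1 line to it: ``HLD = log10(max_quantity) - DQI``.

    Fills the fit fields of ``curve`` and returns ``(dqi, hld)``.  Raises
    :class:`ValueError` when no prefix is linear (non-linear PK at all
    tested doses).
    """
    x, y = curve.log10_dose, curve.log10_quantity
    n = x.size
    if n < 2:
        raise ValueError("need at least two curve points")
    best: tuple[int, float] | None = None
    for k in range(2, n + 1):
        slope, intercept = np.polyfit(x[:k], y[:k], 1)
        if abs(slope - 1.0) <= settings.slope_tolerance:
            best = (k, float(intercept))
    if best is None:
        raise ValueError(
            f"{curve.quantity_name} ({curve.level}): no low-dose region with slope 1 "
            f"within {settings.slope_tolerance}; non-linear PK at all tested doses"
        )
    k, dqi = best
    log10_max = float(y[-1])
    curve.dqi = dqi
    curve.hld = log10_max - dqi
    curve.log10_max_quantity = log10_max
    curve.plateau_reached = bool(abs(y[-1] - y[-2]) < PLATEAU_LOG10_TOLERANCE)
    curve.n_linear_points = k
    return curve.dqi, curve.hld


@dataclass(frozen=True)
class PowerCurveFit:
    """Result of the smooth saturation-curve fit."""

    dqi: float
    hld: float
    log10_max_quantity: float
    converged: bool
    residual_rms: float


_LN10 = np.log(10.0)


def _power_curve(log_dose, log10_max, hld):
    # log10(1 + 10**(hld - x)) computed stably via logaddexp
    return log10_max - np.logaddexp(0.0, (hld - log_dose) * _LN10) / _LN10


def fit_power_curve(curve: DoseQuantityCurve) -> PowerCurveFit:
    """Fit the saturation form
    ``log10(q) = log10(max_quantity) - log10(1 + 10**(HLD - log10(dose)))``
    by nonlinear least squares.

    In the low-dose limit the form reduces to the slope-1 line with
    intercept ``log10_max_quantity - HLD``, so ``DQI = log10_max - HLD``.
    Falls back to the regression estimates (``converged=False``) when the
    optimiser fails; in that case the curve must already be fitted.
    """
    x, y = curve.log10_dose, curve.log10_quantity
    if x.size < 4:
        raise ValueError("power-curve fit needs at least four points")
    m0 = float(y.max())
    half = m0 - np.log10(2.0)
    h0 = float(np.interp(half, y, x)) if y[0] < half < y[-1] else float(x[-1] - 1.0)
    try:
        (m, h), _ = curve_fit(_power_curve, x, y, p0=(m0, h0), maxfev=10000)
        resid = y - _power_curve(x, m, h)
        return PowerCurveFit(dqi=float(m - h), hld=float(h), log10_max_quantity=float(m),
                             converged=True, residual_rms=float(np.sqrt(np.mean(resid**2))))
    except RuntimeError:
        if curve.dqi is None or curve.hld is None:
            raise
        resid = y - _power_curve(x, curve.log10_max_quantity, curve.hld)
        return PowerCurveFit(dqi=curve.dqi, hld=curve.hld,
                             log10_max_quantity=curve.log10_max_quantity,
                             converged=False, residual_rms=float(np.sqrt(np.mean(resid**2))))


def quantity_at_dose(dqi: float, hld: float, dose_mg: float) -> float:
    """Predicted steady-state quantity at a dose from (DQI, HLD).

    ``dose * 10**DQI`` while log10(dose) <= HLD, capped at the maximum
    quantity ``10**(HLD + DQI)`` above it (doses beyond the linear range
    cannot raise exposure further).
    """
    if dose_mg <= 0:
        raise ValueError("dose must be > 0")
    log_dose = np.log10(dose_mg)
    if log_dose <= hld:
        return float(dose_mg * 10.0 ** dqi)
    return float(10.0 ** (hld + dqi))
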