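"""Three-compartment oral pharmacokinetic engine.

Model (single dose, times relative to administration):

* Compartment A is a fixed 0.08 L slug of intestinal fluid at pH 6.5.  The
  dose appears in A as a solid bolus after the gastric lag; dissolution and
  mixing are instantaneous, and only dissolved compound can transfer to the
  central compartment, one way, with rate constant ``k1``.
* While the dose exceeds the amount that saturates the fluid
  (``saturated_amount``), transfer is zero order at ``k1 * saturated_amount``
  (mg min^-1); once the remaining amount drops to the saturation limit the
  transfer becomes first order in A.  Absorption stops at the end of the
  absorption window and whatever is left in A is discarded.
* The absorbed flux is scaled by ``F_h`` (hepatic first pass) on its way
  into the central compartment B, which exchanges with a peripheral
  compartment C (rates k2, k3) and eliminates with k4::

      dB/dt = u(t) + k3*C - (k2 + k4)*B
      dC/dt = k2*B - k3*C

Everything is linear, so each phase has a closed-form modal solution
(exponentials in the disposition roots alpha/beta plus a particular term for
the constant or exponentially decaying input); repeat doses are combined by
superposition.  A numerical ODE integration of the same piecewise system is
used as an independent oracle in the test-suite, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

from .compound_io import Compound, ModelSettings
from .distribution import DistributionScenario
from .physchem import AbsorptionParams

__all__ = [
    "DoseEvent",
    "CompartmentTrace",
    "SingleDoseSolution",
    "dose_events",
    "build_time_grid",
    "single_dose_response",
    "superpose",
    "simulate_protocol",
    "steady_state_quantities",
    "simpson_auc",
    "QUANTITY_NAMES",
]

#: Steady-state quantities computed over the final dosing interval.
QUANTITY_NAMES = (
    "css_central_max",
    "css_central_avg",
    "css_central_min",
    "auc_central",
    "css_peripheral_max",
    "css_peripheral_avg",
    "css_peripheral_min",
    "auc_peripheral",
)


@dataclass(frozen=True)
class DoseEvent:
    """Timing of one repeat dose.

    ``t_dose`` is administration, ``t_absorption_start`` adds the gastric
    lag, ``t_absorption_end`` closes the absorption window, and
    ``t_unsaturated`` (when present) is the moment the intestinal fluid
    drops below saturation and absorption switches from zero to first order.
    """

    index: int
    t_dose: float
    t_absorption_start: float
    t_absorption_end: float
    t_unsaturated: float | None = None

    def __post_init__(self) -> None:
        if not (self.t_dose <= self.t_absorption_start < self.t_absorption_end):
            raise ValueError("dose event times must satisfy t_dose <= t_start < t_end")
        if self.t_unsaturated is not None and not (
            self.t_absorption_start <= self.t_unsaturated <= self.t_absorption_end
        ):
            raise ValueError("t_unsaturated must fall inside the absorption window")


@dataclass(frozen=True)
class CompartmentTrace:
    """Compartment amounts (mg) and central concentration (mg L^-1) on a
    shared, sorted time grid (min)."""

    times: np.ndarray
    amount_a: np.ndarray
    amount_b: np.ndarray
    amount_c: np.ndarray
    v_central: float

    @property
    def conc_central(self) -> np.ndarray:
        return self.amount_b / self.v_central


def dose_events(
    settings: ModelSettings,
    absorption: AbsorptionParams | None = None,
    dose_mg: float | None = None,
) -> list[DoseEvent]:
    """The repeat-dose schedule; includes the saturation switch time of each
    event when ``absorption`` and ``dose_mg`` are given and the dose exceeds
    the saturated amount within the window."""
    events = []
    for i in range(settings.n_doses):
        t_dose = i * settings.dose_interval
        t_start = t_dose + settings.gastric_lag
        t_end = t_start + settings.absorption_window
        t_unsat = None
        if absorption is not None and dose_mg is not None:
            rel = _unsaturation_delay(dose_mg, absorption)
            if rel is not None and rel < settings.absorption_window:
                t_unsat = t_start + rel
        events.append(DoseEvent(i + 1, t_dose, t_start, t_end, t_unsat))
    return events


def _unsaturation_delay(dose_mg: float, absorption: AbsorptionParams) -> float | None:
    """Time after absorption start at which A drops to saturation, or None
    if the dose never saturates the fluid."""
    sat = absorption.saturated_amount
    if dose_mg <= sat:
        return None
    return (dose_mg - sat) / (absorption.k1 * sat)


def build_time_grid(
    settings: ModelSettings,
    events: list[DoseEvent] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulation time grid (min): the regular ``grid_step`` lattice over
    [0, t_end], ``n_random_timepoints`` seeded uniform random times, and the
    special times of every dose event; sorted and unique."""
    regular = np.arange(0.0, settings.t_end + 0.5 * settings.grid_step, settings.grid_step)
    if rng is None:
        rng = np.random.default_rng(settings.rng_seed)
    random_pts = rng.uniform(0.0, settings.t_end, settings.n_random_timepoints)
    if events is None:
        events = dose_events(settings)
    specials = [0.0, settings.t_end]
    for ev in events:
        specials.extend([ev.t_dose, ev.t_absorption_start, ev.t_absorption_end])
        if ev.t_unsaturated is not None:
            specials.append(ev.t_unsaturated)
    grid = np.unique(np.concatenate([regular, random_pts, np.asarray(specials)]))
    return grid[(grid >= 0.0) & (grid <= settings.t_end)]


@dataclass(frozen=True)
class _Segment:
    t0: float
    t1: float
    # A(t) = a_lin0 - a_lin1 * tau  (zero-order)  or  a_exp0 * exp(-k1*tau)
    a_lin: tuple[float, float] | None
    a_exp: float | None
    # B/C modal coefficients: x(tau) = ca*va*e^{-alpha tau} + cb*vb*e^{-beta tau} + w*e^{-g tau}
    ca: float
    cb: float
    w1: float
    w2: float
    g: float


class SingleDoseSolution:
    """Closed-form compartment amounts for one dose, as a function of time
    since administration.  Calling the object with a time array returns
    ``(A, B, C)`` amounts in mg; times before administration give zeros.
    """

    def __init__(
        self,
        dose_mg: float,
        absorption: AbsorptionParams,
        scenario: DistributionScenario,
        settings: ModelSettings,
    ) -> None:
        if dose_mg < 0:
            raise ValueError("dose must be >= 0")
        self.dose_mg = float(dose_mg)
        self.scenario = scenario
        k1 = absorption.k1
        sat = absorption.saturated_amount
        if dose_mg > 0 and (k1 <= 0 or sat <= 0):
            raise ValueError("no absorption pathway: k1 * saturated_amount is zero with a positive dose")
        k2, k3, k4 = scenario.k2, scenario.k3, scenario.k4
        alpha, beta = scenario.alpha, scenario.beta
        # Guard the measure-zero resonance k1 == alpha or beta with a tiny nudge.
        if dose_mg > 0 and min(abs(k1 - alpha), abs(k1 - beta)) < 1e-12 * k1:
            k1 = k1 * (1.0 + 1e-9)
        self._k1 = k1
        self._ra = (k2 + k4 - alpha) / k3
        self._rb = (k2 + k4 - beta) / k3

        t_a = settings.gastric_lag
        t_b = t_a + settings.absorption_window
        self.t_absorption_start = t_a
        self.t_absorption_end = t_b
        self.t_unsaturated = None

        segments: list[_Segment] = []
        B = C = 0.0
        fh = absorption.f_h
        if dose_mg == 0:
            self._segments = []
            return
        t = t_a
        if dose_mg > sat:
            delay = _unsaturation_delay(dose_mg, absorption)
            t_sw = min(t_b, t_a + delay)
            if t_a + delay < t_b:
                self.t_unsaturated = t_a + delay
            seg = self._make_segment(t, t_sw, B, C, u0=fh * k1 * sat, g=0.0,
                                     a_lin=(dose_mg, k1 * sat), a_exp=None)
            segments.append(seg)
            B, C = self._eval_segment_end(seg)
            a_remaining = sat if t_sw < t_b else None
            t = t_sw
        else:
            a_remaining = dose_mg
        if a_remaining is not None and t < t_b:
            seg = self._make_segment(t, t_b, B, C, u0=fh * k1 * a_remaining, g=k1,
                                     a_lin=None, a_exp=a_remaining)
            segments.append(seg)
            B, C = self._eval_segment_end(seg)
        # post-absorption: closed two-compartment decay, A discarded
        segments.append(self._make_segment(t_b, np.inf, B, C, u0=0.0, g=0.0,
                                           a_lin=None, a_exp=None))
        self._segments = segments

    def _make_segment(self, t0, t1, B0, C0, u0, g, a_lin, a_exp) -> _Segment:
        k2, k3 = self.scenario.k2, self.scenario.k3
        alpha, beta = self.scenario.alpha, self.scenario.beta
        if u0 == 0.0:
            w1 = w2 = 0.0
        else:
            denom = (g - alpha) * (g - beta)
            w1 = -u0 * (g - k3) / denom
            w2 = k2 * u0 / denom
        d1 = B0 - w1
        d2 = C0 - w2
        ca = (d2 - self._rb * d1) / (self._ra - self._rb)
        cb = d1 - ca
        return _Segment(t0, t1, a_lin, a_exp, ca, cb, w1, w2, g)

    def _eval_segment_end(self, seg: _Segment) -> tuple[float, float]:
        tau = seg.t1 - seg.t0
        ea, eb = np.exp(-self.scenario.alpha * tau), np.exp(-self.scenario.beta * tau)
        eg = np.exp(-seg.g * tau)
        B = seg.ca * ea + seg.cb * eb + seg.w1 * eg
        C = seg.ca * self._ra * ea + seg.cb * self._rb * eb + seg.w2 * eg
        return float(B), float(C)

    def __call__(self, t) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = np.asarray(t, dtype=float)
        A = np.zeros(t.shape)
        B = np.zeros(t.shape)
        C = np.zeros(t.shape)
        alpha, beta = self.scenario.alpha, self.scenario.beta
        for seg in self._segments:
            mask = (t >= seg.t0) & (t < seg.t1)
            if not mask.any():
                continue
            tau = t[mask] - seg.t0
            ea, eb = np.exp(-alpha * tau), np.exp(-beta * tau)
            eg = np.exp(-seg.g * tau) if seg.g != 0.0 else 1.0
            B[mask] = seg.ca * ea + seg.cb * eb + seg.w1 * eg
            C[mask] = seg.ca * self._ra * ea + seg.cb * self._rb * eb + seg.w2 * eg
            if seg.a_lin is not None:
                a0, rate = seg.a_lin
                A[mask] = a0 - rate * tau
            elif seg.a_exp is not None:
                A[mask] = seg.a_exp * np.exp(-self._k1 * tau)
        return A, B, C


def single_dose_response(
    dose_mg: float,
    absorption: AbsorptionParams,
    scenario: DistributionScenario,
    event: DoseEvent,
    times: np.ndarray,
    settings: ModelSettings,
) -> CompartmentTrace:
    """Compartment trace of one dose event on the global grid; all amounts
    are zero before the event's administration time."""
    solution = SingleDoseSolution(dose_mg, absorption, scenario, settings)
    A, B, C = solution(np.asarray(times, dtype=float) - event.t_dose)
    return CompartmentTrace(np.asarray(times, dtype=float), A, B, C, scenario.v_central)


def superpose(traces: list[CompartmentTrace]) -> CompartmentTrace:
    """Pointwise sum of per-dose traces sharing one global grid."""
    if not traces:
        raise ValueError("no traces to superpose")
    base = traces[0]
    for tr in traces[1:]:
        if tr.times.shape != base.times.shape or not np.array_equal(tr.times, base.times):
            raise ValueError("traces must share an identical time grid")
        if tr.v_central != base.v_central:
            raise ValueError("traces must share the central volume")
    return CompartmentTrace(
        base.times,
        sum(tr.amount_a for tr in traces),
        sum(tr.amount_b for tr in traces),
        sum(tr.amount_c for tr in traces),
        base.v_central,
    )


def simulate_protocol(
    dose_mg: float,
    absorption: AbsorptionParams,
    scenario: DistributionScenario,
    settings: ModelSettings,
    grid: np.ndarray | None = None,
) -> CompartmentTrace:
    """Superposed repeat-dose trace for the full protocol.

    Equivalent to summing :func:`single_dose_response` over all dose events
    (each event contributes the same single-dose solution shifted to its own
    administration time) but evaluated in one vectorised pass.
    """
    solution = SingleDoseSolution(dose_mg, absorption, scenario, settings)
    events = dose_events(settings, absorption, dose_mg)
    if grid is None:
        base = build_time_grid(settings, events)
    else:
        specials = [ev.t_unsaturated for ev in events if ev.t_unsaturated is not None]
        base = np.union1d(grid, np.asarray(specials)) if specials else np.asarray(grid, float)
    offsets = np.asarray([ev.t_dose for ev in events])
    shifted = base[None, :] - offsets[:, None]
    A, B, C = solution(shifted.ravel())
    shape = shifted.shape
    return CompartmentTrace(
        base,
        A.reshape(shape).sum(axis=0),
        B.reshape(shape).sum(axis=0),
        C.reshape(shape).sum(axis=0),
        scenario.v_central,
    )


def simpson_auc(times: np.ndarray, values: np.ndarray) -> float:
    """Composite Simpson's rule integral of ``values`` over ``times``."""
    return float(simpson(values, x=times))


def steady_state_quantities(
    trace: CompartmentTrace,
    scenario: DistributionScenario,
    compound: Compound,
    settings: ModelSettings,
) -> dict[str, dict[str, float] | None]:
    """Steady-state exposure quantities over the final dosing interval.

    Returns ``{"total": {...}, "free": {...} or None}`` with the central and
    peripheral maximum/average/minimum concentrations (mg L^-1) and AUCs
    (mg min L^-1).  Cmax/Cmin are taken over the evaluated grid points in
    the interval; the AUC uses composite Simpson's rule on a uniform
    sub-grid (refined to an even interval count).  Free levels multiply by
    the fraction unbound and are ``None`` when plasma protein binding is
    unknown.
    """
    t_last = (settings.n_doses - 1) * settings.dose_interval
    t_end = settings.t_end
    mask = (trace.times >= t_last) & (trace.times <= t_end)
    if not mask.any() or trace.times[mask][0] > t_last or trace.times[mask][-1] < t_end:
        raise ValueError("trace does not cover the final dosing interval")
    v_per = scenario.v_peripheral
    conc_b = trace.amount_b[mask] / scenario.v_central
    conc_c = trace.amount_c[mask] / v_per

    n = int(round((t_end - t_last) / settings.grid_step))
    if n % 2 == 1:
        n += 1
    uniform = np.linspace(t_last, t_end, n + 1)
    ub = np.interp(uniform, trace.times, trace.amount_b) / scenario.v_central
    uc = np.interp(uniform, trace.times, trace.amount_c) / v_per
    interval = t_end - t_last
    auc_b = simpson_auc(uniform, ub)
    auc_c = simpson_auc(uniform, uc)
    total = {
        "css_central_max": float(conc_b.max()),
        "css_central_avg": auc_b / interval,
        "css_central_min": float(conc_b.min()),
        "auc_central": auc_b,
        "css_peripheral_max": float(conc_c.max()),
        "css_peripheral_avg": auc_c / interval,
        "css_peripheral_min": float(conc_c.min()),
        "auc_peripheral": auc_c,
    }
    fu = compound.fraction_unbound
    free = {k: v * fu for k, v in total.items()} if fu is not None else None
    return {"total": total, "free": free}
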