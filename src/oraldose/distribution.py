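"""Distribution-kinetics scenarios and two-compartment micro rate constants.

At the design stage nothing is usually known about how fast a compound
equilibrates between plasma and tissue, so each simulation is run under five
hypothetical (V_central, V_terminal) combinations that bracket plausible
human behaviour:

=========  ======================  =========================
scenario   V_central               V_terminal / V_ss
=========  ======================  =========================
i          3.0 L (plasma volume)   1.1
ii         50% of V_ss             1.1
iii        3.0 L                   2.0
iv         50% of V_ss             2.0
v          midpoint of i/ii Vc     midpoint of the 1.1/2.0 V_terminal values
=========  ======================  =========================

Given V_central, V_ss, V_terminal and clearance, the micro rate constants of
the two-compartment disposition model follow from the standard relations

* k4 = Cl / V_central              (elimination from the central compartment)
* beta = Cl / V_terminal           (terminal-phase rate; V_terminal is the
  "area"/terminal volume)
* V_ss = V_central (1 + k2/k3)
* alpha + beta = k2 + k3 + k4,  alpha * beta = k3 * k4

which rearrange to the closed form
k3 = (k4 - beta) / (k4/beta - V_ss/V_central) * ... see
:func:`derive_rate_constants`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .compound_io import Compound, ModelSettings

__all__ = [
    "DistributionScenario",
    "derive_rate_constants",
    "scenario_from_volumes",
    "make_scenarios",
    "SCENARIO_IDS",
]

SCENARIO_IDS = ("i", "ii", "iii", "iv", "v")

#: Approximate human plasma volume (L); the lower bound for V_central.
PLASMA_VOLUME_L = 3.0

_VTERM_RATIO_LOW = 1.1
_VTERM_RATIO_HIGH = 2.0


@dataclass(frozen=True)
class DistributionScenario:
    """One (V_central, V_terminal) hypothesis with derived micro constants.

    ``alpha`` and ``beta`` are the fast and slow disposition exponents
    (min^-1) of the two-compartment model; they satisfy
    alpha + beta = k2 + k3 + k4 and alpha * beta = k3 * k4.
    """

    scenario_id: str
    v_central: float    # L
    v_ss: float         # L
    v_terminal: float   # L
    cl: float           # L min^-1
    k2: float           # min^-1, central -> peripheral
    k3: float           # min^-1, peripheral -> central
    k4: float           # min^-1, elimination from central
    alpha: float        # min^-1
    beta: float         # min^-1

    @property
    def v_peripheral(self) -> float:
        """Apparent peripheral volume V_ss - V_central (L)."""
        return self.v_ss - self.v_central


def derive_rate_constants(
    v_central: float, v_ss: float, v_terminal: float, cl: float
) -> tuple[float, float, float, float, float]:
    """Micro rate constants (k2, k3, k4, alpha, beta) from volumes and Cl.

    Parameters are in L and L min^-1 and must satisfy
    0 < v_central < v_ss < v_terminal and cl > 0.  The returned constants
    reproduce the inputs through the forward relations
    V_ss = V_central (1 + k2/k3) and V_terminal = Cl / beta.
    """
    if not (0 < v_central < v_ss < v_terminal):
        raise ValueError(
            f"volume ordering violated: need 0 < Vc ({v_central!r}) < Vss ({v_ss!r}) "
            f"< Vterminal ({v_terminal!r})"
        )
    if cl <= 0:
        raise ValueError("clearance must be > 0 to derive disposition rate constants")
    k4 = cl / v_central
    beta = cl / v_terminal
    ratio = (v_ss - v_central) / v_central          # k2/k3
    # alpha*beta = k3*k4 and alpha+beta = (ratio+1)*k3 + k4 give:
    denom = k4 / beta - (ratio + 1.0)               # = Vterminal/Vc - Vss/Vc > 0
    k3 = (k4 - beta) / denom
    if k3 <= 0:
        raise ValueError("derived k3 <= 0; inconsistent volume ordering")
    k2 = ratio * k3
    alpha = k3 * k4 / beta
    return k2, k3, k4, alpha, beta


def scenario_from_volumes(
    v_central: float,
    v_ss: float,
    v_terminal: float,
    cl: float,
    scenario_id: str = "custom",
) -> DistributionScenario:
    """Build a :class:`DistributionScenario` from explicit volumes (L) and
    clearance (L min^-1)."""
    k2, k3, k4, alpha, beta = derive_rate_constants(v_central, v_ss, v_terminal, cl)
    return DistributionScenario(
        scenario_id=scenario_id,
        v_central=v_central,
        v_ss=v_ss,
        v_terminal=v_terminal,
        cl=cl,
        k2=k2,
        k3=k3,
        k4=k4,
        alpha=alpha,
        beta=beta,
    )


def make_scenarios(compound: Compound, settings: ModelSettings) -> list[DistributionScenario]:
    """The five standard distribution scenarios for a compound.

    V_ss is ``vss_per_kg * body_weight`` (L) and clearance is converted to
    L min^-1.  Raises :class:`ValueError` naming the compound when any
    scenario would need V_central >= V_ss (model degenerate, e.g. V_ss at or
    below plasma volume).
    """
    v_ss = compound.vss_per_kg * settings.body_weight
    cl = compound.cl_per_kg * settings.cl_units_to_l_per_min
    vc_low = PLASMA_VOLUME_L
    vc_high = 0.5 * v_ss
    vt_low = _VTERM_RATIO_LOW * v_ss
    vt_high = _VTERM_RATIO_HIGH * v_ss
    plans = {
        "i": (vc_low, vt_low),
        "ii": (vc_high, vt_low),
        "iii": (vc_low, vt_high),
        "iv": (vc_high, vt_high),
        "v": (0.5 * (vc_low + vc_high), 0.5 * (vt_low + vt_high)),
    }
    scenarios = []
    for sid in SCENARIO_IDS:
        v_central, v_terminal = plans[sid]
        if not (0 < v_central < v_ss):
            raise ValueError(
                f"{compound.name}: scenario {sid} needs V_central ({v_central:.3g} L) "
                f"< V_ss ({v_ss:.3g} L); distribution model degenerate"
            )
        scenarios.append(scenario_from_volumes(v_central, v_ss, v_terminal, cl, scenario_id=sid))
    return scenarios
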