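"""Physicochemical preprocessing for the absorption model.

Converts measured inputs into the parameters the intestinal compartment
needs:

* Henderson-Hasselbalch fraction-neutral for single-pKa acids and bases.
* pH 6.5 solubility from the measured pH 7.4 value via the fraction-neutral
  ratio (the intrinsic, neutral-species solubility is pH independent).
* Human jejunal effective permeability at pH 6.5 from apparent Caco2
  permeability, through a log-log calibration between neutral-species
  membrane permeabilities::

      log10(P_m,human,neutral) = 0.916 * log10(P_m,Caco2,neutral) + 1.579

  The apparent Caco2 value is converted to the neutral-species membrane
  permeability by dividing by the fraction neutral at pH 6.5 (pH-partition
  assumption) and back again after scaling.
* The absorption rate constant k1 from effective permeability and the
  geometry of a uniform cylindrical intestinal segment: SA/V = 2/r for a
  cylinder, doubled by a surface-amplification factor for intestinal folds,
  so k1 = (2 * amplification / r) * P_eff * 60 (min^-1, r in cm).
* The fraction escaping hepatic first pass, F_h = 1 - Cl_b/Q_h, with blood
  clearance taken equal to plasma clearance (blood/plasma ratio of 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compound_io import Compound, ModelSettings

__all__ = [
    "AbsorptionParams",
    "fraction_neutral",
    "solubility_at_ph",
    "solubility_at_ph65",
    "caco2_to_human_permeability",
    "peff_human",
    "k1_from_peff",
    "fraction_escaping_first_pass",
    "absorption_params",
    "CACO2_SCALING_SLOPE",
    "CACO2_SCALING_INTERCEPT",
    "INTESTINAL_PH",
    "PLASMA_PH",
]

#: Calibration of human vs Caco2 neutral-species membrane permeability
#: (log10-log10 regression over 32 reference compounds, r^2 = 0.88).
CACO2_SCALING_SLOPE = 0.916
CACO2_SCALING_INTERCEPT = 1.579

INTESTINAL_PH = 6.5
PLASMA_PH = 7.4


@dataclass(frozen=True)
class AbsorptionParams:
    """Derived absorption inputs for one compound.

    Attributes
    ----------
    solubility_ph65 : float
        Aqueous solubility at intestinal pH 6.5 (M).
    saturated_amount : float
        Amount of compound (mg) that saturates the intestinal fluid volume:
        solubility_ph65 * mol_weight * v_intestinal * 1000.
    p_eff_human_ph65 : float
        Predicted human jejunal effective permeability at pH 6.5 (cm s^-1).
    k1 : float
        First-order absorption rate constant (min^-1).
    f_h : float
        Fraction of absorbed compound escaping hepatic first-pass
        extraction, in (0, 1].
    """

    solubility_ph65: float
    saturated_amount: float
    p_eff_human_ph65: float
    k1: float
    f_h: float


def fraction_neutral(charge_type: str, pka: float | None, ph: float) -> float:
    """Fraction of the compound in its neutral form at the given pH.

    Henderson-Hasselbalch, single ionization: neutral compounds return 1;
    a monoacid returns 1/(1 + 10^(pH - pKa)); a monobase
    1/(1 + 10^(pKa - pH)).
    """
    if charge_type == "neutral":
        return 1.0
    if pka is None:
        raise ValueError(f"pKa required for charge_type {charge_type!r}")
    if charge_type == "monoacid":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    if charge_type == "monobase":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    raise NotImplementedError(
        f"charge_type {charge_type!r} not supported (zwitterions/multiprotics are out of scope)"
    )


def solubility_at_ph(compound: Compound, ph: float) -> float:
    """Solubility (M) at an arbitrary pH from the measured pH 7.4 value.

    Scales by the fraction-neutral ratio, which keeps the neutral-species
    (intrinsic) solubility pH independent:
    S(pH) * f_neutral(pH) = S(7.4) * f_neutral(7.4).
    """
    ratio = fraction_neutral(compound.charge_type, compound.pka, PLASMA_PH) / fraction_neutral(
        compound.charge_type, compound.pka, ph
    )
    return compound.solubility_ph74 * ratio


def solubility_at_ph65(compound: Compound) -> float:
    """Solubility (M) at intestinal pH 6.5; > pH 7.4 value for monobases,
    < for monoacids, unchanged for neutral compounds."""
    return solubility_at_ph(compound, INTESTINAL_PH)


def caco2_to_human_permeability(p_m_caco2_neutral: float) -> float:
    """Neutral-species human membrane permeability (cm s^-1) from the
    neutral-species Caco2 membrane permeability via the log-log calibration."""
    if p_m_caco2_neutral <= 0:
        raise ValueError("neutral-species Caco2 permeability must be > 0")
    return 10.0 ** (CACO2_SCALING_SLOPE * np.log10(p_m_caco2_neutral) + CACO2_SCALING_INTERCEPT)


def peff_human(compound: Compound) -> float:
    """Predicted human jejunal effective permeability at pH 6.5 (cm s^-1).

    Divides the apparent Caco2 permeability by the fraction neutral at
    pH 6.5 to obtain the neutral-species membrane permeability, applies the
    human/Caco2 calibration, and multiplies back by the same fraction
    neutral.  For neutral compounds the two ionization steps are identities.
    """
    fn65 = fraction_neutral(compound.charge_type, compound.pka, INTESTINAL_PH)
    if fn65 <= 0.0:
        raise ValueError(f"{compound.name}: fraction neutral at pH 6.5 underflowed to 0")
    p_m_caco2_neutral = compound.papp_caco2_ph65 / fn65
    p_m_human_neutral = caco2_to_human_permeability(p_m_caco2_neutral)
    return p_m_human_neutral * fn65


def k1_from_peff(p_eff: float, settings: ModelSettings) -> float:
    """Absorption rate constant k1 (min^-1) from effective permeability.

    k1 = SA * P_eff * 60 / V for the cylindrical intestinal segment; the
    cylinder length cancels (SA/V = 2/r), and SA carries the fold
    amplification factor, so k1 = (2 * amplification / r) * p_eff * 60.
    """
    if settings.intestinal_radius <= 0:
        raise ValueError("intestinal radius must be > 0")
    if p_eff < 0:
        raise ValueError("effective permeability must be >= 0")
    return (2.0 * settings.absorption_amplification / settings.intestinal_radius) * p_eff * 60.0


def fraction_escaping_first_pass(cl_per_kg: float, settings: ModelSettings) -> float:
    """Fraction escaping hepatic first-pass extraction, F_h = 1 - Cl_b/Q_h.

    ``cl_per_kg`` is plasma clearance in mL min^-1 kg^-1, assumed equal to
    blood clearance; Q_h is whole-body hepatic blood flow in mL min^-1.
    Raises if whole-body clearance reaches liver blood flow (F_h <= 0 has no
    meaning in this model).
    """
    cl_total = cl_per_kg * settings.body_weight  # mL min^-1
    if cl_total >= settings.q_h:
        raise ValueError(
            f"whole-body clearance {cl_total:.6g} mL/min >= hepatic blood flow "
            f"{settings.q_h:.6g} mL/min; F_h would be <= 0"
        )
    return 1.0 - cl_total / settings.q_h


def absorption_params(compound: Compound, settings: ModelSettings) -> AbsorptionParams:
    """All derived absorption inputs for one compound under one protocol."""
    sol65 = solubility_at_ph65(compound)
    # M * g/mol * L -> g; * 1000 -> mg
    saturated_amount = sol65 * compound.mol_weight * settings.v_intestinal * 1000.0
    p_eff = peff_human(compound)
    return AbsorptionParams(
        solubility_ph65=sol65,
        saturated_amount=saturated_amount,
        p_eff_human_ph65=p_eff,
        k1=k1_from_peff(p_eff, settings),
        f_h=fraction_escaping_first_pass(compound.cl_per_kg, settings),
    )
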