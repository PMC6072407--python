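# oraldose

Oral drug suitability parameters from a minimal pharmacokinetic model.

`oraldose` simulates repeat oral dosing of a compound through a
three-compartment pharmacokinetic (PK) model and distils each steady-state
exposure quantity into two compound-specific parameters that make very
different molecules comparable on one scale:

* **DQI** (dose–quantity intercept) — the intercept of the slope-1
  regression through the linear-PK region of the log₁₀(dose) vs
  log₁₀(quantity) curve, so that `quantity = dose · 10^DQI` while PK is
  linear. It summarises how much steady-state exposure a unit dose buys
  (absorption, distribution and elimination folded into one power term).
* **HLD** (highest linear dose) — the log₁₀(dose) at which that slope-1
  line reaches the curve's maximum quantity,
  `HLD = log₁₀(max_quantity) − DQI`. It approximates the largest dose that
  still behaves linearly before solubility-limited absorption caps
  exposure.

The intended audience is discovery scientists ranking design-stage
compounds from a handful of measured or QSAR-predicted inputs: charge type
and pKa, aqueous solubility at pH 7.4, apparent Caco2 permeability (A→B,
pH 6.5), human V_ss and plasma clearance, optional plasma protein binding,
and molecular weight.

## The model

A dose enters a fixed 0.08 L cylindrical "slug" of intestinal fluid
(compartment A, pH 6.5) after a 1 h gastric lag. Dissolution is
instantaneous but only dissolved drug transfers (one way, rate constant
k₁) to the central compartment; while the dose exceeds the amount that
saturates the fluid, transfer is zero order at `k₁ · saturated_amount`,
then first order. Absorption stops 4 h later and the remainder is
discarded. The absorbed flux is scaled by the hepatic first-pass fraction
`F_h = 1 − Cl_b/Q_h` and enters a standard two-compartment disposition
model (central B, peripheral C; rates k₂, k₃, elimination k₄):

```
dB/dt = F_h·input(t) + k₃·C − (k₂ + k₄)·B
dC/dt = k₂·B − k₃·C
```

Fourteen twice-daily doses are superposed (the system is linear) and
C_ss,max / C_ss,avg / C_ss,min / AUC_ss are read off the final dosing
interval for central and peripheral compartments, at total and free
levels. Supporting steps:

* Henderson–Hasselbalch ionization; pH 6.5 solubility from the pH 7.4
  value via the fraction-neutral ratio.
* Human effective jejunal permeability from Caco2 via the neutral-species
  log–log calibration
  `log₁₀ P_human = 0.916·log₁₀ P_Caco2 + 1.579`, then
  `k₁ = (2·amplification/r)·P_eff·60` for the cylindrical segment
  (r = 1.25 cm, fold amplification 2).
* Micro rate constants from (V_central, V_ss, V_terminal, Cl) via the
  standard two-compartment relations (`k₄ = Cl/V_central`,
  `β = Cl/V_terminal`, `V_ss = V_central(1 + k₂/k₃)`).

Because distribution kinetics are unknown at the design stage, every fit
runs five (V_central, V_terminal) hypotheses spanning plasma volume to
half of V_ss and 1.1–2.0 × V_ss. Input uncertainty is propagated by 50
extra scenarios with V_ss and Cl drawn from log₁₀-Gaussians (SD 0.3).
Each (HLD, DQI) pair is a vertex in the DQI–HLD plane; the resulting
5- or 255-vertex polygon is summarised by its area, centroid and second
moments of area.

## Worked example

```python
from oraldose import DoseQuantityModel, load_reference_compounds

compounds = {c.name: c for c in load_reference_compounds()}
result = DoseQuantityModel(compounds["Diazepam"]).fit(
    quantity="css_central_max", level="total"
)
print(result.summary())
```

```
Dose-quantity suitability fit
==============================================
compound:            Diazepam (neutral)
quantity:            css_central_max [total]
distribution scenarios: 5; input-data scenarios: 1
polygon vertices:    5
----------------------------------------------
centroid HLD:            2.545  log10(mg)
centroid DQI:           -0.761  log10(quantity)/dose
log10 max quantity:      1.784  (HLD + DQI)
polygon area:            0.072  (log10 units)^2
second moment (HLD axis):     0.044
second moment (DQI axis):     0.470
----------------------------------------------
per-scenario spread:
  HLD range: [2.265, 2.891]
  DQI range: [-1.199, -0.491]
```

Reading this: across the five distribution hypotheses a 1 mg diazepam
dose yields a steady-state total C_max of about
`10^-0.761 ≈ 0.17 mg L⁻¹` (`result.predict(1.0)` → 0.173), exposure stays
dose-proportional up to roughly `10^2.5 ≈ 350 mg`, and the largest
attainable C_max is about `10^1.78 ≈ 61 mg L⁻¹`
(`result.predict(1000.0)` → 60.8, capped). The small polygon area says
the estimate is robust to the distribution-kinetics assumption.

Adding `errors=True` (and a `seed`) propagates the V_ss/Cl input-error
ensemble, growing the polygon to 255 vertices.

The same pipeline is scriptable from the shell:

```bash
oraldose-dqi summary --errors on --seed 17 --out polygon_summary.csv
oraldose-dqi sweep --name Diazepam --out curves.csv
oraldose-dqi plot --errors on --seed 17 --out polygons.png
```

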