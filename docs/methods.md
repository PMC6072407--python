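# Methods

This note records the model, the defaults, the numerical choices and the
limitations behind `oraldose`, in the spirit of a statistical package's
methods appendix. Nothing here states an empirical result that the
test-suite or `scripts/acceptance.py` does not itself compute.

## Model structure

The simulation couples solubility-limited oral absorption to linear
two-compartment disposition.

**Compartment A (intestinal fluid).** A fixed 0.08 L volume at pH 6.5
representing a cylindrical slug of intestinal contents (radius 1.25 cm;
the cylinder length cancels out of every formula). The dose arrives as an
instantaneously mixed solid bolus after the gastric lag. Only dissolved
compound is transferable; dissolution itself is instantaneous, so the
dissolved amount is `min(A, saturated_amount)` with
`saturated_amount = solubility_pH6.5 · MW · V_intestinal · 1000` (mg).
While `A > saturated_amount` the transfer to the central compartment is
zero order at `k₁·saturated_amount`; once A falls to the saturation limit
it is first order at `k₁·A`. Absorption is confined to a window
(default 4 h) after the lag (default 1 h); at the window's end the
remaining contents are discarded — this time limit is what creates the
dose–exposure nonlinearity that defines the HLD.

**Compartments B and C.** Standard two-compartment disposition with
first-order exchange (k₂, k₃) and elimination from B only (k₄). The
absorbed flux is multiplied by the hepatic first-pass fraction
`F_h = 1 − Cl_b/Q_h` on its way into B (the conventional insertion point
for an orally absorbed, hepatically cleared drug with no gut-wall
metabolism); blood and plasma concentrations are assumed equal, so plasma
clearance stands in for blood clearance. F_h ≤ 0 (whole-body clearance at
or above liver blood flow) is treated as a hard input error rather than
clamped.

**Repeat dosing.** Doses are identical and the system is linear, so the
multi-dose trace is the superposition of shifted single-dose solutions.
Steady state is assumed reached by the final dosing interval of the
14-dose, 12-hourly, 168 h protocol. This is an approximation for the
slowest compound/scenario combinations: the test-suite compares the
final-interval trough and AUC against a 28-dose run and finds them
within ~15% in the worst case (diazepam under the V_terminal = 2·V_ss
scenario, terminal half-life ≈ 2.5 days) and essentially converged for
the rest.

## Analytic solution and its oracle

Each absorption phase has constant or single-exponential input into a
linear 2×2 system, so the trace is evaluated in closed form per phase:
modal decomposition in the disposition roots α, β
(`α+β = k₂+k₃+k₄`, `α·β = k₃·k₄`) plus a particular term
`w·e^{−g·t}` with `w ∝ 1/((g−α)(g−β))`. The measure-zero resonance
`k₁ ∈ {α, β}` is handled by a 1e-9 relative nudge of k₁. The test-suite
integrates the same piecewise ODE system independently with LSODA at
rtol 1e-11 and checks agreement to 1e-6 relative across unsaturated,
partially saturated and fully saturated regimes, plus a quadrature-based
mass balance (eliminated + remaining = absorbed, 1e-6 relative).

## Default protocol constants

| constant | default | units | note |
|---|---|---|---|
| V_intestinal | 0.08 | L | intestinal fluid volume |
| intestinal radius | 1.25 | cm | cylinder SA/V = 2/r |
| absorption amplification | 2 | – | intestinal folds; k₁ = 192·P_eff min⁻¹ at defaults |
| gastric lag | 60 | min | dose → start of absorption |
| absorption window | 240 | min | absorption duration; remainder discarded |
| dose interval / n doses | 720 / 14 | min / – | twice daily, 168 h; sim length defaults to their product |
| body weight | 70 | kg | scales V_ss and Cl |
| Q_h | 1450 | mL min⁻¹ | liver blood flow |
| dose grid | 20 doses, 1 ng – 10 g | mg | fixed sweep |
| grid step / random points | 15 / 336 | min / – | ≈ 1000 evaluation times |
| slope tolerance | 1e-4 | – | linear-region test |
| error SD | 0.3 | log₁₀ | V_ss and Cl input errors |
| error scenarios | 50 | – | plus the original |

## Time grid and quantity extraction

Evaluation times are the union of the 15 min lattice over the full
simulation, 336 seeded uniform-random times, and the structural times of
every dose event (administration, absorption start/end, and the
saturation-switch time when the dose saturates the fluid). C_max and
C_min are the extrema over evaluated grid points in the final interval —
deliberately *not* an analytic peak solve, matching the time-point
protocol. For smooth concentration profiles the sampling error is
negligible, but scenarios that combine a small central volume with fast
elimination produce post-dose peaks only minutes wide, and there the
grid-sampled C_max can sit well below the analytic peak and depends on
where the random points happen to fall — a property shared with the
protocol being emulated, and one reason C_max-based parameters are the
noisiest of the quantity set. AUC uses composite Simpson's rule on the uniform 15 min sub-grid
of the final interval (48 intervals; refined to an even count if a
non-default protocol makes it odd). Average concentration is
AUC/interval. Peripheral concentrations divide the compartment-C amount
by `V_ss − V_central` (the model names no peripheral volume; this is the
consistent apparent choice). Free levels multiply totals by the fraction
unbound and are simply absent when protein binding is unknown.

## Distribution-kinetics scenarios

Five (V_central, V_terminal) hypotheses per compound: V_central ∈
{3.0 L, 0.5·V_ss, midpoint}; V_terminal/V_ss ∈ {1.1, 2.0, midpoint}
paired as (i) 3.0/1.1, (ii) 0.5·V_ss/1.1, (iii) 3.0/2.0,
(iv) 0.5·V_ss/2.0, (v) midpoints. V_terminal is interpreted as the
terminal-phase ("area") volume Cl/β, which yields the closed form
`k₃ = (k₄ − β)/(V_terminal/V_central − V_ss/V_central)`,
`k₂ = (V_ss/V_central − 1)·k₃`. Any scenario with
V_central ≥ V_ss is rejected by name (degenerate model). The derived
constants always satisfy the interlacing α > k₃ > β and reproduce the
input volumes and clearance to 1e-10 relative (property-tested).

## DQI / HLD estimation

The 20-dose sweep gives a log–log dose–quantity curve per quantity. The
estimator grows a prefix from the lowest dose and keeps the longest
prefix whose OLS slope is within 1e-4 of 1; the DQI is that fit's
intercept. Below the saturated amount the model is exactly linear, so in
practice the prefix is the unsaturated dose range and the measured
log-log slope is 1 to machine precision. The maximum quantity is the
highest-dose value (equal to the plateau when the top two doses agree
within 1e-3 log units, which is the plateau flag); the HLD extrapolates
the slope-1 line — slope exactly 1, not the fitted slope, so that
1e-5-level slope noise is not amplified across several decades — giving
the identity `log₁₀(max) = HLD + DQI` by construction. An alternative
estimator fits the smooth saturation form
`log₁₀ q = log₁₀ q_max − log₁₀(1 + 10^{HLD − log₁₀ d})` by nonlinear
least squares (stable via logaddexp; falls back to the regression values
on non-convergence). Ranking helpers cap predicted quantities at
`10^{HLD+DQI}` above the HLD.

## Input-error ensemble

Each error scenario independently replaces V_ss and Cl by
`10^{N(log₁₀(original), 0.3)}` draws; scenario 0 is the original, so a
compound yields 51 × 5 = 255 (HLD, DQI) vertices. Draws that would make
the model degenerate are redrawn and logged: a clearance at or above
Q_h/body-weight (F_h ≤ 0), or a V_ss at or below the 3.0 L plasma-volume
scenario. For most compounds redraws are rare; for chlorpromazine
(Cl = 16 against a ceiling of ≈ 20.7 mL min⁻¹ kg⁻¹) roughly a third of
clearance draws are redrawn, effectively truncating its error
distribution from above — an unavoidable consequence of keeping every
scenario physically meaningful while holding the scenario count at 50.

## Polygon analytics

Vertices are ordered by angle about their arithmetic mean, which yields
a deterministic, star-shaped (hence non-self-intersecting) polygon
through every vertex; a convex-hull ordering is available as an option
(it encloses the cloud but drops interior vertices, and is the larger of
the two areas). Area and centroid use the shoelace and polygon-centroid
formulas; degenerate (collinear/coincident) clouds get area 0 and the
vertex mean as centroid. Two second-moment conventions are computed:
`second_moment_hld`/`second_moment_dqi` are the moments of area about
the HLD (x) and DQI (y) coordinate axes (∫y²dA and ∫x²dA) — the
convention the summary table reports, whose magnitudes are dominated by
the centroid offset for polygons far from the origin — and
`centroidal_second_moment_*` about centroid-parallel axes, which are
translation invariant and measure pure dispersion. The angular-ordering
choice affects area noticeably for irregular 255-vertex clouds but the
centroid only weakly (the polygon centroid stays within 0.05 log units
of the plain vertex mean for the reference compounds' 5-vertex clouds,
and both are reported). For heavy-tailed 255-vertex clouds —
chlorpromazine's especially, whose truncated clearance draws skew the
low-F_h tail — the area-weighted centroid inherits noticeable
seed-to-seed noise (up to a few tenths of a log unit between arbitrary
seeds) because boundary spikes carry disproportionate signed area; the
vertex mean is the stable alternative summary and is exposed alongside
it.

## Reproducibility and problem sizes

All randomness (grid points, error draws) flows through seeded NumPy
generators; the same seed reproduces a run bit for bit. A full
15-compound × 51 error-scenario × 5 distribution-scenario × 20-dose run
is 76,500 protocol simulations and completes in about a minute on one
CPU, because each simulation is a closed-form evaluation at ~1000 time
points rather than an ODE solve. The acceptance script's four-compound
ensemble benchmark is ~20,400 simulations (≈ 17 s).

## Known limitations

* **Permeability scaling sets the absolute level.** The Caco2→human step
  implemented here is the explicit published pathway: apparent Caco2
  permeability → neutral-species membrane permeability (divide by
  fraction neutral at pH 6.5) → human neutral-species membrane
  permeability (the 0.916/1.579 log–log calibration) → effective
  permeability (multiply back). No aqueous-boundary-layer or
  paracellular correction is applied. The resulting effective
  permeabilities for highly permeable compounds (up to ~5×10⁻³ cm s⁻¹)
  exceed measured human jejunal values (≲ 1×10⁻³ cm s⁻¹), so k₁ — and
  with it saturated plateaus, HLDs and high-clearance DQIs — is at the
  optimistic end of the convention space. Relative comparisons between
  compounds, which are the intended use, are far less sensitive to this
  choice than absolute values; reproductions of published absolute
  centroid coordinates are faithful for low-permeability-sensitivity
  quantities and systematically offset (up to ~1 log unit in HLD+DQI)
  where k₁ dominates.
* The model ignores gut-wall metabolism, transporters, enterohepatic
  recycling, stomach-emptying variability and dissolution-rate kinetics;
  solubilities are room-temperature values.
* Ionization handles single-pKa acids and bases only; zwitterions and
  multiprotic compounds are rejected explicitly.
* C_max is grid-sampled, so sharp peaks (small V_central with fast
  elimination) are measured slightly low; the effect is shared by design
  with the time-point protocol rather than corrected.
* The V_ss/Cl error model is independent and lognormal; no correlation
  structure, and no errors on pKa, solubility or permeability.
* The packaged reference table's molecular weights are standard
  monograph free acid/base values added for the molar→mg conversion; the
  other columns are the published measured inputs.
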