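# Methods

## Problem setting and model assumptions

A recirculating hydroponic installation holds a mixing tank of volume
`V_current` (L) whose ion concentrations drift as the crop takes up
nutrients and water. At each replenishment the controller must bring
the tank to a target volume `V_target` and target concentrations `T_x`
(mg/L) for the major ions, using seven single-salt stock solutions, a
micronutrient concentrate and water, dosed by metering pumps.

The engine works purely on mass balance. It assumes:

- **Perfect, instantaneous mixing.** Injected masses distribute
  uniformly before the next measurement.
- **No precipitation, complexation or pH/temperature speciation.**
  All dissolved salt mass stays available as its nominal ions. This is
  a deliberate idealisation of a well-controlled greenhouse system.
- **No ion removal.** Pumps only add; demands that come out negative
  (ion above target) are clamped to zero and the surplus is left to be
  diluted by future volume growth.
- **Sulfate is unconstrained.** SO4 is harmless to the crop at the
  relevant levels and no demand is tracked for it, which is what makes
  K2SO4 a "free" potassium sink.
- **No crop dynamics.** Plant uptake and evapotranspiration between
  steps are not modelled; the harness isolates dosing-algorithm error
  from biological variability.

## Mass balance

For the electrode-measured ions x ∈ {Ca, K, NO3}:

    N_x = T_x · V_target − D_x · V_current − W_x · (V_target − V_current)

with `D_x` the electrode reading and `W_x` the make-up-water content.
Ammonium has no robust electrode; its demand is pegged to the *signed*
nitrate demand, `N_NH4 = R_NN · N_NO3 − W_NH4 · ΔV`, so an
over-supplied nitrate pool implies no ammonium demand. Magnesium and
phosphate are computed either from laboratory concentrations
("measured" mode) or pegged to calcium and nitrate ("ratio" mode,
the default):

    N_Mg = R_CaMg · N_Ca − W_Mg · ΔV        N_P = R_NP · N_NO3 − W_P · ΔV

Phosphorus is tracked throughout as the H2PO4 ion (the species the
salts actually dissolve into); converters to elemental P exist for
recipes and emission factors written that way.

**Uptake-ratio defaults.** The shipped ratios are the ion-mass ratios
of a modified Hoagland solution for leafy vegetables (NH4 18, Mg 24.3,
H2PO4 97 mg/L against NO3 434 and Ca 80 mg/L): R_NN = 18/434 ≈ 0.0415,
R_CaMg = 24.3/80 ≈ 0.304, R_NP = 97/434 ≈ 0.224. They are plain
configuration: any installation with its own recipe should set its own
ratios.

## Decision-tree allocation

Ion priority: **Ca > H2PO4 = K > NO3 > NH4**. Magnesium is handled by
an independent single-node tree (MgSO4·7H2O is its only source and its
sulfate is untracked). The main tree walks the remaining six salts in
a fixed order, keeping a running ledger of remaining demand:

| order | salt | driver ion | check ion |
|---|---|---|---|
| 1 | Ca(NO3)2·4H2O | Ca | — (NO3 coupling unavoidable) |
| 2 | NH4H2PO4 | NH4 | H2PO4 |
| 3 | KH2PO4 | remaining H2PO4 | K |
| 4 | KNO3 | remaining K | NO3 |
| 5 | NH4NO3 | remaining NO3 | NH4 |
| 6 | K2SO4 | remaining K | — (SO4 unconstrained) |

Each node computes a candidate mass from its driver's remaining demand
("final 1"); if that candidate would overshoot the check ion, the mass
is recomputed from the check ion's remaining demand and supersedes the
candidate ("final 2"). A driver demand at or below the 1e-9 mg epsilon
takes the no-injection branch. Every traversal is recorded in a trace
(salt, driver, candidate, check, chosen, leaf) for audit.

This ordering is the unique simple sequence consistent with the
priority chain and the allocation patterns of the packaged five-step
benchmark: potassium routes through KNO3 before K2SO4 so that K
preferentially carries needed nitrate, K2SO4 is the terminal K sink,
and ammonium nitrate only mops up nitrate left after KNO3.

Two consequences are intrinsic, not bugs:

- **Nitrate may overshoot** exactly by what the calcium salt carries;
  every other ion is never overshot (the package's overdose auditor
  flags anything else above 1e-6 mg).
- **Low-priority shortfall is accepted.** When KNO3's nitrate check
  binds, the ammonium demand is left unmet rather than re-splitting
  nitrate between KNO3 and NH4NO3; the benchmark's fifth step shows
  the same behaviour. Likewise, because NH4 is the carrier ion of
  NH4H2PO4, a *smaller* ammonium demand can reduce deliverable
  phosphate when potassium is also scarce. The test-suite oracle
  therefore ranks allocations by shortfalls of Ca, then P+K, then NO3
  (in priority order), then uncoupled overdose, then total salt mass,
  with no-uncoupled-overdose as a hard feasibility constraint.

## Simplex baseline

The conventional method solves the equality system `A·m = b` (rows:
Ca, H2PO4, K, NO3, NH4; columns: the six non-Mg salts; entries: ion
mass fractions). With six unknowns and five equations the system is
closed by minimising `‖m‖₁` with the masses unbounded below, solved as
a linear program by free-variable splitting (scipy/HiGHS). The signed
"complete" solution delivers every demand exactly; pumps then clip
negative components to zero in a single pass (no re-solve), which
over-delivers the ions the negative salts would have withdrawn. An
infeasible system (impossible with this full-rank matrix, but guarded)
falls back to least squares and is flagged.

## Actuation

Runtime per salt: `P_x = M_x / (C_x · D_x)` with stock concentration
`C_x` = 20,000 mg/L and pump discharge `D_x` (default 1 mL/s).
Micronutrients have no sensors and are replenished in proportion to the
volume deficit: a concentrate at `C_m` = 200× working strength
contributes `V_m = (V_target − V_current)/C_m`. (A multiplicative form
of this rule is dimensionally inconsistent for a 200× concentrate — it
would inject 200·ΔV — and the division form reproduces the benchmark's
fourth-step 37.4 mL from 22.52 → 30 L exactly, so division is what the
package implements.) Water closes the volume budget,
`V_w = ΔV − ΣV_stock − V_m`, floored at zero with a warning rather
than an error so closed-loop operation degrades gracefully. Runtime
quantization snaps to the pump time step (default 0.1 s) and reports
the relative dosing error, bounded by `step/(2·runtime)`; with the
default stocks and pumps, doses above ~1 g stay below the 0.1% design
error.

## Sensing model

Electrode EMF follows `E = E0 + S·log10(c)`. Two-point normalization
against mixed standards (NO3 100/1000, K 30/300, Ca 24/240 mg/L; a
26/260 Ca pair is accepted wherever standards are passed explicitly)
recovers (E0, S) exactly, so measurement error is modelled as Gaussian
noise in concentration space, clipped at zero, with per-ion standard
deviations set to this electrode family's observed accuracies
(29.5 / 10.1 / 6.1 mg/L for NO3 / K / Ca) and replicate arrays of
3 / 3 / 2 electrodes whose readings are averaged. Noise in
concentration rather than EMF space is a modelling choice: accuracy
specifications for these arrays are stated as concentration RMSE, which
makes the concentration-space parameterisation the directly
configurable one. Drift, aging and cross-ion selectivity are not
modelled. The level sensor is read without noise.

## Closed-loop harness

`run_stepwise` executes measure → demand → dose → mix per scheduled
step. Scheduled mode doses at every step (the benchmark protocol);
triggered mode doses only when a reading falls below the lower limits
(defaults: 20% below target concentration, 10% below target volume).
Mixing conserves per-ion mass to 1e-9 relative and volume exactly; the
stock solutions' carrier water contributes volume but no tracked ions.

Under exact sensing the harness converges to within 0.1% of target for
the measured ions in one replenishment *when the demand structure is
conflict-free* (calcium's coupled nitrate below the nitrate demand,
potassium generous enough for KNO3 to carry the nitrate remainder).
On the packaged five-step schedule this is not the case everywhere by
construction — e.g. the first step raises volume at constant Ca while
lowering NO3, so the coupled nitrate necessarily overshoots — and
leftover surpluses persist until diluted; the harness reproduces
exactly this behaviour. What passing simulator tests show is that the
*algorithmic* error behaves as designed; they say nothing about
electrode drift, mixing inhomogeneity or crop uptake in a real system.

## Synthetic data

`generate_random_state` scatters a recipe's concentrations uniformly
within ±deviation% (default use: 20%, matching the band the stepwise
benchmark explores with its 80/100/120% target levels). The test
suite's random requirement vectors span 0–2.5 g per ion (nitrate to
8 g) with 30% head-room for negative (over-target) demands — the
magnitudes a 10–40 L tank produces. These fixtures exercise coupling
and clamping logic; they do not emulate temporal correlation of real
uptake.

## Numerical choices

- Atomic weights: IUPAC standard values to ≥4 decimals; benchmark
  percentages are sensitive at the 0.1% level.
- Decision epsilon: 1e-9 mg of remaining demand; exact zeros take the
  no-injection branch.
- Overdose audit tolerance: 1e-6 mg.
- LP: HiGHS via `scipy.optimize.linprog`; equality feasibility is
  full-rank so the fallback path is defensive only.
- Problem sizes: property sweeps use 1000 random requirement vectors;
  the grid oracle enumerates ≤ 3·10⁵ dose combinations per instance
  (41 points per active salt axis for sparse instances); sensing
  Monte-Carlo uses 200 draws × 5 levels per ion and 1500-draw replicate
  comparisons. The full suite runs in well under a minute.

## Known limitations

- No solubility limits, activity corrections or pH coupling; recipes
  far outside horticultural ranges may be chemically unrealistic even
  though the arithmetic is exact.
- The simplex baseline's objective (minimum ‖m‖₁) is one defensible
  closure of an underdetermined historical method; other closures give
  the same delivered ions but different signed splits.
- Emission factors are single-point production averages (g CO2eq/g of
  elemental N, P, K); no full life-cycle assessment.
- The five-step benchmark's per-step electrode readings are not part
  of the packaged data, so per-step doses are not independently
  recomputable — only the aggregate comparisons are.
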