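# Methods

## Model

Two coupled ODEs describe membrane-bound E-cadherin `E` and the transcription
factor Slug `S` in a single cell (concentrations in ng/mL, time in minutes):

```
dE/dt = α₁ / (1 + (S/IC_S)ⁿ¹) + k₀·H(C/IC_C; n₂) − β₁·E
dS/dt = α₂ − k₁·H(E/IC_E; n₃) + k₂·H(T/IC_T; n₄) − β₂·S
```

`H(x; n) = xⁿ/(1+xⁿ)` is a saturating Hill factor, defined as 0 at `x = 0`
(no 0/0 ambiguity, since every coefficient is ≥ 1) and evaluated as
`1/(1+x⁻ⁿ)` above `x = 1` so it saturates to 1 without overflow. Slug
represses E-cadherin production; membrane E-cadherin represses Slug
(mechanistically via β-catenin sequestration); contact `C` recruits
E-cadherin to the membrane; TGF-β `T` activates Slug. The mutual repression
makes the system a bistable switch with an epithelial (high-E/low-S) and a
mesenchymal (low-E/high-S) state.

Baseline parameter values, the fixed Hill coefficients (3, 4, 2, 3), the
±10% sampling ranges, the treatment levels (C ∈ {0, 1, 2, 6} cells ×
T ∈ {0, 3.64×10⁻⁶} ng/mL) and the per-contact initial conditions ship as
packaged config (`data/defaults.yaml`); they are the published design of the
study this package reimplements, kept verbatim. Two dimensional ranges (α₂,
k₁) — and correspondingly A₂ and K₁ in every nondimensional set — are
shifted off-center with their 20%-of-center width preserved; the shifts are
stored as data because no formula generates them. They exist to keep the
one-at-a-time sweeps monotone and the states nonnegative (see Diagnostics).

## Nondimensionalization

States are rescaled by the half-maximal constants (`E = IC_E·e`,
`S = IC_S·s`), inputs likewise (`C = IC_C·μ`, `T = IC_T·θ`), and time by a
characteristic scale γ (`t = γ·τ`). Seven natural choices of γ exist — one
per rate grouping — giving seven dimensionless models that share the form

```
de/dτ = A₁/(1+sⁿ¹) + K₀·H(μ; n₂) − B₁·e
ds/dτ = A₂ − K₁·H(e; n₃) + K₂·H(θ; n₄) − B₂·s
```

with `A₁ = α₁γ/IC_E`, `K₀ = k₀γ/IC_E`, `B₁ = β₁γ`, `A₂ = α₂γ/IC_S`,
`K₁ = k₁γ/IC_S`, `K₂ = k₂γ/IC_S`, `B₂ = β₂γ`. The grouping matching γ
cancels to exactly 1 and is never sampled. Grouped values are always
regenerated from the dimensional baseline, not hard-coded; the packaged
range tables store the published values verbatim and a consistency check
regenerates them from centers rounded to the 3 decimals at which they were
published. Exactly one cell fails that check: the published Set 1 K₀ value
0.646 is inconsistent with its own definition (k₀/α₁ = 0.6432, whose
reciprocal 1.555 the Set 2 table does print); the package reports the
computed value and samples the published range.

Because time rescaling never moves fixed points, all seven sets share their
equilibria and fold locations exactly (after input rescaling); the suite
verifies this, and it is why treatment levels μ ∈ {0, 0.46, 0.92, 2.76} (the
published roundings of C/IC_C) and one shared set of rescaled initial
conditions serve all seven sets.

The composition of each grouping is derived symbolically (sympy) rather than
hand-coded: the comparison report uses the free symbols of the simplified
grouping formulas to decide which dimensional parameters are visible to a
nondimensional analysis at all. `IC_C` and `IC_T` appear in no grouping of
any set — they rescale the inputs themselves — so their influence is
structurally invisible after nondimensionalization.

## Dynamics and readout

Integration uses LSODA (`scipy.integrate.odeint`) with the analytic
Jacobian, rtol 10⁻¹⁰ and atol 10⁻¹²: dimensional states reach 10⁻⁴ ng/mL,
and looser tolerances corrupt the 4-decimal output rounding. The readout
rule is strictly "state at t = 10000" (minutes or τ-units), with no early
exit; a `converged` flag records whether max |rhs| < 10⁻⁹ at readout, and a
geometric sampling of the trajectory flags any negative excursion. Readouts
are rounded to the frame's grain — 10⁻⁴ dimensional, 10⁻² nondimensional —
with halves away from zero.

Equilibria come from reducing the nullcline system to one scalar equation:
at equilibrium `E = [α₁/(1+(S/IC_S)ⁿ¹) + k₀·H_C]/β₁`, substituted into the
S-equation to give a residual g(S). All roots are bracketed on a 2000-point
grid over `S ∈ [0, 2(α₂+k₂)/β₂]` — an upper bound no steady state can exceed
— and polished with Brent's method; stability follows from the
trace/determinant of the analytic 2×2 Jacobian.

## Bifurcation analysis

Folds are found by bisection on the equilibrium count inside a bracketing
interval (600-point sweeps by default), followed by a tangency polish: at a
saddle-node the reduced residual and its derivative vanish together, so the
double root of (g, g′) in (S, control) is solved directly with analytic g′.
The polish matters: counting sign changes on a finite S-grid misses merging
roots closer than the grid spacing, which biases pure count-bisection by
~10⁻⁵ in the control. A two-state model does not need pseudo-arclength
continuation; count-bisection plus tangency is simpler and exact at the
fold. Classification over an admissible interval (C ∈ [0, 6] cells,
T ∈ [0, 3.64×10⁻⁶] ng/mL): two interior folds = reversible switch, one =
irreversible (the return fold would need an inadmissible input), none = no
switch.

Two deviations from the published anchor values, both established with
independent cross-checks (direct long-horizon simulation bracketing and a
raw 2-D Newton solve, agreeing with the tangency solve):

- `L_M` computes to C = 0.95314, within one unit in the 4th decimal of the
  published 0.9532 but rounding to 0.9531. The residual dip near this fold
  is ~10⁻⁷ deep, so a continuation tool at default resolution plausibly
  overshoots by the observed 6×10⁻⁵. `L_E` = 2.00901 matches exactly.
- The TGF-β threshold at C = 1 computes to 4.9146×10⁻⁷, 2.2% below the
  published ≈5.0224×10⁻⁷, while the C = 2 threshold (1.87570×10⁻⁶) and the
  switch-point states at both contact levels match the published values to
  all printed digits. The published C = 1 threshold appears inconsistent
  with the published parameter values themselves.

## Sampling

Latin hypercube: each varied parameter's range is split into N equal strata,
one point drawn uniformly inside each (or at the midpoint in deterministic
mode), and the stratum order permuted per column. The design-size rule
N > (4/3)K is enforced strictly (K = 11 needs N ≥ 15, K = 6 needs N ≥ 9).
Each column's random stream derives from the global seed keyed by the
parameter *name* (CRC-32 → SeedSequence), with two consequences: adding or
removing a column never perturbs the others, and the same seed yields the
same unit-interval draws for a name in every frame. The full study exploits
the latter — cross-frame grid differences are then not confounded by
sampling noise. A fully independent per-frame design is available
(`shared_design=False`). One design per frame serves all 8 treatment groups.

## PRCC

Both the parameter column and the output are rank-transformed (midranks for
ties — the output rounding makes ties routine, by design), each is regressed
on all remaining rank columns plus an intercept, and the coefficient is the
Pearson correlation of the two residual vectors. This equals the classical
inverse-correlation-matrix partial correlation (the suite checks agreement
to 10⁻¹⁰ against that oracle and against an independent library
implementation) but is numerically stabler with heavily tied ranks.
Significance is a hard cutoff |ρ| ≥ 0.5, configurable; no p-values or
multiplicity correction, matching the study design. Validity gates:

- inter-parameter screen: pairwise PRCC among the sampled columns
  (controlling the other K−2) must stay below 0.5 — on the stratified
  designs used here the maximum is ~0.03 at N = 10000;
- monotonicity: every output must be monotone in every parameter varied
  alone. The scan evaluates rounded readouts on an even grid over each range
  (default 50 points; pass criterion is nonstrict monotonicity of the
  rounded sequence, since rounding produces plateaus). With the published
  (shifted) ranges, all sweeps in all 8 frames × 8 groups are monotone. The
  scan's negative-value diagnostic still flags slightly negative Slug steady
  states (≈ −0.005) at the extreme ends of the shifted A₂/K₁ ranges at
  (μ = 2.76, θ = 0) in five of the seven sets — a property of the published
  ranges, not a solver artifact; monotonicity is unaffected.

## Study sizes and stability

The published design is N = 10000 per frame. The test suite runs the full
eight-frame study at N = 1000: with stratified sampling the coefficients at
N = 1000 sit within a few hundredths of their N = 10000 values, and the
significance grid is identical between the two sizes except for calls within
a few hundredths of the 0.5 cutoff (observed: k₀ at 0.51 vs 0.42 in one
cell, β₁/IC_E at 0.50/0.51 in another). The acceptance script uses N = 1000
for the integration-backed target and N = 10000 for the design-only
inter-parameter screen.

## Known limitations

- The significance grids reproduce every qualitative published finding (the
  published parameter pairs are always the top coefficients in the matching
  cell; the formulation-dependence of nondimensional E-cadherin appears at
  exactly (μ ∈ {0.46, 0.92}, θ = 0); Slug's contact-driven shift from
  degradation to membrane suppression appears in every frame), but in the
  bistable and strongly coupled conditions this pipeline assigns secondary
  parameters coefficients of 0.5–0.77 where the original analysis evidently
  placed them below 0.5 — e.g. E at (C=1, T=0) here depends on {IC_C, α₂,
  β₁}, not {IC_C} alone. The pattern (all original calls equal to our
  top coefficients) suggests a roughly uniform attenuation in the original
  coefficients whose mechanism is not documented; no described variant of
  the procedure (rounding grain, readout time, tie handling, sample size)
  reproduces it. The affected checks are kept asserting the published sets
  and fail honestly.
- Outputs are single-cell steady states under constant inputs; no
  spatial coupling, stochasticity, delays or event detection.
- Only uniform marginals are sampled; grouped nondimensional parameters are
  ratios of uniforms and would have non-uniform induced distributions if
  sampled consistently with the dimensional model — deliberately out of
  scope, as in the study.
- Two-parameter (C, T) bifurcation surfaces are not computed.
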