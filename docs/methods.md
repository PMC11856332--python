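# Methods

## Model structure

The model couples two fixed host strategies — residents and migrants — to
a three-strain SIRS epidemic. Hosts never switch strategy; the two groups
interact through shared-season transmission and through the global density
dependence on births. Ten state variables track the compartments
(Sr, Ir1–Ir3, Rr, Sm, Im1–Im3, Rm) as continuous, non-negative densities;
there is no demographic stochasticity anywhere, so every simulation is
exactly reproducible.

A simulated year has length 1 and is split into two smooth seasonal flows
joined by instantaneous events, executed in a fixed order:

1. **Shared season** (duration T1): both groups occupy Habitat 1.
   Susceptibles of either group are infected by the pooled infecteds
   (Iri + Imi) of each strain; recovery runs at ν1 for everyone; births
   occur only now, each group reproducing into its own susceptible class
   at rate b (b + σ for infected parents, σ = −0.02 so infection carries a
   small fecundity cost), throttled by (1 − γN) with N the total
   population of both groups.
2. **Migration pulse**: Sm, Imi, Rm are multiplied by (1 − δS), (1 − δI),
   (1 − δR). Residents are untouched.
3. **Separate season** (duration T2): transmission is within-group only,
   no births; migrants recover at the elevated Habitat 2 rate ν2 while
   residents stay at ν1.
4. **Migration pulse** again (the return trip).

Migration itself is instantaneous: there are no in-transit infection
dynamics, and the only in-transit effect is the mortality pulse.

## The transmission–virulence trade-off

Strain i buys transmission with virulence through
β(α) = cA·√(cB + α) (`tradeoff_form="concave_sqrt"`, the default): strictly
increasing and strictly concave on α ≥ 0, so marginal transmission gains
shrink as virulence grows. cA = 0.005 scales transmission to a level that
does not swamp the population; cB = 0.14 sets the baseline transmission a
pathogen gets before paying any mortality cost. Two alternative forms are
selectable for sensitivity analysis: `"ratio"` (cA/(cB + α), decreasing in
α) and `"linear"` (cA·cB + α). The ratio form cannot reward virulence at
all — under it the least virulent strain wins everywhere on the default
grid (the test suite reports this map without asserting on it) — which is
why the concave increasing form is the default: it is the only one of the
three consistent with both a virulence–transmission trade-off and
high-virulence strains winning anywhere.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| T1, T2 | season lengths (together / apart), T1+T2=1 | 0.5, 0.5 | year |
| b | birth rate | 2 | /year |
| d | background mortality | 0.14 | /year |
| α1, α2, α3 | strain virulences (strictly increasing) | 0.01, 0.05, 0.1 | /year |
| σ | fecundity cost of infection (added to b) | −0.02 | /year |
| γ | density-dependence strength (capacity 1/γ) | 1e−4 | /indiv |
| δS, δI, δR | per-trip migrant mortality fractions | 0.001, 0.004, 0.001 | — |
| μ | immunity-loss rate (0 = SIR) | 0 (swept 0–1) | /year |
| ν1 | Habitat 1 recovery rate | 0.14 (swept 0–0.5) | /year |
| ν2 | Habitat 2 recovery rate | ν1 + 0.12 | /year |
| cA, cB | trade-off constants | 0.005, 0.14 | — |

The δI default of 4δS encodes migratory culling (infected migrants suffer
the trip disproportionately). All simulations start from 100 individuals
in each of the ten classes (1,000 hosts total, a tenth of the carrying
capacity) and run 2000 years unless noted.

μ, ν1, ν2 and the δ costs may be given as arrays of a common length K, in
which case states of shape (10, K) advance K independent parameter sets in
one batched integration; the sweep module relies on this.

## Outcome definitions

- **Winning strain**: argmax over strains of the pooled final infected
  total Iri + Imi, provided it exceeds 1e−6 individuals; otherwise the
  pathogen is recorded as extinct. The 1e−6 cutoff exists because
  continuous densities never reach exact zero; it is far below any
  meaningful density at these scales. Ties (measure-zero) break toward the
  less virulent strain.
- **Host-strategy dominance**: migrants dominate iff their five
  compartments strictly outnumber the residents' five; exact ties count as
  resident dominance (the migration pulse strictly shrinks migrants, so a
  tie cannot persist).

Because the winner is proportion-based it is invariant to rescaling the
final state, and with no mutation in the model a strain can only win if it
was seeded.

## Numerics

- Seasons are integrated with an adaptive explicit Runge–Kutta 4(5) pair
  (scipy's RK45) at rtol 1e−8, atol 1e−10. The fields are smooth and
  non-stiff at the default scales (even μ = 20 keeps time constants well
  above the step sizes the controller chooses). Pulses live outside the
  integrator, so no event detection is needed.
- Integrator round-off can push a compartment slightly negative at a
  season boundary; values above −1e−8 are clamped to zero, anything worse
  raises an integration error (a real solver failure, not round-off).
- The annual map is checked against an independent fixed-step classical
  RK4 oracle (step 1e−4, scalar-transcribed equations) to 1e−6 relative,
  and both derivative fields against scalar transcriptions at random
  states to 1e−12.
- Transition boundaries are found by bisection on the winner index to a
  ν1 tolerance of 1e−3, after a 6-point prescan that verifies the winner
  is non-decreasing in ν1 (falling back to a 3× denser scan with a logged
  warning if not). The 1→2 and 2→3 thresholds are located as the smallest
  ν1 where the winner reaches 2 and 3 respectively, which keeps them
  ordered even when the winner jumps straight from 1 to 3; independent
  bisections can cross by up to the tolerance when the two transitions
  nearly coincide, and are clipped to respect the ordering.
- An optional steady-state early stop halts a run once the year-over-year
  change satisfies max |Δy|/(1+|y|) < tol (every batch member, all
  compartments). It is off by default; replication-grade runs always
  simulate the full horizon.

## Problem sizes used by the test suite and acceptance script

Full phase maps use the complete 2000-year horizon on the reduced 6×6 grid
(μ ∈ [0,1], ν1 ∈ [0,0.5]). The SI-limit run uses 800 years (the resistant
pool decays at rate μ+d, so it is far below 1e−6 within 150 years, and the
strain-1 win is unambiguous well before 800). The SIS-limit comparison
uses 400 years and the boundary searches 600 years: the compared
structures — cell-by-cell winner agreement with the SIS variant, threshold
ordering, and monotonicity in δI — are stable from a few hundred years on,
even where the absolute threshold values still creep slowly (near a
transition the two leading strains are nearly neutral and exclusion is
slow, which is why threshold estimates are quoted together with the
horizon they were computed at).

## Degenerate limits and what the checks show

- **SI** (ν1 = ν2 = 0): nothing enters R, both R pools decay to zero, and
  with infection lasting for life the least virulent strain wins.
- **SIR** (μ = 0): the default scenario; recovery is permanent.
- **SIS** (μ = 20): mean immune residence 1/20 year, far below every other
  time scale; a finite stand-in for μ → ∞. At this setting the winner map
  over (ν1, δI) is checked cell-by-cell against an independently coded
  8-compartment SIS variant with the resistant class deleted and recovery
  routed directly I → S. The μ axis is meaningless in that limit, so the
  comparison grid is ν1 × δI at fixed μ = 20.
- **disease_free**: susceptibles only; the infected/resistant subspace is
  invariant, a regression guard on the transmission terms.

"Low μ / high ν1" in the migrant-dominance check is made concrete as: a
migrant-dominated cell must sit at μ at or below the grid midpoint and at
a ν1 above the strain-1 region of its μ column — equivalently, migrants
only dominate where a more virulent strain wins. That formalization
follows from the mechanism: migrant numbers hold up only where migratory
recovery (ν2 > ν1) pays off against the per-trip cost, which is also where
shortened infections favor virulent strains.

## Scope and limitations

- The three strains are fixed; there is no mutation, no coinfection, and
  no invasion analysis — "winning" means winning the simultaneous
  three-way competition from equal starts, not an ESS computation.
- Host strategies are fixed at birth; migrants never become residents.
- Density dependence acts on fecundity only; a mortality-based variant
  could behave differently and is out of scope.
- The phase-map and boundary claims verified here are structural
  (orderings, monotonicity, region locations), not cell-by-cell numeric
  values; absolute transition thresholds depend on the chosen trade-off
  constants and horizon.
- The model describes no real parasite system; all conclusions from the
  test suite are about the model's internal consistency and qualitative
  structure, not about any particular organism.
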