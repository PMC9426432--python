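# Methods

## Model and program

The core object is a mixed-integer linear program over flux variables v,
direction binaries z, metabolite log-concentrations ln c, two pH
variables, and per-reaction Gibbs-energy variables ΔG.  Steady state
S·v = 0 is enforced for every metabolite (boundary exchange reactions
close the system).  For each thermodynamically constrained reaction the
flux is split into nonnegative forward/reverse parts tied to binaries, and
big-M rows deactivate the feasibility inequality ΔrG′ ≤ −ε for the
direction whose binary is 0.  The split-variable form was chosen over
solver indicator constraints for portability; the only supported backend
key is `highs` (scipy's HiGHS interface), which is single-threaded and
deterministic, with a relative MIP gap of 1e-9 requested on every solve.

ΔrG′°ᵢ refers to pH 7, ionic strength 0 M, 298.15 K.  Temperature enters
only through the R·T factors of the concentration and proton-gradient
terms; no Gibbs–Helmholtz re-transformation of ΔrG′° is applied, because
reaction enthalpies are unavailable for most genome-scale reactions.  A
`gibbs_helmholtz` config flag reserves the interface (it raises
`NotImplementedError` rather than silently doing nothing).  ΔrG′° is also
treated as pH-invariant within the modeled window [6, 8]; both are
documented approximations that keep the program linear.

Water carries no concentration variable (activity 1); protons are handled
entirely through the pH variables, so they carry none either —
double-counting with the transport pH term is thereby avoided.  Artificial
(biomass-class) pseudometabolites are likewise excluded from concentration
variables and from mass/charge balancing.

### Transport energetics

ΔG_transport = c·F·ΔΨ + h·ln10·R·T·(pH_out − pH_in), where h and c are
the net protons and net charge moved outside→inside.  The membrane
potential is modeled as an affine function of the pH gradient,
ΔΨ = a·ΔpH + b with defaults a = 0.03333 V/pH unit and b = −0.14333 V —
the values used in the original TMFA treatment of a gram-negative
bacterium — because no measured ΔΨ is generally available; both are
configurable.  pH_in and pH_out are free decision variables in [6, 8]
rather than fixed parameters, the less restrictive reading; fixing them is
a matter of setting equal bounds.

### Big-M and tolerances

K is computed per reaction as the attainable |ΔrG′| span (|constant| +
Σ|coefficient|·|bound| over concentration and pH terms) plus |ε| plus a
1 kJ/mol margin.  Per-reaction K keeps the LP relaxation tight; a global
`bigM_K` override is validated against the computed safe value at build
time and rejected with that value in the message if undersized.
Feasibility epsilon defaults to 0 (the canonical inequality ΔrG′ ≤ 0 for
an active direction); it is configurable for strictness studies.  Flux and
steady-state zero tolerances are 1e-9, below the solver's feasibility
tolerance; the direction-classification tolerance is 1e-6 flux units.

## Calibration

The robustness scan fixes ATPM at each grid value and maximizes biomass —
one MILP per point.  The default grid is 50 evenly spaced points from 0 to
the zero-biomass ATPM limit located by bisection (40 halvings of the bound
interval).  The OLS fit is restricted to points with biomass above 1% of
the scan maximum: beyond the linear regime the curve plateaus at zero and
would bias the slope.  Projection inverts the fit at the two ends of the
measured growth window and clips negative maintenance values to 0 with a
warning; a non-negative slope is an error, since it means no
biomass/maintenance trade-off was detected and the calibration concept
does not apply.

## Ensembles

Each draw fixes biomass to μ ~ Uniform(μ_lo, μ_hi) and solves under a
random linear objective over all reaction fluxes with coefficients
~ Uniform(−1, 1), maximized.  The uniform μ distribution is the plainest
reading of "a random value within the measured range"; the random
objective makes each draw land on a different vertex of the μ-constrained
feasible set, which is what gives the ensemble its spread — a fixed
objective would collapse all draws onto near-identical optima.  One solve
per draw; `variability()` remains available for sensitivity checks.  All
randomness flows from the condition seed through one `numpy` generator, so
identical condition specs give bit-identical matrices.  Infeasible draws
are logged and resampled up to 3 times; more than 10% failures aborts with
the offending parameter ranges in the message.

Oxygen handling mirrors the study design: the oxygen concentration upper
bound and exchange lower bound are per-condition inputs (solubility values
for 4/15/20 °C ship as an overridable helper table, `OXYGEN_SOLUBILITY`),
not computed internally.

## Metrics

CUE partitions exchange fluxes by sign (negative = uptake), weights each
by the compound's carbon count, and reports (C_in − C_out)/C_in; it is
undefined (NaN) when nothing carbon-bearing is consumed.  ATP accounting
sums flux × s_ATP per reaction — positive terms are production, negative
consumption — excluding the maintenance reaction, so ATP-per-substrate and
ATP-per-biomass reflect metabolic demands only.  Summary tables use
linear-interpolation quantiles (numpy/pandas default).

## Statistics

Kruskal–Wallis uses the tie-corrected H with a chi-square p on k−1 degrees
of freedom (scipy); the all-identical-data edge case is reported as H = 0,
p = 1 by continuity.  The effect size is ε² = H/(n_total − 1).  Pairwise
comparisons are two-sided Wilcoxon rank-sum tests: exact permutation
p-values (midranks, so ties are handled) whenever C(n1+n2, n1) ≤ 2·10⁵,
otherwise the normal approximation with tie and continuity corrections.
The two-sided exact p is defined as P(|W − E W| ≥ |w_obs − E W|) under the
permutation null, which coincides with the usual doubled-tail definition
in the tie-free case and agrees with R's `wilcox.test` exact p there (the
test suite cross-checks against `kruskal.test` and
`pairwise.wilcox.test`).  Pairwise p-values are Holm-adjusted by default —
the default of the reference pairwise-testing function — with
`bonferroni`/`none` available.  The screen verdict is `significant` iff
KW p ≤ 0.05 AND ε² ≥ 0.36 AND every adjusted pairwise p ≤ 0.05; groups
that are element-wise identical multisets are reported `ND` (no
difference) rather than not-significant.  RMS scaling divides each
condition's value by the root mean square across conditions and flags the
all-zero case instead of dividing by zero.

## Synthetic study conditions

The generators define the conditions every test and the acceptance script
run under; their defaults are fixed, not tuning knobs.

**Chain model** — substrate exchange (uptake cap U = 10 flux units) →
transport (h = 1, c = 1, ΔrG′° = −5) → an ATP-generating step (+1 ATP per
substrate, ΔrG′° = −10) → n−1 further steps (−10 each) → biomass
(1 pathway product + y = 2 ATP per unit) with an overflow secretion route
and a free phosphate exchange standing in for unrestricted small-ion
exchanges.  Carbon metabolites all use formula C6H12O6 and the energy
currency uses P3/P2/P1, so every internal reaction is exactly mass- and
charge-balanced and carbon accounting is integer-exact.  Analytics:
μ_max(ATPM m) = (U − m)/y, robustness slope −1/y = −0.5, intercept
U/y = 5, ATP yield 1 per substrate.  Optional extras: a bypass route
(degenerate alternative path) and a 3-reaction internal cycle.

**Cycle fixture** — the planted cycle's standard energies are (−2, −2, +5)
kJ/mol, summing to +1: concentration terms cancel around a closed cycle,
so the three forward directions can never be simultaneously feasible and
the loop-law check is exact rather than tolerance-dependent.  The small
positive sum mimics the inconsistencies of independently estimated
group-contribution energies; a thermodynamically consistent cycle (sum 0)
with ε = 0 would admit an equilibrium-circulation edge case and cannot
serve as a sharp fixture.  Cycle reactions are irreversible so the reverse
circulation (sum −1, feasible) is excluded by bounds.

**Temperature-switch model** — two routes from substrate to biomass.  The
payoff route's key reaction A → B has minimum attainable
ΔrG′ = d − R·T·Δln with Δln = ln(0.02/10⁻⁵) ≈ 7.60, so any
d ∈ (R·T_low·Δln, R·T_high·Δln) is blocked at T_low and available at
T_high; d is placed at the interval midpoint (≈ 18.02 kJ/mol for
277.15/293.15 K), and an empty interval raises with the admissible bounds.
ATP yields are 2 per substrate through the payoff route and 1 through the
bypass.  The per-condition growth ranges (μ ∈ [2.0, 2.2] cold,
[5.0, 5.5] warm, maintenance fixed at 1) are chosen so that warm-condition
ATP demand 2μ + 1 exceeds the bypass-only supply (capped by U = 10): the
payoff route is then obligate in every warm draw and ATP-per-substrate is
exactly 1 cold versus ≥ 1.1 warm — the rerouting comparison holds for
every draw, not just on average.  This mirrors the biology (faster growth
at the optimal temperature) at toy scale.

## What the toys do and do not show

The generators exercise every pipeline mechanism — balancing, thermo
assembly, MILP coupling, calibration, ensembles, metrics, statistics — on
networks whose correct answers are known in closed form or by exhaustive
enumeration (all direction assignments × LP, feasible for ≤ 8 constrained
reactions).  They do not emulate genome-scale degeneracy, correlated
group-contribution errors in ΔrG′°, realistic biomass compositions, or
growth-rate measurement noise; passing tests demonstrate that the
machinery is implemented correctly, not that any particular organism-scale
prediction is right.  Running the pipeline on a real model requires an
SBML/TSV/YAML reconstruction plus the four thermodynamic tables
(per-reaction ΔrG′°, exclusion list, transport parameters, concentration
and exchange bounds); a formation-energy fallback (`dG0_from_formation`)
assembles per-reaction energies by Σ s·ΔfG′° and excludes reactions with
missing data.  An external validation path — loading a published
genome-scale reconstruction and checking its reaction/gene/metabolite
counts and per-temperature calibration windows — needs that model's
deposited files and is not part of the test suite.

## Problem sizes used

Test and acceptance runs use chains of 2–5 steps (11–17 reactions),
ensembles of 20–200 draws, 50-point calibration grids, 100 loop-law
solves, and 1,000 null repetitions for the screen's false-positive rate;
each MILP solves in milliseconds at these sizes, keeping the full suite
and the acceptance script to a few minutes.

## Known limitations

* ε = 0 permits flux at exact thermodynamic equilibrium (ΔrG′ = 0).
* Point estimates of ΔrG′° only; no uncertainty propagation.
* Ionic-strength and pressure corrections are out of scope.
* Compartments are restricted to inside/outside ({c, e}); other
  compartments are merged into `c` on load, consistent with transport
  parameters that only distinguish the membrane's two sides.
* The SBML dialect does not round-trip the `artificial` metabolite flag
  (no standard SBML slot); TSV/YAML do.
* The MILP is exponential in the worst case; genome-scale runs depend on
  solver performance and are expected to take minutes to hours.
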