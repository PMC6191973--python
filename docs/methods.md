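# Methods

## Model and parametrization

All computations assume the heteroscedastic linear mixed model described in
the README: a common between-subject intercept variance σ0² and
treatment-dependent within-subject error variances σ_εA², σ_εB², with
normal outcomes and no carryover.  Treatment and period are coded 0/1; the
estimators' optimal allocations and relative efficiencies are invariant to
recoding, so no alternative codings are supported.  A treatment-dependent
*between*-subject variance is not modelled.

The package works on the intraclass-correlation scale.  Given (ρ_A, ρ_B)
and the total variance σ_y² = σ_A² + σ_B², the components are uniquely

σ_A² = σ_y² ρ_B/(ρ_A+ρ_B), σ_B² = σ_y² ρ_A/(ρ_A+ρ_B),
σ0² = σ_y² ρ_A ρ_B/(ρ_A+ρ_B),

and the mapping round-trips exactly.  ρ = 0 is rejected (it appears in
denominators of every allocation and variance formula); ρ = 1 (no
within-subject error) is supported, including in simulation.  σ_y²
defaults to 2 so that the standardized effect size ES = β/√(0.5 σ_y²) and
the coefficient β coincide numerically; every reported design quantity is
scale-free in σ_y²/C.

## Variances, allocation, budget

`variance_at_allocation` implements the five asymptotic-variance cells
(three designs × treatment effect, two designs × interaction) as functions
of (ρ_A, ρ_B, p, N).  `optimal_variance` is the closed-form minimum under
the budget constraint; an internal consistency contract — enforced by
tests — is that it equals `variance_at_allocation` at the optimal p with N
implied by the budget identity.

Per-subject arm costs are (c_A+c_t+c_sp, c_B+c_t+c_sp) for the parallel
design, c_A+c_B+2c_t+c_s2p for the crossover, and
(2c_A+2c_t+c_s2p, 2c_B+2c_t+c_s2p) for the extended parallel design.  The
factor 2 on c_t in the extended parallel design reflects that each subject
is measured twice, consistently with its budget function; the same
coefficients enter the allocation ratios, the maximin conditions (through
λ = (2c_A+2c_t+c_s2p)/(2c_B+2c_t+c_s2p)) and the sample-size formulas.

The extended-parallel interaction allocation ratio contains 1−ρ factors;
at ρ_A = 1 or ρ_B = 1 no interior optimum exists (the closed ratio
degenerates to 0 or ∞) and `optimal_allocation` raises.  The corresponding
*variance* expressions stay finite and are used directly; maximin and
sample-size code falls back to an equal split in that degenerate corner.

## Maximin search

The worst case of each design's variance surface over an ICC rectangle is
found by arg-max over a finite candidate set:

* the four rectangle corners;
* for the parallel design, a representative of the interior locus
  ρ_B/ρ_A = φ* = (c_A+c_t+c_sp)/(c_B+c_t+c_sp) when φ* lies in the induced
  φ range (the variance is constant along the locus; the representative
  reported has ρ_B = min(ρ_B^U, φ*ρ_A^U));
* for the extended parallel design, the closed-form stationary points on
  all four edges (the 1-D stationarity condition in the free ICC has an
  explicit solution on any edge), kept only when feasible and inside the
  edge.

The published five-case decision cascades are evaluated alongside in
printed order; a disagreement with the candidate arg-max beyond relative
1e−9 raises a warning and the candidate answer wins.  Across hundreds of
randomized cost/rectangle draws in the test suite the two routes agree and
the closed form dominates a 201×201 brute-force grid (the default oracle
resolution, which locates the worst case to < 0.005 in ρ — finer than any
quantity reported).  Ties between designs in `relative_efficiency` are
reported as co-best rather than broken arbitrarily.

## Sample sizes, rounding, corrections

The unrounded total solves the normal-approximation power identity with the
optimal-allocation variance under the budget function; for a subject-count
budget this reduces to n = 2((z_{1−α/2}+z_{1−γ})/ES)²·V with V the
scale-free variance coefficient.  Rounding to integer arms is a convention
the asymptotic theory does not fix.  The package uses:

* crossover: the optimal allocation is exactly 1:1, so each sequence gets
  ⌈n/2⌉ (arms stay equal);
* parallel and extended parallel: round the total up to ⌈n⌉, then give arm
  1 the nearest integer to ⌈n⌉·p1 (half away from zero) and arm 2 the rest.

This reconstruction reproduces the reference sample-size tables checked in
the test suite, including odd totals such as N = 23 for the interaction
AA/BB plan at α = 0.01, where an unequal 12/11 split arises; two published
cells (15 and 51 in the interaction table) resist any single rounding
order we found (the reconstruction gives 16 and 52) and are documented
here rather than forced.

The t-test corrections (+1/+2 per arm for pooled-variance analyses at
α = 0.05/0.01; +2/+4 for unpooled analyses with both arms ≥ 8, else +3/+4)
are applied after rounding; the "fewer than 8" trigger is evaluated on
post-rounding, pre-correction counts.  The rules are validated for
α ∈ {0.05, 0.01} and planned powers of 80–90%; for other α the code picks
the 0.01 rules when α ≤ 0.025 and the 0.05 rules otherwise.  A ceiling
with a 1e−9 slack guards against float dust; whole-percent efficiency
reports round half-up with the same slack so that exact rational ties
(e.g. 17/40 = 42.5%) land on the half-up side.  Power planning uses the
normal approximation plus these additive corrections by construction; no
noncentral-t calculation is performed — the corrections' sufficiency is
what the simulator verifies.

## Simulator

`simulate_trial` draws the mixed model directly (one intercept per subject,
treatment-dependent error per measurement); the parallel design uses the
single-measurement reduction, where intercept and error are not separable.
`analyze` reduces each subject to a score (difference, mean or raw) and
applies the two-sample t-test that is exact under the model: pooled
variance for the crossover analyses (the model implies equal score
variances across its sequences), Welch with Welch–Satterthwaite degrees of
freedom for the parallel designs (the published analyses name the unpooled
test but not a df rule; Welch–Satterthwaite is the standard choice).
Exactly constant scores in both groups are resolved by an exact-separation
convention (p = 0 for distinct means, p = 1 otherwise), which matters only
in the ρ = 1 corner.

`monte_carlo_power` generates at the worst-case ICC pair by default — the
point where the plan must still deliver its power — with the effect placed
on the coefficient of interest, β_time = 0.25 and the remaining fixed
effects 0 (the tests are exactly invariant to the nuisance coefficients).
Each replication uses its own stream spawned from the master seed, making
estimates reproducible and independent of replication order.

What the simulations do and do not show: they emulate exactly the
generating model — normality, a shared intercept variance, no carryover,
no dropout, no covariates.  Passing power checks therefore validate the
normal-approximation planning plus corrections *under the model*, not
robustness to skewed outcomes, carryover or missing data.

## Problem sizes and numerical choices

The default grid-oracle resolution is 201 per axis.  Reference simulated
powers are computed at 25,000 replications (predictive interval
[0.795, 0.805] around an 80% target); the test suite runs the
bold-design power sweep at 2,500 replications with correspondingly wider
predictive bounds, and the type-I calibration at 25,000 — sizes chosen so
the whole suite completes in well under a minute while keeping Monte Carlo
error far below the margins being checked.  Randomized property tests use
fixed seeds throughout; hypothesis-based tests are derandomized.

## Known limitations

Two treatments, two sequences, at most two periods; no carryover, dropout,
prerandomization covariates, or >2-arm extensions.  No ML/REML fitting of
the mixed model to real data is provided — the engines evaluate closed-form
asymptotic variances, and the simulator analyzes with the exact t-tests.
The evaluation-grid sweep recomputes each cell's maximin solutions in a
Python loop; full-factorial sweeps over all published cost ratios and
range pairs (~180k cells) take minutes, so the CLI defaults to restricted
sweeps.
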