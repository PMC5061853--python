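# Methods

## Model class and standing assumptions

A compartmental system is the linear nonautonomous ODE
`dx/dt = B(t) x + s(t)` on a time interval whose lower end may be
finite or conceptually unbounded (represented by a flag plus a
practical lower bound).  The defining sign conditions — negative
diagonal, nonnegative off-diagonals, nonpositive column sums of
`B(t)`, nonnegative `s(t)` — are verified by sampling on a user grid
(default 201 points per requested interval).  Continuous-time
verification is impossible for black-box callables, so the grid is
part of the validation report; the built-in generator additionally
guarantees its contracts between sample points by construction (see
below).  An input that is identically zero is reported as a soft
flag rather than an error: the stability theory concerns only the
homogeneous part, and homogeneous runs are legitimate.

Non-finite coefficients are a hard error, distinct from sign-condition
violations.

## Mass integration

`solve_mass` wraps an adaptive, implicit-capable integrator (LSODA;
relative tolerance 1e-8, absolute 1e-10 by default).  The carbon-cycle
application has rates spanning four orders of magnitude (2.5/yr for
metabolic litter vs 4e-4/yr for passive soil), i.e. mild stiffness,
which LSODA's automatic switching handles without tuning.  Negative
excursions beyond tolerance are warned about, never clamped.  The
transition operator `Φ(t, t0)` is computed by integrating the d²
matrix ODE in one pass; the pullback solution is approximated by
finite burn-in from zero initial mass with a burn-in-doubling check
whose difference is reported, since the defining improper integral
cannot be evaluated directly.  When the burn-in would reach before the
practical lower bound, the caller chooses between an error and a
freeze-extension that holds `B`, `s` constant there.

Mass-balance auditing compares the centrally differenced total mass
with the flux balance `Σs + Σ_j c_j x_j` (`c_j` the column sums); the
residual is dominated by the O(h²) differencing error of the output
grid, not by the solver, and is judged against that scale in tests.

## Autonomous theory

All closed forms are evaluated by linear solves, never explicit
inverses; with timescales up to 2500 yr the rate matrix is poorly
scaled and a solve against `(1, …, 1)` or `s` is the accurate route.
A condition number above 1e12 triggers a warning, and singularity an
error naming the offending singular value.  Equilibria with
nonpositive entries (pools unreachable from the inputs) cause mean-age
computations to be refused rather than patched with a pseudo-inverse:
the mean-age equation divides by pool masses, and an answer for an
empty pool would be fiction.

The per-pool transit times satisfy two independent characterisations —
the linear system `0 = Bᵀ r + 1` and the renewal relation
`r_i = -1/b_ii + Σ_{j≠i} p_ij r_j` — and the test suite checks one
against the other, plus a seeded Monte-Carlo particle simulation of
the jump chain (entry by β, exponential sojourns at rates −b_ii,
transfer probabilities p_ij = −b_ji/b_ii) that reproduces `R` within
three standard errors at 1e5 particles.

## The mean-age system

The mean-age right-hand side is implemented exactly as the formula
`g_i = 1 + [Σ_j (ā_j − ā_i) b_ij x_j − ā_i s_i]/x_i`; its linear form
`dā/dt = A(t, x) ā + 1` with
`A = X⁻¹ (b_ij x_j − δ_ij (s_i + Σ_{k≠i} b_ik x_k))` is verified
against it on random arguments.  The coupled mass+age system is
integrated as one 2d-dimensional ODE so the adaptive stepper sees the
coupling; a two-pass mode (mass first with dense output, then the
linear age equation along it) exists for debugging and agrees to
integration tolerance.

Positivity floor: the age equation is undefined where any pool mass
vanishes.  Masses below 1e-12 of the initial total trigger a terminal
event and an error naming the failure time, rather than a silent
division.  `R_t` is undefined at times when every column sum of `B`
vanishes (a momentarily closed system); such points are emitted as
missing values (NaN in memory, empty CSV cells), never interpolated.

Initial ages for a run started at finite t0 default to the
frozen-equilibrium ages `ā*` of `(B(t0), s(t0))` — the spin-up
convention of the carbon application; a zero-age start is available.
For runs not started at a frozen equilibrium this default is a
convention, not a theorem, and callers with better information should
pass their own `ā0`.

## Stability diagnostics

The sufficient criterion checks that, after a permutation, `B(t)` is
lower block triangular for all sampled times with every diagonal block
strictly diagonally dominant **by rows** with a uniform margin δ.  The
block structure is computed once from the union-over-time sparsity
pattern (edge threshold 1e-12) via strongly connected components,
ordered topologically with ties broken by smallest pool index, so one
fixed block form is valid for all times.  Note the deliberate
asymmetry: the compartmental property constrains *column* sums while
the dominance criterion constrains *row* sums of diagonal blocks; the
two are implemented and labelled separately and never conflated.  The
criterion is sufficient, not necessary — the classic two-pool feedback
example fails it while being plainly stable, as does the soil block of
the carbon model — so the package also fits an empirical decay rate:
spectral norms of `Φ(t, t0)` on a grid, least squares on the log over
the tail half to skip transients.  The fit uses relative-error-
dominated solver tolerances (atol 1e-60) because the norm may fall
through many orders of magnitude and an absolute floor would flatten
the tail into noise.  The fitted prefactor can come out below 1; the
theoretical envelope always has `K ≥ 1`, so convergence tests floor it
there.

The mean-age stability conditions (inputs into the first block bounded
below, and a donor edge from an earlier block for every later pool)
are checked with witnesses recorded per pool and the largest
admissible δ reported.

## The age-density oracle

The age densities `p_i(a, t)` obey a transport equation at unit aging
speed with age-local pool coupling and boundary value `s_i(t)` at age
zero.  The solver commits to the unit CFL step `dt = da`: transport is
then an exact one-cell shift (no numerical diffusion in age), and only
the coupling is approximated — the diagonal self-loss by its exact
exponential factor over the step, the off-diagonal transfers
explicitly.  For a decoupled pool the stationary density is therefore
exact at the nodes.  Sub-CFL steps are refused rather than supported
badly, since they would reintroduce age diffusion.  The scheme is
first order in `da`; grid-halving tests observe order ≈ 1.0 on random
two- and three-pool systems, constant and sinusoidal.

Mass older than `a_max` (default 10× the largest frozen-system
equilibrium age) is lumped into a tail cell carrying its own mass and
first-moment trackers.  Because the coupling is age-local, both obey
the same linear dynamics as any age slice, so extracted mean ages are
not biased low by truncation.  Moments use the trapezoidal rule plus
the tail; empty pools report missing mean ages.  This module is a
verification oracle: its accuracy targets serve testing, not
production performance.

## Carbon-cycle application

Nine pools (leaves, roots, wood; three litter; three soil), 25
transfer/loss coefficients, time in years since 1850.  The forcing
chain is CO₂ → temperature → (fertilised input flux, Q10-style
decomposition multiplier ξ with ξ(20 °C) = 1); ξ multiplies the litter
diagonal rates and every entry of the three soil rows, leaving plant
rows and plant-to-litter transfers temperature-blind.  Column sums
split into a ξ-scaled and an unscaled part, both nonpositive, so
validity is temperature-independent and checked once at construction.

Three parameters have no published value and are explicit knobs with
documented defaults: the input scale `s0` (default 1; all age and
transit outputs are provably invariant to it, which the suite asserts
to ~1e-10), the sensitivity base `xi_b` (default 2.0, a standard Q10
magnitude), and the soil coefficient `b89` (default 0, the choice that
keeps column 9 nonpositive; 1e-4, mirroring `b98`, is accepted).  The
CO₂ trajectory is the standard logistic closed form rising from
285 ppm toward 1715 ppm at 0.0305/yr; an alternative "verbatim"
closed form that starts at 1715 ppm is retained behind a flag for
comparison and documented as inconsistent with the 285 ppm baseline
used by the temperature and fertilisation formulas.

Runs spin up by freezing the forcing at t = 0 and starting from the
resulting autonomous equilibrium with its equilibrium mean ages, so
the initial mean age equals the frozen-equilibrium value by
construction.  The scenario integrates the skew product over
[0, 650] yr on a yearly output grid (seconds of runtime) and attaches
the frozen `R`, `M` series as the history-blind baseline.

Measured behaviour under defaults: stored carbon is ~20× older than
exported carbon; the frozen mean age undershoots the true `M_t` by up
to a factor ~3.  The initial net carbon uptake is parameter-sensitive:
at `xi_b = 1.5` total carbon rises ~1.4 % before declining, at 2.0 the
rise is ~1e-4 of the stock, and at 2.4 the warming term dominates from
the start and total carbon declines monotonically — the spin-up start
forces dΣx/dt = 0 at t = 0, leaving the sign of the curvature to the
balance between fertilisation and warming.

## Synthetic systems

The generator draws sparse nonnegative off-diagonals and input
vectors, then sets each diagonal to dominate whatever the requested
contract requires (column sums with slack; additionally within-block
row sums with margin; additionally first-block inputs and cross-block
donor edges).  Time dependence is one smooth multiplicative factor in
[0.7, 1.3] applied to the whole matrix and another to the inputs —
deliberately not per-entry, so every enforced inequality is preserved
exactly between sample points at the cost of less general time
dependence.  Every generated system re-verifies its own contract on a
echo grid and retries on failure (bounded).  Generation is
deterministic under the seed, and stochastic tests use fixed seeds.

What the generator does not emulate: realistic ecological parameter
priors, correlated or abruptly switching forcing, near-singular rate
matrices, and age-dependent rates.  Tests passing on generated systems
therefore certify the mathematics on well-posed inputs; they do not
certify behaviour on data-calibrated models beyond the carbon-cycle
example shipped here.

## Numerical defaults at a glance

| quantity | default | why |
|---|---|---|
| ODE tolerances | rtol 1e-8, atol 1e-10 | stiffness-safe, leaves headroom below the 1e-6 test tolerances |
| validation tolerance | 1e-10 | plant columns of the carbon model sum to exactly 0, permitted as ≤ 0 |
| condition-number warning | 1e12 | approaching double-precision loss |
| mass positivity floor | 1e-12 × initial total | below it the age equation's standing assumption has failed |
| PDE step | dt = da | exact transport along characteristics |
| tail cutoff | 10 × max ā* | tail mass fraction ~e⁻¹⁰; tracked, not discarded |
| decay-fit window | tail half of the grid | skips transients before the slowest mode dominates |
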