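# Methods

## Model

Each dormant primordial follicle carries a scalar activity `X(t)` (the
follicle's integrated stress state; the scale is arbitrary, so `X(0) = x0 =
1`). On a lattice, `X` moves by `±Δx` each time step `Δt`, upward with
probability `p`; in the continuum limit this is Brownian motion with
diffusivity `D = Δx²/(2Δt)` and downward drift `V = (2Δx/Δt)(1/2 − p)`. The
follicle leaves the reserve at the first exit of `X` from `(0, L)`: crossing
0 means growth activation, crossing the death threshold `L` means death
before activation. Exit times are iid across a woman's `N` follicles, so her
expected reserve is `E[F(t)] = N·S(t)` with `S(t) = P(τ > t)`. Menopause is
declared at the first time the (stochastic) reserve falls strictly below a
threshold of 1,000 follicles, on a monthly grid.

Assumptions worth stating plainly: follicles are independent and
exchangeable; activation is a single-unit decision (no multi-cell
granulosa structure); dynamics after activation (growth, atresia,
ovulation) are out of scope; the menopause threshold is a fixed count.

## Closed-form survival and its evaluation

For `L = ∞` the exit-time law is the inverse-Gaussian-type survival

S(t) = ½[ erfc(−a) − e^{V·x0/D} erfc(b) ],  a = (x0 − Vt)/√(4Dt),  b = (x0 + Vt)/√(4Dt).

Since `b² − a² = V·x0/D`, the overflow-prone product is rewritten as
`e^{V·x0/D} erfc(b) = erfcx(b)·e^{−a²}` (scipy's scaled complementary error
function), stable for arbitrary `V/D` (the human value is 12.75; user
parameters may be far worse). For `b < 0` (strong upward drift) the identity
`erfcx(b) = 2e^{b²} − erfcx(−b)` supplies the stable branch. The formula is
the standard `x0`-generalisation of the unit-start case and reduces to it
exactly at `x0 = 1`; it is verified in the tests against Monte-Carlo walk
frequencies.

The finite-`L` two-sided survival uses the eigenfunction expansion of the
forward equation `p_t = D p_xx + V p_x` on `(0, L)` with absorbing ends
(separation of variables after the substitution `p = e^{−Vx/(2D)} w`),
integrated over the interval in closed form. The series is summed in blocks
of 64 terms until an entire block falls below 1e−12 in magnitude, with a
hard cap of 10⁴ terms (small `t` needs the most terms; `t = 0` returns 1
exactly). The probability of dying before activating is the scale-function
ratio `(e^{V·x0/D} − 1)/(e^{V·L/D} − 1)`, evaluated via `expm1` or in log
space; at the human parameters and `L = 2` it is ≈ 2.9e−6, which is why the
one-sided law is the default (`L = ∞`).

Threshold-crossing ages solve `N·S(t) = threshold` by Brent root-finding on
`[0, 200]` years (doubling the bracket if needed) to 1e−6 yr; the curve is
strictly decreasing so the root is unique.

## Simulation

**Lattice walks.** `x0` and `L` are snapped to the nearest lattice multiple
of `Δx` (an error if that lands on a boundary); absorption occurs at the
first step with position ≤ 0 or ≥ L; walks censor at `max_age` (120 yr
default). The sampler advances all active walkers in lockstep through blocks
of 2048 steps (walker chunks of 8192), accumulating integer positions by
cumulative sums; because all walks share the step clock, an age-dependent
`p` applies uniformly. One seeded numpy Generator consumed in this fixed
order makes every run reproducible from `(seed, config)`.

**Occupancy propagation.** The same transition law applied to the full
probability mass gives the exact marginal survival and per-step hazards,
including under age-varying `p`; interior mass plus absorbed mass is
conserved to 1e−12 and is asserted. An infinite `L` is replaced by a ceiling
the walk cannot reach within the horizon (or, for drift-confined problems, a
ceiling with excursion probability ≤ e⁻³⁰).

**Subjects.** Two distributionally equivalent methods:

- *binomial thinning* (default): `F(t_{k+1}) | F(t_k) ~ Binomial(F(t_k),
  S(t_{k+1})/S(t_k))` on the monthly grid — exact for iid exit times, cost
  per month rather than per follicle. Conditional ratios are validated
  against numerical noise (error beyond 1e−12 above 1).
- *per follicle*: `N` exit times by inverse-transform sampling of `S`
  (linear interpolation on the monthly grid), counted down the grid. Used
  as the independent cross-check and for common-random-number couplings
  (same seed, larger `N` ⇒ ANM not earlier; larger drift ⇒ not later).

Acute losses multiply the reserve by a surviving fraction at the first grid
point at or after the event age (random removal leaves survivors' exit law
unchanged). The loss magnitude is a free parameter.

**Populations.** Starting supplies are `round(exp(μ + σZ))` (defaults μ =
12.686, σ = 0.497, i.e. median 3.23e5); per-subject drift multipliers are `1
+ cY` (default c = 0; 0.03 for the heterogeneous-drift condition).
Non-positive sampled multipliers are kept — the model is faithfully normal;
their probability at c = 0.03 is ~Φ(−33) — but logged if they ever occur.
Thinning is vectorised across subjects in chunks of 2000. The retained
"quantile trajectories" are expected curves `N_q · S(t)` for the supply
quantiles {1, 5, 25, 75, 95, 99}%.

**Time-variant drift.** Piecewise-constant schedules (left-closed segments:
the value switches exactly at each breakpoint age; the packaged
acceleration schedule is 0.024/yr before 38, 0.033/yr from 38) have no
closed-form survival once the drift changes mid-course, because the
survivors' positions matter. Survival is therefore occupancy-propagated at
an internal step of 1/48 yr (which divides the monthly grid; at the default
diffusivity the lattice discretisation error is below 1% absolute in `S`,
comparable to a monthly discrete-walk simulation). When subjects also carry
drift multipliers, curves are computed on a multiplier grid no coarser than
0.004 spanning the sampled range and interpolated log-linearly per subject;
the curvature of `log S` in the drift makes that interpolation error ~1e−5,
far below sampling noise.

## Estimation

`(D, V)` minimise the sum of squared errors between log expected counts and
log observed counts (natural log), the scale on which follicle counts spread
over five orders of magnitude. Only postnatal records enter (the curve
starts at birth). `N` is fixed beforehand — normally to the supply-fit
median, mirroring the supply-first sequencing — with a joint 3-parameter fit
available behind `fit_N=True`. The optimiser is L-BFGS-B in log10-parameter
space (bounds `D ∈ (1e−6, 1)`, `V ∈ (1e−6, 1)`) from the three best starts
of a 5×5 log-spaced grid (`D ∈ [1e−4, 0.1]`, `V ∈ [0.01, 0.2]`): the surface
can be multimodal and the original search procedure is undocumented, so this
is the package's own deterministic choice. On noiseless self-generated data
the generating parameters are recovered to better than 1e−6.

The supply fit is the closed-form normal MLE on log counts (σ with
denominator n — the estimator used upstream is unstated, and at n = 30 the
difference is ~2%), with a KS adequacy statistic and optional bootstrap
percentile intervals.

The synthetic-count generator draws
`count = max(1, round(E[F(age)]·e^ε))`, `ε ~ N(0, sd²)`, seeded. It emulates
cross-sectional histological counts with multiplicative scatter; it does
*not* emulate sampling-protocol biases, age-dependent noise, or the
prenatal rise of real datasets, so recovery tests certify the estimator's
self-consistency, not robustness to those artefacts.

## Numerical and design choices

- ANM is the first **monthly** grid age with `F < threshold` (strict),
  reported in years; month resolution matches the discrete-month framing.
- Root bracket `[0, 200]` yr with doubling; series tolerance 1e−12 / cap
  10⁴ terms; occupancy conservation tolerance 1e−9 (asserted at 1e−12 per
  step); survival clipped to `[0, 1]` after evaluation.
- Defaults: `x0 = 1`, `L = ∞`, `Δt = 1/12` yr for walks, horizon 120 yr
  with explicit censoring, threshold 1,000, 10⁴ subjects.
- Degenerate inputs: supply below threshold ⇒ ANM 0 (with a warning for the
  deterministic curve); `threshold ≤ 0`, negative ages, out-of-range
  probabilities, and boundary-snapped starts raise typed errors.

## Problem sizes

The test suite exercises the closed form against Monte Carlo at 10⁵ walks
with a 10⁻³-yr step (KS distance ~0.003), occupancy against 3×10⁴ walks,
populations of 10⁴ subjects, and 50-replicate recovery studies at 100
observations; unit tests use smaller sizes (2–3×10⁴ walks, 200–2000
subjects) chosen so that binomial/KS tolerances stated in each test hold
with wide margin.

## Known limitations

- The monthly grid quantises ANM to 1/12 yr; reported medians inherit that
  granularity.
- Occupancy-based survival for drift schedules is a lattice approximation
  (error ≲1% absolute in `S` at the defaults); constant-drift paths use the
  exact closed form.
- The accelerating schedule's published drift values (0.024/0.033 per
  year) decay far more slowly than the single fitted drift 0.051/yr; under
  the fitted diffusivity they push threshold crossings decades later. The
  package implements the schedule as specified and leaves the tension to
  the user's parameter choices.
- The eigenfunction series loses efficiency at very small times (falls back
  to warning past 10⁴ terms); `t = 0` is handled exactly.
- Exchangeable, independent follicles: no spatial correlation between
  neighbouring follicles' microenvironments, though the biology suggests
  regional fluctuations are shared.
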