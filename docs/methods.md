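# Methods

## The individual-level model

One generation of unit-resource competition is specified by four
parameters: the per-capita fecundity ceiling `λ > 0` (expected offspring of
a reproductive individual, dimensionless), the resource unit size `u > 0`
(resource units an individual can obtain at a time), the expected total
resource pool `R̄ > 0` (same units as `u`), and the reproduction threshold
`s ≥ 1` in units (equivalently the required amount `s′ = u·s`).

Given a realised pool `R`, the `M = ⌊R/u⌋` units are assigned
independently and uniformly to the `N` competitors, so one individual's
count is `Binomial(M, 1/N)` and its allocated amount `u·m` has variance
`u·R·(1 − 1/N)/N`: at fixed pool, the allocation inequality is
proportional to the unit size. An individual reproduces if `m ≥ s`; the
expected next generation at known `R` is `λ·N·Q(M)` with
`Q(M) = P(Binomial(M, 1/N) ≥ s)`.

The pool itself is taken exponential with mean `R̄` — the maximum-entropy
choice when only the expected pool is known (equally readable as random
between-year variation). Then `M` is geometric,
`P_M = (1 − e^{−u/R̄}) e^{−M u/R̄}`, and averaging `λNQ(M)` over it gives a
Hassell map

    f(N) = λN / (1 + aN)^s,   a = e^{u/R̄} − 1,

whose exponent `s = s′/u` is inversely proportional to the unit size. The
`s = 1` case is Beverton–Holt (maximal inequality, ideal contest); the
`u → 0` limit at fixed `s′` is Ricker `λN e^{−s′N/R̄}` (equal shares,
ideal scramble).

Two extensions:

* **Varying threshold.** `s − s₀` negative binomial with mean excess `δ`
  and shape `k` (so mean `s̄ = s₀ + δ`, variance `δ + δ²/k`). The map
  becomes `nb_full`; under `k = s₀` it is again a Hassell map with
  exponent `k` and scale `(1 + δ/k)a`. The moment conversions are
  `k = s̄′/(u + σ²_{s′}/s̄′)` and `δ = (σ²_{s′}/u)/(u + σ²_{s′}/s̄′)`:
  threshold variation *lowers* the exponent. In the `u → 0` limit the
  threshold law becomes gamma (mean `s̄′`, shape `k = s̄′²/σ²_{s′}`, now
  any positive real) and the map `gamma_limit` keeps a finite exponent
  even under equal allocation. At `u = 0` the unit-level excess `δ`
  diverges; `shape_from_moments` returns `inf` there rather than a
  fabricated finite value, and the fully degenerate case
  `u = 0, σ² = 0` raises.
* **Saturating fecundity.** Above the threshold the expected offspring is
  `λ(1 − e^{−γu(m−s+1)})` with saturation rate `γ > 0` per unit amount.
  The map `fecundity_full` replaces one factor `(1 + aN)` of the Hassell
  denominator by `(1 + ξaN)` with `ξ = (1 − e^{−γu})^{−1} ≥ 1`, so it is
  dominated by the step-fecundity map; `γ → ∞` recovers it exactly, `s = 1`
  gives a Beverton–Holt form, and `u → 0` gives Ricker times a
  Beverton–Holt factor.

All maps predict the **expected** next population. They are therefore not
iterated as forecasts of the stochastic process; the simulator's
trajectory mode realises offspring stochastically instead.

## Series oracles and truncation

`allocation.series_expected_population` evaluates the defining infinite
sums directly, as an oracle independent of the closed forms:

* fixed threshold: `Σ_M λN Q(M) P_M` over the geometric pool law;
* varying threshold: `Σ_s λN (1 + aN)^{−s} p_s` over the
  negative-binomial threshold law;
* saturating fecundity: `N Σ_{m≥s} λ_m p̂_m` over the geometric marginal
  count law `p̂_m = (aN/(1+aN)) (1+aN)^{−m}`.

Each sum is truncated with a rigorous geometric tail bound: every summand
is at most `λN` times a tail mass (geometric in `M` or `m`,
negative-binomial survival in `s`), and the cutoff is chosen so the bound
is below `tol` (default `1e-12`, hard cap 10⁷ terms with an explicit
`ConvergenceError` beyond — never a silently under-converged value).
`Q(M)` is computed through the binomial survival function (regularised
incomplete beta), not term-by-term addition, so large pools do not lose
precision; `a = e^{u/R̄} − 1` is always evaluated with `expm1`, so
`u/R̄ = 1e−12` does not underflow and the Ricker limit is approached
smoothly. With `0⁰ ≡ 1`, the `N = 1` allocation law is degenerate at
`m = M`.

The formula `Var[u·m] = u·R·(1 − 1/N)/N` is applied with `R = u·M` exact;
non-integer `R/u` is outside its intended use and the simulator always
floors.

## Simulator

`simulate_generation` draws `R` (fixed or exponential), floors to `M`,
and assigns units as one `N`-sided multinomial of size `M` — the same law
as a per-unit loop at O(N) cost. Threshold modes: fixed `s`;
per-individual negative-binomial draws; or gamma-distributed required
amounts compared against the obtained amount `u·m_i` (the natural
embedding of the continuum threshold law at finite `u`; its exact
expectation is the mixture `λN Σ_m p̂_m F_gamma(u·m)`, which is what the
tests compare against, since the gamma-limit closed form applies only at
`u → 0`). Fecundity modes: step or saturating.

`estimate_f` reports the mean and standard error over independent
replicates (expected-offspring semantics, matching the closed forms).
`stochastic_trajectory` realises each generation's offspring as one
Poisson draw with mean equal to the offspring expectation — equivalent to
independent Poisson(λ_m) broods per reproducer, a choice made here because
the derivation fixes only the mean offspring number — or as a rounded
expectation; zero is absorbing. A single seeded `numpy` generator drives
each run, so equal seeds reproduce results bitwise.

### Statistical comparisons

Monte-Carlo checks use a 4-standard-error band with a fixed seed. Because
per-replicate offspring lie in `[0, λN]`, the sampling variance of the
mean is at most `λN·f/reps`; the band uses
`4·max(sample stderr, sqrt(λN·f/reps))` so that rare-event grid points
(where the sample standard error can degenerate to zero) are still judged
by a valid a-priori bound rather than skipped. Goodness-of-fit checks
(binomial allocation at fixed `M`, geometric pool sizes) are Pearson
chi-square tests at `α = 0.001` with sparse tail bins pooled to expected
counts ≥ 5; the allocation-variance check uses the exact sampling variance
of the sample variance computed from binomial moments. Verification grids
span `N ∈ {1, 2, 5, 20, 100}`, `u/R̄ ∈ {0.01, 0.1, 1, 3}`,
`s ∈ {1, 2, 5, 20}` at `λ = 2`, with 10⁵ replicates per Monte-Carlo point
(reduced `N ≤ 20` and two `u/R̄` values for the extension modes); these
sizes keep the full suite under a minute on one CPU while leaving the
4-sigma bands tight enough to detect percent-level bias.

## Dynamics

Fixed points solve `f(N) = N` by Brent's method on `[1e−12, N_up]`, with
`N_up` doubled until `f(N_up) < N_up`; strict decrease of `f(N)/N`
guarantees a unique sign change whenever `λ > 1`, and `λ ≤ 1` short-cuts
to the trivial fixed point. If no bracket is found the result is flagged
unconverged, never fabricated. Stability is `|f′(N_*)| < 1` with a
central-difference derivative (`h = 1e−6·max(1, N_*)`), uniform across all
maps instead of per-model symbolic derivatives. `calibrate_a` inverts the
phenomenological fixed point `N_* = (λ^{1/b} − 1)/a`.

Numerical-limit tolerances follow the leading error terms: `u → 0`
comparisons use `u/R̄ = 1e−8` against relative `1e−6` (error `O(u)`),
`k → ∞` uses `k = 10⁶` against `1e−4` (error `O(1/k)`).

## Design choices

* Closed-form maps accept any real `N ≥ 0` (reproduction curves are
  continuous); the simulator requires integer `N`.
* Exponents are integers where the derivation demands it (`s` in the core
  map, `k = s₀` in the varying-threshold Hassell form, enforced at call
  time) and real only in `gamma_limit`.
* `hassell_nb` refuses `k ≠ s₀` rather than silently evaluating a formula
  outside its derivation.
* The CLI is a thin layer: results to stdout/files, logs and a JSON echo
  of the fully resolved configuration (defaults and seed included) to
  stderr, so any output is reproducible from its echo.

## What the tests do and do not show

The simulator *is* the model the maps were derived from, so agreement
demonstrates internal correctness of the derivation chain
(process → series → closed form), not realism: real populations have
heterogeneous competitiveness, non-exponential resource variation,
spatial/patch structure and inter-species interactions, none of which are
modelled here. Model fitting to field data, two-species extensions,
bifurcation/chaos analysis and the Maynard-Smith–Slatkin map are out of
scope.
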