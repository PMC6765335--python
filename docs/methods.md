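# Methods

## Models

`glifa` implements two coupled models of glucose (G, mg/dl), insulin
(I, μU/ml) and free fatty acids (F, μM) over the ~180-minute horizon of an
intravenous glucose tolerance test (IVGTT).

**Explicit time-delay model.** Plasma insulin is a state variable and
pancreatic secretion responds to glucose with an explicit lag τ:

    G'(t) = H − S_i·G(t)·I(t) − S_g·G(t)
    I'(t) = σ1·h(G(t−τ); α, γ) + σ2·h(F(t); σ, β) − d_i·I(t)
    F'(t) = g0 + g1 / (1 + (I(t)/I2)^κ) − d_f·F(t)

where h(x; K, n) = xⁿ/(Kⁿ + xⁿ) is the Hill response and
H = (S_i·I_b + S_g)·G_b is the constant hepatic glucose input. H is stored
*lumped* — the parameter actually estimated — and the basal levels
(G_b, I_b, F_b) are always recovered from it by solving the equilibrium
(below), never supplied by the user. This guarantees that stability
analysis and simulation refer to the same basal state.

**Minimal model with FFA.** The Bergman-type comparator treats measured
plasma insulin I(t) as an external forcing and routes its action through a
remote compartment X:

    G'(t) = S_G·G_b − (S_G + S_I·X(t))·G(t)
    X'(t) = c_X·(I(t) − X(t) − I_b)
    F'(t) = l0 + l2 / (1 + (X(t)/X2)^A) − c_f·F(t)

The forcing is piecewise-linear interpolation of the measured insulin with
constant extrapolation at both ends — the standard minimal-model
convention. Because the minimal model has no insulin equation, G_b and I_b
are required configuration inputs; the packaged minimal-model fixtures set
them to the basal state of the paired delay-model parameter set so the two
models describe the same subject. When a noisy forcing dips below basal, X
can transiently go negative; its action on lipolysis is then clamped at
zero (absent, not negative), keeping the fractional-power term defined.

An "implied plasma insulin" for the minimal model is reported as
I_b + X(t). This is needed only to put the two models on a common footing
in per-series goodness-of-fit tables; it is a reporting convention, not a
model equation.

## Basal state (equilibrium)

Setting the delay-model derivatives to zero and eliminating G and F gives
a scalar equation in the equilibrium insulin I*:

    σ1·h(G*(I*)) + σ2·h(F*(I*)) − d_i·I* = 0,
    G*(I*) = H / (S_i·I* + S_g),
    F*(I*) = (g0 + g1/(1 + (I*/I2)^κ)) / d_f.

Both Hill terms decrease in I* and −d_i·I* is strictly decreasing, so the
residual is strictly decreasing and has exactly one positive root: the
model has a unique equilibrium. The solver brackets the sign change on
[1e−6, 1e6] μU/ml (with automatic two-decade expansion, up to six rounds)
and refines with Brent's method at absolute tolerance 1e−10. The returned
state carries `residual_norm`, the max-absolute vector-field component at
the solution, and refuses solutions above 1e−9 (configurable). The
degenerate case σ1 = σ2 = 0 has only the boundary equilibrium I* = 0,
which violates positivity; the solver raises a diagnostic error rather
than returning it.

## Stability analysis

Linearization at the equilibrium yields the characteristic function

    Δ(λ) = λ³ + (b1+b2)λ² + (b1b2+b3)λ − b4·λ·e^(−λτ) + b1b3 − b4·d_f·e^(−λτ)

with b1 = S_i·I_b + S_g, b2 = d_i + d_f, b3 = d_i·d_f − B̂·Ĉ,
b4 = S_i·G_b·Â, where Â, B̂, Ĉ are the equilibrium sensitivities of
glucose-stimulated secretion (Â < 0 as written, so b4 < 0), FFA-stimulated
secretion (B̂ ≤ 0) and insulin inhibition of lipolysis (Ĉ ≥ 0). The
implementation is validated against a complex-step numerical Jacobian of
the vector field rather than against intermediate algebra: some
sensitivities are ~1e−8 against function values ~1e1, where ordinary
central differences lose most significant digits to cancellation.

* **τ = 0:** Routh–Hurwitz for the cubic — all coefficients positive and
  (b1+b2)(b1b2+b3−b4) > b1b3 − d_f·b4.
* **Any τ:** a delay-induced instability requires a purely imaginary root
  ±iω; substituting λ = iω reduces Δ = 0 to the cubic
  p(u) = u³ + c2u² + c1u + c0 in u = ω², with

      c2 = (b1+b2)² − 2(b1b2+b3)
      c1 = (b1b2+b3)² − 2b1b3(b1+b2) − b4²
      c0 = (b1b3)² − (b4·d_f)²

  If p has no positive root the equilibrium is stable for *every* delay.
  c2, c1, c0 > 0 is a sufficient condition (Descartes) and is reported
  separately (`descartes_sufficient`) from the exhaustive numerical root
  check (`positive_u_roots`, via companion-matrix eigenvalues; a root
  counts as positive real when |Im| < 1e−9·max(1, |Re|) and Re > 1e−12),
  because coefficient positivity is sufficient but not necessary.

All eight packaged group archetypes satisfy the sign criterion, and the
verdict is confirmed dynamically: perturbed simulations return to basal
for τ = 0, the fitted τ, and 5× the fitted τ.

**Reproducibility caveat.** The published stability-coefficient table that
accompanies these parameter estimates cannot be reproduced numerically
from the printed parameter values under *any* choice of basal levels: for
the control group (d_f = 5.8/min, d_i = 0.072/min) the identity
c2 = b1² + b2² − 2b3 forces c2 ≳ 33 regardless of (G_b, I_b, F_b), against
a printed value of 0.0226, and the remaining groups deviate by 15% to two
orders of magnitude. The table was evidently computed from parameter
values that differ from the printed estimates. The package therefore
treats the *qualitative* verdict — all coefficients positive in every
group, hence delay-independent stability — as the reproducible result, and
reports its own solved-equilibrium coefficient values alongside it.

## Simulation

The DDE is integrated by the method of steps: on each interval
[kτ, (k+1)τ] the lagged glucose is a known function (the dense interpolant
of the previous segment, or the constant history), so each segment is an
ODE solve. Segments restart the adaptive solver (LSODA, rtol 1e−8,
atol 1e−10 by default), which respects the derivative discontinuities that
propagate from t = 0 to multiples of τ. Lagged values come from the
solver's own dense interpolant. τ = 0 degrades to a single ODE solve.

**History convention.** The pre-bolus history is a constant glucose level,
configurable per call and defaulting to the initial glucose. The dataset
generator and the fitting layer pass the model's solved basal glucose G_b
instead: physiologically the subject sits at the fasting steady state
until the bolus elevates G at t = 0, and this choice preserves the
delay's observable signature (secretion responds to pre-bolus glucose for
the first τ minutes). With an elevated-history convention the lagged Hill
term is saturated from t = 0 onward and τ becomes practically
unidentifiable from IVGTT data (the fit objective varies by <2% over
τ ∈ [0, 30] at 5% noise). Because the bolus makes G discontinuous at
t = 0, the lagged term at s = 0 takes the post-bolus trajectory value, not
the history value (right-continuity); the integrator and the fixed-step
reference implementation in the tests both follow this convention, which
matters at the 1e−4 accuracy level near t = τ.

The bolus itself is not modelled as an input term: trajectories start from
a post-bolus elevated glucose (default 3×G_b with insulin and FFA at
basal, configurable), matching how IVGTT models are conventionally fitted
from the t = 0 sample.

## Synthetic data generator

The generator emulates group-averaged IVGTT series: simulate the delay
model from the bolus state on the clinical protocol grid (draws at 2, 3,
4, 5, 6, 8, 10, 12, 14, 16, 19, 22, 25, 30, 40, 50, 60, 70, 80, 100, 120,
140, 160, 180 min, plus the t = 0 row), prepend three pre-bolus baseline
rows (−15, −10, −5 min) as noisy copies of the basal state flagged
`pre_bolus`, and apply observation noise. Default noise is multiplicative
lognormal with a 5% coefficient of variation per series — plasma assays
have roughly constant CV — with an additive-Gaussian alternative;
observations are floored at 1e−6 to preserve positivity. The generating
parameters, initial state, history and noise specification are recorded on
the dataset (`truth`) whenever it is synthetic.

What the generator does *not* emulate: between-subject heterogeneity
(group-averaged curves only), assay-specific error structure,
within-protocol timing jitter, and the true post-bolus peak magnitudes of
any particular cohort (the bolus multiplier is a free setting, not a
fidelity claim). Passing recovery tests therefore demonstrate internal
consistency of the estimation machinery under the stated noise model, not
performance on clinical data.

## Estimation and model comparison

Fitting minimizes a weighted residual sum of squares over the G, I, F
series jointly; each series' residuals are divided by that series' data
mean so the three contribute comparably despite unit disparity (raw RSS
would be glucose-dominated). Initial conditions are taken from the data at
t = 0; only post-bolus rows enter the loss. The optimizer is SciPy's
trust-region reflective bound-constrained least squares with Jacobian
column scaling, started from a seeded Latin-hypercube sample of the box
constraints (log-spaced in each positive parameter, linear in τ); the best
start wins, with ties broken by lower cost then lexicographically smaller
parameter vector, making fits bit-for-bit reproducible given (data,
bounds, seed, n_starts). τ is estimated on a continuous scale within
[0, 30] min, re-integrating the DDE per candidate. Simulation failures
inside the objective return a large finite penalty instead of raising.
Objective simulations run at rtol 1e−6 (atol 1e−8) — accurate to far below
the 5% observation noise — and can be tightened per call.

Only a declared subset of parameters is freed per fit (defaults:
S_i, S_g, d_i, σ1, τ for the delay model; S_G, S_I, c_X, c_f, X2 for the
minimal model); the rest stay frozen at the supplied base values, and k in
AIC counts only the freed parameters. Freeing all 16 delay parameters
against a single averaged IVGTT series is not meaningfully identifiable
and is deliberately not the default.

AIC uses the Gaussian least-squares form AIC = n·ln(RSS/n) + 2k per
series, in native units, with totals formed by summation. Since the
absolute AIC values depend on this convention (the source analysis states
none) only the *ranking* of the two models is treated as meaningful, and
the packaged comparison study checks the direction: on data generated by
the delay model, the fitted delay model attains lower total AIC than the
fitted minimal model in ≥ 8/10 seeded replicates.

The recovery study (analysis/03) uses the IFG pre-surgery archetype
because its parameter configuration makes the targets structurally
identifiable: S_i is large enough that insulin-mediated removal competes
with S_g (for the control archetype S_i ≈ 1e−7 contributes ~0.01% of
glucose clearance and no estimator could recover it), and the secretion
delay acts in a sensitive region of the Hill response. Study sizes
(10 replicates, 3 multistarts, 25 time points) are chosen to give stable
medians at interactive runtimes.

## Numerical choices, edge cases, limitations

* Hill evaluation uses the ratio form 1/(1 + (K/x)ⁿ) to avoid overflow at
  large xⁿ; h(0) = 0 exactly.
* σ1 and σ2 may be zero (pathway knockouts for closed-form checks); all
  other rates and thresholds must be strictly positive, Hill exponents
  ≥ 1, τ ≥ 0.
* Positivity of simulated trajectories is checked at output time points;
  violations raise with the offending time.
* The equilibrium consistency guard in the stability layer refuses basal
  states whose vector-field residual exceeds 1e−6, preventing
  stability verdicts at non-equilibria.
* The units of σ2 (1/min) are inconsistent with an insulin-production term
  dimensionally; they are implemented as defined in the parameter tables.
* Critical-delay computation (solving for the ω, τ pairs when p(u) *does*
  have a positive root) is out of scope; the package reports the candidate
  u-roots only.
* The two-phase ("double peak") insulin pattern seen in some clinical
  IVGTT series arises, in this model class, only for parameter/initial
  configurations in the sensitive region of the glucose Hill response; the
  packaged archetypes with near-saturated secretion produce a single
  insulin peak.
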