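# Methods

## Model and decision rule

We consider two observed real-valued variables where one causes the other
without confounding, written E = φ(C) + αN after defining φ(c) = E[E|c]
and N = E − φ(C) (so E[N|c] = 0 by construction; N need *not* be
statistically independent of C). The analysis assumes:

1. **Invertible mechanism** — φ: [0,1] → [0,1] strictly increasing, twice
   differentiable, φ(0)=0, φ(1)=1, with bounded inverse derivative.
2. **Compact supports** — C attains 0 and 1 as extremes; the conditional
   noise support is contained in [n₋, n₊] with n₋ < 0 < n₊, so the effect
   support is [αn₋, 1+αn₊] and the shifted/rescaled effect
   Ẽ = (E − αn₋)/(1 + αn₊ − αn₋) is scaled like C.
3. **Unit noise variance** — E[Var[N|C]] = 1 (the level is carried by α).
4. **Independence postulate** — the functions c ↦ φ′(c) and
   c ↦ Var[N|c]·p_C(c) are uncorrelated under the uniform measure on
   [0,1]. This is the asymmetry-generating assumption; it is weaker than,
   and distinct from, statistical independence of C and N.

Under 1–3 the anticausal/causal ratio of expected conditional variances
converges as α → 0 to I(φ) = ∫₀¹ Var[N|c] p_C(c) / φ′(c)² dc, and under 4
additionally I(φ) ≥ 1 with equality only for linear φ. The decision rule
follows: scale both variables, estimate both conditional expectations by
least squares within a chosen function family, and declare the direction
with the smaller run-averaged held-out MSE. The confidence score is
ξ = 1 − min(e₁,e₂)/max(e₁,e₂) ∈ [0,1]; a threshold t on ξ optionally
converts uncertain cases into "no decision" (t = 0 reproduces the plain
rule exactly — this identity is verified on 50 simulated pairs by the
acceptance script).

The theory is a small-α limit statement. How large α may grow before the
asymmetry inverts depends on φ, p_C and the noise profile in a complicated
way; the convergence report surfaces per-mechanism behavior over a noise
grid but deliberately does not adjudicate a universal threshold.

## Estimation protocol

- **Scaling.** Min-max normalization to [0,1] by default (matching
  assumption 2); z-scoring (population convention, divisor n) as the
  alternative for unbounded or heavy-tailed data. Scaling is applied to
  both variables before any regression, and re-applied to the survivors of
  the density filter so the working domain stays [0,1].
- **Density filter (optional).** A bivariate Gaussian KDE (plug-in "scott"
  bandwidth by default) is evaluated at each sample point; points with
  joint density below a threshold (default 0.1, against the density
  normalized to integrate to 1) are removed. This reduces the influence of
  isolated outliers on the MSE but can underestimate heavy-tailed noise.
  The threshold's meaning depends on the density normalization convention;
  with strongly concentrated data the absolute densities are large
  everywhere and the default threshold removes little — both the threshold
  and the bandwidth rule are configurable.
- **Splits and averaging.** Each of n_runs (default 100) runs draws one
  random train/test partition (train fraction 0.7 by default; 0.5 and 0.3
  are the supported alternatives), fits the family in both directions on
  the training part, and records both test MSEs. Run MSEs are averaged
  per direction *before* comparison; the per-run split is a pure function
  of (seed, run index), so runs are reproducible and order-free. For the
  expensive families (linear-kernel SVR, neural networks) each run first
  draws a uniform 500-point subsample without replacement.
- **Family selection.** Every polynomial degree (1–9), monomial exponent
  (2–9) and network layout is a separate candidate. The selected candidate
  minimizes the *sum* of the two direction-averaged test errors. Summing
  keeps the criterion direction-symmetric, so model selection cannot leak
  the answer; ties break by candidate order. Whether to select per dataset
  across families, split ratios, or both jointly is genuinely open; the
  symmetric per-dataset sum is this package's choice.
- **Regression families.**
  - LOG: a + (b−a)/(1+exp(c(d−x))), fitted by nonlinear least squares
    (Levenberg–Marquardt with a trust-region fallback), 5 seeded restarts,
    best training MSE wins.
  - MON: a·xⁿ + b is linear in (a, b) and solved exactly by linear least
    squares — no iteration or restarts needed.
  - POLY: ordinary polynomial least squares.
  - SVR_LIN: linear-kernel support vector regression with fixed
    hyperparameters (regularization 1.0, tube width 0.1), exposed in the
    spec object.
  - NN: dense feedforward networks with logistic activations, full-batch
    quasi-Newton (L-BFGS) training, 2,000-iteration budget, seeded
    initialization. The layout menu is 2, 5, 10, 20, 2-4, 4-8 hidden
    units. The training recipe is fixed here so fits are reproducible;
    simple families that underfit are often *good* for this task, since
    underfitting tends to penalize the anticausal direction more.
- **Ties.** Exact equality of the two averaged errors yields "no
  decision"; no tolerance band is applied (exact ties have measure zero on
  continuous data).

## Synthetic generators

### Dependent-noise suites

These emulate a worst case for independence-based methods: cause and noise
share hidden sources. Per dataset: weights w₁, w₂ ~ U(0,1); two sources
S₁, S₂ drawn i.i.d. from a menu (uniform on [0,1]; Gaussians with spread
σ ~ U(0.5, 1.5) drawn once per dataset; a two-component Gaussian mixture
at means 0.3/0.7 with spread 0.1), each mean-centered; then

    C′ = w₁·f₁(S₁) + (1−w₁)·f₂(S₂),   N′ = w₂·f₃(S₁) + (1−w₂)·f₄(S₂),
    C = minmax(C′),   N = α·standardize(N′),   E = φ(C) + N,

with f₁..f₄ drawn independently from {identity, exp, s₅ ∘ minmax} and s₅ a
random convex combination of five Gaussian CDFs (component weights uniform
then normalized to sum 1; means uniform on [0,1]; spreads uniform on
(0, 0.1]). The mechanism φ is the identity (Linear suite), a fresh s₅
(Invertible suite), or one of rescale(·,−2,2)², rescale(·,−2,2)⁴,
sin(rescale(·,−2π,2π)) (Non-invertible suite; mechanism outputs are not
rescaled before the noise is added, matching the generating equations).
Standard suites use 100 datasets per α with grids 0–1 in steps of 0.1
(Linear, Non-invertible) and 0.025 (Invertible); all overridable.

What this emulates — strong cause/noise dependence, arbitrary monotone
mechanisms, heavy-tailed marginals (the exp menu entry produces causes
whose min-max scale is set by single extreme points). What it does not —
measurement noise on the cause, confounders beyond the shared sources,
discrete or ordinal marginals, and sample-size heterogeneity of real
benchmark collections. Passing tests on these suites therefore shows the
method behaves as the theory predicts *under the stated generative
assumptions*, not that real-data accuracy will match. On the Invertible
suite at α = 0.05 the heavy-tailed menu makes a substantial fraction of
datasets effectively scale-degenerate, and direction recovery with
polynomial candidates runs at roughly 60% (about 75% under z-scoring) —
for comparison, a flexible k-nearest-neighbor regression oracle reaches
80% on the same data, which bounds what any regression-error comparison
can achieve there.

### Theorem regime

E_α = φ(C) + αN with φ from a registry of named mechanisms (linear;
(c+c²)/2; (c+c³)/2; normalized exponential; a gentle sinusoidal
perturbation of the identity whose slope stays within [1−0.2π, 1+0.2π]),
C from any [0,1]-supported distribution (uniform by default), and N|c
uniform on [−√3·s(c), √3·s(c)] — the simplest compact-support law with a
controllable variance profile. The supplied profile s(·) is renormalized by
quadrature so E[Var[N|C]] = 1 exactly (assumption 3); the generator record
retains φ, φ′, the renormalized profile, the cause density and the noise
support bounds for the theory module.

## Numerical verification

- **Quadrature.** Composite Simpson on uniform grids (default 10,001
  points) for I(φ), the normalization identity ∫φ′·Var[N|c]·p_C dc = 1 and
  the postulate covariance. A Richardson-style refinement check (half vs
  double grid) flags non-stabilizing integrals — e.g. mechanisms whose
  slope vanishes inside the interval, making 1/φ′² non-integrable — rather
  than regularizing them.
- **Conditional variances.** Estimated by equal-count (quantile) binning:
  sort on the conditioning variable, split into bins of equal counts
  (default 100 at n = 2×10⁵), average within-bin variances with
  bin-probability weights. Binning is chosen for transparency; its floor
  is the within-bin variation of the conditional mean, ≈ E[φ′²]·w²/12 for
  bin width w, which is ~2% of α² at the default settings. Monte-Carlo
  standard errors use the distribution-free large-sample variance of a
  sample variance, (m₄ − v²)/n per bin, propagated to the ratio to first
  order.
- **Finite-α bias.** The rescaled effect Ẽ divides the causal conditional
  variance by (1 + α(n₊ − n₋))², so the empirical ratio exceeds its limit
  by roughly that factor (≈ (1 + 2√3·α)² for uniform noise), partially
  offset by support-edge truncation of the anticausal variance. At
  α = 0.02 the linear equality case therefore measures ≈ 1.105, not 1;
  the equality case is asserted at α = 0.01 (≈ 1.05) together with the
  monotone decay of the bias across 0.05/0.02/0.01. No extrapolation to
  α = 0 is attempted.
- **Bound check.** A convergence report marks the theorem's bound satisfied
  when the smallest-α ratio is ≥ 1 − 2 Monte-Carlo standard errors.

## Problem sizes

Defaults were chosen to make every check sharp at interactive run times on
one CPU: n = 2×10⁵ samples and 100 bins for conditional-variance
estimates (binning floor ≪ sampling error), 10,001-point quadrature grids
(Simpson error far below the 10⁻⁹ tolerances used), 50–100 datasets of
n = 500 for suite-level decision checks with 10 splits per dataset. The
full test suite runs in well under a minute; the acceptance script in a
few seconds.

## Known limitations

- The theory is asymptotic in α; nothing is claimed for strong noise, and
  the package intentionally reports (rather than hides) finite-α bias.
- Linear mechanisms are undecidable by construction (the equality case);
  near-linear mechanisms yield low confidence.
- Heavy-tailed marginals undermine the min-max scaling convention that the
  error comparison relies on; z-scoring and density filtering mitigate but
  do not remove this, and the KDE threshold's effect depends strongly on
  how concentrated the data are.
- Only the bivariate unconfounded setting is addressed: no confounder
  detection, no multivariate pairs (such files are rejected on read), no
  significance testing of decisions.
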