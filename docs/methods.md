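# Methods

## Model

Observations live on an equal-interval age–period grid: age group
`i = 1..I`, period group `j = 1..J`, cohort `k = j − i + I`,
`K = I + J − 1`.  The likelihood is Gaussian,

```
y_n ~ Normal(b0 + bA_i + bP_j + bC_k, σ),   n = 1..N,
```

with hard sum-to-zero constraints on each effect block.  Centering the
indexes (`v_m = m − (M+1)/2`) makes the identification problem explicit:
`vA − vP + vC = 0` cell-wise, so the slope of each block on its centered
index is free to move by a common shift `s` (age `+s`, period `−s`,
cohort `+s`) without changing any fitted mean.  Only the orthogonal
residuals after regression on the centered index — the *nonlinear*
components — are likelihood-identified.

Three priors close the model:

* **random effects** — `bX_m ~ N(0, σX)` independently within each block,
  one scale per block.  Log-prior (constants dropped):
  `−Σ_X M_X log σX − ½ Σ_X ||bX||²/σX²`.
* **ridge** — the same with a single shared scale λ; equivalent in effect
  to the intrinsic estimator's minimum-norm allocation.
* **random walk** — first differences `bX_{m+1} − bX_m ~ N(0, σX)`;
  log-prior `−Σ_X (M_X−1) log σX − ½ Σ_X ||diff(bX)||²/σX²`.

Rewriting each prior through the slope/residual decomposition shows the
mechanism (implemented and property-tested as `log_prior_re_indexed` /
`log_prior_rw_indexed`): magnitude shrinkage penalizes the block slopes
with weights `Σ vX² = M(M+1)(M−1)/12`, difference shrinkage with weights
`M − 1`.  The cohort block is always the longest, and the ratio of its
weight to the period weight exceeds the random-walk ratio by
`(K−1)(2J+I)(I−1)/[J(J+1)(J−1)] > 0` for every grid
(`index_weight_gap`), so magnitude-shrinkage priors flatten the cohort
trend disproportionately.

Hyperpriors on `σ, σA, σP, σC, λ` are flat (improper uniform) on their
allowed ranges and contribute nothing to the log-posterior; the three
models therefore differ only through the effect priors above.  Lower
bounds on the scales are part of the model specification: 0.05 for the
random-effects block SDs (without it the flat prior puts a log-divergent
spike at σX → 0, and the bounded model is the one whose behaviour the
systematic study documents), and a numerical floor of 1e-3 elsewhere
(the random-walk scale posterior is proper at 0 but collapsed blocks
would otherwise drive the effect-precision matrix toward singularity;
1e-3 is two orders of magnitude below the effect scales of interest, so
it acts as "effectively zero").  The likelihood SD has the same 1e-3
floor.  Random-walk fits require every block length ≥ 3: for a length-2
block the flat-prior scale conditional is improper.

## Sampler

The posterior is conditionally conjugate and is sampled by a blocked
Gibbs scheme, all chains advanced together through batched linear
algebra:

1. **effects | scales** — one joint Gaussian draw of `(b0, free effect
   coordinates)`.  Each block is parameterized by its first `M − 1`
   entries with the last the negative partial sum, so sum-to-zero holds
   exactly on every draw and the level of each block stays identified
   against `b0`.  Replicates collapse into per-cell counts and sums, so
   the draw costs one Cholesky of a `P × P` precision
   (`P = I + J + K − 2`).  Because the draw is joint, the unidentified
   shift direction is resampled in one step.
2. **σ² | effects** and **scale² | effects** — inverse-gamma conditionals
   implied by the prior forms above, truncated at the lower bounds and
   sampled exactly by inverse CDF in the gamma domain
   (`gammaincinv`), which stays accurate when a truncation is deep.
3. **collapsed scale moves** (every 8th iteration) — the magnitude-
   shrinkage posteriors are genuinely multimodal on trend-bearing data:
   on a 10×10 grid with a pure cohort trend (slope 0.1, cosine amplitude
   0.05) the "cohort flattened" and "cohort kept" modes are separated by
   a ≈ 14-nat density barrier, with roughly 89% of mass on the flattened
   mode (checked by direct quadrature of the effects-marginalized
   density).  Conjugate Gibbs cannot cross such a barrier, so all prior
   scales are additionally updated jointly by independence Metropolis:
   the effects-marginalized density (a closed-form Gaussian integral) is
   tabulated once per fit on a regular grid in log-scale space at a
   plug-in σ̂ from the within-cell variance, proposals draw a grid cell
   by weight and jitter uniformly inside it, and acceptance uses the
   exact marginal at the chain's current σ.  The move is exact for any
   grid resolution; the grid only shapes the proposal.

Steps 1–3 compose into a valid (partially collapsed) Gibbs sampler:
marginalized scale updates always precede the effects redraw.

Fitting protocol: 4 chains × 2000 iterations, 500 warmup, post-warmup
draws thinned by 3 (500 kept per chain, 2000 pooled), deterministic given
the configuration seed.  Convergence requires classical split-R̂ < 1.05
for every sampled parameter (each chain halved; between/within variance
ratio; rank normalization is deliberately not applied so the diagnostic
matches the era of the protocol).  Point estimates are coordinate-wise
pooled posterior medians; because coordinate medians do not satisfy the
sum-to-zero constraint exactly, each block is recentered and the means
folded into the intercept — a pure reparameterization that changes
neither fitted cells nor the bias statistic.

## Synthetic data

Effect vectors are built as `β_m = β0 + slope·v_m + amp·cos(πm)` per
block.  The cosine alternation is used for the nonlinear component
because it carries (almost) no linear component, can be dialed
independently of the slope, and deliberately matches none of the priors.
`cos(πm)` is computed as `(−1)^m` exactly.  For odd block lengths the
intercept correction `β0 = −amp(cos(πM) − 1)/(2M)` restores exact
zero sums.  The cosine is *not* exactly orthogonal to the centered index
on even-length blocks: the leaked slope is `amp·|Σ v·(−1)^m|/Σv²`
(≈ 0.0030 at amplitude 0.05, M = 10).  The generator documents and keeps
this leakage rather than correcting it; recovery tests bound slope errors
by it.

Study conditions: `I = J = 10`, 10 replicates per cell (`N = 1000`),
noise SD `γ = 0.1` — small against structured components of size 0.1.

* **Systematic study** (13 cases): sign patterns over the three effects,
  `+` = slope 0.1 with amplitude 0.05, excluding the all-zero triple and
  global sign flips; one seeded dataset per case, shared by all three
  models.  Per-case seeds derive from `(seed, case)`, so restricting the
  case list never changes the remaining datasets.
* **Replicated study 2**: slopes and amplitudes drawn
  `Normal(0, variance 0.1)` — linear-only and nonlinear-only patterns
  equally likely.  The 0.1 is a variance (component SD `√0.1 ≈ 0.316`):
  with SD-0.1 draws the aggregate bias δ of both replicated studies comes
  out an order of magnitude below its documented scale, while
  variance-0.1 draws reproduce it (the likelihood noise γ = 0.1 is an SD;
  the systematic-study results pin that down independently).
* **Replicated study 3**: per effect, amplitude `~ Normal(0, var 0.1)`
  then slope `~ Normal(0, SD |amplitude|)` — near-pure-linear patterns
  become 5-sigma events, matching the premise of estimating linear
  components from nonlinear ones.  Coupling every slope to the *age*
  amplitude instead (`literal_coupling=True`) is kept as an option but is
  not the default: it reintroduces cohort-linear-only patterns and
  erases the random-walk model's advantage that the study design is
  meant to expose.
* **Polynomial generator** (applicability check): centered random
  polynomials `η = Σ_h w_h z_h` with standardized power columns of the
  centered index; `w_h ~ Normal(0, 0.1)` (scale-free for the gray-area
  frequencies of interest).  Low degree (H = 2) produces near-pure-linear
  draws routinely; H = 8 essentially never.

What the generator does *not* emulate: unequal interval widths,
non-Gaussian outcomes, heteroscedastic noise, and empirically realistic
effect shapes.  Passing tests demonstrate recovery behaviour of the
priors under controlled linear/nonlinear mixes, not performance on real
surveillance data.

## Bias evaluation

`solve_s` returns the closed-form minimizer of
`f(s) = Σ[estA − (βA + s·vA)]² + Σ[estP − (βP − s·vP)]² +
Σ[estC − (βC + s·vC)]²`; grades band `|s|` at 0.02/0.04/0.06/0.08
(strict upper bounds — a value exactly at a boundary takes the weaker
grade).  Replicated studies report `δ = mean(s²)` over converged runs
only (`T` is the converged count), with a Monte-Carlo half-width
`3·SD(s²)/√T` estimated from the run itself.  δ is heavy-tailed —
dominated by rare large-|s| replicates — so reduced-scale runs carry wide
bands.

## Problem sizes and numerical choices

The test suite runs the replicated studies at 100 replicates (the
package's reduced desk scale; full 500-replicate runs take hours) and the
systematic study at its natural size.  A 4-chain protocol fit takes well
under a second on one core.  Degenerate inputs are rejected early:
grids need `I, J ≥ 2`, decompositions need two points, δ of an empty
converged set raises, and dataset construction validates the cohort
identity row-wise.  Sum-to-zero violations beyond 1e-8 on construction
raise rather than being silently re-centered.

## Known limitations

* The random-effects posterior is honestly bimodal on trend-bearing
  data; reported medians summarize the full mixture.  Samplers that
  cannot traverse the modes (including the common single-mode HMC runs)
  will report mode-conditional values instead — on replicates where
  chains agree within a wrong mode, such values pass the R̂ screen and
  inflate δ relative to this package's estimates.
* Flat hyperpriors make the ridge scale posterior improper at λ → 0 in
  principle; the 1e-3 floor removes a region whose posterior mass is
  astronomically small, but alternative hyperpriors would change the
  scale posteriors more visibly than the effect posteriors.
* Only Gaussian likelihoods and equal-interval grids are supported.
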