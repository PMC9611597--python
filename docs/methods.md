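# Methods

This note records the statistical model, the algorithmic and numerical
choices the implementation makes where several defensible options exist,
what the synthetic-data generator does and does not emulate, and the
known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Classification stage (k-modes)

Respondents are classified on ten nominal items with simple matching
distance (count of mismatching items, 0–10). The algorithm is primed
with five fixed initial modes (more / less / modal / autonomous / other
empowered) rather than random observations, so clusters retain their
substantive interpretation; k = 5 is fixed a priori.

Choices made where the method family leaves freedom:

* **Batch iteration.** Assignment and mode-update passes alternate over
  the whole sample (Lloyd-style) rather than Huang's online single-pass
  update. Batch iteration is deterministic and order-independent; with
  the tie-breaks below, permuting respondents provably leaves the
  converged solution unchanged.
* **Tie-breaks.** Equal distance to several modes → lowest mode index.
  Plurality ties in the mode update → lowest level in the declared level
  order (the order is part of the item registry contract).
* **Empty clusters** are reseeded with the observation farthest from the
  empty cluster's current mode, preserving k.
* **Missing data** are rejected at input (complete-case contract); the
  missing-as-level variant of k-modes is therefore unreachable.
* **`no_earnings`** on the spending item is kept as its own nominal
  level; collapsing it into another level would be an unstated transform.

Convergence is guaranteed (finite label space, non-increasing cost). The
converged state is coordinate-wise optimal — every respondent sits at a
nearest mode, and each mode is item-wise optimal for its members (checked
by brute-force enumeration in the tests). Like Lloyd's k-means, the
batch algorithm is *not* in general optimal against a single relabelling
combined with mode recomputation; the tests exhibit this distinction
rather than papering over it.

## Map stage

Per PSU the counts over categories 1–3 are converted to proportions
(categories 4–5 excluded from numerator and denominator; PSUs with no
dominant-category respondents are flagged) and blended as
(r, g, b) = round(255·(p2, p3, p1)). The map artifact is a data table
(PSU, proportions, hex colour); no cartographic projection handling is
attempted.

## The multinomial STAR model

Three-category multinomial logit with reference category 3 and, for
k = 1, 2, predictor η = Xβ_k + f_k(age) + b_k + s_k. Priors: flat β;
cubic B-spline f_k with second-order random-walk (RW2) prior; iid PSU
effects; intrinsic MRF (ICAR) region effects; IG(0.001, 0.001) on all
three variances, independently across k.

**Spline basis.** The age span [min, max] observed is divided into 20
equal intervals; boundary knots are extended outward with the same
spacing, giving M = 20 + 3 = 23 cubic basis functions that form a
partition of unity on the span. Ages outside the span (possible when a
basis is reused) are clamped to the boundary with a warning. The RW2
penalty K = D₂'D₂ has rank M − 2 with null space spanned by constant and
linear trends in knot position.

**Sampler.** Gibbs with exact Pólya-Gamma augmentation. Each category k
is reduced to a Bernoulli-logit problem by conditioning on the other
category's predictor (partial-logit / Holmes–Held reduction):
Y_ik ~ Bernoulli(logistic(η_ik − c_ik)) with
c_ik = log Σ_{l≠k} exp(η_il). Augmenting ω_i ~ PG(1, η_ik − c_ik) makes
the updates for β (flat prior = zero prior precision), γ (RW2), b
(diagonal) and s (dense J×J Cholesky) conjugate Gaussians, and the
variance updates conjugate inverse-gamma — no tuning parameters. The
PG(1, z) variates come from the exact Devroye alternating-series
rejection sampler implemented in-package and JIT-compiled with numba;
its correctness is pinned by closed-form moment identities
(E = tanh(z/2)/2z, Var(PG(1,0)) = 1/24) and by agreement of the full
sampler with a deterministic 2-D quadrature oracle on an intercept-only
model.

**Identifiability.** After each sweep the sampled spline curve and the
region effects are mean-centred, with the means absorbed into the
intercept (the basis rows summing to one makes the γ shift exact). The
spline's linear null-space component is deliberately left in f_k rather
than reallocated to a slope covariate. Every retained draw satisfies
Σ_j s_jk = 0 to numerical precision.

**Degenerate inputs.** A non-positive-definite conditional precision or
a non-finite deviance aborts the run with a diagnostic; a disconnected
region graph is rejected up front naming the components (the ICAR prior
assumes one connected component; islands would need their own constraint).

**Initialisation** is neutral (all effects 0, variances 1); the
augmentation variables are drawn first, and burn-in absorbs the start.
Multi-chain runs offset the seed by a fixed stride per chain.

**DIC** uses p_D = D̄ − D(θ̄) with D(θ̄) the plug-in deviance at the
posterior means of every block entering η (Spiegelhalter's definition).
Posterior summaries are medians and 2.5/97.5% quantiles with linear
(type-7) interpolation; odds ratios exponentiate the endpoints, exact by
monotonicity.

## Diagnostics

Geweke z compares the first 10% of the chain against the last 50%, with
variances from a spectral-density-at-zero estimate using a Bartlett lag
window truncated at 4% of the segment length (a constant segment is an
error — zero spectral density). The Gelman–Rubin PSRF follows the
classical between/within variance decomposition with the
degrees-of-freedom correction and an F-quantile 97.5% upper limit;
the multivariate PSRF (Brooks–Gelman) summarises the 2×8 fixed-effect
block. Default pass thresholds: |z| < 1.96, PSRF upper < 1.02.

## Synthetic-data generator

The generator emulates the survey's nesting and anonymisation: a rook
lattice stands in for the region adjacency graph; PSUs are placed
uniformly within their region cell and then displaced in a uniform
direction by a uniform distance up to 2 km (urban) or 5 km (rural),
converted at 111.32 km/degree (no cos-latitude correction — the jitter
caps, not geodesy, are the contract). Each PSU's respondent count is
uniform on a configurable range, [15, 100] by default. Covariates
default to age ~ uniform 15–49, urban ~ Bernoulli(0.4) at PSU level, and
configurable education/income compositions that may vary by region — the
deliberate confounding switch used to check that the model separates
composition from the structured spatial effect. Region effects are drawn
from the intrinsic GMRF (eigen-decomposition of the graph Laplacian,
sampling in the positive eigenspace, which enforces the sum-to-zero
constraint); category labels follow the multinomial logit; items are the
category's response template with independent per-item flip noise ε
(default 0.05) to a uniformly chosen different level. By default only
the three dominant categories are generated; a flag adds small
autonomous/other shares to exercise the full k = 5 clustering.

What the generator does **not** emulate: real administrative geography,
sampling weights (the analysis is unweighted throughout, consistent with
a model containing none), non-response (complete cases only), and any
item-response structure beyond template-plus-noise. Passing recovery
tests therefore show the estimator is correct *under its own model
family* with realistically sized, noisy, hierarchically clustered data —
not that the substantive findings from any restricted real dataset are
reproduced.

## Validation studies and problem sizes

The studies in `empowermap.validation` (used by the tests and the
reproduction script) run at desk scale, chosen so each completes in
minutes on one CPU with Monte-Carlo error well below the effects checked:

* **Quadrature oracle** — intercept-only model, n = 40, 20,000 retained
  sweeps vs an 801² trapezoid grid; agreement within 3 batch-means
  standard errors.
* **Recovery study** — 5 replicate surveys (J = 20 regions, 4 PSUs per
  region, 15–30 respondents per PSU, ≈1,800 respondents), 10,000
  iterations / 2,000 burn-in / thinning 10; reports coverage of the 16
  fixed-effect 95% intervals and region-effect correlation.
* **Directional full-vs-null study** — J = 16, 5 PSUs per region,
  4,000 / 1,000 / 10. The generating region effect here is a
  deterministic ±1.2 diagonal gradient rather than a random intrinsic
  draw: on a 16-region lattice a single ICAR draw is not reliably
  spatially autocorrelated, so a gradient guarantees the premise
  ("spatially structured effect") that the directional claims — full
  model preferred by DIC, residual Moran's I reduced — are about.

Moran's I of PSU effects is reported in two labelled weighting modes,
because the aggregation is a genuine analysis choice: region-median
aggregation with first-order region adjacency (primary), and direct
PSU-level symmetrised 10-nearest-neighbour binary weights.

## Known limitations

* The sampler is single-threaded; multi-chain runs are sequential.
* The region-effect update is a dense J×J Cholesky per sweep — fine for
  J in the hundreds, wasteful for very large lattices (a sparse solver
  would be the next step).
* The intrinsic-MRF conditional-mean property ("slope 1" against the
  neighbour average) holds exactly only for the unconstrained prior; the
  sum-to-zero constraint attenuates the pooled regression slope on small
  graphs (closed form 0.879 on a 4×4 lattice, 1.000 on 10×10), and the
  tests assert the closed-form value rather than the idealised one.
* Batch k-modes is not 1-swap optimal (see above); exact reproduction of
  any particular real-data cluster sizes is not claimed.
* DIC is the only model-comparison criterion implemented (no WAIC/LOO),
  matching the analysis design this package supports.
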