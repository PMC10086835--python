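# Methods

`ostreg` fits ordinal-on-ordinal state-trait regressions for intensive
longitudinal data (experience sampling, ecological momentary assessment).
This note records the model, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Model

Data are repeated ordinal measurements nested in subjects: for subject
*i* = 1..*I* and occasion *j* = 1..*J<sub>i</sub>*, an ordinal predictor
*x<sub>ij</sub>* ∈ {1..*M<sub>x</sub>*} and an ordinal response
*y<sub>ij</sub>* ∈ {1..*M<sub>y</sub>*}.  The subject's *trait* level is the
median x̃<sub>i</sub> of their own predictor values; the current value
*x<sub>ij</sub>* is the *state*.  Medians rather than means keep the trait on
the ordinal scale; ties in even-length samples are resolved to the lower of
the two middle order statistics so the trait is always an attained level
(the package's own convention — the upper or interpolated median would be
equally defensible, but only the lower/upper choices keep the trait inside
the level set, and lower is the common order-statistics default).

A continuous latent response

  ℓ<sub>ij</sub> = f(x̃<sub>i</sub>, x<sub>ij</sub>) + u<sub>i</sub> + ε<sub>ij</sub>

with u<sub>i</sub> ~ N(0, σ<sub>u</sub>²) and standard logistic
ε<sub>ij</sub>, is cut at increasing thresholds θ₁ < … < θ<sub>M_y−1</sub>
(anchored θ₁ = −1 for identifiability) to produce *y*.  Equivalently,
logit P(Y<sub>ij</sub> ≤ m) = θ<sub>m</sub> − f(x̃<sub>i</sub>, x<sub>ij</sub>) − u<sub>i</sub>.

The surface *f* lives on the key set K of trait-state pairs (r, s) that occur
in the data and decomposes as f(r, s) = α + τ<sub>r</sub> + γ<sub>r,s</sub>
with the structural constraints τ<sub>x̃</sub> = 0 (x̃ the global median) and
γ<sub>r,r</sub> = 0: τ measures between-person (trait) effects,
γ within-person (state) effects.  Constraints are implemented structurally
(the constrained parameters simply have no column).  If the global median is
not itself an attained trait level — impossible in the benchmark designs but
possible in principle — the constraint moves to the nearest attained level
(ties to the lower), keeping α identified.

When τ<sub>r</sub> ∝ (r − x̃) and γ<sub>r,s</sub> ∝ (s − r), the model
collapses to the classical three-coefficient between/within-person
disaggregation ℓ = β₀ + β₁(x̃<sub>i</sub> − x̃) + β₂(x<sub>ij</sub> − x̃<sub>i</sub>) + u + ε;
that is exactly the set of *f* linear in (r, s).

## Penalty

Unrestricted *f* has |K| coefficients and overfits rare cells; forcing
linearity may underfit.  The compromise is a ridge-type penalty

  J\*(f) = Σ (Δ<sub>rr</sub> f)² + 2 Σ (Δ<sub>rs</sub> f)² + Σ (Δ<sub>ss</sub> f)²,

the discrete analogue of the thin-plate bending energy, built from row-wise,
mixed, and column-wise second differences of *f* on the grid.  Each sum runs
over the windows whose every referenced cell occurs in the data; after
optional merging of rare cells, values are read through the merge map.
J\*(f) = 0 exactly when *f* is linear, and on the full grid only then (null
space dimension 3).  In coefficient space J\*(f) = ζᵀPζ with P = AᵀDᵀDA,
where A maps ζ = (α, τ, γ) to f values and D stacks the difference rows
(mixed rows pre-scaled by √2).  The penalized criterion is
ℓ(ζ, θ, σ<sub>u</sub>) − (λ/2) ζᵀPζ.

Rare-cell merging (off by default, `min_count=0`) assigns a cell with fewer
than `min_count` observations to the nearest (Chebyshev) well-populated
cell, preferring the same off-diagonal band s − r — where a linear surface
is constant — then bands nearer the diagonal, with deterministic ties.

## Estimation

* **Marginal likelihood.** The random intercept is integrated out by
  Gauss-Hermite quadrature.  The optimizer maximizes a fixed-node rule in
  the standardized scale u = σ<sub>u</sub>·z (21 nodes by default): the node
  positions depend on σ<sub>u</sub> only through an explicit scale factor, so
  the objective has exact analytic gradients in all parameters.  Reported
  log-likelihoods (and AIC) are recomputed with adaptive quadrature — 15
  nodes centered at each subject's posterior mode with curvature-matched
  scaling.  On the benchmark problems the two rules agree to ~1e−7, far
  below every comparison made with them; the fixed-node rule exists because
  the adaptive rule's gradient would require third derivatives through the
  mode equations.
* **Parametrization.** Cutpoints use θ₁ = −1 plus log-increments
  (monotonicity by construction); σ<sub>u</sub> enters as log σ<sub>u</sub>,
  bounded in [e⁻⁸, e⁸].
* **Optimization.** L-BFGS-B; deterministic initialization (θ from pooled
  cumulative response frequencies shifted so θ₁ = −1; ζ = 0; σ<sub>u</sub> = 1).
  Convergence: relative objective change < 1e−8 or projected-gradient max
  norm < 1e−6, max 500 iterations; non-convergence is flagged on the result,
  not raised.  Penalized problems are optimized in penalty-whitened
  coordinates (eigenvectors of P scaled by 1/√(1 + λd<sub>i</sub>)), which
  keeps the Hessian condition number bounded in λ and makes the λ → ∞ limit
  (the linear model) reachable at λ = 1e8.
* **Degenerate inputs.** Empty response categories raise (the adjoining
  cutpoints are unidentified); the study driver first collapses empty
  *extreme* categories, which is the only kind the generator produces.
  A subject's entire row block missing x or y is dropped with a warning.

## Shrinkage selection

λ is chosen on a log-spaced grid (default 10⁻²..10⁶, 17 points, descending
with warm starts) by a Laplace-approximate marginal criterion: treating the
penalized coefficients as random effects with implied prior
N(0, (λP)⁻) on the penalized directions and a flat prior on the null space,

  V(λ) = ℓ<sub>pen</sub>(ζ̂<sub>λ</sub>) + ½ rank(P) log λ − ½ log det(H + λP),

with H the negative Hessian of the unpenalized log-likelihood in ζ at the
estimate.  Ties break toward more shrinkage.  The study driver abandons the
descending path after two criterion values fall more than 0.5 below the
running best; the criterion is unimodal in λ in regular problems, so this
only prunes fits clearly past the peak.

## Complexity and AIC

The fixed-effect effective degrees of freedom are
EDF = tr[(H + λP)⁻¹H], partitioned across α, the τ block, and the γ block by
the corresponding diagonal entries; EDF equals dim(ζ) at λ = 0 and falls to
the penalty null-space dimension (3) as λ → ∞.

AIC = −2·loglik + 2·(EDF<sub>c</sub> + (M<sub>y</sub> − 2) + 1), counting the
free cutpoints and σ<sub>u</sub> as full parameters.  The complexity term
EDF<sub>c</sub> = tr(2M − M²), M = (H + λP)⁻¹H, is the corrected EDF that
accounts for the uncertainty of the data-driven λ (the convention of modern
penalized-regression software).  It matters: at heavy shrinkage the
penalized fit coincides with the linear model to optimizer precision, and
the classical trace would let numerical noise decide their AIC ranking; the
correction, which is strictly larger at interior λ and equals the classical
value at λ = 0 and in the λ → ∞ limit, restores the systematic parsimony
ordering.  `edf_fixed` and its partition always report the classical trace.

## Summaries

* **Latent R².** R² = Var̂(f̂)/(Var̂(f̂ + û) + c) with sample variances over
  observations and the posterior-mode intercepts û repeated within subject.
  The error-variance constant c defaults to 1; `error_variance=pi^2/3` (the
  variance of the standard logistic) is available, which uniformly lowers
  R² but not orderings or ratios.  Because û are shrunken toward zero, the
  denominator slightly understates the latent variance, so this R² sits a
  few points above the plug-in value with true random effects — a property
  of the estimator's definition, shared by comparable mixed-model R²s.
* **Standardized coefficients** divide every coefficient by
  √(Var̂(f̂ + û) + c), an estimate of the latent response SD, making
  estimates comparable across models with different cutpoints.
* **Trait-only model** deletes the γ block (every observation reads
  f(x̃, x̃)); its penalty is the second difference of τ along the diagonal
  (null space: τ linear in r), re-using the same λ machinery.  The ratio
  R²<sub>T</sub>/R²<sub>TS</sub> indexes how trait-driven a relationship is.
* **Lagged response** adds the previous y (raw, as a numeric covariate,
  unpenalized) and drops each subject's — or each subject-day's — first
  observation; models with different sample sizes are compared by AIC/n.

## Synthetic benchmark

The generator reproduces the two-setting study design: 400 subjects × 15
observations; person medians 1..7 with frequencies (16, 46, 85, 106, 85,
46, 16) (pooled median 4); latent surface
0.17 − 0.15·sgn(r−4)|r−4|^p − 0.72·sgn(s−r)|s−r|^p with p = 1 (linear
truth) or p = 1/3 (nonlinear truth); σ<sub>u</sub> = 1, logistic errors,
cutpoints (−1, 1, 3, 5, 7, 9).

The conditional law of states around the person median is not part of the
published design.  Here x<sub>ij</sub> ~ 1 + Binomial(M<sub>x</sub>−1, q)
with q = (x̃<sub>i</sub> − ½)/M<sub>x</sub>, re-drawn until the sample median
equals the target (per-target acceptance ≥ 50%; a deterministic repair of
the central order statistics guarantees termination).  This respects the
level support, enforces the trait construct exactly, and gives within-person
state spreads of one-to-two levels, similar to momentary self-report data.
It is *not* the original authors' sampler: quantities that depend on the
state spread — absolute AIC values, the exact win percentages, per-parameter
MSE reductions — are reproduced only approximately, and the extreme response
categories can be empty in a finite replicate (they are collapsed, see
above).  Qualitative conclusions (which method wins under which truth, EDF
adapting to the truth, shrinkage reducing MSE under the linear truth) are
the reproducible surface.

The three-method comparison (`run_study`) fits the linear, unpenalized, and
penalized models to each replicate and records AIC rankings, per-coefficient
bias/MSE against the generating surface mapped through
τ<sub>r</sub> = g(r,r) − g(4,4), γ<sub>r,s</sub> = g(r,s) − g(r,r), and the
penalized EDF distribution.  Replicates default to 100; the acceptance
script and test suite run 35 per setting, the package's scaled-down default
for replicated checks, with per-replicate seeds spawned deterministically
from the master seed.

## Known limitations

* Logit link only; random intercepts only (no random slopes); one predictor
  at a time; no person-level covariates.
* No standard errors for τ̂, γ̂ (the information matrix is available on the
  fit result for users who need delta-method intervals).
* The λ grid is finite (10⁻²..10⁶ by default); truths requiring shrinkage
  outside that range would be clipped to the grid ends.
* The lagged-response model treats lagged y as continuous and assumes a
  constant lag effect, which is coarse for irregularly spaced contacts.
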