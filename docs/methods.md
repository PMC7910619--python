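# Methods

## The generative model

Items x_1..x_N ∈ R^D are modelled as draws from a K-component mixture of
isotropic Gaussians whose means lie on a latent manifold indexed by fixed
node coordinates u_1..u_K ∈ [−1,1]^L, L ≤ 3. Mixing rates are fixed at
1/K and never estimated. The manifold map factorizes as
y_k = g(u_k)·h(u_k):

- **g — scale field.** Positive, with a truncated-GP prior: the Gaussian
  process N(0, C_g) restricted to the all-positive orthant, where
  C_g(i,j) = ν_g exp(−‖u_i−u_j‖²/(2 l_g)). The exponent divides by
  2·l_g — the length-scale enters linearly. That is the covariance this
  model family defines, and it is implemented verbatim; the conventional
  squared form is available through
  `Hyperparams(kernel_g_denominator="l_squared")` for sensitivity checks.
- **h — manifold field.** Each feature dimension h_d is an independent GP
  with the nonstationary Gibbs kernel
  C_h(i,j) = {2 l_i l_j/(l_i²+l_j²)}^{L/2} exp(−‖u_i−u_j‖²/(l_i²+l_j²)),
  with per-node length-scales l_k = exp(r_k). Its diagonal is exactly 1,
  and for constant l it reduces to the stationary RBF kernel
  exp(−d²/(2l²)). This latent-dependent length-scale is the ingredient
  that lets the manifold be smooth in one region of the table and wiggly
  in another.
- **r — log length-scale field.** A GP with the same covariance family as
  C_g but hyperparameters (ν_r, l_r). The covariance form of r is not
  uniquely dictated by the model family; using the c_g family is this
  package's documented choice and is visible in the config.
- **β — noise precision.** Gamma(a₀, b₀) prior.

Hyperparameter defaults: ν_g = ν_r = 1/3, l_g = l_r = 3 (the standard
operating point for element-table runs; the latent cube has side 2, so
these give fields with order-unity correlation across neighbouring nodes),
a₀ = b₀ = 10⁻³ (vague). Feature tables are standardized column-wise to
mean 0, variance 1 on load, with the means and standard deviations
retained so held-out data can be projected consistently.

## Inference

Gibbs sampling over θ = {Z, β, H, g, r} in the fixed order
(Z, β, H, g, r):

- **Z** — exact categorical draw per item with probabilities ∝
  exp(−β/2 ‖x_n−y_k‖²), computed in log space via the Gumbel-max trick so
  distant nodes cannot underflow a whole row.
- **β** — conjugate: Gamma(a₀ + ND/2, b₀ + SSE/2), SSE the squared
  residual to assigned manifold points.
- **H** — conjugate Gaussian per dimension: precision
  A = C_h⁻¹ + β·diag(g_k² m_k) (m_k = items on node k), mean
  A⁻¹·β·g·(Z X). One Cholesky factorization of A serves all D dimensions.
- **g** — elliptical slice sampling with prior N(0, C_g); the truncation
  to g > 0 is a zero-likelihood barrier inside the slice step, which keeps
  the update rejection-free on the valid region. The bracket-shrinkage
  loop is capped (200 steps) and raises rather than looping forever.
- **r** — elliptical slice sampling with prior N(0, C_r); the
  "likelihood" is the GP density of the current H under C_h(exp(r)).
  Proposals whose kernel fails to factorize are treated as zero-density.

The update mechanics for g and r (barrier-ESS) are this package's design;
they are validated by a Geweke-style successive-conditional test
(resimulate data, sweep parameters; β, g and r marginals must stay at
their priors — KS on a thinned chain, since KS assumes independent
draws) and by closed-form moment checks for the two conjugate updates,
rather than by matching any particular historical implementation.
Deliberately, the synthetic-data generator samples the truncated GP by
plain rejection — a different mechanism than the inference-side slice
sampler — so the prior-reproduction test cross-validates the two.

Initialization is deterministic: r = 0, g = 1, β = 1, H by projecting the
node coordinates through the top-L principal axes of the data (classic
topographic-mapping initialization), Z by nearest manifold point. All
kernel matrices get 10⁻⁶ diagonal jitter before factorization, escalating
×10 on failure (6 tries) before raising.

The point estimate from an ensemble is the posterior mean of β, g, H, r;
Z is the one-hot argmax of the mean responsibilities per item, ties
broken by the lowest node index.

## Coarse-to-fine refinement

One-to-one tables need K ≥ N, but training directly with redundant nodes
is unstable, so fitting starts on a coarse layout (5×5 for the square
table, 4-slice cone with counts [1,4,8,12]). Refinement inserts all
half-step points (grid side s → 2s−1, hence 5×5 → 9×9; cone slices
doubled to [1,4,8,12,16,20,24], extending the arithmetic progression of
the base schedule; cylinders double both resolutions). Original nodes are
always retained.

The fitted fields transfer to the refined nodes by noiseless GP
conditional means under their own priors — noiseless because the field
values are latent quantities, not noisy observations. r is interpolated
first; H's interpolation then uses the Gibbs kernel evaluated with the
interpolated l = exp(r). Values at retained nodes are kept exactly.
Interpolated g is floored at 10⁻⁸ to preserve positivity — flooring
rather than truncated-conditional sampling because the fine-tuning stage
immediately refits g anyway. Conditional means (not posterior draws) are
used so the step is deterministic.

Cone geometry convention: apex (0,0,1), base circle of radius 1 at
z = −1, ring radius linear in (1−z)/2, ring angles starting at 0 with
equal spacing and aligned across slices. Any fixed convention works; this
one is recorded and tested. Staggered ring offsets are a flagged
alternative that has not been explored.

## One-to-one assignment

The final stage replaces the categorical Z draw with exact maximization
of its log conditional subject to Σ_k z_kn = 1 and Σ_n z_kn ≤ 1 — a
transportation problem with unit supplies and demands. The constraint
matrix is totally unimodular, so the LP optimum is integral and the
problem is solved as a rectangular linear assignment
(`scipy.optimize.linear_sum_assignment`); β scales the objective without
changing the argmax. Ten modified sweeps (Z maximized, β, H, g, r still
sampled) fine-tune the parameters and the highest-log-density iterate is
returned. Among equal-cost optima the solver's output is accepted as-is;
tests compare objectives, never particular matchings, under ties.

## Landscapes and descriptors

Property landscapes use a Nadaraya–Watson smoother with a Gaussian
kernel; the default bandwidth is half the nearest-neighbour spacing of
the occupied nodes — small enough to resolve single cells, large enough
to connect neighbours. Values are convex combinations of the item
feature values, hence always within their range. Cone and cylinder
tables are evaluated on the unrolled (angle, height) chart with distances
taken in the embedded 3-D space, so the angular seam is handled
correctly.

A table's coordinates serve as an element descriptor; a compound's
descriptor is φ(S) = Σ_n w_n(S)·u_{k(n)} with atomic fractions w. The
reference registry provides the standard periodic table encoded as
integer (group 1–18, period 1–5) coordinates for H–Xe — the natural
reading of "two-dimensional coordinates of the standard table" — plus
PCA and t-SNE coordinates computed from a supplied feature matrix.
Descriptor quality is measured by k-fold cross-validated regression
(default: random forest with library-default hyperparameters, recorded
in the report; the fold partition depends only on n, k and the seed).
Formulas are parsed by a small in-house parser (Hill-style symbols,
integer or decimal subscripts, parenthesised groups).

## Synthetic data

`synthetic.generate` draws from the generative model exactly as written
(r from its GP, g by rejection from the truncated GP, h_d from the Gibbs
kernel GP, uniform or injective assignments, Gaussian noise), returning
the full generating state so recovery experiments can compare against
ground truth. `synthetic.element_fixture` is an openly synthetic stand-in
for a 54-element × 39-feature table: each feature mixes a smooth trend in
atomic number with group/period-driven periodic components plus mild
noise, standardized column-wise. It emulates the dimensions and the
smooth-plus-periodic character of real element data — not its actual
values, correlation structure, or heavy tails — so end-to-end tests
passing on it demonstrate the pipeline's mechanics, not chemical
validity on measured data.

## Problem sizes and runtime

Default analysis settings are 10,000 sweeps with 5,000 burn-in and 10
fine-tuning iterations. The test suite and the reproduction script use
reduced sizes chosen to exercise every code path at meaningful
statistical resolution: recovery experiments run 1,000 sweeps on the
5×5 → 9×9 schedule with N=40, D=10, β=100; the sampler-validation chain
runs 5,000 successive-conditional sweeps on K=9, N=6, D=3; the
end-to-end fixture run uses 200 sweeps. These are the package's chosen
experiment sizes; the longer defaults change the posterior quality, not
the code paths.

## Known limitations

- **Latent orientation is unidentifiable.** All field priors depend on
  nodes only through ‖u_i−u_j‖, so the posterior is exactly invariant
  under every isometry of the node set (8 for a square grid) and nearly
  invariant under smooth area-preserving warps. Two runs — or a run and
  the ground truth that generated the data — can disagree on orientation
  while describing the same table. Recovery experiments therefore show
  fitted manifolds at the noise floor and well-preserved latent geometry
  (pairwise-distance correlation), while exact node-identity agreement
  with a generating configuration is low and should not be expected.
  Interpret tables up to rotation/reflection of the layout.
- At β=100 and fine-grid spacing 0.25 the observation noise alone moves a
  noticeable fraction of items past the midpoint to a neighbouring node:
  even assignment with the true generating parameters misplaces ~10–35%
  of items. Exact-recovery rates are bounded by this regardless of
  inference quality.
- The Gibbs chain explores a multimodal posterior; distinct runs can land
  in different (symmetry-related or genuinely different) modes. The
  ensemble average is meaningful only within a mode; for table-making
  this is harmless since the fine-tuning stage selects a single
  highest-likelihood state.
- Elliptical slice updates make small moves when the conditional is very
  concentrated (large β, many items per node); the fine-tuning stage
  compensates by refitting only briefly from an already-good state.
- The g barrier-ESS requires the current g to be strictly positive; the
  interpolation floor (10⁻⁸) guarantees a valid restart point.
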