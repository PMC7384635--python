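# Methods

## Model

Observations fall into `T` known groups (in the motivating application,
time periods of a document corpus).  Within group `t`, rows are modeled as
`Y_i ~ N_p(mu_t, Omega_t^{-1})`; the sparsity pattern of the precision matrix
`Omega_t` is the group's conditional-independence network.  Three prior
ingredients shape the estimate:

* **Lasso part.**  Off-diagonal elements `omega_{j1j2}^t` carry independent
  double-exponential priors with rate `lambda_t`; diagonal elements carry
  exponential priors with rate `lambda_t / 2`.  This is the Bayesian analogue
  of an l1 penalty: posterior mass concentrates near zero for weak partial
  associations without ever being exactly zero.
* **Fused part.**  For every unordered pair of groups, element-wise
  differences `omega^{t} - omega^{t'}` carry double-exponential priors with
  rate `lambda_{t,t'}`, shrinking the group networks toward a shared
  structure when the data support it.
* **Hyperpriors.**  All penalties are `Gamma(shape r, rate s)`; defaults
  `r = 0.001`, `s = 1` (a near-flat penalty prior with a unit rate scale).

Sparsification is post hoc: an edge is reported when the equal-tailed
credible interval of its precision element (default level 0.95) excludes
zero.  Networks are exported as partial correlations,
`rho_{j1j2} = -omega_{j1j2} / sqrt(omega_{j1j1} omega_{j2j2})`.

## Sampler

Every double exponential is represented as a scale mixture of normals with
an exponentially distributed latent variance `tau`, after which all
conditionals are standard:

* one column/row of each `Omega_t` at a time: a `(p-1)`-variate Gaussian for
  the off-diagonal block and a Gamma for the Schur complement
  `gamma = omega_22 - omega_12' Omega_11^{-1} omega_12`; positivity of
  `gamma` keeps every stored state positive definite by construction;
* inverse-Gaussian conditionals for the latent scales (one per element per
  group, and one per element per unordered group pair, applied symmetrically
  to both groups);
* Gamma conditionals for the penalties, with the shape increment
  `p(p+1)/2` (the printed form of the update, which counts the full upper
  triangle including the diagonal in the rate);
* a conjugate normal draw for each group mean, `mu | Omega, Y`, with prior
  `mu | Omega ~ N(mu0, (kappa0 Omega)^{-1})` (defaults `mu0 = 0`,
  `kappa0 = 1`), so the scatter matrix entering the likelihood is always
  taken about the currently sampled mean.

The scatter `S_t` is the un-normalized sum of outer products (not divided by
`n_t`); only this convention makes the `|Omega_t|^{n_t/2}` likelihood factor
exact.  Columns are swept in fixed order `1..p`; `Sigma_delta` is formed by
solving against the Cholesky factor of `Omega_11`.  With `T = 1` every fusion
term vanishes and the sampler is exactly the single-group Bayesian graphical
lasso.  Default budget: 1000 sweeps, burn-in 100, no thinning.

Degenerate conditionals are guarded: when `|omega|` (or a difference) falls
below 1e-10 the inverse-Gaussian mean is capped at 1e10, and scale draws are
capped at 1e15 so reciprocals stay representable.  Penalty draws from the
near-flat hyperprior are truncated below at 1e-6.

## Mixture layer

Each group may consist of several unknown sub-populations.  Component
memberships follow a Chinese-restaurant-process prior with concentration
`alpha ~ Gamma(a, b)` (defaults `a = b = 1`, updated by the standard
auxiliary-variable move).  The data-integrative variant (DI-CRP) multiplies
an existing component's weight by

* `n*_{-i,k}`: the number of k's members whose external similarity to `i`
  reaches `i`'s own third-quartile threshold (0.75 empirical quantile,
  linear interpolation), and
* `h_i(k) = 1 +` the summed similarity between `i` and k's members.

At zero similarity both factors reduce to cluster size and one, so CRP and
DI-CRP coincide draw for draw under a shared seed — the CRP code path *is*
the DI-CRP path with `S = 0`.

One MCMC sweep per group runs: a birth-death Metropolis pass (non-singletons
may open a fresh component with prior-drawn parameters, accepted with
probability `min{1, [alpha/(n_t-1)] phi'/phi}`; singletons may be absorbed
into an existing component proposed proportionally to `n*`, accepted with
`min{1, [(n_t-1)/alpha] h' phi'/(h phi)}`), a membership-exchange pass, a
conjugate mean update per component, and a graphical-lasso precision update —
stage-wise per component (BSM) or one fused sweep coupling all live
components of all groups (BFM), with fusion scales/penalties created from
their priors when a component is born and discarded at death.

### Design choices in the mixture layer

The following choices were genuinely open and are the package's own; each
was made for the reason stated.

* **Group-level lasso penalty.**  The penalty is indexed by group, not by
  component: all components of group `t` share `lambda_t`, whose Gamma
  conditional aggregates shape `r + K_t p(p+1)/2` and rate
  `s + sum_k sum_{j1<=j2} |omega^{t,k}|`.  A per-component penalty under the
  near-flat hyperprior is numerically improper for singleton components (the
  penalty and the precision can drift jointly to 0 and infinity), which
  permanently locks spurious components in.
* **Singleton precision freeze.**  A component keeps its birth-draw
  precision until it has at least two members.  One observation cannot
  inform a `p x p` precision matrix, and updating it anyway feeds the same
  degenerate drift.  Means are still updated (the conjugate mean conditional
  is proper for any `n_k`).
* **Constructive prior draws.**  The graphical-lasso prior has no direct
  sampler; a prior draw of `Omega` runs 10 data-free column sweeps of the
  block-Gibbs kernel (S = 0, n_t = 0, no fusion) from the identity, followed
  by a scale refresh — positive definite by construction.  Birth moves and
  the new-component marginal use the hierarchical draw (`lambda ~ G(r, s)`
  truncated); under the default near-flat hyperprior these candidates are
  extremely diffuse-or-spiked, so in practice births are almost never
  accepted and the component count is governed by initialization plus
  consolidation — the regime in which the birth-death scheme is stable.  A
  fixed reference penalty can be supplied (`birth_penalty`) to make births
  active, at the documented risk of upward drift in K.
* **Initialization.**  Sequential density-argmax assignment capped at
  `K_max` components (default 10).  Candidate precisions are drawn at a unit
  reference penalty (`init_penalty = 1`, the scale set by `s = 1`), and the
  candidate mean prior is centered at the observation under consideration,
  which guarantees every data region can open a component.  Spurious
  candidates die in the first sweeps through the singleton-absorption move.
* **Monte-Carlo marginal.**  The new-component marginal likelihood is
  approximated with `M = 50` prior draws, drawn once per sweep per group and
  shared as a pool: the same pool supplies birth proposals (a uniformly
  chosen member).  Batching the pool's kernel sweeps is what keeps the
  mixture sampler fast.
* **Estimator of K.**  The reported component count is the modal K over
  post-burn-in sweeps (ties toward the smaller value); the final-sweep count
  is also stored.  A single-sweep snapshot is a posterior draw and would be
  noisy under any birth-death move.
* **Concentration per group.**  `alpha` is maintained per group, since
  allocation is carried out group-wise.
* **Prediction.**  Held-out rows are scored against their own group's
  mixture with plug-in posterior means and final-state occupancy weights
  `n_k/n_t`.

## Synthetic data

The generator builds precision matrices from explicit edge sets: a chain
backbone (`p-1` edges) plus `p//2` random extras, off-diagonal entries of
magnitude `edge_strength` (default 0.4) with a fixed random sign per edge,
and diagonals set to the absolute row sum plus 0.1 (diagonal dominance, so
positive definiteness is guaranteed and the sparsity pattern is exact).  In
"shared" mode a `shared_frac` fraction (default 0.8) of the base edges forms
a core present in every matrix and the remainder is redrawn per matrix; in
"random" mode every matrix gets an independent edge set.  Mixture designs
place component means `mean_separation` apart (default 3.0) along the unit
diagonal direction, with balanced shuffled memberships, and emit the
ground-truth binary similarity (1 within a true cluster).  These defaults
are desk-scale stand-ins chosen to reproduce the qualitative orderings of
the study designs; the original parameter tables for the second simulation
design are not reproduced.

What the generator does **not** emulate: heavy-tailed or zero-inflated
features (tf-idf data are nonnegative and sparse), unbalanced clusters,
within-cluster covariance drift, or similarity matrices that are informative
but noisy.  Passing tests therefore demonstrate correctness of the
machinery under Gaussian assumptions, not robustness on real corpora.

## Evaluation and problem sizes

Frobenius loss is reported per matrix (square root of the summed squared
differences); the F-score is computed over upper-triangle edges; clustering
accuracy is the best label-matching agreement, computed exactly via the
Hungarian assignment (equivalent to the factorial scan at any K).

The test suite runs every stochastic check at desk scale, chosen so the full
suite completes on one CPU: component-count recovery uses 20 replicates of
(p=5, n=50) at the full 1000-sweep budget; the fused-vs-stagewise comparison
uses 10 replicates of (p=10, T=3, n_t=100) at 600 sweeps; cross-validation
uses (p=5, T=3, K=(1,2,2), n_t=60) at 400 sweeps; the sampler-vs-quadrature
check uses (p=2, n=200) with a 150^3 grid oracle.  The quadrature oracle
integrates the exact 3-parameter marginal posterior (mean and penalty
integrated analytically) and is independent of the sampler code path.

## Known limitations

* The fusion penalty cannot switch itself off: its gamma conditional has
  shape `r + p(p+1)/2`, so `lambda_fuse` stays bounded away from zero no
  matter how unrelated the group networks are.  When the groups genuinely
  share structure the fused fit beats the stage-wise fit, but on entirely
  unrelated precision matrices the induced shrinkage bias can exceed the
  stage-wise estimation error by tens of percent at moderate n (measured
  ~+17% to +50% at p=10, n=100 across random-matrix designs).  Use the
  stage-wise variant when there is no reason to expect shared structure.
* The birth-death scheme is a heuristic Metropolis design, not a reversible
  sampler targeting the exact mixture posterior; with births effectively
  disabled the component count can only fall after initialization, so
  `K_max` bounds the number of discoverable sub-populations.
* Under plain CRP (no similarity), well-separated clusters can occasionally
  be absorbed into one broad component and cannot re-split; informative
  similarity prevents this (its `n*` gate zeroes cross-cluster moves), which
  is the direction the method is designed for.
* Column-wise sweeps cost `O(T p^4)` per iteration; dimensions beyond a few
  hundred variables are impractical without further structure.
* The tf-idf front end consumes an already-counted term-document matrix;
  tokenization, stemming and stop-word removal are out of scope.
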