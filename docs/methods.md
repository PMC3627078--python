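# Methods

`phylogp` models a function-valued trait (a curve sampled on a common
grid) evolving along a known rooted phylogeny, and provides four pieces
of machinery: a generative simulator, a source-separation step, a
hyperparameter estimator, and a Gaussian-process ancestral
reconstructor. This note records the model, the numerical choices, and
the places where the design was genuinely open.

## Model

The curve at taxon *j* is a fixed linear mixture of *k* basis functions,

    d_j(s) = sum_i X_ij * phi_i(s),

where the basis `phi` does not evolve and the per-component mixing
coefficients `X_i.` do. Rows for different components are modelled as
statistically independent. Each row is a stationary phylogenetic
Ornstein–Uhlenbeck (OU) Gaussian process on the tree plus independent
non-phylogenetic noise at extant tips, giving the marginal covariance
between taxa *j*, *g* at patristic distance `D`:

    k(D) = sigma_f^2 * exp(-D / (2*ell)) + sigma_n^2 * delta,

with `delta = 1` only when *j* = *g* is an extant tip.

- `sigma_f` (trait units) — stationary phylogenetic sd. It is the
  stationary sd, not the diffusion coefficient of the OU SDE: only then
  is `sigma_f^2 / (sigma_f^2 + sigma_n^2)` the fraction of tip variance
  attributable to phylogeny (the quantity related to Pagel's lambda).
- `ell` (tree-distance units) — characteristic length-scale, equal to
  `1/(2*alpha)` for OU strength-of-selection `alpha`. Correlation decays
  by `1/e` over a patristic distance of `2*ell`.
- `sigma_n` (trait units) — within-species/environmental/measurement sd,
  applied only at tips; ancestral (internal-node) traits are noise-free
  by construction.

The prior mean is identically zero: the cross-taxon mean curve is
removed before any inference and added back at reconstruction, so a
stationary OU optimum is absorbed into the mean curve. Ancestors are
therefore assumed to share the extant mean curve — an explicit modelling
choice.

## Synthetic data generator

The generator is first-class, tested code; it defines the study
conditions used throughout the tests and the acceptance script.

- **Tree**: Yule (pure-birth) topology with i.i.d. branch lengths.
  Default branch-length distribution: lognormal(mu = −2.62, s = 1.0)
  (mean ≈ 0.12, heavy right tail), a documented stand-in for typical
  gene-family branch-length distributions; exponential and fixed lengths
  are alternatives. For study-scale runs the tree is rescaled so the
  maximum tip–tip patristic distance is 8.22, the reference value to
  which the length-scales 6.17 (= 0.75·lmax) and 2.06 (= 0.25·lmax) are
  anchored.
- **Basis**: three fixed, non-orthogonal, unimodal bumps on a uniform
  1024-point grid of [0, 1] — beta densities with shapes (4, 9), (7, 7),
  (9, 4), each normalised to unit maximum and scaled by (1.0, 0.9, 1.1).
  The exact reference curves are not published; any user basis is
  accepted.
- **Coefficients**: three independent OU rows with
  (sigma_f, ell, sigma_n) = (2.5, 6.17, 0.5), (0, –, 1.0) and
  (1.5, 2.06, 0.5). The middle row has no phylogenetic variation at all
  and exercises the no-signal diagnostics.
- **Simulation**: recursive branch-wise conditionals — root
  ~ N(0, sigma_f^2), child = parent·exp(−b/(2·ell)) +
  N(0, sigma_f^2·(1 − exp(−b/ell))) — rather than one joint draw. This
  is O(n) per replicate and, crucially, is an independent oracle for the
  closed-form kernel: the test suite checks their covariance agreement
  at every node pair by Monte Carlo.
- **Seeding**: per-component child streams are spawned from the master
  `SeedSequence` in component order (OU stream, then noise stream), so
  adding components never perturbs earlier ones. Identical seeds give
  bitwise-identical output.

What the generator does **not** emulate: irregular or sparse sampling
grids, non-Gaussian measurement error, rate heterogeneity across
branches, multiple selective optima, or basis functions that themselves
evolve. Passing tests therefore demonstrate correctness of the machinery
under the stated model, not robustness of the model to real-data
violations of it.

## Separation (IPCA)

Curves are centred by the cross-taxon mean; the retained dimension is
the smallest k whose top-k principal components explain ≥ 95% of
variance (the reference work states no criterion; 0.95 is the package
default and is configurable). Within the retained subspace an orthogonal
rotation maximises an independence contrast.

- **Contrast**: joint third- and fourth-order cumulant maximisation
  (CubICA-style), `sum_i k3_i^2/12 + k4_i^2/48`, optimised by pairwise
  Jacobi sweeps; each pair's angle is located on a coarse grid over
  [−pi/4, pi/4) and refined by bounded scalar minimisation. A fixed-point
  negentropy alternative (scikit-learn's FastICA) and a plain-PCA
  baseline are pluggable. In practice the cumulant contrast separates
  the skewed bump-shaped curves markedly better than the symmetric
  FastICA contrasts.
- **Orientation**: in `d = X·phi` the basis curves are the independent
  components and `X` is the mixing matrix, so by default the rotation is
  computed on the functional side — the retained PC curves are the ICA
  signals and grid points the samples, where the unimodal bumps are
  strongly non-Gaussian (skewed). The dual view (taxa as samples,
  `orientation="loadings"`) is also implemented; it is the right place
  to detect the classical ICA degeneracy of Gaussian mixing
  coefficients, which the `degenerate_` flag reports whenever the
  fitted contrast falls below 5·k/n_samples (the Gaussian noise floor of
  sample cumulants is ~k/n).
- **Indeterminacies**: scale/sign are fixed (unit-norm basis rows,
  largest-magnitude entry positive); permutation is resolved only in
  evaluation code by maximum-|correlation| matching, never in the core.
- The factorisation is exact on the retained subspace by construction;
  taxa-order invariance is guaranteed by a deterministic sign convention
  on the principal components.

## Hyperparameter estimation

Per component, (sigma_f, ell, sigma_n) maximise the Gaussian marginal
log-likelihood of the tip coefficients, optimised in log-parameters by
L-BFGS-B with analytic gradients.

- **Bounds**: [1e−3, 1e3] × data sd for the sigmas, [1e−3, 1e3] × lmax
  for ell.
- **Restarts**: one deterministic central start plus a seeded Latin
  hypercube spanning sigma in [0.05, 5]·(sd/√2) and ell in
  [1e−3, 2]·lmax (log scale). The small-ell corner must be sampled: for
  data without phylogenetic signal the likelihood is flat in ell, and
  the narrow spikes at very small ell are unreachable across that
  plateau from moderate starts. Default 10 restarts for a single fit, 5
  per bag.
- **Tie-breaking**: restarts whose negative log-likelihood is within
  1.92 nats of the best (half the chi-square(1) 95% quantile — the
  resolution of a one-parameter likelihood-ratio test) form a tie set,
  resolved toward the least claimed phylogenetic structure: the sigma
  values of the smallest-sigma_f member combined with the ell of the
  smallest-ell member (when sigma_f ≈ 0 the kernel no longer depends on
  ell, so this composite stays inside the band; if it does not, the tied
  optima are genuinely distinct and the best is returned unmodified).
  Without this rule, no-signal data — whose likelihood is flat in ell
  and in the sigma_f/sigma_n split — return an arbitrary,
  restart-dependent triple; with it they consistently return
  sigma_f ≈ 0, sigma_n ≈ the full noise sd, and an unrealistically
  small ell, which is exactly what the no-signal diagnostic looks for.
  Signal-bearing data have strict optima and are unaffected.
- **Bagging**: 100 tip subsets of size round(100/128·n) drawn without
  replacement; per-subset MLEs are averaged on the natural scale
  (arithmetic mean of sigma-hats, not of logs) and their sd reported.
  Since induced subtrees preserve patristic distances exactly, each bag
  uses the corresponding distance submatrix directly. Failed bags are
  dropped (error if > 20% fail).
- **Diagnostics**: an aggregated ell below the 1st (above the 99th)
  percentile of the tree's tip-pair distances raises
  `signal_absent_small_ell` (`..._large_ell`); both extremes mean the
  data carry no usable phylogenetic correlation structure.
- **Known-ratio variant**: when r = sigma_f^2/sigma_n^2 is known, a
  2-parameter fit substitutes sigma_n^2 = sigma_f^2/r (closed form at
  r = 0; noise-free model at r = infinity). Across replicates it shrinks
  the spread of sigma_f estimates.
- **Estimator behaviour worth knowing**: with ell = 0.75·lmax the whole
  tree is one correlated blob and sigma_f is effectively estimated from
  a handful of deep clades — its sampling spread across
  tree/realisation draws is of the same order as its value (measured sd
  ≈ 1.4 at the study configuration). Bagging over subsets of one
  realisation cannot remove that realisation-level variance; across
  replicates the bagged and full-tree estimators have statistically
  indistinguishable spread at desk scale. Estimation accuracy improves
  with the number of taxa when the tree's extent grows with n; adding
  tips to a tree of fixed total depth saturates quickly.

## Ancestral reconstruction

Per component, the GP posterior at any node is the standard conditional
Gaussian with `sigma_n^2` on the observed-tip diagonal only; targets
(including tip targets) are noise-free, i.e. the posterior concerns the
phylogenetic component of the trait. Component independence then gives
the functional posterior

    mean(s) = mean_curve(s) + sum_i mu_i phi_i(s),
    var(s)  =                 sum_i v_i  phi_i(s)^2,

and, for tip targets, a separate non-phylogenetic band
`sqrt(sum_i sigma_n_i^2 phi_i(s)^2)`. Only marginal (per-node)
posteriors are surfaced; the kernel layer supports joint multi-node
posteriors internally. ICA uncertainty in the basis estimates is not
propagated.

The same weights give a phylogeny-aware autocovariance estimate of the
trait, `C(s,t) = sum_i (sigma_f_i^2 + sigma_n_i^2) phi_i(s) phi_i(t)`,
positive semidefinite by construction as a rank-k Gram matrix.

## Numerics

- All solves are Cholesky-based; no explicit inverses on solve paths.
  (The likelihood gradient forms `K^{-1}` once per evaluation via
  Cholesky backsolves of the identity, the standard trace-form
  gradient.)
- Cholesky failures retry with additive jitter 1e−8·(trace/n), doubled
  up to 3 times, then raise with the condition number.
- Covariance matrices are accepted as PSD when the smallest eigenvalue
  is ≥ −1e−8 × mean diagonal; posterior covariances are symmetrised and
  negative posterior variances clipped at zero before taking square
  roots.
- Degenerate inputs: zero-variance curve panels and all-zero coefficient
  vectors are rejected or returned at the lower parameter bounds with an
  explicit flag.

## Scale of the shipped experiments

The test suite runs the full protocol at reduced sizes chosen so the
statistical claims remain decisive: bagged recovery uses 40 bags of 100
tips on the 128-tip study tree; the pipeline coverage check uses 96-tip
trees with 192-point grids; the robustness study uses 64 runs of 64-tip
trees; Monte-Carlo kernel checks use 10^4 replicates. The acceptance
script (`scripts/acceptance.py`) runs the full 100-bags-of-100 protocol.

## Known limitations

- Single fixed optimum, homogeneous rates, stationary OU only — the
  Hansen-model and branch-transformation extensions are out of scope.
- The exact reference basis curves and the empirical branch-length
  distribution behind the study tree are unpublished; the defaults here
  are documented stand-ins, so curve-shape comparisons with the
  reference figures are statistical, not pointwise.
- With strong phylogenetic correlation (ell comparable to tree depth),
  per-realisation hyperparameter estimates are intrinsically noisy;
  treat single-dataset sigma_f estimates as order-of-magnitude.
- The no-signal length-scale diagnostic depends on the documented
  tie-breaking rule; a different optimizer would report an arbitrary
  length-scale on ridge-flat likelihoods.
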