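# phylogp

Phylogenetic Gaussian processes for **function-valued traits**: simulate
curve-valued phenotypes evolving along a phylogeny, separate observed tip
curves into basis functions and mixing coefficients, estimate the
evolutionary hyperparameters by bagged maximum likelihood, and
reconstruct posterior distributions of **ancestral curves**.

## Who this is for

Comparative biologists and methods developers working with phenotypes
that are functions rather than scalars — growth and mortality curves,
reaction norms, spectral or distributional phenotypes — observed only at
the tips of a known phylogeny, who want phylogenetically-aware estimates
of (a) the independent components of variation, (b) how heritable and
how persistent each component is, and (c) what ancestral phenotypes
looked like, with calibrated uncertainty.

## The model

A curve at taxon *j* is a fixed mixture of *k* basis functions,
`d_j(s) = Σ_i X_ij φ_i(s)`. Rows of the mixing matrix `X` evolve
independently of each other; each row is a stationary phylogenetic
Ornstein–Uhlenbeck Gaussian process on the tree **T** plus i.i.d. noise
at the tips, with covariance between taxa at patristic distance `D`

    k(D) = σ_f² · exp( −D / (2ℓ) ) + σ_n² · δ(same extant taxon)

— `σ_f` the phylogenetic (heritable) sd, `ℓ` the characteristic
length-scale (`1/(2α)` for OU selection strength `α`), `σ_n` the
non-phylogenetic sd. The pipeline is:

1. **simulate** — OU mixtures of three non-orthogonal unimodal basis
   curves on a random 128-tip tree (the study conditions), or any
   user-supplied configuration;
2. **decompose** — centre, PCA for the effective dimension, then a
   cumulant-based ICA rotation (CubICA-style) for maximally independent
   components (`FunctionalIPCA`);
3. **fit** — per-component MLE of γ = (σ_f, ℓ, σ_n) through the GP
   marginal likelihood, bagged over 100 random 100-tip subtrees
   (`BaggedOUEstimator`), with diagnostics for absent phylogenetic
   signal;
4. **reconstruct** — per-node Gaussian posteriors of ancestral curves
   with pointwise phylogenetic / non-phylogenetic bands
   (`AncestralTraitGP`), plus a positive-semidefinite autocovariance
   estimate `C(s,t) = Σ_i (σ_f,i² + σ_n,i²) φ_i(s) φ_i(t)`.

Everything is exposed both as scikit-learn-style estimators
(`fit` / `transform` / `predict`, `get_params`) and as plain functions;
a `phylogp` CLI wires the stages together on Newick + CSV files.

## Worked example

```python
import numpy as np
import phylogp as pg

tree = pg.random_tree(128, seed=1, scale_lmax=8.22)   # lmax = 8.22
tips, ancestors, truth = pg.synthesize_dataset(tree, seed=2)

model = pg.AncestralTraitGP(n_bags=40, bag_size=100, random_state=3)
model.fit(tips, tree)

print("k_hat =", model.separation_.k_hat)
for i, (g, d) in enumerate(zip(model.gammas_, model.diagnostics_)):
    print(f"comp {i+1}: sigma_f={g.sigma_f:6.2f}  ell={g.ell:5.2f}  "
          f"sigma_n={g.sigma_n:5.2f}  no_signal={d['signal_absent_small_ell']}")

root = model.predict_posterior([0])[0]
true_root = ancestors.curves[list(ancestors.taxa_ids).index(0)]
inside = np.mean(np.abs(true_root - root.mean_curve) <= 2 * root.phylo_sd_curve)
print(f"true root curve within +/-2 sd at {100*inside:.1f}% of grid points")
```

prints (exact numbers for these seeds):

```
k_hat = 3
comp 1: sigma_f= 19.88  ell= 0.60  sigma_n= 0.02  no_signal=False
comp 2: sigma_f= 27.74  ell= 1.78  sigma_n= 4.36  no_signal=False
comp 3: sigma_f=  5.54  ell= 0.42  sigma_n=13.05  no_signal=True
true root curve within +/-2 sd at 100.0% of grid points
```

Reading this: the decomposition found 3 components. Estimated basis
curves are unit-norm, so each component's amplitude sits in its
coefficients — here the true basis rows have norms ≈ 15–17, which is
why the σ's are an order of magnitude above the generating values;
ratios and length-scales are scale-free. Components 1–2 carry strong
phylogenetic signal (σ_f ≫ σ_n); component 3 is dominated by
non-phylogenetic noise and its bagged ℓ falls below the 1st percentile
of tip–tip distances, raising the **no-signal diagnostic** — matching
how the data were generated (one mixture row has σ_f = 0). Note that ℓ
itself is the hardest parameter: on a single realization it is
determined only to order of magnitude (here the ℓ = 6.17 component is
estimated far too short — refitting the *true* coefficients of this
realization gives nearly the same answer, so this is sampling
variation, not a pipeline artifact). The simulated root curve lies
entirely inside the 2-sd posterior band.

The same pipeline from the shell:

```bash
phylogp simulate --n-tips 128 --seed 1 --out-dir run/
phylogp decompose --tips run/tips.csv --out-dir run/
phylogp fit --coeffs run/coeffs_hat.csv --tree run/tree.nwk --out-dir run/
phylogp reconstruct --basis run/basis_hat.csv --coeffs run/coeffs_hat.csv \
    --gamma run/gamma_hat.json --tree run/tree.nwk --mean-curve run/mean_curve.csv
phylogp autocov --basis run/basis_hat.csv --gamma run/gamma_hat.json
phylogp reproduce --seed 1 --out report.json   # full experiment + evaluation
```

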