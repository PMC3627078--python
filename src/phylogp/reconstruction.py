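"""Ancestral reconstruction of function-valued traits.

Per component, Gaussian-process regression on the tree gives a univariate
posterior (mu_i, v_i) for the mixing coefficient at any node; because the
component rows are modelled as independent, these combine into a
functional Gaussian posterior

    mean(s)      = mean_curve(s) + sum_i mu_i  phi_i(s)
    phylo var(s) =                 sum_i v_i   phi_i(s)^2

and, for tip targets, a separate non-phylogenetic band
``sqrt(sum_i sigma_n_i^2 phi_i(s)^2)``.  The same weights give a
phylogenetically informed autocovariance estimate
``C(s, t) = sum_i (sigma_f_i^2 + sigma_n_i^2) phi_i(s) phi_i(t)``,
positive semidefinite by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .inference import bagged_mle
from .kernel import gp_posterior
from .separation import SeparationResult, ipca
from .synthesis import BasisSet, FunctionalDataset
from .tree import Phylogeny

__all__ = [
    "FunctionalPosterior",
    "AutocovarianceEstimate",
    "reconstruct_node",
    "reconstruct_all",
    "autocovariance",
    "AncestralTraitGP",
]


@dataclass
class FunctionalPosterior:
    """Marginal functional posterior at one node: mean curve plus pointwise
    phylogenetic (and, for tips, non-phylogenetic) sd bands."""

    node_id: int
    grid: np.ndarray
    mean_curve: np.ndarray
    phylo_sd_curve: np.ndarray
    nonphylo_sd_curve: np.ndarray


@dataclass
class AutocovarianceEstimate:
    """Estimated autocovariance surface C(s, t) on the grid."""

    grid: np.ndarray
    values: np.ndarray
    component_weights: np.ndarray  # per-component sigma_f^2 + sigma_n^2


def _basis_of(sep) -> BasisSet:
    return sep.basis_hat if isinstance(sep, SeparationResult) else sep


def _combine_components(mu, var, basis: BasisSet, mean_curve):
    """Map per-component coefficient posteriors through the basis.

    ``mu``/``var`` have shape (k,); returns (mean_curve_out, phylo_var_curve).
    Under row independence the pointwise variance is
    ``sum_i var_i * phi_i(s)**2``.
    """
    phi = basis.curves
    mean = mean_curve + mu @ phi
    pvar = var @ phi**2
    return mean, pvar


def _component_posteriors(sep: SeparationResult, gammas, tree: Phylogeny, target_ids):
    """Per-component GP posteriors at the target nodes.

    Returns (means, vars), each (k, n_targets).
    """
    pm = tree.patristic_matrix(include_internal=True)
    obs_idx = tree.tip_ids
    target_ids = np.asarray(target_ids, dtype=np.int64)
    k = sep.coeffs_hat.shape[0]
    if len(gammas) != k:
        raise ValueError("one gamma per component required")
    mus = np.empty((k, target_ids.size))
    vs = np.empty((k, target_ids.size))
    for i in range(k):
        post = gp_posterior(
            sep.coeffs_hat[i], gammas[i], pm, target_ids, obs_idx=obs_idx
        )
        mus[i] = post.mean
        vs[i] = np.clip(np.diag(post.cov), 0.0, None)
    return mus, vs


def reconstruct_node(
    sep: SeparationResult,
    gammas,
    tree: Phylogeny,
    node_id: int,
    include_tip_noise_band: bool = True,
) -> FunctionalPosterior:
    """Functional posterior at one node (internal, root, or tip).

    Tip targets get the posterior of their phylogenetic component plus a
    separate non-phylogenetic sd band from the ``sigma_n`` estimates.
    """
    node_id = int(node_id)
    if not 0 <= node_id < tree.n_nodes:
        raise KeyError(f"unknown node id {node_id}")
    mus, vs = _component_posteriors(sep, gammas, tree, [node_id])
    basis = _basis_of(sep)
    mean, pvar = _combine_components(mus[:, 0], vs[:, 0], basis, sep.mean_curve)
    if tree.is_tip[node_id] and include_tip_noise_band:
        sn2 = np.array([g.sigma_n**2 for g in gammas])
        nonphylo = np.sqrt(sn2 @ basis.curves**2)
    else:
        nonphylo = np.zeros(basis.m)
    return FunctionalPosterior(
        node_id=node_id,
        grid=basis.grid,
        mean_curve=mean,
        phylo_sd_curve=np.sqrt(pvar),
        nonphylo_sd_curve=nonphylo,
    )


def reconstruct_all(
    sep: SeparationResult,
    gammas,
    tree: Phylogeny,
    include_tips: bool = False,
) -> list[FunctionalPosterior]:
    """Marginal functional posteriors at every internal node (and
    optionally every tip)."""
    targets = list(tree.internal_ids)
    if include_tips:
        targets += list(tree.tip_ids)
    targets = np.asarray(targets, dtype=np.int64)
    mus, vs = _component_posteriors(sep, gammas, tree, targets)
    basis = _basis_of(sep)
    sn2 = np.array([g.sigma_n**2 for g in gammas])
    nonphylo_tip = np.sqrt(sn2 @ basis.curves**2)
    out = []
    for j, node_id in enumerate(targets):
        mean, pvar = _combine_components(mus[:, j], vs[:, j], basis, sep.mean_curve)
        out.append(
            FunctionalPosterior(
                node_id=int(node_id),
                grid=basis.grid,
                mean_curve=mean,
                phylo_sd_curve=np.sqrt(pvar),
                nonphylo_sd_curve=(
                    nonphylo_tip if tree.is_tip[node_id] else np.zeros(basis.m)
                ),
            )
        )
    return out


def autocovariance(sep, gammas) -> AutocovarianceEstimate:
    """Phylogenetically informed autocovariance of the trait,
    C(s, t) = sum_i (sigma_f_i^2 + sigma_n_i^2) phi_i(s) phi_i(t)."""
    basis = _basis_of(sep)
    w = np.array([g.sigma_f**2 + g.sigma_n**2 for g in gammas])
    if w.size != basis.k:
        raise ValueError("one gamma per basis curve required")
    C = (basis.curves.T * w) @ basis.curves
    return AutocovarianceEstimate(grid=basis.grid, values=C, component_weights=w)


class AncestralTraitGP(BaseEstimator):
    """End-to-end model: IPCA separation + per-component bagged OU MLE +
    Gaussian-process ancestral reconstruction.

    ``fit(X, tree)`` takes an (n_tips, m) curve panel whose rows align
    with ``tree.tip_labels`` (or a FunctionalDataset) and the phylogeny;
    ``predict`` returns posterior mean curves at nodes and
    ``predict_posterior`` full pointwise bands.

    Parameters mirror :class:`FunctionalIPCA` and :func:`bagged_mle`.
    """

    def __init__(
        self,
        n_components="auto",
        retention: float = 0.95,
        algorithm: str = "cubica",
        n_bags: int = 100,
        bag_size: int | None = None,
        n_restarts: int = 5,
        random_state=None,
    ):
        self.n_components = n_components
        self.retention = retention
        self.algorithm = algorithm
        self.n_bags = n_bags
        self.bag_size = bag_size
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, tree: Phylogeny):
        if isinstance(X, FunctionalDataset):
            if X.labels is not None and list(X.labels) != tree.tip_labels:
                order = {lab: i for i, lab in enumerate(X.labels)}
                missing = [t for t in tree.tip_labels if t not in order]
                if missing:
                    raise ValueError(f"curves missing for tips {missing[:5]}...")
                X = FunctionalDataset(
                    grid=X.grid,
                    taxa_ids=tree.tip_ids,
                    labels=tree.tip_labels,
                    curves=X.curves[[order[t] for t in tree.tip_labels]],
                )
        elif np.atleast_2d(np.asarray(X)).shape[0] != tree.n_tips:
            raise ValueError("one curve row per tip required")
        ss = np.random.SeedSequence(self.random_state)
        ica_ss, bag_ss = ss.spawn(2)
        self.separation_ = ipca(
            X,
            k=self.n_components,
            method=self.algorithm,
            seed=int(ica_ss.generate_state(1)[0] % (2**31)),
            retention=self.retention,
        )
        self.tree_ = tree
        self.bag_results_ = []
        gammas = []
        for i, child in enumerate(bag_ss.spawn(self.separation_.k_hat)):
            est = bagged_mle(
                self.separation_.coeffs_hat[i],
                tree=tree,
                n_bags=self.n_bags,
                bag_size=self.bag_size,
                n_restarts=self.n_restarts,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            self.bag_results_.append(est)
            gammas.append(est.gamma_hat)
        self.gammas_ = tuple(gammas)
        self.diagnostics_ = [b.diagnostics for b in self.bag_results_]
        return self

    def predict(self, node_ids=None) -> np.ndarray:
        """Posterior mean curves at the given nodes (default: all internal)."""
        return np.vstack(
            [p.mean_curve for p in self.predict_posterior(node_ids)]
        )

    def predict_posterior(self, node_ids=None) -> list[FunctionalPosterior]:
        check_is_fitted(self, "gammas_")
        if node_ids is None:
            return reconstruct_all(self.separation_, self.gammas_, self.tree_)
        return [
            reconstruct_node(self.separation_, self.gammas_, self.tree_, nid)
            for nid in np.atleast_1d(node_ids)
        ]

    def autocovariance(self) -> AutocovarianceEstimate:
        """Autocovariance estimate from the fitted basis and gammas."""
        check_is_fitted(self, "gammas_")
        return autocovariance(self.separation_, self.gammas_)
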