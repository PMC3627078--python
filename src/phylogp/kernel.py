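"""Phylogenetic Ornstein-Uhlenbeck covariance and Gaussian-process algebra.

The marginal covariance between the mixing coefficients of two taxa at
patristic distance ``D`` is

    k(D) = sigma_f^2 * exp(-D / (2 * ell)) + sigma_n^2 * delta,

where ``delta`` is 1 only when both indices refer to the same extant tip:
``sigma_f`` is the stationary phylogenetic standard deviation, ``ell`` the
characteristic length-scale (equal to 1/(2*alpha) for OU strength of
selection alpha) and ``sigma_n`` the non-phylogenetic (within-species /
measurement) standard deviation, which applies only at tips.

All solves go through a Cholesky factorisation with an additive-jitter
fallback; no explicit matrix inverses are formed on the solve paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, cholesky

__all__ = [
    "HyperParams",
    "GaussianPosterior",
    "ou_cov",
    "cov_matrix",
    "log_marginal_likelihood",
    "gp_posterior",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class HyperParams:
    """Per-component OU hyperparameter triple (sigma_f, ell, sigma_n).

    ``ell`` may be ``None`` only when ``sigma_f == 0`` (no phylogenetic
    variation, so the length-scale plays no role).
    """

    sigma_f: float
    ell: float | None
    sigma_n: float

    def __post_init__(self):
        if self.sigma_f < 0 or self.sigma_n < 0:
            raise ValueError("sigma_f and sigma_n must be non-negative")
        if self.ell is None:
            if self.sigma_f != 0:
                raise ValueError("ell may be None only when sigma_f == 0")
        elif self.ell <= 0:
            raise ValueError("ell must be positive")

    @property
    def alpha(self) -> float:
        """OU strength of selection, 1 / (2 * ell)."""
        if self.ell is None:
            raise ValueError("alpha undefined when sigma_f == 0 (ell is None)")
        return 1.0 / (2.0 * self.ell)

    @property
    def phylo_fraction(self) -> float:
        """Proportion of tip variance attributable to the phylogeny,
        sigma_f^2 / (sigma_f^2 + sigma_n^2)."""
        tot = self.sigma_f**2 + self.sigma_n**2
        if tot == 0:
            raise ValueError("phylo_fraction undefined for sigma_f=sigma_n=0")
        return self.sigma_f**2 / tot

    def astuple(self) -> tuple:
        return (self.sigma_f, self.ell, self.sigma_n)


@dataclass
class GaussianPosterior:
    """Mean vector and covariance matrix of coefficients at target nodes."""

    node_ids: np.ndarray
    mean: np.ndarray
    cov: np.ndarray

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


def _phylo_cov(gamma: HyperParams, d: np.ndarray) -> np.ndarray:
    """sigma_f^2 * exp(-d / (2 ell)), handling the sigma_f == 0 case."""
    d = np.asarray(d, dtype=float)
    if gamma.sigma_f == 0:
        return np.zeros_like(d)
    return gamma.sigma_f**2 * np.exp(-d / (2.0 * gamma.ell))


def ou_cov(gamma: HyperParams, d, same_extant_taxon: bool = False) -> float:
    """Marginal OU covariance at patristic distance ``d``.

    The non-phylogenetic term ``sigma_n^2`` is added only when both
    indices refer to the same extant tip taxon.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("patristic distance must be non-negative")
    out = _phylo_cov(gamma, d)
    if same_extant_taxon:
        out = out + gamma.sigma_n**2
    return float(out) if out.ndim == 0 else out


def _as_dist(dist):
    """Accept a PatristicMatrix or a bare ndarray; return (D, is_tip)."""
    if hasattr(dist, "dist"):
        return np.asarray(dist.dist, dtype=float), np.asarray(dist.is_tip, bool)
    D = np.asarray(dist, dtype=float)
    return D, np.ones(D.shape[0], dtype=bool)


def cov_matrix(gamma: HyperParams, dist, extant_mask=None) -> np.ndarray:
    """OU covariance matrix over a set of nodes.

    ``sigma_n^2`` is added on diagonal entries of extant (tip) taxa only,
    as flagged by ``extant_mask`` (defaults to the tip mask of a
    PatristicMatrix, or all-extant for a bare distance matrix).
    """
    D, default_mask = _as_dist(dist)
    mask = default_mask if extant_mask is None else np.asarray(extant_mask, bool)
    K = _phylo_cov(gamma, D)
    K[np.diag_indices_from(K)] += np.where(mask, gamma.sigma_n**2, 0.0)
    return K


def _chol_jitter(K: np.ndarray):
    """Lower Cholesky factor with additive jitter fallback.

    Jitter starts at 1e-8 * mean(diag) and doubles up to 3 times before
    raising, reporting the conditioning of the failing matrix.
    """
    try:
        return cholesky(K, lower=True), 0.0
    except np.linalg.LinAlgError:
        pass
    base = 1e-8 * float(np.trace(K)) / K.shape[0]
    if base <= 0:
        base = 1e-12
    jitter = base
    for _ in range(4):
        try:
            return cholesky(K + jitter * np.eye(K.shape[0]), lower=True), jitter
        except np.linalg.LinAlgError:
            jitter *= 2.0
    raise np.linalg.LinAlgError(
        "Cholesky failed after jitter; condition number ~ "
        f"{np.linalg.cond(K):.3g}"
    )


def log_marginal_likelihood(y, gamma: HyperParams, dist) -> float:
    """Gaussian log marginal likelihood of tip coefficients ``y``.

    ``-1/2 y^T K^-1 y - 1/2 log|K| - n/2 log 2pi`` with K the OU
    covariance over tips (``sigma_n^2`` on every diagonal entry).
    """
    y = np.asarray(y, dtype=float)
    D, _ = _as_dist(dist)
    if y.shape[0] != D.shape[0]:
        raise ValueError("y length must match the number of tips in dist")
    K = cov_matrix(gamma, D)
    L, _ = _chol_jitter(K)
    alpha = cho_solve((L, True), y)
    return float(
        -0.5 * y @ alpha - np.log(np.diag(L)).sum() - 0.5 * y.size * _LOG2PI
    )


def gp_posterior(
    y,
    gamma: HyperParams,
    dist_all,
    target_idx,
    obs_idx=None,
    targets_with_noise: bool = False,
) -> GaussianPosterior:
    """Posterior of coefficients at target nodes given tip observations.

    Parameters
    ----------
    y : array, shape (n_obs,)
        Observed (centred) coefficients at the observed tips.
    gamma : HyperParams
    dist_all : PatristicMatrix or ndarray
        Distances over the union of observed tips and targets.
    target_idx : array of int
        Row indices of the target nodes within ``dist_all``.
    obs_idx : array of int, optional
        Row indices of the observed tips within ``dist_all``.  Defaults to
        the tip rows of a PatristicMatrix.
    targets_with_noise : bool
        If True, add ``sigma_n^2`` on the target/cross entries where a
        target coincides with an observed tip (posterior of the noisy
        observable rather than of its phylogenetic component).  Default
        False: ancestral and tip targets are noise-free, i.e. the
        posterior concerns the phylogenetic part of variation.

    Notes
    -----
    mean = K(x*, x) K(x, x)^-1 y and
    cov = K(x*, x*) - K(x*, x) K(x, x)^-1 K(x, x*), with ``sigma_n^2``
    always included on the diagonal of K(x, x).
    """
    y = np.asarray(y, dtype=float)
    D, is_tip = _as_dist(dist_all)
    target_idx = np.asarray(target_idx, dtype=np.int64)
    if obs_idx is None:
        obs_idx = np.flatnonzero(is_tip)
    obs_idx = np.asarray(obs_idx, dtype=np.int64)
    if y.shape[0] != obs_idx.size:
        raise ValueError("y length must match the number of observed tips")
    P = _phylo_cov(gamma, D)
    Kxx = P[np.ix_(obs_idx, obs_idx)].copy()
    Kxx[np.diag_indices_from(Kxx)] += gamma.sigma_n**2
    Ksx = P[np.ix_(target_idx, obs_idx)].copy()
    Kss = P[np.ix_(target_idx, target_idx)].copy()
    if targets_with_noise:
        same = target_idx[:, None] == obs_idx[None, :]
        Ksx[same] += gamma.sigma_n**2
        tt = target_idx[:, None] == target_idx[None, :]
        Kss[tt & is_tip[target_idx][:, None]] += gamma.sigma_n**2
    L, _ = _chol_jitter(Kxx)
    alpha = cho_solve((L, True), y)
    mean = Ksx @ alpha
    V = np.linalg.solve(L, Ksx.T)  # lower-triangular solve
    cov = Kss - V.T @ V
    cov = 0.5 * (cov + cov.T)
    return GaussianPosterior(node_ids=target_idx, mean=mean, cov=cov)
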