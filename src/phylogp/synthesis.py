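"""Generative model for function-valued traits on a phylogeny.

A curve at taxon ``j`` is a fixed linear mixture ``d_j = sum_i X_ij phi_i``
of ``k`` basis functions, where each row of mixing coefficients evolves as
an independent stationary phylogenetic OU process plus i.i.d. Gaussian
noise at the tips.  The simulator is recursive (branch-wise conditional
normals) and therefore serves as an independent oracle for the closed-form
kernel of :mod:`phylogp.kernel`:

    root        ~ N(0, sigma_f^2)
    child|parent = parent * exp(-b / (2 ell)) + N(0, sigma_f^2 (1 - e^{-b/ell}))

for branch length ``b`` -- the stationary OU bridge with alpha = 1/(2 ell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist

from .kernel import HyperParams
from .tree import Phylogeny

__all__ = [
    "BasisSet",
    "MixingMatrix",
    "FunctionalDataset",
    "SimulationTruth",
    "default_basis",
    "simulate_ou_on_tree",
    "add_tip_noise",
    "synthesize_dataset",
    "TABLE1_GAMMAS",
]

#: The three-component configuration used throughout the worked examples:
#: gamma_1 = (2.5, 6.17, 0.5), gamma_2 = (0, n/a, 1.0), gamma_3 = (1.5, 2.06, 0.5).
#: 6.17 and 2.06 are 0.75 and 0.25 of lmax = 8.22 for the reference tree scale.
TABLE1_GAMMAS = (
    HyperParams(2.5, 6.17, 0.5),
    HyperParams(0.0, None, 1.0),
    HyperParams(1.5, 2.06, 0.5),
)


@dataclass
class BasisSet:
    """``k`` basis curves sampled on a common grid (rows of the mixture)."""

    grid: np.ndarray
    curves: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("grid must be 1-D with at least 2 points")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.curves.shape[1] != self.grid.size:
            raise ValueError("curves must have one column per grid point")
        if not np.all(np.isfinite(self.curves)):
            raise ValueError("basis curves must be finite")

    @property
    def k(self) -> int:
        return self.curves.shape[0]

    @property
    def m(self) -> int:
        return self.grid.size

    def gram(self) -> np.ndarray:
        """k x k matrix of pairwise inner products (non-orthogonality check)."""
        return self.curves @ self.curves.T


@dataclass
class MixingMatrix:
    """Per-component coefficients indexed by taxa (k x n_taxa)."""

    values: np.ndarray
    taxa_ids: np.ndarray
    component_index: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.taxa_ids = np.asarray(self.taxa_ids)
        if self.values.shape[1] != self.taxa_ids.size:
            raise ValueError("values must have one column per taxon")
        if self.component_index is None:
            self.component_index = np.arange(self.values.shape[0])


@dataclass
class FunctionalDataset:
    """Curves observed (or simulated) at a set of taxa on a common grid."""

    grid: np.ndarray
    taxa_ids: np.ndarray
    curves: np.ndarray
    labels: list | None = None
    mean_curve: np.ndarray | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        self.taxa_ids = np.asarray(self.taxa_ids)
        if self.curves.shape[0] != self.taxa_ids.size:
            raise ValueError("one curve row per taxon required")
        if self.curves.shape[1] != self.grid.size:
            raise ValueError("curve columns must match the grid")
        if self.mean_curve is None:
            self.mean_curve = np.zeros(self.grid.size)

    @property
    def n_taxa(self) -> int:
        return self.curves.shape[0]


@dataclass
class SimulationTruth:
    """Ground truth retained for evaluation only: X = Y + eps at tips, W at
    internal nodes, plus the generating basis and hyperparameters."""

    gammas: tuple
    basis: BasisSet
    X: MixingMatrix
    Y: MixingMatrix
    W: MixingMatrix


# ---------------------------------------------------------------------------


_BETA_PARAMS = ((4.0, 9.0), (7.0, 7.0), (9.0, 4.0))
_BETA_AMPLITUDES = (1.0, 0.9, 1.1)


def default_basis(m: int = 1024) -> BasisSet:
    """Three fixed non-orthogonal unimodal bumps on a uniform grid of [0, 1].

    Scaled beta densities with shape parameters (4, 9), (7, 7) and (9, 4)
    (modes near 0.27, 0.5 and 0.73), each normalised to unit maximum and
    multiplied by amplitudes (1.0, 0.9, 1.1).  Their overlapping support
    makes the 3 x 3 Gram matrix non-diagonal.
    """
    if m < 16:
        raise ValueError("m must be >= 16")
    grid = np.linspace(0.0, 1.0, m)
    curves = np.empty((3, m))
    for i, ((a, b), amp) in enumerate(zip(_BETA_PARAMS, _BETA_AMPLITUDES)):
        pdf = beta_dist.pdf(grid, a, b)
        curves[i] = amp * pdf / pdf.max()
    return BasisSet(grid=grid, curves=curves)


def simulate_ou_on_tree(tree: Phylogeny, gamma: HyperParams, seed=None, size=None):
    """Simulate a stationary phylogenetic OU process at every node.

    Returns an array of shape ``(n_nodes,)`` (or ``(n_nodes, size)`` for
    vectorised replicates) indexed by preorder node id.  ``gamma.sigma_n``
    is ignored here; tip noise is added separately.  ``sigma_f == 0``
    yields exact zeros.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    shape = (tree.n_nodes,) if size is None else (tree.n_nodes, int(size))
    vals = np.zeros(shape)
    if gamma.sigma_f == 0:
        return vals
    sf, ell = gamma.sigma_f, gamma.ell
    vals[0] = sf * rng.standard_normal(shape[1:])
    for i in range(1, tree.n_nodes):
        b = tree.branch_lengths[i]
        rho = np.exp(-b / (2.0 * ell))
        innov_sd = sf * np.sqrt(max(1.0 - rho * rho, 0.0))
        vals[i] = rho * vals[tree.parent[i]] + innov_sd * rng.standard_normal(shape[1:])
    return vals


def add_tip_noise(values, sigma_n: float, seed=None):
    """Add i.i.d. N(0, sigma_n^2) to each entry (X = Y + eps)."""
    if sigma_n < 0:
        raise ValueError("sigma_n must be non-negative")
    values = np.asarray(values, dtype=float)
    if sigma_n == 0:
        return values.copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return values + sigma_n * rng.standard_normal(values.shape)


def synthesize_dataset(
    tree: Phylogeny,
    gammas=TABLE1_GAMMAS,
    basis: BasisSet | None = None,
    seed=None,
):
    """Simulate function-valued traits at tips and internal nodes.

    Per component ``i`` an OU process is simulated over the whole tree
    (row ``Y_i`` at tips, ``W_i`` at internal nodes) and i.i.d. noise with
    sd ``gamma_i.sigma_n`` is added at tips (``X = Y + eps``); the curves
    are then ``X^T phi`` at tips and ``W^T phi`` (noise-free) at internal
    nodes.  Child streams are spawned from the master seed per component
    (OU stream then noise stream), so adding components does not perturb
    earlier ones.

    Returns ``(tips, ancestors, truth)``.
    """
    basis = default_basis() if basis is None else basis
    gammas = tuple(gammas)
    if len(gammas) != basis.k:
        raise ValueError(
            f"number of hyperparameter triples ({len(gammas)}) must equal "
            f"the number of basis curves ({basis.k})"
        )
    tip_idx = tree.tip_ids
    int_idx = tree.internal_ids
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(basis.k)
    Y = np.empty((basis.k, tip_idx.size))
    W = np.empty((basis.k, int_idx.size))
    X = np.empty((basis.k, tip_idx.size))
    for i, gamma in enumerate(gammas):
        ou_ss, noise_ss = children[i].spawn(2)
        node_vals = simulate_ou_on_tree(tree, gamma, np.random.default_rng(ou_ss))
        Y[i] = node_vals[tip_idx]
        W[i] = node_vals[int_idx]
        X[i] = add_tip_noise(Y[i], gamma.sigma_n, np.random.default_rng(noise_ss))
    tips = FunctionalDataset(
        grid=basis.grid,
        taxa_ids=tip_idx,
        labels=tree.tip_labels,
        curves=X.T @ basis.curves,
    )
    ancestors = FunctionalDataset(
        grid=basis.grid,
        taxa_ids=int_idx,
        labels=[tree.labels[i] if tree.labels[i] else f"node{i}" for i in int_idx],
        curves=W.T @ basis.curves,
    )
    truth = SimulationTruth(
        gammas=gammas,
        basis=basis,
        X=MixingMatrix(X, tip_idx),
        Y=MixingMatrix(Y, tip_idx),
        W=MixingMatrix(W, int_idx),
    )
    return tips, ancestors, truth
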