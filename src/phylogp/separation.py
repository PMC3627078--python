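"""Dimension reduction and source separation for curve panels (IPCA).

The tip curves are centred by the cross-taxon mean, projected onto the
top-``k`` principal-component subspace, and the retained scores are then
rotated to maximise statistical independence of the per-taxon mixing
coefficients.  The default independence contrast is cumulant-based
(joint third- and fourth-order, CubICA-style, via pairwise Jacobi
rotations); a fixed-point negentropy alternative (FastICA) and a plain
PCA baseline are pluggable.

Scale/sign indeterminacy is resolved by returning unit-norm basis curves
whose largest-magnitude entry is positive; permutation indeterminacy is
left to evaluation code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.utils.validation import check_is_fitted

from .synthesis import BasisSet, FunctionalDataset

__all__ = ["FunctionalIPCA", "SeparationResult", "select_dimension", "ipca"]


# ---------------------------------------------------------------------------
# CubICA: joint diagonalisation of 3rd/4th-order cumulants by Jacobi sweeps


def _pair_contrast_moments(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Joint sample moments E[u^a v^b] for a+b in {3, 4} (9 values)."""
    m = np.empty(9)
    idx = 0
    for total in (3, 4):
        for a in range(total, -1, -1):
            m[idx] = np.mean(u**a * v ** (total - a))
            idx += 1
    return m


def _pair_contrast(phi: float, m: np.ndarray) -> float:
    """Cumulant contrast of a pair after rotation by angle phi.

    psi = sum_i k3(y_i)^2 / 12 + k4(y_i)^2 / 48 over the two rotated
    coordinates; the data are exactly white, so k4 = E[y^4] - 3.
    """
    c, s = np.cos(phi), np.sin(phi)
    # third-order moments of u' = c u + s v and v' = -s u + c v
    m30, m21, m12, m03, m40, m31, m22, m13, m04 = m
    k3u = c**3 * m30 + 3 * c**2 * s * m21 + 3 * c * s**2 * m12 + s**3 * m03
    k3v = -(s**3) * m30 + 3 * s**2 * c * m21 - 3 * s * c**2 * m12 + c**3 * m03
    m4u = (
        c**4 * m40
        + 4 * c**3 * s * m31
        + 6 * c**2 * s**2 * m22
        + 4 * c * s**3 * m13
        + s**4 * m04
    )
    m4v = (
        s**4 * m40
        - 4 * s**3 * c * m31
        + 6 * s**2 * c**2 * m22
        - 4 * s * c**3 * m13
        + c**4 * m04
    )
    k4u, k4v = m4u - 3.0, m4v - 3.0
    return (k3u**2 + k3v**2) / 12.0 + (k4u**2 + k4v**2) / 48.0


def _total_contrast(Y: np.ndarray) -> float:
    k3 = np.mean(Y**3, axis=0)
    k4 = np.mean(Y**4, axis=0) - 3.0
    return float(np.sum(k3**2) / 12.0 + np.sum(k4**2) / 48.0)


def _cubica_rotation(Z: np.ndarray, max_sweeps: int = 100, tol: float = 1e-8):
    """Orthogonal rotation of white data maximising the cumulant contrast.

    Pairwise Jacobi sweeps; each pair's angle is found by a coarse grid
    over [-pi/4, pi/4) refined with bounded scalar optimisation.  Returns
    (R, converged) with sources ``Z @ R``.
    """
    n, k = Z.shape
    R = np.eye(k)
    Y = Z.copy()
    if k == 1:
        return R, True
    grid = np.linspace(-np.pi / 4, np.pi / 4, 65)
    converged = False
    for _ in range(max_sweeps):
        max_angle = 0.0
        for p in range(k - 1):
            for q in range(p + 1, k):
                m = _pair_contrast_moments(Y[:, p], Y[:, q])
                vals = [_pair_contrast(g, m) for g in grid]
                g0 = grid[int(np.argmax(vals))]
                res = minimize_scalar(
                    lambda phi: -_pair_contrast(phi, m),
                    bounds=(g0 - 0.05, g0 + 0.05),
                    method="bounded",
                    options={"xatol": 1e-12},
                )
                phi = float(res.x)
                if abs(phi) < 1e-14:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                G = np.array([[c, -s], [s, c]])
                Y[:, [p, q]] = Y[:, [p, q]] @ G
                R[:, [p, q]] = R[:, [p, q]] @ G
                max_angle = max(max_angle, abs(phi))
        if max_angle < tol:
            converged = True
            break
    return R, converged


# ---------------------------------------------------------------------------


@dataclass
class SeparationResult:
    """Estimated basis and mixing coefficients of a curve panel."""

    basis_hat: BasisSet
    coeffs_hat: np.ndarray  # (k_hat, n_taxa)
    mean_curve: np.ndarray
    explained_variance: np.ndarray  # per-PC fractions (full spectrum)
    k_hat: int
    converged: bool
    contrast: float
    degenerate: bool
    taxa_ids: np.ndarray | None = None


def _curve_matrix(curves):
    if isinstance(curves, FunctionalDataset):
        return np.asarray(curves.curves, float), curves.grid, curves.taxa_ids
    X = np.atleast_2d(np.asarray(curves, float))
    return X, np.linspace(0.0, 1.0, X.shape[1]), None


def select_dimension(curves, retention: float = 0.95):
    """Smallest k whose top-k PCs explain >= ``retention`` of variance.

    Returns ``(k_hat, explained_variance_fractions)``.
    """
    X, _, _ = _curve_matrix(curves)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if not 0.0 < retention < 1.0:
        raise ValueError("retention must be in (0, 1)")
    Xc = X - X.mean(axis=0)
    sv = np.linalg.svd(Xc, compute_uv=False)
    total = np.sum(sv**2)
    if total == 0:
        raise ValueError("degenerate data: zero variance across taxa")
    frac = sv**2 / total
    k_hat = int(np.searchsorted(np.cumsum(frac), retention) + 1)
    k_hat = min(k_hat, frac.size)
    return k_hat, frac


class FunctionalIPCA(TransformerMixin, BaseEstimator):
    """PCA-then-ICA decomposition of a panel of curves.

    Fitting centres the curves, selects the retained dimension by a PCA
    variance-retention rule (unless ``n_components`` is an int), and
    rotates the whitened scores to maximally independent components.

    Parameters
    ----------
    n_components : int or "auto"
        Retained dimension; "auto" selects the smallest k explaining at
        least ``retention`` of the variance.
    retention : float
        PCA variance retention threshold used when ``n_components="auto"``.
    algorithm : {"cubica", "fastica", "pca"}
        Independence contrast ("pca" skips the rotation and is the
        orthogonal baseline).
    orientation : {"functional", "loadings"}
        Which side of the factorisation the independence contrast is
        evaluated on.  "functional" (default) treats the retained PC
        curves as signals sampled on the grid, so the recovered basis
        functions are the maximally non-Gaussian curve directions -- the
        natural reading of the mixture model, whose basis curves are the
        independent components.  "loadings" rotates the whitened
        per-taxon scores instead (taxa as samples).
    random_state : int or None
        Seed for the FastICA variant (CubICA and PCA are deterministic).

    Attributes
    ----------
    mean_ : (m,) cross-taxon mean curve.
    components_ : (k, m) unit-norm estimated basis curves, sign fixed so
        each row's largest-magnitude entry is positive.
    n_components_ : retained dimension k.
    explained_variance_ratio_ : full per-PC variance fractions.
    contrast_ : final cumulant contrast of the estimated coefficients.
    degenerate_ : True when the contrast is at the level expected of pure
        Gaussian coefficients (rotation unidentifiable).
    converged_ : False when the rotation hit the sweep limit.
    """

    def __init__(
        self,
        n_components="auto",
        retention: float = 0.95,
        algorithm: str = "cubica",
        orientation: str = "functional",
        max_sweeps: int = 100,
        tol: float = 1e-8,
        random_state=None,
    ):
        self.n_components = n_components
        self.retention = retention
        self.algorithm = algorithm
        self.orientation = orientation
        self.max_sweeps = max_sweeps
        self.tol = tol
        self.random_state = random_state

    def _rotation(self, Z):
        """Orthogonal unmixing of white samples-by-k data; (R, converged)."""
        k = Z.shape[1]
        if k == 1 or self.algorithm == "pca":
            return np.eye(k), True
        if self.algorithm == "cubica":
            return _cubica_rotation(Z, self.max_sweeps, self.tol)
        if self.algorithm == "fastica":
            ica = FastICA(
                n_components=k,
                whiten=False,
                max_iter=1000,
                random_state=self.random_state,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ica.fit(Z)
            return ica.components_.T, ica.n_iter_ < 1000
        raise ValueError(f"unknown algorithm: {self.algorithm!r}")

    def fit(self, X, y=None):
        X, grid, _ = _curve_matrix(X)
        n, m = X.shape
        if n < 3:
            raise ValueError("need at least 3 taxa")
        if self.orientation not in ("functional", "loadings"):
            raise ValueError(f"unknown orientation: {self.orientation!r}")
        self.grid_ = grid
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
        if np.sum(sv**2) == 0:
            raise ValueError("degenerate data: zero variance across taxa")
        # deterministic PC sign convention, for taxa-order invariance
        for j in range(Vt.shape[0]):
            i_max = int(np.argmax(np.abs(Vt[j])))
            if Vt[j, i_max] < 0:
                Vt[j] *= -1.0
                U[:, j] *= -1.0
        frac = sv**2 / np.sum(sv**2)
        self.explained_variance_ratio_ = frac
        if self.n_components == "auto":
            k = int(np.searchsorted(np.cumsum(frac), self.retention) + 1)
            k = min(k, frac.size)
        else:
            k = int(self.n_components)
            if not 1 <= k <= min(n, m):
                raise ValueError("n_components out of range")
        self.n_components_ = k
        V = Vt[:k]  # (k, m) orthonormal PC curves
        T = U[:, :k] * sv[:k]  # (n, k) scores, Xc = T @ V
        if self.orientation == "functional":
            # rotate the PC curves: grid points are the ICA samples
            Vc = V - V.mean(axis=1, keepdims=True)
            cov = Vc @ Vc.T / m
            w, Q = np.linalg.eigh(cov)
            w = np.clip(w, 1e-15 * w.max(), None)
            cinv_half = Q @ ((w**-0.5)[:, None] * Q.T)
            R, conv = self._rotation((cinv_half @ Vc).T)
            lmap = R.T @ cinv_half  # basis = lmap @ V
            basis = lmap @ V
            coeffs = T @ np.linalg.inv(lmap)  # (n, k)
            n_contrast_samples = m
        else:
            # rotate the whitened scores: taxa are the ICA samples
            Z = U[:, :k] * np.sqrt(n)  # exactly white
            R, conv = self._rotation(Z)
            basis = R.T @ (sv[:k, None] / np.sqrt(n) * V)
            coeffs = Z @ R
            n_contrast_samples = n
        self.converged_ = bool(conv)
        if not conv:
            warnings.warn("ICA rotation did not converge; best iterate returned")
        # unit-norm basis rows, sign fixed by the largest-magnitude entry
        norms = np.linalg.norm(basis, axis=1)
        norms[norms == 0] = 1.0
        basis /= norms[:, None]
        coeffs *= norms[None, :]
        flip = np.ones(k)
        for i in range(k):
            j = int(np.argmax(np.abs(basis[i])))
            if basis[i, j] < 0:
                flip[i] = -1.0
        basis *= flip[:, None]
        coeffs *= flip[None, :]
        self.components_ = basis
        # contrast of the rotated sources on the chosen orientation
        if self.orientation == "functional":
            src = basis - basis.mean(axis=1, keepdims=True)
            src = (src / src.std(axis=1, ddof=0, keepdims=True)).T
        else:
            src = (coeffs - coeffs.mean(0)) / coeffs.std(0, ddof=0)
        self.contrast_ = _total_contrast(src)
        # pure Gaussian sources give E[contrast] ~ k / n_samples
        self.degenerate_ = bool(self.contrast_ < 5.0 * k / n_contrast_samples)
        # coefficients of a new curve: (x - mean_) @ projection
        if self.orientation == "functional":
            P = V.T @ np.linalg.inv(lmap) * norms[None, :]
        else:
            P = V.T @ ((np.sqrt(n) / sv[:k])[:, None] * R) * norms[None, :]
        self._projection = P * flip[None, :]
        return self

    def transform(self, X):
        """Coefficients of curves in the fitted basis, shape (n, k)."""
        check_is_fitted(self, "components_")
        X, _, _ = _curve_matrix(X)
        return (X - self.mean_) @ self._projection

    def inverse_transform(self, S):
        """Curves reconstructed from coefficients: mean + S @ components."""
        check_is_fitted(self, "components_")
        return np.asarray(S) @ self.components_ + self.mean_


def ipca(
    curves,
    k="auto",
    method: str = "cubica",
    seed=None,
    retention: float = 0.95,
    orientation: str = "functional",
) -> SeparationResult:
    """Functional IPCA of a curve panel; see :class:`FunctionalIPCA`.

    ``curves`` may be a :class:`FunctionalDataset` or an (n_taxa, m) array.
    """
    X, grid, taxa_ids = _curve_matrix(curves)
    est = FunctionalIPCA(
        n_components=k,
        retention=retention,
        algorithm=method,
        orientation=orientation,
        random_state=seed,
    ).fit(X)
    coeffs = est.transform(X).T  # (k, n_taxa)
    return SeparationResult(
        basis_hat=BasisSet(grid=grid, curves=est.components_),
        coeffs_hat=coeffs,
        mean_curve=est.mean_,
        explained_variance=est.explained_variance_ratio_,
        k_hat=est.n_components_,
        converged=est.converged_,
        contrast=est.contrast_,
        degenerate=est.degenerate_,
        taxa_ids=taxa_ids,
    )
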