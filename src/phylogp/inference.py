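"""Hyperparameter estimation for the phylogenetic OU model.

Per component the triple (sigma_f, ell, sigma_n) is estimated by
maximising the Gaussian marginal likelihood of the tip coefficients over
log-parameters with multi-start L-BFGS-B (analytic gradients), and the
estimate is stabilised by bagging: many random tip subsets (whose induced
subtrees preserve patristic distances exactly) are fitted independently
and the per-subset MLEs are averaged on the natural scale.

Exceptionally small or large aggregated length-scales, relative to the
1st/99th percentiles of the tree's tip patristic distances, are flagged
as diagnostics of absent phylogenetic signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve
from scipy.optimize import OptimizeResult, minimize
from scipy.stats import qmc
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .kernel import HyperParams, _chol_jitter, log_marginal_likelihood
from .synthesis import add_tip_noise, simulate_ou_on_tree
from .tree import Phylogeny, random_tree

__all__ = [
    "mle_gamma",
    "mle_gamma_known_ratio",
    "bagged_mle",
    "BagEstimate",
    "BaggedOUEstimator",
    "robustness_study",
]

_LOG2PI = float(np.log(2.0 * np.pi))


def _as_tip_dist(dist_or_tree):
    if isinstance(dist_or_tree, Phylogeny):
        return np.asarray(dist_or_tree.patristic_matrix().dist)
    if hasattr(dist_or_tree, "dist"):
        return np.asarray(dist_or_tree.dist, dtype=float)
    return np.asarray(dist_or_tree, dtype=float)


def _nll_and_grad(theta, D, y, mode="free", aux=None):
    """Negative log marginal likelihood and gradient in log-parameters.

    mode "free":        theta = (log sf, log ell, log sn)
    mode "ratio":       theta = (log sf, log ell), sn^2 = sf^2 / aux
    mode "no_noise":    theta = (log sf, log ell), sn = 0
    mode "fixed_noise": theta = (log sf, log ell), sn = aux
    """
    if mode == "free":
        lf, ll, ln = theta
        sn2 = np.exp(2.0 * ln)
    elif mode == "ratio":
        lf, ll = theta
        sn2 = np.exp(2.0 * lf) / aux
    elif mode == "no_noise":
        lf, ll = theta
        sn2 = 0.0
    elif mode == "fixed_noise":
        lf, ll = theta
        sn2 = aux**2
    else:  # pragma: no cover
        raise ValueError(mode)
    sf2 = np.exp(2.0 * lf)
    ell = np.exp(ll)
    n = y.size
    E = np.exp(-D / (2.0 * ell))
    K = sf2 * E
    K[np.diag_indices_from(K)] += sn2
    L, _ = _chol_jitter(K)
    alpha = cho_solve((L, True), y)
    nll = 0.5 * y @ alpha + np.log(np.diag(L)).sum() + 0.5 * n * _LOG2PI
    Kinv = cho_solve((L, True), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv
    # dNLL/dtheta_i = -1/2 sum(A * dK/dtheta_i)
    g_f = -0.5 * np.sum(A * (2.0 * sf2 * E))
    g_l = -0.5 * np.sum(A * (sf2 * E * D)) / (2.0 * ell)
    g_n = -0.5 * 2.0 * sn2 * np.trace(A)
    if mode == "free":
        grad = np.array([g_f, g_l, g_n])
    elif mode == "ratio":
        grad = np.array([g_f + g_n, g_l])  # sn tied to sf
    else:
        grad = np.array([g_f, g_l])
    return nll, grad


def _default_box(s, lmax):
    """Log-space box bounds, [1e-3, 1e3] relative to the data / tree scale."""
    return np.array(
        [
            [np.log(1e-3 * s), np.log(1e3 * s)],
            [np.log(1e-3 * lmax), np.log(1e3 * lmax)],
            [np.log(1e-3 * s), np.log(1e3 * s)],
        ]
    )


def _start_points(s, lmax, n_restarts, seed):
    """Deterministic first start plus a seeded Latin hypercube.

    The hypercube spans sigma in [0.05, 5] * s/sqrt(2) and, crucially,
    ell in [1e-3, 2] * lmax (log-uniform): likelihood surfaces for
    no-signal data have narrow optima at very small length-scales that
    are unreachable from moderate-ell starts across the flat ridge.
    """
    s0 = s / np.sqrt(2.0)
    starts = [np.log([s0, lmax / 4.0, s0])]
    if n_restarts > 1:
        sampler = qmc.LatinHypercube(d=3, seed=seed)
        u = sampler.random(n_restarts - 1)
        lo = np.log([0.05 * s0, 1e-3 * lmax, 0.05 * s0])
        hi = np.log([5.0 * s0, 2.0 * lmax, 5.0 * s0])
        starts.extend(list(lo + u * (hi - lo)))
    return starts


#: Restarts whose NLL is within this band of the best are treated as ties
#: and resolved toward the smallest ell (least phylogenetic structure).
#: The band is half the 95% quantile of chi^2(1): a local optimum that
#: beats another by less than a one-parameter likelihood-ratio test can
#: resolve is not a meaningful improvement.  Without this rule, no-signal
#: data (whose likelihood is flat in ell) returns an arbitrary restart-
#: dependent length-scale instead of a consistent "unrealistically small"
#: one.
_TIE_TOL_NATS = 1.92


def _optimize(D, y, mode, aux, box, starts, param_idx):
    """Run L-BFGS-B from each start; return best (theta, nll, log).

    Near-ties in likelihood are broken toward the smallest length-scale
    (parameter index 1), a parsimony rule that makes the no-signal
    diagnostic deterministic instead of a restart lottery.
    """
    results = []
    log = []
    for x0 in starts:
        x0 = np.asarray(x0)[param_idx]
        try:
            res = minimize(
                _nll_and_grad,
                x0,
                args=(D, y, mode, aux),
                jac=True,
                method="L-BFGS-B",
                bounds=box[param_idx],
            )
        except np.linalg.LinAlgError as exc:
            log.append({"start": x0, "error": str(exc)})
            continue
        log.append({"start": x0, "nll": res.fun, "nit": res.nit})
        if np.isfinite(res.fun):
            results.append(res)
    if not results:
        raise RuntimeError(f"all restarts failed: {log}")
    best_fun = min(r.fun for r in results)
    tied = [r for r in results if r.fun <= best_fun + _TIE_TOL_NATS]
    cand_sf = min(tied, key=lambda r: r.x[0])
    cand_ell = min(tied, key=lambda r: r.x[1])
    if cand_sf is cand_ell:
        return cand_sf, log
    # Flat-ridge parsimony: report the least phylogenetic structure the
    # tie set supports -- sigma values from the smallest-sigma_f member,
    # ell from the smallest-ell member.  (When sigma_f ~ 0 the kernel no
    # longer depends on ell, so the composite stays inside the band; if
    # it does not, the optima are genuinely distinct and the best one is
    # returned unmodified.)
    x = cand_sf.x.copy()
    x[1] = cand_ell.x[1]
    fun, _ = _nll_and_grad(x, D, y, mode, aux)
    if fun <= best_fun + _TIE_TOL_NATS:
        composite = OptimizeResult(x=x, fun=fun, nit=0)
        return composite, log
    return min(tied, key=lambda r: r.fun), log


def mle_gamma(
    y,
    dist,
    bounds=None,
    n_restarts: int = 10,
    seed=None,
    return_details: bool = False,
):
    """Maximum-likelihood (sigma_f, ell, sigma_n) for tip coefficients.

    Optimises the marginal likelihood over (log sigma_f, log ell,
    log sigma_n) with box bounds [1e-3, 1e3] relative to the data scale
    (and to the maximum tip distance for ell), multi-starting from a
    seeded Latin hypercube.  Deterministic for a fixed seed.

    With ``return_details`` also returns a dict with the best negative
    log-likelihood, at-bound flags and the per-restart log.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 tip observations")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    D = _as_tip_dist(dist)
    s = float(np.std(y))
    degenerate = s == 0.0
    if degenerate:
        s = 1.0
    lmax = float(D.max())
    box = _default_box(s, lmax) if bounds is None else np.asarray(bounds)
    starts = _start_points(s, lmax, n_restarts, seed)
    best, log = _optimize(D, y, "free", None, box, starts, [0, 1, 2])
    gamma = HyperParams(*np.exp(best.x))
    at_lower = np.isclose(best.x, box[:, 0], atol=1e-6)
    at_upper = np.isclose(best.x, box[:, 1], atol=1e-6)
    if return_details:
        return gamma, {
            "nll": float(best.fun),
            "at_lower_bound": at_lower,
            "at_upper_bound": at_upper,
            "degenerate_data": degenerate,
            "restart_log": log,
        }
    return gamma


def mle_gamma_known_ratio(
    y,
    dist,
    ratio: float,
    bounds=None,
    n_restarts: int = 10,
    seed=None,
    return_details: bool = False,
):
    """MLE constrained by a known ratio r = sigma_f^2 / sigma_n^2.

    ``ratio = 0`` is the pure-noise model (closed form, ell
    unidentifiable and flagged); ``ratio = inf`` the noise-free model.
    """
    y = np.asarray(y, dtype=float)
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    D = _as_tip_dist(dist)
    if ratio == 0:
        sn = float(np.sqrt(np.mean(y**2)))
        gamma = HyperParams(0.0, None, sn)
        if return_details:
            return gamma, {"ell_unidentifiable": True, "nll": -log_marginal_likelihood(y, gamma, D)}
        return gamma
    s = float(np.std(y)) or 1.0
    lmax = float(D.max())
    box = _default_box(s, lmax) if bounds is None else np.asarray(bounds)
    starts = _start_points(s, lmax, n_restarts, seed)
    mode = "no_noise" if np.isinf(ratio) else "ratio"
    aux = None if np.isinf(ratio) else float(ratio)
    best, log = _optimize(D, y, mode, aux, box, starts, [0, 1])
    sf, ell = np.exp(best.x)
    sn = 0.0 if np.isinf(ratio) else sf / np.sqrt(ratio)
    gamma = HyperParams(sf, ell, sn)
    if return_details:
        return gamma, {"nll": float(best.fun), "restart_log": log}
    return gamma


@dataclass(frozen=True)
class GammaSpread:
    """Per-parameter standard deviation across bags (plain container;
    unlike HyperParams, zeros are legal everywhere)."""

    sigma_f: float
    ell: float
    sigma_n: float


@dataclass
class BagEstimate:
    """Bagged hyperparameter estimate with per-bag spread and diagnostics."""

    gamma_hat: HyperParams
    gamma_sd: GammaSpread
    per_bag: pd.DataFrame
    n_bags: int
    bag_size: int
    diagnostics: dict = field(default_factory=dict)


def bagged_mle(
    y,
    tree=None,
    dist=None,
    n_bags: int = 100,
    bag_size: int | None = None,
    n_restarts: int = 5,
    seed=None,
    known_ratio: float | None = None,
) -> BagEstimate:
    """Bootstrap-aggregated MLE of (sigma_f, ell, sigma_n).

    Each bag samples ``bag_size`` tips without replacement (the induced
    subtree preserves their patristic distances exactly, so the distance
    submatrix is used directly), fits the MLE, and the per-bag estimates
    are averaged on the natural scale.  Defaults follow the 100-bags /
    100-of-128-tips protocol: ``bag_size = round(100/128 * n_tips)``.

    Bags whose optimisation fails are dropped with a warning; more than
    20% failures is an error.  The aggregated length-scale is compared
    with the 1st/99th percentiles of tip patristic distances to flag
    absent phylogenetic signal.
    """
    y = np.asarray(y, dtype=float)
    if tree is not None:
        pm = tree.patristic_matrix()
        D = pm.dist
    elif dist is not None:
        D = _as_tip_dist(dist)
    else:
        raise ValueError("provide tree or dist")
    n = D.shape[0]
    if y.size != n:
        raise ValueError("y length must match the number of tips")
    if bag_size is None:
        bag_size = int(round(100.0 / 128.0 * n))
    if not 2 <= bag_size <= n:
        raise ValueError("bag_size out of range")
    ss = np.random.SeedSequence(seed)
    pick_ss, mle_ss = ss.spawn(2)
    rng = np.random.default_rng(pick_ss)
    mle_seed = int(mle_ss.generate_state(1)[0] % (2**31))
    rows, failures = [], 0
    for b in range(n_bags):
        idx = np.sort(rng.choice(n, size=bag_size, replace=False))
        sub_y, sub_D = y[idx], D[np.ix_(idx, idx)]
        try:
            if known_ratio is None:
                g = mle_gamma(sub_y, sub_D, n_restarts=n_restarts, seed=mle_seed)
            else:
                g = mle_gamma_known_ratio(
                    sub_y, sub_D, known_ratio, n_restarts=n_restarts, seed=mle_seed
                )
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            failures += 1
            warnings.warn(f"bag {b} failed: {exc}")
            continue
        rows.append(
            {"bag": b, "sigma_f": g.sigma_f, "ell": g.ell, "sigma_n": g.sigma_n}
        )
    if failures > 0.2 * n_bags:
        raise RuntimeError(f"{failures}/{n_bags} bags failed")
    per_bag = pd.DataFrame(rows)
    means = per_bag[["sigma_f", "ell", "sigma_n"]].mean()
    sds = per_bag[["sigma_f", "ell", "sigma_n"]].std(ddof=1).fillna(0.0)
    iu = np.triu_indices(n, k=1)
    q1, q99 = np.percentile(D[iu], [1.0, 99.0])
    diagnostics = {
        "signal_absent_small_ell": bool(means["ell"] < q1),
        "signal_absent_large_ell": bool(means["ell"] > q99),
        "ell_percentiles": (float(q1), float(q99)),
        "n_failed": failures,
    }
    return BagEstimate(
        gamma_hat=HyperParams(means["sigma_f"], means["ell"], means["sigma_n"]),
        gamma_sd=GammaSpread(
            float(sds["sigma_f"]), float(sds["ell"]), float(sds["sigma_n"])
        ),
        per_bag=per_bag,
        n_bags=len(per_bag),
        bag_size=bag_size,
        diagnostics=diagnostics,
    )


class BaggedOUEstimator(BaseEstimator):
    """Scikit-learn style wrapper around :func:`bagged_mle`.

    ``fit(y, tree)`` estimates the OU hyperparameters of one coefficient
    row; fitted attributes are ``gamma_``, ``gamma_sd_``, ``per_bag_``
    and ``diagnostics_``.
    """

    def __init__(
        self,
        n_bags: int = 100,
        bag_size: int | None = None,
        n_restarts: int = 5,
        known_ratio: float | None = None,
        random_state=None,
    ):
        self.n_bags = n_bags
        self.bag_size = bag_size
        self.n_restarts = n_restarts
        self.known_ratio = known_ratio
        self.random_state = random_state

    def fit(self, y, tree=None, dist=None):
        est = bagged_mle(
            y,
            tree=tree,
            dist=dist,
            n_bags=self.n_bags,
            bag_size=self.bag_size,
            n_restarts=self.n_restarts,
            seed=self.random_state,
            known_ratio=self.known_ratio,
        )
        self.gamma_ = est.gamma_hat
        self.gamma_sd_ = est.gamma_sd
        self.per_bag_ = est.per_bag
        self.diagnostics_ = est.diagnostics
        self.result_ = est
        return self

    def score(self, y, tree=None, dist=None):
        """Log marginal likelihood of ``y`` under the fitted gamma."""
        check_is_fitted(self, "gamma_")
        D = _as_tip_dist(tree if tree is not None else dist)
        return log_marginal_likelihood(y, self.gamma_, D)


def robustness_study(
    n_runs: int,
    n_tips: int = 64,
    branch_dist=None,
    gamma_prior: dict | None = None,
    seed=None,
    n_restarts: int = 5,
    fix: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Relative estimation errors over randomly regenerated problems.

    Per run a fresh tree and a fresh gamma are drawn, tip coefficients are
    simulated (OU + tip noise), a single full-tree MLE is computed, and
    the per-parameter relative errors ``(hat - true) / true`` recorded.
    The default gamma prior is log-uniform: sigma_f, sigma_n in
    [0.25, 4.0] and ell in [0.1, 1.0] * lmax of the run's tree.

    ``fix`` may hold parameters at their true value, e.g.
    ``{"sigma_n": True}`` fits only (sigma_f, ell).

    Returns the full table and the per-parameter medians.
    """
    from .tree import DEFAULT_BRANCH_DIST

    if branch_dist is None:
        branch_dist = DEFAULT_BRANCH_DIST
    prior = {"sigma": (0.25, 4.0), "ell_frac": (0.1, 1.0)}
    if gamma_prior:
        prior.update(gamma_prior)
    fix = fix or {}
    ss = np.random.SeedSequence(seed)
    rows = []
    for run, child in enumerate(ss.spawn(max(n_runs, 1))[:n_runs]):
        rng = np.random.default_rng(child)
        tree_seed, ou_rng, noise_rng, mle_seed = (
            int(rng.integers(2**31)),
            np.random.default_rng(rng.integers(2**31)),
            np.random.default_rng(rng.integers(2**31)),
            int(rng.integers(2**31)),
        )
        tree = random_tree(n_tips, branch_dist, seed=tree_seed)
        pm = tree.patristic_matrix()
        lo, hi = np.log(prior["sigma"][0]), np.log(prior["sigma"][1])
        sf, sn = np.exp(rng.uniform(lo, hi, size=2))
        flo, fhi = np.log(prior["ell_frac"][0]), np.log(prior["ell_frac"][1])
        ell = float(np.exp(rng.uniform(flo, fhi)) * pm.lmax)
        gamma = HyperParams(sf, ell, sn)
        yv = simulate_ou_on_tree(tree, gamma, ou_rng)[tree.tip_ids]
        yv = add_tip_noise(yv, sn, noise_rng)
        try:
            if fix.get("sigma_n"):
                box = _default_box(float(np.std(yv)) or 1.0, pm.lmax)
                starts = _start_points(
                    float(np.std(yv)) or 1.0, pm.lmax, n_restarts, mle_seed
                )
                best, _ = _optimize(pm.dist, yv, "fixed_noise", sn, box, starts, [0, 1])
                ghat = HyperParams(*np.exp(best.x), sn)
            else:
                ghat = mle_gamma(yv, pm.dist, n_restarts=n_restarts, seed=mle_seed)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            rows.append({"run": run, "failed": True, "error": str(exc)})
            continue
        rows.append(
            {
                "run": run,
                "failed": False,
                "sigma_f": sf,
                "ell": ell,
                "sigma_n": sn,
                "sigma_f_hat": ghat.sigma_f,
                "ell_hat": ghat.ell,
                "sigma_n_hat": ghat.sigma_n,
                "rel_err_sigma_f": (ghat.sigma_f - sf) / sf,
                "rel_err_ell": (ghat.ell - ell) / ell,
                "rel_err_sigma_n": (ghat.sigma_n - sn) / sn,
            }
        )
    df = pd.DataFrame(rows)
    medians = {}
    if n_runs and not df.empty and "rel_err_sigma_f" in df:
        ok = df[~df["failed"]]
        medians = {
            p: float(ok[f"rel_err_{p}"].median())
            for p in ("sigma_f", "ell", "sigma_n")
        }
    return df, medians
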