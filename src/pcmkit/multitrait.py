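"""Multivariate and rate-heterogeneous Brownian-motion models.

* ``evolvcv_lite`` — regime-dependent bivariate BM on a mapped tree, the
  hierarchy of four models of rates/correlations (common/common,
  different/common, common/different, different/different).
* ``multirate_bm`` — penalized-likelihood variable-rate BM: the log rate
  itself evolves by Brownian motion over the tree, with a smoothing
  coefficient weighting the rate process against data fit.
* ``phyl_pca`` — principal components of the phylogenetic (GLS-centred,
  C-weighted) trait covariance or correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .cont import gls_mean, phylo_vcv_with_internals, pic_variance
from .tree import MappedTree, Tree

__all__ = [
    "EvolVCVFit",
    "MultiRateBMFit",
    "evolvcv_lite",
    "multirate_bm",
    "phyl_pca",
    "regime_vcv",
]


# ---------------------------------------------------------------------------
# regime-dependent multivariate BM


def regime_vcv(tree: MappedTree) -> dict[str, np.ndarray]:
    """Per-regime tip covariance: shared path length spent in each state."""
    n = tree.n_tips
    h = tree.node_heights()
    states = tree.states
    out = {s: np.zeros((n, n)) for s in states}
    # time in state s along the root->node path, per node
    path = {tree.root: {s: 0.0 for s in states}}
    for v in tree.preorder():
        for c in tree.children[v]:
            acc = dict(path[v])
            for s, d in tree.maps[c]:
                acc[s] = acc.get(s, 0.0) + d
            path[c] = acc
    # C_s[i, j] = time in s on the path root -> mrca(i, j)
    desc: dict[int, list[int]] = {v: [v - 1] for v in tree.tips()}
    for v in tree.postorder():
        if tree.is_tip(v):
            continue
        kids = [desc[c] for c in tree.children[v]]
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                for s in states:
                    t = path[v][s]
                    a, b = np.array(kids[i]), np.array(kids[j])
                    out[s][np.ix_(a, b)] = t
                    out[s][np.ix_(b, a)] = t
        desc[v] = [t for k in kids for t in k]
    for tip in tree.tips():
        for s in states:
            out[s][tip - 1, tip - 1] = path[tip][s]
    return out


@dataclass
class EvolVCVFit:
    """One fitted model of the evolvcv hierarchy."""

    model: int
    description: str
    R: dict[str, np.ndarray]      # per-regime 2x2 rate matrix
    means: np.ndarray             # per-trait root means
    loglik: float
    df: int
    converged: bool = True

    @property
    def aic(self) -> float:
        return 2 * self.df - 2 * self.loglik

    # duck-type into compare_models / ModelTable
    @property
    def name(self) -> str:
        return f"model {self.model}"


_DESCR = {
    1: "common rates, common correlation",
    2: "different rates, common correlation",
    3: "common rates, different correlation",
    4: "no common structure",
}


def _mvbm_loglik(theta_to_R, theta, Cs, regimes, y, D, n, m):
    Rs = theta_to_R(theta)
    V = np.zeros((n * m, n * m))
    for s in regimes:
        V += np.kron(Rs[s], Cs[s])
    try:
        Vinv_y = np.linalg.solve(V, y)
        Vinv_D = np.linalg.solve(V, D)
    except np.linalg.LinAlgError:
        return None, None, -np.inf
    A = D.T @ Vinv_D
    a = np.linalg.solve(A, D.T @ Vinv_y)
    r = y - D @ a
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return None, None, -np.inf
    quad = r @ np.linalg.solve(V, r)
    logL = -0.5 * quad - 0.5 * n * m * np.log(2 * np.pi) - 0.5 * logdet
    return Rs, a, float(logL)


def evolvcv_lite(tree: MappedTree, X, models: Sequence[int] = (1, 2, 3, 4),
                 nstarts: int = 10, seed=None) -> list[EvolVCVFit]:
    """Fit the hierarchy of regime-dependent bivariate BM models.

    ``X`` is an (n, 2) trait table (DataFrame indexed by tip label, or
    array in tip order).  Model 1 shares one rate matrix across regimes;
    model 2 frees the rates; model 3 frees the correlation; model 4 frees
    everything.  Rates are optimized on the log scale, correlations on
    (-1, 1); each fit keeps the best of ``nstarts`` random restarts.
    Degrees of freedom count the rate/correlation parameters plus the two
    root means (5, 7, 6, 8 for two regimes).
    """
    import pandas as pd
    if isinstance(X, pd.DataFrame):
        Xm = X.loc[list(tree.labels)].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
    n, m = Xm.shape
    if m != 2:
        raise ValueError("evolvcv_lite handles exactly 2 traits")
    Cs = regime_vcv(tree)
    regimes = sorted(Cs)
    p = len(regimes)
    y = Xm.T.reshape(-1)                       # trait-major stacking
    D = np.kron(np.eye(m), np.ones((n, 1)))
    sv = [pic_variance(tree, Xm[:, j]) for j in range(m)]
    rng = np.random.default_rng(seed)
    tol = 1e-10

    def corr_R(v1, v2, r):
        c = r * np.sqrt(v1 * v2)
        return np.array([[v1, c], [c, v2]])

    def builder(model):
        if model == 1:
            def to_R(th):
                R = corr_R(np.exp(th[0]), np.exp(th[1]), th[2])
                return {s: R for s in regimes}
            k = 3
            def init():
                return np.r_[rng.normal(size=2) * np.log(sv),
                             rng.uniform(-1, 1, 1)]
        elif model == 2:
            def to_R(th):
                r = th[-1]
                return {s: corr_R(np.exp(th[2 * i]), np.exp(th[2 * i + 1]), r)
                        for i, s in enumerate(regimes)}
            k = 2 * p + 1
            def init():
                return np.r_[rng.normal(size=2 * p) * np.log(sv * p),
                             rng.uniform(-1, 1, 1)]
        elif model == 3:
            def to_R(th):
                v1, v2 = np.exp(th[0]), np.exp(th[1])
                return {s: corr_R(v1, v2, th[2 + i])
                        for i, s in enumerate(regimes)}
            k = 2 + p
            def init():
                return np.r_[rng.normal(size=2) * np.log(sv),
                             rng.uniform(-1, 1, p)]
        else:
            def to_R(th):
                return {s: corr_R(np.exp(th[2 * i]), np.exp(th[2 * i + 1]),
                                  th[2 * p + i])
                        for i, s in enumerate(regimes)}
            k = 3 * p
            def init():
                return np.r_[rng.normal(size=2 * p) * np.log(sv * p),
                             rng.uniform(-1, 1, p)]
        return to_R, k, init

    fits = []
    for model in models:
        to_R, k, init = builder(model)
        nlog = k - (p if model in (3, 4) else 1)  # count of log-rate params
        bounds = ([(np.log(min(sv) * 1e-4), np.log(max(sv) * 1e4))] * nlog
                  + [(-1 + 1e-8, 1 - 1e-8)] * (k - nlog))

        def nll(th):
            _, _, logL = _mvbm_loglik(to_R, th, Cs, regimes, y, D, n, m)
            return -logL if np.isfinite(logL) else 1e50

        best = None
        for _ in range(nstarts):
            th0 = np.clip(init(), [b[0] for b in bounds], [b[1] for b in bounds])
            res = minimize(nll, th0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        Rs, a, logL = _mvbm_loglik(to_R, best.x, Cs, regimes, y, D, n, m)
        fits.append(EvolVCVFit(model, _DESCR[model], Rs, a, logL, k + m,
                               converged=bool(best.success)))
    return fits


# ---------------------------------------------------------------------------
# penalized-likelihood variable-rate BM


@dataclass
class MultiRateBMFit:
    """Variable-rate BM fit: per-node rates and the penalized objective."""

    sig2: dict[int, float]          # node id -> rate
    lambda_pen: float
    penalized_loglik: float
    loglik: float                   # data term at the fitted rates
    root_state: float
    converged: bool = True


def _log_mean(x1: float, x2: float) -> float:
    """Logarithmic mean (x1 - x2) / (ln x1 - ln x2); the average rate on an
    edge whose log-rate interpolates linearly between its endpoints."""
    if x1 == x2:
        return x1
    return (x1 - x2) / (np.log(x1) - np.log(x2))


def multirate_bm(tree: Tree, x, lambda_pen: float = 1.0,
                 maxiter: int = 500) -> MultiRateBMFit:
    """Penalized-likelihood BM with a rate that evolves by geometric BM.

    The objective is ``logL(data | edge rates) + lambda_pen *
    logP(ln sig2 | BM on the tree, unit rate, rooted at the root's
    value)``; edge rates are the logarithmic mean of the rates at the two
    subtending nodes.  Larger ``lambda_pen`` shrinks the rate surface
    toward a single global rate.
    """
    import pandas as pd
    if lambda_pen <= 0:
        raise ValueError("lambda_pen must be > 0")
    if hasattr(x, "items"):
        xv = np.array([float(x[lab]) for lab in tree.labels])
    else:
        xv = np.asarray(x, dtype=float)
    n, nn = tree.n_tips, tree.n_nodes
    nodes = list(range(1, nn + 1))              # tips + internals
    Cn, order = phylo_vcv_with_internals(tree)  # for the penalty term
    Cn_inv = np.linalg.inv(Cn)
    _, Cn_logdet = np.linalg.slogdet(Cn)
    pos = {v: i for i, v in enumerate(order)}
    root = tree.root
    mpen = Cn.shape[0]

    # tip covariance assembly from per-edge scaled lengths
    h = tree.node_heights()
    # list of (child, parent) edges
    edges = [(v, tree.parent[v]) for v in nodes if v != root]
    # tip-pair -> set of edges on shared path handled via mrca structure:
    # C = sum over edges of rate_e * t_e * indicator(edge on both paths).
    # Build shared-edge incidence via descendant tip sets.
    desc_tips: dict[int, np.ndarray] = {}
    for v in tree.postorder():
        if tree.is_tip(v):
            desc_tips[v] = np.array([v - 1])
        else:
            desc_tips[v] = np.concatenate([desc_tips[c] for c in tree.children[v]])

    def data_loglik(sig2_nodes: np.ndarray) -> float:
        C = np.zeros((n, n))
        for v, pnt in edges:
            rate = _log_mean(sig2_nodes[v - 1], sig2_nodes[pnt - 1])
            d = desc_tips[v]
            C[np.ix_(d, d)] += rate * tree.edge_length[v]
        try:
            Cinv1 = np.linalg.solve(C, np.ones(n))
        except np.linalg.LinAlgError:
            return -np.inf
        a = float(Cinv1 @ xv / Cinv1.sum())
        r = xv - a
        sign, logdet = np.linalg.slogdet(C)
        if sign <= 0:
            return -np.inf
        return float(-0.5 * r @ np.linalg.solve(C, r)
                     - 0.5 * n * np.log(2 * np.pi) - 0.5 * logdet)

    def penalty(ln_sig2: np.ndarray) -> float:
        z = np.array([ln_sig2[v - 1] for v in order]) - ln_sig2[root - 1]
        return float(-0.5 * z @ Cn_inv @ z - 0.5 * mpen * np.log(2 * np.pi)
                     - 0.5 * Cn_logdet)

    def objective(ln_sig2: np.ndarray) -> float:
        val = data_loglik(np.exp(ln_sig2)) + lambda_pen * penalty(ln_sig2)
        return -val if np.isfinite(val) else 1e50

    init = np.full(nn, np.log(pic_variance(tree, xv) * (n - 1) / n))
    vv = np.log(np.var(xv) / max(tree.max_height(), 1e-12))
    bounds = [(vv - 10, vv + 10)] * nn
    res = minimize(objective, np.clip(init, vv - 10, vv + 10),
                   method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "maxfun": 10 ** 6})
    ln_hat = res.x
    sig2_hat = np.exp(ln_hat)
    dl = data_loglik(sig2_hat)
    return MultiRateBMFit(
        sig2={v: float(sig2_hat[v - 1]) for v in nodes},
        lambda_pen=lambda_pen,
        penalized_loglik=float(-res.fun),
        loglik=float(dl),
        root_state=float(gls_mean(_rate_scaled_C(tree, sig2_hat, desc_tips), xv)),
        converged=bool(res.success),
    )


def _rate_scaled_C(tree: Tree, sig2_nodes: np.ndarray, desc_tips) -> np.ndarray:
    n = tree.n_tips
    C = np.zeros((n, n))
    for v in range(1, tree.n_nodes + 1):
        if v == tree.root:
            continue
        rate = _log_mean(sig2_nodes[v - 1], sig2_nodes[tree.parent[v] - 1])
        d = desc_tips[v]
        C[np.ix_(d, d)] += rate * tree.edge_length[v]
    return C


# ---------------------------------------------------------------------------
# phylogenetic PCA


def phyl_pca(tree: Tree, X, mode: str = "cov"):
    """Phylogenetic principal components analysis.

    The trait covariance is estimated with GLS centring and C-weighting:
    ``V = (X - a)' C^-1 (X - a) / (n - 1)``.  In ``corr`` mode traits are
    standardized by their phylogenetic standard deviations first.  Returns
    an object with ``loadings`` (trait-PC correlations), ``scores``
    (GLS-centred data rotated by the eigenvectors), ``sdev``
    (sqrt eigenvalues), ``evecs`` and ``mean``.
    """
    import pandas as pd
    if mode not in ("cov", "corr"):
        raise ValueError("mode must be 'cov' or 'corr'")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.loc[list(tree.labels)].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        names = [f"x{i+1}" for i in range(Xm.shape[1])]
    n, m = Xm.shape
    if not (n > m >= 2):
        raise ValueError("need n > m >= 2")
    C = tree.mrca_heights()
    invC = np.linalg.inv(C)
    one = np.ones(n)

    def gls_center(Y):
        a = (invC @ Y).sum(axis=0) / invC.sum()
        return a, Y - a

    a, R = gls_center(Xm)
    V = R.T @ invC @ R / (n - 1)
    if mode == "corr":
        sd = np.sqrt(np.diag(V))
        Xm = Xm / sd
        V = V / np.outer(sd, sd)
        a, R = gls_center(Xm)
    evals, evecs = np.linalg.eigh(V)
    idx = np.argsort(evals)[::-1][:min(n - 1, m)]
    evals, evecs = evals[idx], evecs[:, idx]
    S = R @ evecs
    Ccv = R.T @ invC @ S / (n - 1)
    L = Ccv / np.sqrt(np.outer(np.diag(V), evals))
    pcs = [f"PC{i+1}" for i in range(len(evals))]

    class _PCA:
        pass

    out = _PCA()
    out.sdev = pd.Series(np.sqrt(evals), index=pcs)
    out.evecs = pd.DataFrame(evecs, index=names, columns=pcs)
    out.loadings = pd.DataFrame(L, index=names, columns=pcs)
    out.scores = pd.DataFrame(S, index=list(tree.labels), columns=pcs)
    out.mean = pd.Series(a, index=names)
    out.mode = mode
    return out
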