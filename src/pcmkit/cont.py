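"""Continuous-trait evolution under Brownian motion.

The Brownian covariance kernel is sig2 * C, where C holds the shared
root-to-MRCA path lengths of every tip pair.  On top of it sit the two
standard phylogenetic-signal statistics (Blomberg's K with a permutation
test; Pagel's lambda with a likelihood-ratio test), ML ancestral states,
Bayesian-MCMC ancestral states, and trait simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm

from .tree import Tree

__all__ = [
    "PhyloVCV",
    "SignalResult",
    "MCMCControl",
    "phylo_vcv",
    "phylo_vcv_with_internals",
    "bm_loglik",
    "blomberg_k",
    "pagel_lambda",
    "fast_anc",
    "anc_bayes",
    "sim_bm",
    "gls_mean",
    "pic_variance",
]


@dataclass
class PhyloVCV:
    """Shared-path-length matrix among tips, in tip-id order."""

    C: np.ndarray
    labels: tuple[str, ...]


def phylo_vcv(tree: Tree) -> PhyloVCV:
    """C_ij = height of the MRCA of tips i and j; C_ii = tip height."""
    return PhyloVCV(tree.mrca_heights(), tuple(tree.labels))


def phylo_vcv_with_internals(tree: Tree) -> tuple[np.ndarray, list[int]]:
    """BM covariance over tips and non-root internal nodes.

    Rows/columns are ordered tips ``1..n`` then internal nodes
    ``n+2..2n-1`` (the root is excluded — its value is the process mean).
    Entry (u, v) is the height of the MRCA of the two nodes.
    """
    n, nn = tree.n_tips, tree.n_nodes
    h = tree.node_heights()
    order = list(range(1, n + 1)) + list(range(n + 2, nn + 1))
    pos = {v: i for i, v in enumerate(order)}
    m = len(order)
    C = np.zeros((m, m))
    # descendant lists per node (tips and internals separately tracked)
    desc: dict[int, list[int]] = {}
    for v in tree.postorder():
        mine = [v] if v != tree.root else []
        kids = [desc[c] for c in tree.children[v]]
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                for a in kids[i]:
                    for b in kids[j]:
                        C[pos[a], pos[b]] = C[pos[b], pos[a]] = h[v]
        for k in kids:
            for a in k:
                if v in pos:
                    C[pos[v], pos[a]] = C[pos[a], pos[v]] = h[v]
            mine.extend(k)
        desc[v] = mine
    for v in order:
        C[pos[v], pos[v]] = h[v]
    return C, order


def _vec(tree: Tree, x) -> np.ndarray:
    """Trait values in tip-id order from a dict/Series or ordered array."""
    if hasattr(x, "items"):
        return np.array([float(x[lab]) for lab in tree.labels])
    x = np.asarray(x, dtype=float)
    if x.shape != (tree.n_tips,):
        raise ValueError("x must have one value per tip")
    return x


def gls_mean(C: np.ndarray, x: np.ndarray) -> float:
    """Phylogenetic (GLS) mean (1'C^-1 1)^-1 1'C^-1 x."""
    w = np.linalg.solve(C, np.ones(len(x)))
    return float(w @ x / w.sum())


def bm_loglik(tree: Tree, x, sig2: float, a: float,
              C: np.ndarray | None = None) -> float:
    """Multivariate-normal log density of tip data: mean a, covariance sig2*C."""
    xv = _vec(tree, x)
    if C is None:
        C = tree.mrca_heights()
    n = len(xv)
    V = sig2 * C
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular phylogenetic covariance")
    r = xv - a
    return float(-0.5 * r @ np.linalg.solve(V, r)
                 - 0.5 * n * np.log(2 * np.pi) - 0.5 * logdet)


def pic_variance(tree: Tree, x) -> float:
    """Mean squared phylogenetically independent contrast (a rate estimate)."""
    xv = _vec(tree, x)
    val = {i + 1: xv[i] for i in range(tree.n_tips)}
    vlen = {v: float(tree.edge_length[v]) for v in range(1, tree.n_nodes + 1)}
    contrasts = []
    for v in tree.postorder():
        if tree.is_tip(v):
            continue
        kids = list(tree.children[v])
        # peel children pairwise (handles polytomies by sequential merging)
        c0 = kids[0]
        x0, l0 = val[c0], vlen[c0]
        for c in kids[1:]:
            x1, l1 = val[c], vlen[c]
            contrasts.append((x0 - x1) / np.sqrt(l0 + l1))
            x0 = (x0 / l0 + x1 / l1) / (1 / l0 + 1 / l1)
            l0 = l0 * l1 / (l0 + l1)
        val[v] = x0
        vlen[v] = vlen.get(v, 0.0) + l0
    return float(np.mean(np.square(contrasts)))


@dataclass
class SignalResult:
    """Result of a phylogenetic-signal test (K or lambda)."""

    statistic: str
    value: float
    pvalue: float | None = None
    loglik: float | None = None
    loglik0: float | None = None
    lr: float | None = None
    null_sample: np.ndarray | None = None
    profile: object = None

    def __repr__(self):
        bits = [f"{self.statistic} = {self.value:.6f}"]
        if self.loglik is not None:
            bits.append(f"logL = {self.loglik:.4f}")
        if self.lr is not None:
            bits.append(f"LR = {self.lr:.5f}")
        if self.pvalue is not None:
            bits.append(f"p = {self.pvalue:.6g}")
        return "<SignalResult " + ", ".join(bits) + ">"


def _k_statistic(x: np.ndarray, C: np.ndarray, invC: np.ndarray) -> float:
    n = len(x)
    a = float((invC @ x).sum() / invC.sum())
    r = x - a
    mse0_over_mse = (r @ r) / (r @ invC @ r)
    expected = (np.trace(C) - n / invC.sum()) / (n - 1)
    return float(mse0_over_mse / expected)


def blomberg_k(tree: Tree, x, nperm: int = 1000, seed=None) -> SignalResult:
    """Blomberg's K with a tip-permutation significance test.

    K compares the observed ratio of mean squared error under a star
    phylogeny vs the tree to its Brownian expectation; E[K] = 1 under BM.
    The p-value is the upper-tail frequency of K over random permutations
    of the tip data, with the observed arrangement included in the count.
    """
    xv = _vec(tree, x)
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips")
    if np.ptp(xv) == 0:
        raise ValueError("K is undefined for constant data")
    C = tree.mrca_heights()
    invC = np.linalg.inv(C)
    K = _k_statistic(xv, C, invC)
    rng = np.random.default_rng(seed)
    sims = np.empty(nperm)
    perm = xv.copy()
    hits = 0
    for i in range(nperm):
        sims[i] = _k_statistic(perm, C, invC)   # first draw is the observed
        if sims[i] >= K:
            hits += 1
        perm = rng.permutation(perm)
    return SignalResult("K", K, pvalue=hits / nperm, null_sample=sims)


def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def _lambda_profile_loglik(lam: float, C: np.ndarray, x: np.ndarray) -> float:
    Cl = _lambda_transform(C, lam)
    n = len(x)
    try:
        invCl = np.linalg.inv(Cl)
    except np.linalg.LinAlgError:
        return -np.inf
    a = float((invCl @ x).sum() / invCl.sum())
    r = x - a
    sig2 = float(r @ invCl @ r / n)
    if sig2 <= 0:
        return -np.inf
    sign, logdet = np.linalg.slogdet(sig2 * Cl)
    if sign <= 0:
        return -np.inf
    return float(-r @ invCl @ r / (2 * sig2) - n * np.log(2 * np.pi) / 2
                 - logdet / 2)


def max_lambda(tree: Tree) -> float:
    """Largest lambda keeping the rescaled covariance consistent with tip
    heights (max tip height over max internal-node height, ultrametric)."""
    if tree.is_ultrametric():
        h = tree.node_heights()
        return float(h[1:tree.n_tips + 1].max()
                     / h[tree.n_tips + 1:tree.n_nodes + 1].max())
    return 1.0


def pagel_lambda(tree: Tree, x, niter: int = 10,
                 profile: bool = False) -> SignalResult:
    """ML estimate of Pagel's lambda with a chi-square(1) LR test vs lambda=0.

    sigma^2 and the root state are profiled analytically; lambda is
    optimized over ``niter`` subintervals of [0, lambda_max] to dodge
    local optima.
    """
    xv = _vec(tree, x)
    C = tree.mrca_heights()
    lmax = max_lambda(tree)
    best = (None, -np.inf)
    edges = np.linspace(0, lmax, niter + 1)
    for lo, hi in zip(edges[:-1], edges[1:]):
        res = minimize_scalar(lambda l: -_lambda_profile_loglik(l, C, xv),
                              bounds=(lo, hi), method="bounded")
        if -res.fun > best[1]:
            best = (float(res.x), float(-res.fun))
    lam, logL = best
    logL0 = _lambda_profile_loglik(0.0, C, xv)
    lr = 2 * (logL - logL0)
    p = float(chi2.sf(lr, df=1))
    prof = None
    if profile:
        grid = np.linspace(0, lmax, 101)
        prof = (grid, np.array([_lambda_profile_loglik(l, C, xv) for l in grid]))
    return SignalResult("lambda", lam, pvalue=p, loglik=logL, loglik0=logL0,
                        lr=lr, profile=prof)


# ---------------------------------------------------------------------------
# ancestral states


def fast_anc(tree: Tree, x, ci: bool = False):
    """ML (GLS) ancestral states for internal nodes under Brownian motion.

    Each node's estimate is the conditional mean of the node value given
    the tip data — equivalently the phylogenetic mean of the tree
    re-rooted at that node.  With ``ci=True`` also returns variances and
    95% intervals (scaled by the REML rate estimate).
    """
    import pandas as pd
    xv = _vec(tree, x)
    n, nn = tree.n_tips, tree.n_nodes
    # Solve the tree-structured weighted least squares system: ancestral
    # values are the harmonic (1/branch-length weighted) interpolants.
    nodes = list(tree.internals())
    pos = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    b = np.zeros(len(nodes))
    for v in nodes:
        neigh = list(tree.children[v])
        if v != tree.root:
            neigh.append(tree.parent[v])
        for u in neigh:
            t = tree.edge_length[u if u != tree.parent[v] else v]
            w = 1.0 / t
            A[pos[v], pos[v]] += w
            if tree.is_tip(u):
                b[pos[v]] += w * xv[u - 1]
            else:
                A[pos[v], pos[u]] -= w
    est = np.linalg.solve(A, b)
    out = pd.DataFrame({"estimate": est}, index=nodes)
    if ci:
        C, order = phylo_vcv_with_internals(tree)
        Ct = C[:n, :n]
        r = xv - gls_mean(Ct, xv)
        sig2 = float(r @ np.linalg.solve(Ct, r) / (n - 1))
        var = np.empty(len(nodes))
        solve_t = np.linalg.inv(Ct)
        for v in nodes:
            if v == tree.root:
                # variance of the GLS mean itself
                var[pos[v]] = sig2 / np.linalg.solve(Ct, np.ones(n)).sum()
                continue
            i = order.index(v)
            cvec = C[i, :n]
            var[pos[v]] = sig2 * (C[i, i] - cvec @ solve_t @ cvec
                                  + (1 - (solve_t @ cvec).sum()) ** 2
                                  / solve_t.sum())
        out["variance"] = var
        half = 1.959963984540054 * np.sqrt(var)
        out["ci_lower"] = est - half
        out["ci_upper"] = est + half
    return out


@dataclass
class MCMCControl:
    """Control parameters of the Bayesian ancestral-state MCMC.

    Defaults follow the conventional diffuse setup: exponential prior on
    sig2 with mean 1000, Normal(0, 1000) node priors, all proposal
    variances set to 0.01 x tree height x the GLS rate estimate, sampling
    every 100 generations with the initial state included.
    """

    sig2: float | None = None
    a: float | None = None
    y: np.ndarray | None = None
    pr_mean_sig2: float = 1000.0
    pr_mean_nodes: float = 0.0
    pr_var_nodes: float = 1000.0
    prop: np.ndarray | float | None = None
    sample: int = 100
    burnin_frac: float = 0.2
    seed: object = None


def anc_bayes(tree: Tree, x, ngen: int = 10_000,
              control: MCMCControl | None = None):
    """Bayesian MCMC sampling of ancestral states under Brownian motion.

    One-parameter-at-a-time Gaussian random-walk Metropolis updates cycle
    over (sig2, root, each internal node); sig2 proposals reflect at zero.
    The chain is recorded at generation 0 and every ``sample`` generations
    (``ngen/sample + 1`` rows).  Returns ``(chain, means)``: the sampled
    chain as a DataFrame and the posterior means per node excluding the
    first ``burnin_frac`` of generations.
    """
    import pandas as pd
    con = control or MCMCControl()
    xv = _vec(tree, x)
    n, nn = tree.n_tips, tree.n_nodes
    if ngen % con.sample:
        raise ValueError("sample interval must divide ngen")
    C, order = phylo_vcv_with_internals(tree)
    Ct = tree.mrca_heights()
    invC = np.linalg.inv(C)
    _, logdetC = np.linalg.slogdet(C)
    m = C.shape[0]

    # initial values: GLS rate (n-1 divisor) and mean
    invCt = np.linalg.inv(Ct)
    a0 = float((invCt @ xv).sum() / invCt.sum())
    r = xv - a0
    sig2_0 = float(r @ invCt @ r / (n - 1))
    sig2 = con.sig2 if con.sig2 is not None else sig2_0
    a = con.a if con.a is not None else a0
    y = (np.asarray(con.y, dtype=float) if con.y is not None
         else np.full(nn - n - 1, a))
    nodes = list(range(n + 2, nn + 1))          # non-root internal nodes
    npar = 2 + len(nodes)                       # sig2, root a, node values
    if con.prop is None:
        prop = np.full(npar, 0.01 * Ct.max() * sig2_0)
    else:
        prop = np.broadcast_to(np.asarray(con.prop, dtype=float), (npar,)).copy()
    if np.any(prop <= 0):
        raise ValueError("proposal variances must be positive")
    sd = np.sqrt(prop)
    rng = np.random.default_rng(con.seed)

    def loglik(sig2, a, y):
        z = np.concatenate([xv, y]) - a
        return float(-z @ invC @ z / (2 * sig2) - m * np.log(2 * np.pi) / 2
                     - m * np.log(sig2) / 2 - logdetC / 2)

    def logprior(sig2, a, y):
        lp = -sig2 / con.pr_mean_sig2 - np.log(con.pr_mean_sig2)
        vals = np.concatenate([[a], y]) - con.pr_mean_nodes
        lp += float(-0.5 * np.sum(vals ** 2) / con.pr_var_nodes
                    - 0.5 * len(vals) * np.log(2 * np.pi * con.pr_var_nodes))
        return lp

    L = loglik(sig2, a, y)
    Pr = logprior(sig2, a, y)
    rows = np.empty((ngen // con.sample + 1, npar + 2))
    rows[0] = [0, sig2, a, *y, L]
    accept = 0
    for i in range(1, ngen + 1):
        j = (i - 1) % npar
        if j == 0:
            prop_sig2 = abs(sig2 + rng.normal(0, sd[0]))
            cand = (prop_sig2, a, y)
        elif j == 1:
            cand = (sig2, a + rng.normal(0, sd[1]), y)
        else:
            y2 = y.copy()
            y2[j - 2] += rng.normal(0, sd[j])
            cand = (sig2, a, y2)
        L2 = loglik(*cand)
        Pr2 = logprior(*cand)
        if np.log(rng.random()) < (L2 + Pr2) - (L + Pr):
            sig2, a, y = cand
            L, Pr = L2, Pr2
            accept += 1
        if i % con.sample == 0:
            rows[i // con.sample] = [i, sig2, a, *y, L]
    cols = ["gen", "sig2", str(n + 1), *[str(v) for v in nodes], "logLik"]
    chain = pd.DataFrame(rows, columns=cols)
    burn = con.burnin_frac * ngen
    post = chain[chain["gen"] >= burn]
    means = post[cols[2:-1]].mean()
    means.index = [int(c) for c in means.index]
    chain.attrs["acceptance_rate"] = accept / ngen
    return chain, means


# ---------------------------------------------------------------------------
# simulation


def sim_bm(tree: Tree, sig2: float = 1.0, a: float = 0.0, seed=None,
           internal: bool = False):
    """Simulate Brownian motion: Gaussian increments var = sig2 * t per edge.

    Returns a dict tip label -> value; with ``internal=True`` instead a
    dict node id -> value over all nodes.
    """
    if sig2 < 0:
        raise ValueError("sig2 must be >= 0")
    rng = np.random.default_rng(seed)
    vals = {tree.root: float(a)}
    for v in tree.preorder():
        for c in tree.children[v]:
            vals[c] = vals[v] + rng.normal(0.0, np.sqrt(sig2 * tree.edge_length[c]))
    if internal:
        return vals
    return {tree.labels[t - 1]: vals[t] for t in tree.tips()}
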