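"""Diversification analyses on reconstructed phylogenies.

Lineage-through-time curves, the Pybus–Harvey gamma statistic with its
asymptotic normal test, the Monte Carlo constant-rates (MCCR) test for
incompletely sampled trees, and ML fitting of Yule / birth–death models
with a sampling fraction rho (Nee-type reconstructed-tree likelihood,
conditioned on the crown age and survival of both root lineages).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import norm

from .tree import Tree, drop_tips, sim_bd_tree

__all__ = [
    "LTTResult",
    "GammaResult",
    "MCCRResult",
    "BDFit",
    "ltt_curve",
    "gamma_test",
    "mccr_test",
    "fit_yule",
    "fit_bd",
    "bd_loglik",
]


@dataclass
class LTTResult:
    """Lineage counts through time: times from the root, counts after each
    event.  The root appears at time 0 with the count stepping 1 -> 2."""

    times: np.ndarray
    counts: np.ndarray
    tree: Tree | None = None

    def at(self, t: float) -> int:
        """Lineage count at time t (right-continuous step function)."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return int(self.counts[max(i, 0)])


@dataclass
class GammaResult:
    gamma: float
    pvalue: float


@dataclass
class MCCRResult:
    gamma: float
    pvalue: float
    null_gamma: np.ndarray
    rho: float


def ltt_curve(tree: Tree) -> LTTResult:
    """Lineage-through-time curve of an ultrametric extant-only tree.

    Counts step +1 at every internal-node height; the final entry repeats
    the tip count at the total tree height.
    """
    h = tree.node_heights()
    H = h[1:tree.n_tips + 1].max()
    internal_h = np.sort(h[tree.n_tips + 1:tree.n_nodes + 1])
    # count children-1 per event height (handles polytomies)
    order = np.argsort(h[tree.n_tips + 1:tree.n_nodes + 1], kind="stable")
    steps = np.array([len(tree.children[tree.n_tips + 1 + i]) - 1
                      for i in order])
    counts = np.concatenate([[1], 1 + np.cumsum(steps), [tree.n_tips]])
    times = np.concatenate([[0.0], internal_h, [H]])
    return LTTResult(times, counts, tree)


def _gamma_from_ltt(times: np.ndarray, counts: np.ndarray) -> float:
    n = int(counts.max())
    g = np.diff(times)                      # g[k-1] = interval with k lineages
    if n < 3:
        raise ValueError("gamma needs at least 3 tips")
    kk = np.arange(2, n + 1)
    T = float(np.sum(kk * g[1:n]))
    inner = np.cumsum(kk * g[1:n])          # partial sums up to i lineages
    doublesum = float(np.sum(inner[:-1]))   # i = 2 .. n-1
    return (doublesum / (n - 2) - T / 2) / (T * math.sqrt(1.0 / (12 * (n - 2))))


def gamma_test(tree_or_ltt) -> GammaResult:
    """Pybus & Harvey's gamma with its two-tailed normal p-value.

    gamma is asymptotically N(0,1) under complete-sampling pure birth;
    negative values indicate branching concentrated toward the root.
    """
    ltt = tree_or_ltt if isinstance(tree_or_ltt, LTTResult) else ltt_curve(tree_or_ltt)
    if ltt.tree is not None and not ltt.tree.is_ultrametric():
        raise ValueError("gamma requires an ultrametric tree")
    g = _gamma_from_ltt(ltt.times, ltt.counts)
    p = float(2 * norm.sf(abs(g)))
    return GammaResult(g, p)


def mccr_test(tree_or_ltt, rho: float, nsim: int = 1000, seed=None,
              birth: float = 1.0) -> MCCRResult:
    """Monte Carlo constant-rates test of gamma with sampling fraction rho.

    Each replicate simulates a pure-birth tree of ``round(n_obs / rho)``
    tips, randomly prunes it back to ``n_obs``, and records gamma.  The
    two-tailed p-value doubles the empirical tail on the side of the
    observed statistic relative to the null median (capped at 1).
    """
    if not (0 < rho <= 1):
        raise ValueError("rho must be in (0, 1]")
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    ltt = tree_or_ltt if isinstance(tree_or_ltt, LTTResult) else ltt_curve(tree_or_ltt)
    n_obs = int(ltt.counts.max())
    gobs = _gamma_from_ltt(ltt.times, ltt.counts)
    N = int(round(n_obs / rho))
    rng = np.random.default_rng(seed)
    null = np.empty(nsim)
    for i in range(nsim):
        t = sim_bd_tree(birth, 0.0, ntips=N, seed=rng)
        if N > n_obs:
            dropped = rng.choice(t.labels, size=N - n_obs, replace=False)
            t = drop_tips(t, dropped)
        null[i] = gamma_test(t).gamma
    if gobs > np.median(null):
        p = 2 * float(np.mean(null >= gobs))
    else:
        p = 2 * float(np.mean(null <= gobs))
    return MCCRResult(gobs, min(p, 1.0), null, rho)


# ---------------------------------------------------------------------------
# birth-death fitting


def bd_loglik(b: float, d: float, branching: np.ndarray, rho: float) -> float:
    """Reconstructed-tree birth-death log-likelihood with sampling fraction.

    ``branching`` holds node ages sorted decreasing (crown age first).
    Conditions on the crown age and on both root lineages surviving to be
    sampled; includes the (N-1)! labelled-orderings constant.
    """
    t = np.asarray(branching, dtype=float)
    N = len(t) + 1
    lam, mu = b, d
    if lam <= 0 or mu < 0:
        return -np.inf
    r = lam - mu
    ert = np.exp(-r * t)
    denom = rho * lam + (lam * (1 - rho) - mu) * ert
    if np.any(denom <= 0):
        return -np.inf
    with np.errstate(over="ignore"):
        p0 = 1 - rho * r / denom
        p1 = rho * r ** 2 * ert / denom ** 2
    if np.any(p1 <= 0) or p0[0] >= 1:
        return -np.inf
    lik = 2 * math.log(p1[0]) - 2 * math.log1p(-p0[0])
    lik += float(np.sum(np.log(lam) + np.log(p1[1:])))
    return lik + math.lgamma(N)


@dataclass
class BDFit:
    """ML birth-death (or Yule) fit with its exported likelihood function."""

    b: float
    d: float
    rho: float
    loglik: float
    model: str
    lik: Callable[[float, float], float] = field(repr=False, default=None)

    @property
    def df(self) -> int:
        return 1 if self.model == "yule" else 2

    @property
    def aic(self) -> float:
        return 2 * self.df - 2 * self.loglik

    @property
    def name(self) -> str:
        return self.model


def _branching(tree: Tree) -> np.ndarray:
    if not tree.is_ultrametric():
        raise ValueError("birth-death fitting requires an ultrametric tree")
    return np.sort(tree.branching_times())[::-1]


def fit_yule(tree: Tree, rho: float = 1.0) -> BDFit:
    """ML pure-birth (Yule) fit under the rho-corrected likelihood (d = 0)."""
    t = _branching(tree)
    qb = (tree.n_tips - 2) / tree.total_edge_length()
    res = minimize_scalar(lambda b: -bd_loglik(b, 0.0, t, rho),
                          bounds=(1e-8, 2 * qb / rho), method="bounded")
    b = float(res.x)
    return BDFit(b, 0.0, rho, float(-res.fun), "yule",
                 lik=lambda bb, dd=0.0: bd_loglik(bb, dd, t, rho))


def fit_bd(tree: Tree, rho: float = 1.0, nstarts: int = 10, seed=None) -> BDFit:
    """Joint ML of (b, d) under the rho-corrected birth-death likelihood."""
    t = _branching(tree)
    qb = (tree.n_tips - 2) / tree.total_edge_length()
    rng = np.random.default_rng(seed)

    def nll(theta):
        v = bd_loglik(theta[0], theta[1], t, rho)
        return -v if np.isfinite(v) else 1e50

    starts = [np.array([1.1 * qb, 0.1 * qb])]
    for _ in range(nstarts - 1):
        starts.append(rng.uniform(0, 2, size=2) * np.array([1.1 * qb, 0.1 * qb]))
    best = None
    for s in starts:
        res = minimize(nll, s, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    b, d = float(best.x[0]), float(abs(best.x[1]))
    return BDFit(b, d, rho, float(-best.fun), "birth-death",
                 lik=lambda bb, dd: bd_loglik(bb, dd, t, rho))
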