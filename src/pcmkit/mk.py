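"""Extended Mk models for discrete characters.

The Mk model is a continuous-time Markov chain on the k observed levels of
a trait with instantaneous rate matrix Q.  Model structure is specified by
an integer *design matrix*: zeros forbid a transition, equal positive
integers tie transitions to a shared rate class.  Likelihoods are computed
by Felsenstein pruning with per-node rescaling; transition matrices
exp(Q t) use an eigendecomposition fast path with a scaling-and-squaring
fallback for ill-conditioned Q.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm as _expm
from scipy.optimize import minimize

from .tree import MappedTree, Tree

__all__ = [
    "DesignMatrix",
    "QMatrix",
    "RootPrior",
    "DiscreteTrait",
    "MkFit",
    "ModelTable",
    "build_design",
    "mk_loglik",
    "fit_mk",
    "compare_models",
    "ancr",
    "sim_mk",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DesignMatrix:
    """k x k integer template: 0 = forbidden, equal integers = shared rate."""

    matrix: np.ndarray
    levels: tuple[str, ...]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=int)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "levels", tuple(self.levels))
        k = len(self.levels)
        if m.shape != (k, k):
            raise ValueError("design matrix must be k x k")
        if np.any(np.diag(m) != 0):
            raise ValueError("design diagonal must be 0")
        if np.any(m < 0):
            raise ValueError("design entries must be >= 0")
        classes = sorted(set(m[m > 0].tolist()))
        if classes != list(range(1, len(classes) + 1)):
            raise ValueError("rate classes must be 1..m with no gaps")

    @property
    def n_classes(self) -> int:
        return int(self.matrix.max(initial=0))

    def q_from_rates(self, rates: Sequence[float]) -> "QMatrix":
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (self.n_classes,):
            raise ValueError("one rate per rate class required")
        Q = np.zeros_like(self.matrix, dtype=float)
        nz = self.matrix > 0
        Q[nz] = rates[self.matrix[nz] - 1]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return QMatrix(Q, self.levels)


@dataclass(frozen=True)
class QMatrix:
    """Instantaneous transition-rate matrix; rows sum to zero."""

    matrix: np.ndarray
    levels: tuple[str, ...]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "levels", tuple(self.levels))
        k = len(self.levels)
        if m.shape != (k, k):
            raise ValueError("Q must be k x k")
        off = m.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.any(np.abs(m.sum(axis=1)) > 1e-10 * max(1.0, np.abs(m).max())):
            raise ValueError("rows of Q must sum to 0")

    @property
    def k(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class RootPrior:
    """Root-state prior: flat ('equal'), FitzJohn nuisance weighting, or fixed."""

    kind: str = "equal"
    probs: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("equal", "fitzjohn", "fixed"):
            raise ValueError("kind must be equal, fitzjohn or fixed")
        if self.kind == "fixed":
            p = np.asarray(self.probs, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1) > 1e-10:
                raise ValueError("fixed prior must be a probability vector")
            object.__setattr__(self, "probs", p)


class DiscreteTrait:
    """Tip -> level mapping with an explicit, ordered level set.

    Values may be ambiguous: a tip mapped to a set (or tuple) of levels
    contributes a partial likelihood of 1 on each allowed level.
    """

    def __init__(self, values: Mapping[str, object],
                 levels: Sequence[str] | None = None):
        self.values: dict[str, frozenset[str]] = {}
        seen: dict[str, None] = {}
        for tip, val in values.items():
            if isinstance(val, str):
                lv = frozenset([val])
            else:
                lv = frozenset(val)
            if not lv:
                raise ValueError(f"tip {tip!r} has no level")
            self.values[tip] = lv
            for s in sorted(lv):
                seen.setdefault(s)
        if levels is None:
            levels = sorted(seen)
        self.levels: tuple[str, ...] = tuple(levels)
        missing = set(seen) - set(self.levels)
        if missing:
            raise ValueError(f"observed levels not in level set: {sorted(missing)}")

    def tip_matrix(self, tree: Tree, levels: Sequence[str] | None = None) -> np.ndarray:
        """(n_tips, k) indicator matrix of allowed levels, ordered by tip id."""
        levels = tuple(levels) if levels is not None else self.levels
        idx = {s: i for i, s in enumerate(levels)}
        L = np.zeros((tree.n_tips, len(levels)))
        for tip in tree.tips():
            lab = tree.labels[tip - 1]
            try:
                allowed = self.values[lab]
            except KeyError:
                raise KeyError(f"no trait value for tip {lab!r}") from None
            for s in allowed:
                if s not in idx:
                    raise ValueError(f"tip level {s!r} not in model levels")
                L[tip - 1, idx[s]] = 1.0
        return L

    @classmethod
    def from_csv(cls, path, levels=None, sep=None) -> "DiscreteTrait":
        import pandas as pd
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
        vals = {str(r[0]): str(r[1]) for r in df.itertuples(index=False)}
        return cls(vals, levels=levels)


@dataclass
class MkFit:
    """A fitted Mk model: design, ML rates, Q, root prior, logL, df, AIC."""

    design: DesignMatrix
    rates: np.ndarray
    Q: QMatrix
    prior: RootPrior
    loglik: float
    tree: Tree
    trait: DiscreteTrait
    converged: bool = True
    name: str = "mk"
    root_probs: np.ndarray | None = None  # realized pi (fitzjohn resolves here)

    @property
    def df(self) -> int:
        return int(self.design.n_classes)

    @property
    def aic(self) -> float:
        return 2.0 * self.df - 2.0 * self.loglik

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "levels": list(self.design.levels),
            "design": self.design.matrix.tolist(),
            "rates": self.rates.tolist(),
            "Q": self.Q.matrix.tolist(),
            "prior": self.prior.kind,
            "logLik": self.loglik,
            "df": self.df,
            "AIC": self.aic,
        }, indent=1)


@dataclass
class ModelTable:
    """AIC model comparison: names, logL, df, AIC, Akaike weights."""

    fits: list
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.fits:
            raise ValueError("need at least one fitted model")
        if not self.names:
            self.names = [getattr(f, "name", f"model{i+1}")
                          for i, f in enumerate(self.fits)]

    @property
    def loglik(self) -> np.ndarray:
        return np.array([f.loglik for f in self.fits])

    @property
    def df(self) -> np.ndarray:
        return np.array([f.df for f in self.fits])

    @property
    def aic(self) -> np.ndarray:
        return np.array([f.aic for f in self.fits])

    @property
    def weights(self) -> np.ndarray:
        a = self.aic
        d = a - a.min()
        w = np.exp(-d / 2.0)
        return w / w.sum()

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "log(L)": self.loglik, "d.f.": self.df,
            "AIC": self.aic, "weight": self.weights,
        }, index=self.names)

    def __repr__(self):
        return self.to_frame().to_string()


# ---------------------------------------------------------------------------
# transition probabilities


class _Propagator:
    """exp(Q t) for many t: eigendecomposition fast path, expm fallback."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self.k = Q.shape[0]
        self._eig = None
        if self.k > 1:
            try:
                w, V = np.linalg.eig(Q)
                cond = np.linalg.cond(V)
                if np.isfinite(cond) and cond < 1e8:
                    self._eig = (w, V, np.linalg.inv(V))
            except np.linalg.LinAlgError:
                pass

    def __call__(self, t: float) -> np.ndarray:
        return self.many(np.array([t]))[0]

    def many(self, ts: np.ndarray) -> np.ndarray:
        ts = np.asarray(ts, dtype=float)
        if self._eig is not None:
            w, V, Vinv = self._eig
            E = np.exp(np.multiply.outer(ts, w))  # (m, k)
            P = np.einsum("ij,tj,jl->til", V, E, Vinv)
            P = np.real(P)
        else:
            P = np.stack([_expm(self.Q * t) for t in ts])
        np.clip(P, 0.0, None, out=P)
        # renormalize rows (guards tiny negative round-off)
        P /= P.sum(axis=2, keepdims=True)
        return P


def _edge_propagators(tree: Tree, Q: np.ndarray) -> dict[int, np.ndarray]:
    prop = _Propagator(Q)
    nodes = [v for v in range(1, tree.n_nodes + 1) if v != tree.root]
    ts = tree.edge_length[nodes]
    P = prop.many(ts)
    return {v: P[i] for i, v in enumerate(nodes)}


# ---------------------------------------------------------------------------
# likelihood


def _prune(tree: Tree, tip_liks: np.ndarray, Q: np.ndarray,
           prior: RootPrior, return_partials: bool = False):
    """Felsenstein pruning with per-node rescaling.

    Returns (logL, pi, partials, edge_P) where partials[v] is the scaled
    conditional likelihood vector of the subtree below node v and pi the
    realized root prior (FitzJohn resolves to the normalized root partials).
    """
    k = Q.shape[0]
    P = _edge_propagators(tree, Q)
    D = np.zeros((tree.n_nodes + 1, k))
    logcomp = 0.0
    for v in tree.postorder():
        if tree.is_tip(v):
            D[v] = tip_liks[v - 1]
            continue
        vv = np.ones(k)
        for c in tree.children[v]:
            vv = vv * (P[c] @ D[c])
        if v == tree.root:
            if prior.kind == "fitzjohn":
                s = vv.sum()
                if s <= 0:
                    return -np.inf, None, D, P
                pi = vv / s
            elif prior.kind == "fixed":
                pi = prior.probs
            else:
                pi = np.full(k, 1.0 / k)
            vv = vv * pi
        comp = vv.sum()
        if comp <= 0 or not np.isfinite(comp):
            return -np.inf, None, D, P
        D[v] = vv / comp
        logcomp += np.log(comp)
    if return_partials:
        return logcomp, pi, D, P
    return logcomp, pi, None, None


def mk_loglik(tree: Tree, trait: DiscreteTrait, Q: QMatrix,
              prior: RootPrior = RootPrior("equal")) -> float:
    """Log-likelihood of tip data under the Mk process with rate matrix Q."""
    tips = trait.tip_matrix(tree, Q.levels)
    logL, _, _, _ = _prune(tree, tips, Q.matrix, prior)
    return float(logL)


# ---------------------------------------------------------------------------
# fitting


def build_design(k: int, model="ER", levels: Sequence[str] | None = None) -> DesignMatrix:
    """ER / SYM / ARD templates, or validate an explicit integer matrix.

    ER ties all allowed transitions to one class; SYM one class per
    unordered pair; ARD one class per ordered pair.
    """
    if levels is None:
        levels = tuple(f"s{i}" for i in range(1, k + 1))
    levels = tuple(levels)
    if len(levels) != k or k < 2:
        raise ValueError("need k >= 2 levels")
    if isinstance(model, str):
        m = np.zeros((k, k), dtype=int)
        if model == "ER":
            m[:] = 1
            np.fill_diagonal(m, 0)
        elif model == "SYM":
            c = 0
            for i in range(k):
                for j in range(i + 1, k):
                    c += 1
                    m[i, j] = m[j, i] = c
        elif model == "ARD":
            c = 0
            for i in range(k):
                for j in range(k):
                    if i != j:
                        c += 1
                        m[i, j] = c
        else:
            raise ValueError(f"unknown model {model!r}")
        return DesignMatrix(m, levels)
    m = np.asarray(model, dtype=int)
    # re-index classes to 1..m preserving the distinct positive values
    vals = sorted(set(m[m > 0].tolist()))
    remap = {v: i + 1 for i, v in enumerate(vals)}
    mm = np.zeros_like(m)
    for v, i in remap.items():
        mm[m == v] = i
    return DesignMatrix(mm, levels)


def fit_mk(tree: Tree, trait: DiscreteTrait, design="ER",
           prior: RootPrior | str = "equal", nstarts: int = 1,
           seed=None, name: str | None = None) -> MkFit:
    """Maximum-likelihood fit of an Mk model.

    Rates are optimized on the log scale (L-BFGS-B) with the conventional
    box [1e-12, 100 x tree height]; the default start is the total number
    of levels divided by the summed edge length, with additional random
    exponential restarts when ``nstarts > 1``.
    """
    if isinstance(prior, str):
        prior = RootPrior(prior)
    if not isinstance(design, DesignMatrix):
        design = build_design(len(trait.levels), design, trait.levels)
    tips = trait.tip_matrix(tree, design.levels)
    m = design.n_classes
    q0 = len(design.levels) / max(tree.total_edge_length(), 1e-12)
    lo, hi = 1e-12, 100.0 * max(tree.max_height(), 1e-12)
    rng = np.random.default_rng(seed)

    def nll(logq):
        Q = design.q_from_rates(np.exp(logq))
        logL, _, _, _ = _prune(tree, tips, Q.matrix, prior)
        return -logL if np.isfinite(logL) else 1e50

    best = None
    starts = [np.full(m, np.log(q0))]
    for _ in range(max(0, nstarts - 1)):
        starts.append(np.log(rng.exponential(q0, size=m)))
    bounds = [(np.log(lo), np.log(hi))] * m
    converged = False
    for s in starts:
        s = np.clip(s, np.log(lo), np.log(hi))
        res = minimize(nll, s, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    rates = np.exp(best.x)
    Q = design.q_from_rates(rates)
    logL, pi, _, _ = _prune(tree, tips, Q.matrix, prior)
    return MkFit(design, rates, Q, prior, float(logL), tree, trait,
                 converged=converged, name=name or "mk", root_probs=pi)


def compare_models(fits: Sequence, names: Sequence[str] | None = None) -> ModelTable:
    """Akaike-weight comparison table; w_i = exp(-dAIC_i/2) / sum_j."""
    return ModelTable(list(fits), list(names) if names else [])


# ---------------------------------------------------------------------------
# ancestral reconstruction


def _marginals_single(fit: MkFit, tips_too: bool = False) -> np.ndarray:
    """Marginal state probabilities by the up/down message-passing algorithm."""
    tree = fit.tree
    k = fit.Q.k
    tip_liks = fit.trait.tip_matrix(tree, fit.Q.levels)
    logL, pi, D, P = _prune(tree, tip_liks, fit.Q.matrix, fit.prior,
                            return_partials=True)
    if not np.isfinite(logL):
        raise ValueError("zero likelihood; cannot reconstruct")
    # up-pass: U[v] is the likelihood of everything outside v's subtree,
    # as seen at node v, times the root prior.
    U = np.zeros((tree.n_nodes + 1, k))
    U[tree.root] = pi
    down = {v: P[v] @ D[v] for v in range(1, tree.n_nodes + 1) if v != tree.root}
    for v in tree.preorder():
        for c in tree.children[v]:
            sib = np.ones(k)
            for c2 in tree.children[v]:
                if c2 != c:
                    sib = sib * down[c2]
            msg = U[v] * sib
            U[c] = P[c].T @ msg
            s = U[c].sum()
            if s > 0:
                U[c] /= s
    M = (U * D)[1:]
    M /= M.sum(axis=1, keepdims=True)
    if tips_too:
        return M
    return M[tree.n_tips:]


def _joint_single(fit: MkFit) -> dict[int, str]:
    """Most-probable joint assignment (max-product; ties to lowest index)."""
    tree = fit.tree
    k = fit.Q.k
    tips = fit.trait.tip_matrix(tree, fit.Q.levels)
    P = _edge_propagators(tree, fit.Q.matrix)
    # L[v][j] = max log-prob of subtree below v given parent state j (after edge)
    Lmax = np.zeros((tree.n_nodes + 1, k))
    argmax = np.zeros((tree.n_nodes + 1, k), dtype=int)
    with np.errstate(divide="ignore"):
        for v in tree.postorder():
            if v == tree.root:
                continue
            if tree.is_tip(v):
                own = np.log(tips[v - 1])
            else:
                own = np.sum([Lmax[c] for c in tree.children[v]], axis=0)
            scores = np.log(P[v]) + own[None, :]  # (parent, child)
            argmax[v] = np.argmax(scores, axis=1)
            Lmax[v] = scores[np.arange(k), argmax[v]]
        pi = fit.root_probs if fit.root_probs is not None else np.full(k, 1.0 / k)
        root_score = np.log(pi) + np.sum(
            [Lmax[c] for c in tree.children[tree.root]], axis=0)
    states: dict[int, int] = {tree.root: int(np.argmax(root_score))}
    for v in tree.preorder():
        for c in tree.children[v]:
            states[c] = int(argmax[c][states[v]])
    return {v: fit.Q.levels[s] for v, s in states.items()}


def ancr(model, method: str = "marginal", tips: bool = False):
    """Ancestral state reconstruction under one model or a weighted set.

    With a :class:`ModelTable`, marginals are model-averaged with Akaike
    weights.  Returns a pandas DataFrame of per-node state probabilities
    (rows indexed by node id) for ``method='marginal'``, or a node->state
    dict for ``method='joint'``.
    """
    import pandas as pd
    if method == "joint":
        if isinstance(model, ModelTable):
            best = model.fits[int(np.argmax(model.weights))]
            return _joint_single(best)
        return _joint_single(model)
    if isinstance(model, ModelTable):
        fits = model.fits
        w = model.weights
        trees = {id(f.tree) for f in fits}
        levels = {f.Q.levels for f in fits}
        if len(levels) > 1:
            raise ValueError("models reconstruct different level sets")
        M = sum(wi * _marginals_single(f, tips_too=tips)
                for wi, f in zip(w, fits))
        fit0 = fits[0]
    else:
        fit0 = model
        M = _marginals_single(model, tips_too=tips)
    tree = fit0.tree
    start = 1 if tips else tree.n_tips + 1
    idx = list(range(start, tree.n_nodes + 1))
    return pd.DataFrame(M, index=idx, columns=list(fit0.Q.levels))


# ---------------------------------------------------------------------------
# simulation


def _sim_path(state: int, t: float, Q: np.ndarray, rng) -> list[tuple[int, float]]:
    """Forward-simulate one edge; returns (state, duration) segments."""
    segs = []
    pos = 0.0
    while True:
        rate = -Q[state, state]
        if rate <= 0:
            segs.append((state, t - pos))
            return segs
        wait = rng.exponential(1.0 / rate)
        if pos + wait >= t:
            segs.append((state, t - pos))
            return segs
        segs.append((state, wait))
        pos += wait
        p = Q[state].copy()
        p[state] = 0.0
        p /= p.sum()
        state = int(rng.choice(len(p), p=p))


def sim_mk(tree: Tree, Q: QMatrix, root_state: str | None = None,
           root_prior: np.ndarray | None = None, seed=None,
           history: bool = False):
    """Simulate a discrete trait down the tree under Q.

    Returns a :class:`DiscreteTrait`, or ``(trait, MappedTree)`` when
    ``history=True`` (the mapped tree carries the full realized history).
    """
    rng = np.random.default_rng(seed)
    k = Q.k
    if root_state is not None:
        s0 = Q.levels.index(root_state)
    else:
        p = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)
        s0 = int(rng.choice(k, p=p / p.sum()))
    node_state = {tree.root: s0}
    maps: dict[int, list[tuple[str, float]]] = {}
    for v in tree.preorder():
        for c in tree.children[v]:
            segs = _sim_path(node_state[v], tree.edge_length[c], Q.matrix, rng)
            node_state[c] = segs[-1][0]
            maps[c] = [(Q.levels[s], d) for s, d in _merge_segments(segs)]
    vals = {tree.labels[t - 1]: Q.levels[node_state[t]] for t in tree.tips()}
    trait = DiscreteTrait(vals, levels=Q.levels)
    if history:
        mt = MappedTree(tree.parent.copy(), tree.edge_length.copy(),
                        list(tree.labels), maps)
        return trait, mt
    return trait


def _merge_segments(segs: list[tuple[int, float]]) -> list[tuple[int, float]]:
    out: list[tuple[int, float]] = []
    for s, d in segs:
        if out and out[-1][0] == s:
            out[-1] = (s, out[-1][1] + d)
        else:
            out.append((s, d))
    return out
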