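"""Stochastic character mapping and summaries of sampled histories.

Histories are sampled model-by-model: node states are drawn from their
joint conditional distribution (root from prior x partial likelihoods,
then preorder conditional sampling given the sampled parent), and each
edge's path is simulated conditional on its endpoint states, by forward
rejection sampling with a uniformization fallback.  With a model table,
each replicate first draws a model in proportion to its Akaike weight,
which averages the mapped histories over model uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mk import MkFit, ModelTable, _prune
from .tree import MappedTree, Tree

__all__ = [
    "MapSet",
    "ChangeDensity",
    "sample_maps",
    "summarize_maps",
    "change_density",
    "density_map",
    "ltt_by_state",
]


@dataclass
class MapSet:
    """A set of stochastic character maps sharing one tree and tip data."""

    maps: list[MappedTree]
    levels: tuple[str, ...]
    model_index: np.ndarray            # which model generated each map
    weights: np.ndarray                # sampling weights over models
    seed: object = None

    def __len__(self):
        return len(self.maps)

    @property
    def tree(self) -> Tree:
        return self.maps[0]


@dataclass
class ChangeDensity:
    """Distribution of state-change counts over a map set, per ordered pair."""

    counts: dict[tuple[str, str], np.ndarray]
    summary: "object" = field(default=None)  # pandas DataFrame
    hpd: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# endpoint-conditioned path simulation


def _path_rejection(a: int, b: int, t: float, Q: np.ndarray, rng,
                    max_tries: int = 1000):
    k = Q.shape[0]
    for _ in range(max_tries):
        segs = []
        s, pos = a, 0.0
        ok = True
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                segs.append((s, t - pos))
                break
            wait = rng.exponential(1.0 / rate)
            if pos + wait >= t:
                segs.append((s, t - pos))
                break
            segs.append((s, wait))
            pos += wait
            p = Q[s].copy()
            p[s] = 0.0
            p /= p.sum()
            s = int(rng.choice(k, p=p))
        if segs[-1][0] == b:
            return segs
    return None


def _path_uniformization(a: int, b: int, t: float, Q: np.ndarray,
                         P_t: np.ndarray, rng, nmax: int = 10_000):
    """Sample a path conditioned on endpoints by uniformization."""
    mu = max(-Q.diagonal().min(), 1e-300)
    k = Q.shape[0]
    R = np.eye(k) + Q / mu
    # P(N = n | a -> b in t) propto Pois(n; mu t) * R^n[a, b]
    pab = max(P_t[a, b], 1e-300)
    Rpow = np.eye(k)
    log_pois = -mu * t
    probs = []
    Rpows = [Rpow]
    total = 0.0
    for n in range(nmax):
        pn = math.exp(log_pois) * Rpow[a, b] / pab
        probs.append(pn)
        total += pn
        if total > 1 - 1e-10 and n > 2:
            break
        Rpow = Rpow @ R
        Rpows.append(Rpow)
        log_pois += math.log(mu * t) - math.log(n + 1)
    probs = np.array(probs)
    probs /= probs.sum()
    N = int(rng.choice(len(probs), p=probs))
    # sample the virtual-jump state sequence backwards
    states = [a]
    for i in range(1, N + 1):
        prev = states[-1]
        w = R[prev, :] * Rpows[N - i][:, b]
        w = np.clip(w, 0.0, None)
        if w.sum() <= 0:
            w = R[prev, :].copy()
        states.append(int(rng.choice(k, p=w / w.sum())))
    if N == 0:
        return [(a, t)]
    times = np.sort(rng.uniform(0.0, t, size=N))
    segs = []
    cur, last = a, 0.0
    for st, tm in zip(states[1:], times):
        if st != cur:
            segs.append((cur, tm - last))
            cur, last = st, tm
    segs.append((cur, t - last))
    return segs


def _merge(segs):
    out = []
    for s, d in segs:
        if out and out[-1][0] == s:
            out[-1] = (s, out[-1][1] + d)
        else:
            out.append((s, d))
    return out


# ---------------------------------------------------------------------------
# sampling


def _prep(fit: MkFit):
    tips = fit.trait.tip_matrix(fit.tree, fit.Q.levels)
    logL, pi, D, P = _prune(fit.tree, tips, fit.Q.matrix, fit.prior,
                            return_partials=True)
    if not np.isfinite(logL):
        raise ValueError("model has zero likelihood on its data")
    prop = {v: P[v] for v in P}
    return D, prop, pi


def sample_maps(model: MkFit | ModelTable, nsim: int = 100,
                weighted: bool = True, seed=None) -> MapSet:
    """Draw ``nsim`` stochastic character maps.

    ``model`` may be a single fit or a model table; with a table and
    ``weighted=True`` each replicate samples its generating model with
    probability equal to the model's Akaike weight, otherwise the
    best-AIC model is used throughout.
    """
    rng = np.random.default_rng(seed)
    if isinstance(model, ModelTable):
        fits = model.fits
        w = model.weights if weighted else None
        if w is None:
            best = int(np.argmin(model.aic))
            fits, w = [fits[best]], np.array([1.0])
    else:
        fits, w = [model], np.array([1.0])
    levels = fits[0].Q.levels
    for f in fits:
        if f.Q.levels != levels:
            raise ValueError("models have different level sets")
    tree = fits[0].tree
    prepped = [_prep(f) for f in fits]
    k = len(levels)

    maps = []
    chosen = rng.choice(len(fits), p=w, size=nsim)
    for mi in chosen:
        fit = fits[mi]
        D, P, pi = prepped[mi]
        Q = fit.Q.matrix
        # joint node-state draw: root, then preorder conditionals
        state = {}
        p0 = D[tree.root] / D[tree.root].sum()
        state[tree.root] = int(rng.choice(k, p=p0))
        edges: dict[int, list] = {}
        for u in tree.preorder():
            for c in tree.children[u]:
                pc = P[c][state[u], :] * D[c]
                pc = pc / pc.sum()
                state[c] = int(rng.choice(k, p=pc))
                segs = _path_rejection(state[u], state[c],
                                       tree.edge_length[c], Q, rng)
                if segs is None:
                    segs = _path_uniformization(state[u], state[c],
                                                tree.edge_length[c], Q,
                                                P[c], rng)
                edges[c] = [(levels[s], d) for s, d in _merge(segs)]
        maps.append(MappedTree(tree.parent.copy(), tree.edge_length.copy(),
                               list(tree.labels), edges))
    return MapSet(maps, levels, np.asarray(chosen), w, seed)


# ---------------------------------------------------------------------------
# summaries


def summarize_maps(mapset: MapSet):
    """Node-state frequency table plus mean change counts.

    Returns ``(freqs, mean_changes)``: a DataFrame of per-node state
    frequencies over the maps (rows = internal node ids, each summing to
    1), and a DataFrame of mean transition counts per ordered state pair
    (with the overall mean total under key ``('total', 'total')``).
    """
    import pandas as pd
    if not mapset.maps:
        raise ValueError("empty map set")
    tree = mapset.tree
    levels = mapset.levels
    idx = {s: i for i, s in enumerate(levels)}
    nodes = list(range(tree.n_tips + 1, tree.n_nodes + 1))
    F = np.zeros((len(nodes), len(levels)))
    for m in mapset.maps:
        for r, v in enumerate(nodes):
            F[r, idx[m.state_at_node(v)]] += 1
    F /= len(mapset.maps)
    freqs = pd.DataFrame(F, index=nodes, columns=list(levels))
    cd = change_density(mapset)
    rows = {pair: float(np.mean(c)) for pair, c in cd.counts.items()}
    rows[("total", "total")] = float(np.sum(list(rows.values())))
    mean_changes = pd.Series(rows).rename("mean_changes")
    return freqs, mean_changes


def _hpd_discrete(sample: np.ndarray, level: float = 0.95) -> tuple[int, int]:
    """Shortest contiguous interval of the empirical distribution holding
    at least ``level`` of the sample."""
    vals = np.sort(sample)
    n = len(vals)
    m = int(np.ceil(level * n))
    widths = vals[m - 1:] - vals[:n - m + 1]
    i = int(np.argmin(widths))
    return int(vals[i]), int(vals[i + m - 1])


def change_density(mapset: MapSet, level: float = 0.95) -> ChangeDensity:
    """Per-transition-type change-count distributions with HPD intervals."""
    import pandas as pd
    levels = mapset.levels
    pairs = [(a, b) for a in levels for b in levels if a != b]
    counts = {p: np.zeros(len(mapset.maps), dtype=int) for p in pairs}
    for i, m in enumerate(mapset.maps):
        for v, segs in m.maps.items():
            # count within-edge changes plus none at nodes (segments are
            # continuous across nodes by construction)
            for (s1, _), (s2, _) in zip(segs[:-1], segs[1:]):
                if s1 != s2:
                    counts[(s1, s2)][i] += 1
    hpd = {p: _hpd_discrete(c, level) for p, c in counts.items()}
    summ = pd.DataFrame({
        "min": {p: c.min() for p, c in counts.items()},
        "median": {p: float(np.median(c)) for p, c in counts.items()},
        "mean": {p: float(np.mean(c)) for p, c in counts.items()},
        "max": {p: c.max() for p, c in counts.items()},
        "hpd_low": {p: hpd[p][0] for p in pairs},
        "hpd_high": {p: hpd[p][1] for p in pairs},
    })
    return ChangeDensity(counts, summ, hpd)


def _state_at_position(segs, pos: float) -> str:
    acc = 0.0
    for s, d in segs:
        acc += d
        if pos <= acc + 1e-12:
            return s
    return segs[-1][0]


def density_map(mapset: MapSet, res: int = 100):
    """Per-edge posterior probability of the second state of a binary trait.

    Each edge is evaluated at ``res + 1`` evenly spaced points (both ends
    included); the value at a point is the fraction of maps whose history
    is in ``levels[1]`` there.  Returns ``{child node id: array}``.
    """
    if len(mapset.levels) != 2:
        raise ValueError("density_map requires a binary mapped character")
    hot = mapset.levels[1]
    tree = mapset.tree
    out = {}
    for v in range(1, tree.n_nodes + 1):
        if v == tree.root:
            continue
        t = tree.edge_length[v]
        grid = np.linspace(0.0, t, res + 1)
        acc = np.zeros(res + 1)
        for m in mapset.maps:
            segs = m.maps[v]
            bounds = np.cumsum([d for _, d in segs])
            ix = np.searchsorted(bounds - 1e-12, grid)
            ix = np.clip(ix, 0, len(segs) - 1)
            acc += np.array([segs[i][0] == hot for i in ix], dtype=float)
        out[v] = acc / len(mapset.maps)
    return out


def ltt_by_state(mapset: MapSet, return_per_map: bool = True):
    """Lineage counts per mapped state through time.

    Returns ``(times, mean_counts, per_map)``: the pooled event-time grid
    (node heights plus state-change points across all maps), the pointwise
    mean count per state (len(times) x k, right-continuous), and — unless
    ``return_per_map=False`` — the per-map count matrices on the same
    grid.  Rows sum to the total number of lineages present at that time.
    """
    tree = mapset.tree
    levels = mapset.levels
    idx = {s: i for i, s in enumerate(levels)}
    h = tree.node_heights()
    H = h[1:tree.n_tips + 1].max()

    all_ev = {0.0, H}
    for m in mapset.maps:
        for v in range(1, tree.n_nodes + 1):
            if v == tree.root:
                continue
            all_ev.add(h[tree.parent[v]])
            acc = h[tree.parent[v]]
            for _, d in m.maps[v][:-1]:
                acc += d
                all_ev.add(acc)
    times = np.array(sorted(all_ev))
    eps = 1e-9 * max(H, 1.0)
    eval_at = np.minimum(times + eps, H - eps)
    nt, k = len(times), len(levels)

    # per map: difference-array accumulation per state segment interval
    per_map = [] if return_per_map else None
    total = np.zeros((nt, k))
    for m in mapset.maps:
        diff = np.zeros((nt + 1, k))
        for v in range(1, tree.n_nodes + 1):
            if v == tree.root:
                continue
            a = h[tree.parent[v]]
            for j, (s, d) in enumerate(m.maps[v]):
                b = a + d
                hi_t = np.inf if (tree.is_tip(v) and j == len(m.maps[v]) - 1) else b
                i0 = int(np.searchsorted(eval_at, a))
                i1 = int(np.searchsorted(eval_at, hi_t)) if np.isfinite(hi_t) else nt
                if i1 > i0:
                    diff[i0, idx[s]] += 1
                    diff[i1, idx[s]] -= 1
                a = b
        counts = np.cumsum(diff[:-1], axis=0)
        total += counts
        if return_per_map:
            per_map.append(counts)
    mean = total / len(mapset.maps)
    return times, mean, per_map
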