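"""State-space expansions of the Mk model.

Two families are built here and fitted through the shared pruning engine:

* the polymorphic trait evolution model, in which a transition between
  monomorphic levels a and b must pass through the polymorphic condition
  "a+b", and polymorphism is gained/lost one level at a time; and
* the hidden-rates model, in which each observed level carries one or more
  unobserved rate categories (starred labels: O, O*, O**, ...).  The
  "umbral" variant permits observed-state change only from the labile
  (unstarred) category.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .mk import DesignMatrix, DiscreteTrait, MkFit, RootPrior, fit_mk
from .tree import Tree

__all__ = [
    "PolyStateSpace",
    "HRMStateSpace",
    "build_poly_space",
    "fit_polymk",
    "build_hrm_space",
    "fit_hrm",
    "canonical_condition",
]


def canonical_condition(cond: str, order: Sequence[str] | None = None) -> str:
    """Canonicalize a '+'-joined polymorphic condition ('b+a' -> 'a+b')."""
    parts = [p.strip() for p in cond.split("+")]
    if order is not None:
        pos = {s: i for i, s in enumerate(order)}
        parts = sorted(parts, key=lambda s: pos[s])
    else:
        parts = sorted(parts)
    return "+".join(parts)


@dataclass(frozen=True)
class PolyStateSpace:
    """Monomorphic levels plus polymorphic conditions, with a design matrix."""

    levels: tuple[str, ...]          # monomorphic levels (in order if ordered)
    states: tuple[str, ...]          # full state labels, canonicalized
    design: DesignMatrix
    ordered: bool
    model: str

    def canonical(self, cond: str) -> str:
        lab = canonical_condition(cond, self.levels if self.ordered else None)
        if lab not in self.states:
            raise ValueError(f"condition {cond!r} not in state space")
        return lab


def _poly_states(levels: Sequence[str], ordered: bool) -> list[tuple[str, ...]]:
    k = len(levels)
    if ordered:
        subsets = [tuple(levels[i:j + 1]) for i in range(k) for j in range(i, k)]
    else:
        subsets = [c for r in range(1, k + 1) for c in combinations(sorted(levels), r)]
    # monomorphic first, then by polymorphism size, then componentwise
    pos = {s: i for i, s in enumerate(levels)}
    subsets.sort(key=lambda s: (len(s), tuple(pos[x] for x in s)))
    return subsets


def build_poly_space(levels: Sequence[str], ordered: bool = False,
                     order: Sequence[str] | None = None,
                     model: str = "ER") -> PolyStateSpace:
    """Construct the polymorphic state space and its design matrix.

    Unordered: all non-empty subsets of the monomorphic levels.  Ordered:
    contiguous runs of the level order only, and polymorphism is gained or
    lost at the ends of the run.  ``model`` is 'ER' (one shared rate),
    'ARD' (one class per ordered transition) or 'transient' (one class for
    every polymorphism-increasing move, another for every decreasing move).
    """
    if ordered:
        if order is not None:
            if set(order) != set(levels):
                raise ValueError("order must cover exactly the monomorphic levels")
            levels = list(order)
        else:
            levels = sorted(levels)  # alphanumeric default
    else:
        levels = sorted(levels)
    if model not in ("ER", "ARD", "transient"):
        raise ValueError("model must be ER, ARD or transient")
    subsets = _poly_states(levels, ordered)
    labels = tuple("+".join(s) for s in subsets)
    sets = [frozenset(s) for s in subsets]
    k = len(sets)
    allowed = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            a, b = sets[i], sets[j]
            if len(a ^ b) == 1 and (a < b or b < a):
                allowed[i, j] = True
    design = np.zeros((k, k), dtype=int)
    if model == "ER":
        design[allowed] = 1
    elif model == "transient":
        for i in range(k):
            for j in range(k):
                if allowed[i, j]:
                    design[i, j] = 1 if len(sets[j]) > len(sets[i]) else 2
    else:  # ARD
        c = 0
        for i in range(k):
            for j in range(k):
                if allowed[i, j]:
                    c += 1
                    design[i, j] = c
    return PolyStateSpace(tuple(levels), labels, DesignMatrix(design, labels),
                          ordered, model)


def fit_polymk(tree: Tree, trait: Mapping[str, str] | DiscreteTrait,
               model: str = "ER", ordered: bool = False,
               order: Sequence[str] | None = None,
               prior: RootPrior | str = "equal", nstarts: int = 1,
               seed=None, name: str | None = None) -> MkFit:
    """ML fit of the polymorphic trait model (delegates to the Mk engine).

    ``trait`` maps tip label -> condition string with '+' separating the
    levels of a polymorphic condition (order-insensitive).
    """
    if isinstance(trait, DiscreteTrait):
        values = {tip: "+".join(sorted(v)) if len(v) > 1 else next(iter(v))
                  for tip, v in trait.values.items()}
    else:
        values = dict(trait)
    comps: set[str] = set()
    for cond in values.values():
        comps.update(p.strip() for p in cond.split("+"))
    space = build_poly_space(sorted(comps), ordered=ordered, order=order,
                             model=model)
    canon = {tip: space.canonical(cond) for tip, cond in values.items()}
    dtrait = DiscreteTrait(canon, levels=space.states)
    fit = fit_mk(tree, dtrait, space.design, prior=prior, nstarts=nstarts,
                 seed=seed, name=name or f"polyMk-{model}"
                 f"-{'ordered' if ordered else 'unordered'}")
    fit.space = space
    return fit


# ---------------------------------------------------------------------------
# hidden-rates model


@dataclass(frozen=True)
class HRMStateSpace:
    """Expanded (level, rate-category) state space for the hidden-rates model."""

    levels: tuple[str, ...]
    ncat: tuple[int, ...]
    states: tuple[str, ...]     # e.g. ("O", "O*", "V", "V*")
    design: DesignMatrix
    umbral: bool

    def hidden_of(self, level: str) -> tuple[str, ...]:
        i = self.levels.index(level)
        return tuple(level + "*" * j for j in range(self.ncat[i]))


def build_hrm_space(levels: Sequence[str], ncat=2,
                    umbral: bool = False) -> HRMStateSpace:
    """Expanded state space and design for the hidden-rates model.

    Each observed level gets ``ncat`` rate categories (an int, or one per
    level); hidden moves step between adjacent categories of the same
    level.  Observed-state moves connect equal categories of different
    levels — or, under the umbral variant, only the labile (category-0)
    conditions.  Every allowed transition is its own rate class, numbered
    row-major to match conventional design print-outs.
    """
    levels = tuple(sorted(levels))
    if isinstance(ncat, int):
        ncats = tuple(ncat for _ in levels)
    else:
        ncats = tuple(int(c) for c in ncat)
    if len(ncats) != len(levels) or any(c < 1 for c in ncats):
        raise ValueError("ncat must be >= 1 per level")
    states: list[tuple[str, int]] = []
    for lev, c in zip(levels, ncats):
        for j in range(c):
            states.append((lev, j))
    labels = tuple(lev + "*" * j for lev, j in states)
    k = len(states)
    allowed = np.zeros((k, k), dtype=bool)
    for i, (la, ca) in enumerate(states):
        for j, (lb, cb) in enumerate(states):
            if i == j:
                continue
            if la == lb and abs(ca - cb) == 1:
                allowed[i, j] = True            # hidden-category move
            elif la != lb:
                if umbral:
                    if ca == 0 and cb == 0:
                        allowed[i, j] = True    # labile observed move
                elif ca == cb:
                    allowed[i, j] = True        # observed move, same category
    design = np.zeros((k, k), dtype=int)
    c = 0
    for i in range(k):
        for j in range(k):
            if allowed[i, j]:
                c += 1
                design[i, j] = c
    return HRMStateSpace(levels, ncats, labels, DesignMatrix(design, labels),
                         umbral)


def fit_hrm(tree: Tree, trait: Mapping[str, str] | DiscreteTrait, ncat=2,
            umbral: bool = False, prior: RootPrior | str = "fitzjohn",
            nstarts: int = 10, seed=None, name: str | None = None) -> MkFit:
    """ML fit of the hidden-rates model.

    Observed tip states are spread across their hidden categories (partial
    likelihood 1 on each).  The model is weakly identified, so ``nstarts``
    random restarts (default 10) are used.  ``ncat=1`` reduces to a plain
    ARD Mk fit.
    """
    if isinstance(trait, DiscreteTrait):
        values = {tip: next(iter(v)) if len(v) == 1 else tuple(v)
                  for tip, v in trait.values.items()}
    else:
        values = dict(trait)
    observed = sorted({v for v in values.values() if isinstance(v, str)})
    space = build_hrm_space(observed, ncat=ncat, umbral=umbral)
    expanded = {}
    for tip, v in values.items():
        if isinstance(v, str):
            expanded[tip] = space.hidden_of(v)
        else:  # ambiguous observed state: union of hidden levels
            expanded[tip] = tuple(h for lev in v for h in space.hidden_of(lev))
    dtrait = DiscreteTrait(expanded, levels=space.states)
    fit = fit_mk(tree, dtrait, space.design, prior=prior, nstarts=nstarts,
                 seed=seed, name=name or ("umbral" if umbral else "hrm"))
    fit.space = space
    return fit
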