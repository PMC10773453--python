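"""Rooted phylogenetic trees: data model, Newick/SIMMAP I/O, and simulation.

Node numbering follows the convention of the major comparative-methods
ecosystems: tips are ``1..n`` in the order they appear in the source text,
the root is ``n + 1``, and internal nodes are ``n+1 .. 2n-1`` assigned in
preorder ("cladewise").  Keeping this convention means node-indexed result
tables (ancestral states, posterior node samples) can be compared
row-for-row with published print-outs.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tree",
    "MappedTree",
    "TreeParseError",
    "parse_tree",
    "write_tree",
    "node_heights",
    "drop_tips",
    "sim_bd_tree",
    "ExtinctionError",
]


class TreeParseError(ValueError):
    """Raised on malformed Newick/SIMMAP text; carries the character offset."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)
        self.offset = offset


class ExtinctionError(RuntimeError):
    """All lineages died before the simulation's stopping condition."""


class Tree:
    """A rooted, edge-length-bearing phylogeny with integer node ids.

    Parameters
    ----------
    parent : sequence of int, indexed by node id (entry 0 unused); the
        root's parent is 0.
    edge_length : sequence of float indexed by child node id; the root's
        entry is ignored (held at 0).
    labels : tip labels; ``labels[i - 1]`` is the label of tip ``i``.
    """

    def __init__(self, parent: Sequence[int], edge_length: Sequence[float],
                 labels: Sequence[str]):
        self.parent = np.asarray(parent, dtype=int)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.labels = list(labels)
        self.n_tips = len(self.labels)
        if len(set(self.labels)) != self.n_tips:
            raise ValueError("tip labels must be unique")
        n_nodes = self.parent.shape[0] - 1
        self.n_nodes = n_nodes
        self.root = self.n_tips + 1
        if np.any(self.edge_length[1:] < 0):
            raise ValueError("negative edge length")
        roots = [v for v in range(1, n_nodes + 1) if self.parent[v] == 0]
        if roots != [self.root]:
            raise ValueError(f"tree must have exactly one root at node {self.root}")
        self.children: list[list[int]] = [[] for _ in range(n_nodes + 1)]
        for v in range(1, n_nodes + 1):
            p = self.parent[v]
            if p:
                self.children[p].append(v)
        self.edge_length = self.edge_length.copy()
        self.edge_length[self.root] = 0.0

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def postorder(self) -> list[int]:
        return self.preorder()[::-1]

    def tips(self) -> range:
        return range(1, self.n_tips + 1)

    def internals(self) -> range:
        return range(self.n_tips + 1, self.n_nodes + 1)

    def is_tip(self, v: int) -> bool:
        return 1 <= v <= self.n_tips

    def tip_index(self, label: str) -> int:
        try:
            return self.labels.index(label) + 1
        except ValueError:
            raise KeyError(f"unknown tip label: {label!r}") from None

    # -- geometry ----------------------------------------------------------

    def node_heights(self) -> np.ndarray:
        """Height above the root for every node (index by node id)."""
        h = np.zeros(self.n_nodes + 1)
        for v in self.preorder():
            if v != self.root:
                h[v] = h[self.parent[v]] + self.edge_length[v]
        return h

    def max_height(self) -> float:
        return float(self.node_heights()[1:].max())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        th = self.node_heights()[1:self.n_tips + 1]
        return bool(np.ptp(th) <= rtol * max(th.max(), 1e-300))

    def branching_times(self) -> np.ndarray:
        """Ages (time before the present) of internal nodes, ultrametric trees."""
        h = self.node_heights()
        H = h[1:self.n_tips + 1].max()
        return H - h[self.n_tips + 1:self.n_nodes + 1]

    def total_edge_length(self) -> float:
        return float(self.edge_length[1:].sum())

    def mrca_heights(self) -> np.ndarray:
        """n x n matrix of the height of the MRCA of every tip pair (0-indexed)."""
        n = self.n_tips
        h = self.node_heights()
        C = np.zeros((n, n))
        # accumulate tip descendants up the tree
        desc: dict[int, list[int]] = {v: [v - 1] for v in self.tips()}
        for v in self.postorder():
            if self.is_tip(v):
                continue
            kids = [desc[c] for c in self.children[v]]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    a = np.array(kids[i])
                    b = np.array(kids[j])
                    C[np.ix_(a, b)] = h[v]
                    C[np.ix_(b, a)] = h[v]
            desc[v] = [t for k in kids for t in k]
        th = h[1:n + 1]
        C[np.diag_indices(n)] = th
        return C

    # -- misc ---------------------------------------------------------------

    def copy(self) -> "Tree":
        return Tree(self.parent.copy(), self.edge_length.copy(), list(self.labels))

    def __repr__(self):
        return f"<{type(self).__name__} with {self.n_tips} tips>"

    def write(self, digits: int = 12) -> str:
        return write_tree(self, digits=digits)


class MappedTree(Tree):
    """A tree whose edges carry an ordered (state, duration) segment list.

    ``maps[v]`` holds the segments of the edge above node ``v``, running
    rootward to tipward; durations are non-negative and sum to the edge
    length (within 1e-8).
    """

    def __init__(self, parent, edge_length, labels,
                 maps: dict[int, list[tuple[str, float]]]):
        super().__init__(parent, edge_length, labels)
        self.maps = {v: list(segs) for v, segs in maps.items()}
        for v in range(1, self.n_nodes + 1):
            if v == self.root:
                continue
            segs = self.maps.get(v)
            if not segs:
                raise ValueError(f"edge above node {v} has no segment map")
            tot = sum(d for _, d in segs)
            if any(d < 0 for _, d in segs):
                raise ValueError("negative segment duration")
            if abs(tot - self.edge_length[v]) > 1e-8 * max(1.0, self.edge_length[v]):
                raise ValueError(
                    f"segments on edge above node {v} sum to {tot}, "
                    f"edge length is {self.edge_length[v]}")

    @property
    def states(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in sorted(self.maps):
            for s, _ in self.maps[v]:
                seen.setdefault(s)
        return sorted(seen)

    def state_at_node(self, v: int) -> str:
        """State of the segment adjacent to node v (tipward end of its edge)."""
        if v == self.root:
            c = self.children[v][0]
            return self.maps[c][0][0]
        return self.maps[v][-1][0]

    def mapped_edge(self) -> dict[str, np.ndarray]:
        """Total time spent in each state on each edge (indexed by child id)."""
        out = {s: np.zeros(self.n_nodes + 1) for s in self.states}
        for v, segs in self.maps.items():
            for s, d in segs:
                out[s][v] += d
        return out

    def as_tree(self) -> Tree:
        return Tree(self.parent.copy(), self.edge_length.copy(), list(self.labels))

    def copy(self) -> "MappedTree":
        return MappedTree(self.parent.copy(), self.edge_length.copy(),
                          list(self.labels), self.maps)


# ---------------------------------------------------------------------------
# parsing


def _tokenize_label(text: str, i: int) -> tuple[str, int]:
    if i < len(text) and text[i] in "'\"":
        q = text[i]
        j = i + 1
        out = []
        while j < len(text):
            if text[j] == q:
                if j + 1 < len(text) and text[j + 1] == q:  # doubled quote
                    out.append(q)
                    j += 2
                    continue
                return "".join(out), j + 1
            out.append(text[j])
            j += 1
        raise TreeParseError("unterminated quoted label", i)
    j = i
    while j < len(text) and text[j] not in "(),:;{}[]":
        j += 1
    return text[i:j].strip(), j


def _parse_number(text: str, i: int) -> tuple[float, int]:
    j = i
    while j < len(text) and (text[j] in "+-.eE" or text[j].isdigit()):
        j += 1
    try:
        return float(text[i:j]), j
    except ValueError:
        raise TreeParseError(f"bad number {text[i:j]!r}", i) from None


def _parse_segments(text: str, i: int) -> tuple[list[tuple[str, float]], int]:
    """Parse ``{state,len:state,len:...}`` starting at the '{'."""
    if text[i] != "{":
        raise TreeParseError("expected '{'", i)
    j = i + 1
    segs: list[tuple[str, float]] = []
    while True:
        state, j = _tokenize_label(text, j)
        if j >= len(text) or text[j] != ",":
            raise TreeParseError("expected ',' in segment", j)
        dur, j = _parse_number(text, j + 1)
        if dur < 0:
            raise TreeParseError("negative segment duration", j)
        segs.append((state, dur))
        if j < len(text) and text[j] == ":":
            j += 1
            continue
        if j < len(text) and text[j] == "}":
            return segs, j + 1
        raise TreeParseError("expected ':' or '}' in segment list", j)


def parse_tree(text: str, format: str = "newick") -> Tree | MappedTree:
    """Parse a Newick or SIMMAP-extended Newick string into a tree.

    The SIMMAP dialect attaches ``{state,len:state,len:...}`` in place of a
    plain branch length; segments are stored rootward -> tipward.  Per-edge
    segment order in the text is auto-detected from state continuity at the
    nodes and normalized.
    """
    if format not in ("newick", "simmap"):
        raise ValueError("format must be 'newick' or 'simmap'")
    text = text.strip()
    if not text.endswith(";"):
        raise TreeParseError("tree text must end with ';'", len(text))

    tip_labels: list[str] = []
    # temp structure: nested lists built by recursive descent
    # node record: [children, label, length, segments]

    def parse_clade(i: int):
        children = []
        label = ""
        length = None
        segs = None
        if text[i] == "(":
            i += 1
            while True:
                child, i = parse_clade(i)
                children.append(child)
                if i >= len(text):
                    raise TreeParseError("unexpected end of text", i)
                if text[i] == ",":
                    i += 1
                    continue
                if text[i] == ")":
                    i += 1
                    break
                raise TreeParseError(f"unexpected {text[i]!r}", i)
        if i < len(text) and text[i] not in "(),:;{}":
            label, i = _tokenize_label(text, i)
        if i < len(text) and text[i] == ":":
            i += 1
            if i < len(text) and text[i] == "{":
                segs, i = _parse_segments(text, i)
                length = sum(d for _, d in segs)
            else:
                length, i = _parse_number(text, i)
                if length < 0:
                    raise TreeParseError("negative branch length", i)
        return [children, label, length, segs], i

    node, i = parse_clade(0)
    if i >= len(text) or text[i] != ";":
        raise TreeParseError("trailing characters before ';'", i)
    if not node[0]:
        raise TreeParseError("tree must have at least 2 tips", 0)

    # count tips, assign ids: tips in text order, internals preorder
    def count_tips(nd):
        return 1 if not nd[0] else sum(count_tips(c) for c in nd[0])

    n = count_tips(node)
    parent = [0] * (2 * n)
    lengths = [0.0] * (2 * n)
    labels: list[str] = [""] * n
    maps: dict[int, list[tuple[str, float]]] = {}
    next_tip = [1]
    next_int = [n + 1]
    any_segs = [False]

    def assign(nd, parent_id):
        children, label, length, segs = nd
        if children:
            v = next_int[0]
            next_int[0] += 1
        else:
            v = next_tip[0]
            next_tip[0] += 1
            labels[v - 1] = label if label else f"t{v}"
        parent[v] = parent_id
        if parent_id != 0:
            if length is None:
                raise TreeParseError("missing branch length")
            lengths[v] = length
        if segs is not None:
            any_segs[0] = True
            maps[v] = segs
        for c in children:
            assign(c, v)

    assign(node, 0)
    # polytomies leave fewer than n-1 internals; trim the id arrays
    parent = parent[:next_int[0]]
    lengths = lengths[:next_int[0]]
    if format == "newick":
        if any_segs[0]:
            raise TreeParseError("segment maps found; use format='simmap'")
        return Tree(parent, lengths, labels)
    if not any_segs[0]:
        raise TreeParseError("no segment maps found in simmap text")
    tree = MappedTree(parent, lengths, labels, maps)
    return _normalize_segment_order(tree)


def _normalize_segment_order(tree: MappedTree) -> MappedTree:
    """Orient every edge's segments rootward -> tipward.

    Writers differ on whether segments run root-to-tip or tip-to-root.  The
    orientation is detected globally by counting state mismatches between the
    rootward end of each edge and the tipward end of its parent edge; the
    orientation with fewer mismatches wins (ties keep the given order).
    """
    mismatch_fwd = mismatch_rev = 0
    for v, segs in tree.maps.items():
        p = tree.parent[v]
        if p == tree.root or p == 0:
            continue
        psegs = tree.maps[p]
        if segs[0][0] != psegs[-1][0]:
            mismatch_fwd += 1
        if segs[-1][0] != psegs[0][0]:
            mismatch_rev += 1
    if mismatch_rev < mismatch_fwd:
        maps = {v: segs[::-1] for v, segs in tree.maps.items()}
        return MappedTree(tree.parent, tree.edge_length, tree.labels, maps)
    return tree


# ---------------------------------------------------------------------------
# writing


def _fmt(x: float, digits: int) -> str:
    return f"{float(x):.{digits}g}"


def _needs_quotes(label: str) -> bool:
    return any(c in label for c in "(),:;{}[] \t'\"")


def _write_label(label: str) -> str:
    if _needs_quotes(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_tree(tree: Tree, format: str | None = None, digits: int = 12) -> str:
    """Serialize to Newick, or SIMMAP-extended Newick for a MappedTree."""
    if format is None:
        format = "simmap" if isinstance(tree, MappedTree) else "newick"
    if format == "simmap" and not isinstance(tree, MappedTree):
        raise ValueError("simmap output requires a MappedTree")

    def branch(v: int) -> str:
        if format == "simmap":
            segs = tree.maps[v]  # type: ignore[attr-defined]
            inner = ":".join(f"{_write_label(s)},{_fmt(d, digits)}" for s, d in segs)
            return "{" + inner + "}"
        return _fmt(tree.edge_length[v], digits)

    def rec(v: int) -> str:
        if tree.is_tip(v):
            core = _write_label(tree.labels[v - 1])
        else:
            core = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
        if v == tree.root:
            return core
        return f"{core}:{branch(v)}"

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# module-level operations


def node_heights(tree: Tree) -> dict[int, float]:
    """Map node id -> height above the root."""
    h = tree.node_heights()
    return {v: float(h[v]) for v in range(1, tree.n_nodes + 1)}


def drop_tips(tree: Tree, drop: Iterable[str]) -> Tree:
    """Induced tree on the remaining tips; unary nodes are suppressed with
    their edge lengths merged.  Segment maps (MappedTree) are concatenated."""
    drop = set(drop)
    unknown = drop - set(tree.labels)
    if unknown:
        raise KeyError(f"unknown tip labels: {sorted(unknown)}")
    keep = [lab for lab in tree.labels if lab not in drop]
    if len(keep) < 2:
        raise ValueError("fewer than 2 tips would remain")
    if not drop:
        return tree.copy()

    mapped = isinstance(tree, MappedTree)
    keep_ids = {tree.tip_index(lab) for lab in keep}
    # mark retained nodes: any node with >= 1 retained tip descendant
    retained = np.zeros(tree.n_nodes + 1, dtype=bool)
    n_desc = np.zeros(tree.n_nodes + 1, dtype=int)
    for v in tree.postorder():
        if tree.is_tip(v):
            n_desc[v] = 1 if v in keep_ids else 0
        else:
            n_desc[v] = sum(n_desc[c] for c in tree.children[v])
        retained[v] = n_desc[v] > 0

    # build pruned topology with merged unary chains, via recursion from root
    segs_of: dict[int, list[tuple[str, float]]] = {}

    def collapse(v: int) -> tuple[object, float, list]:
        """Return (subtree-node, stem length, stem segments) under pruning."""
        length = tree.edge_length[v]
        segs = list(tree.maps[v]) if mapped and v != tree.root else []
        while True:
            kids = [c for c in tree.children[v] if retained[c]]
            if tree.is_tip(v) or len(kids) >= 2:
                break
            if len(kids) == 0:
                raise AssertionError("collapse reached an empty subtree")
            c = kids[0]
            length += tree.edge_length[c]
            if mapped:
                csegs = list(tree.maps[c])
                if segs and csegs and segs[-1][0] == csegs[0][0]:
                    s, d = segs.pop()
                    csegs[0] = (s, d + csegs[0][1])
                segs = segs + csegs
            v = c
        if tree.is_tip(v):
            return (tree.labels[v - 1], length, segs)
        parts = [collapse(c) for c in tree.children[v] if retained[c]]
        return (parts, length, segs)

    top, _, _ = collapse(tree.root)

    # assign new ids
    def count_tips(nd):
        return 1 if isinstance(nd, str) else sum(count_tips(c[0]) for c in nd)

    m = count_tips(top)
    parent = [0] * (2 * m)
    lengths = [0.0] * (2 * m)
    labels = [""] * m
    new_maps: dict[int, list[tuple[str, float]]] = {}
    next_tip, next_int = [1], [m + 1]

    def assign(nd, stem, segs, parent_id):
        if isinstance(nd, str):
            v = next_tip[0]; next_tip[0] += 1
            labels[v - 1] = nd
        else:
            v = next_int[0]; next_int[0] += 1
        parent[v] = parent_id
        lengths[v] = stem
        if mapped and parent_id != 0:
            new_maps[v] = segs if segs else []
        if not isinstance(nd, str):
            for child, clen, csegs in nd:
                assign(child, clen, csegs, v)

    assign(top, 0.0, [], 0)
    parent = parent[:next_int[0]]
    lengths = lengths[:next_int[0]]
    if mapped:
        return MappedTree(parent, lengths, labels, new_maps)
    return Tree(parent, lengths, labels)


def sim_bd_tree(birth: float, death: float = 0.0, *, ntips: int | None = None,
                time: float | None = None, seed=None,
                extant_only: bool = True, max_tries: int = 1000) -> Tree:
    """Simulate a birth-death tree by Gillespie sampling.

    Exactly one of ``ntips`` / ``time`` must be given.  With ``ntips`` the
    process runs until the target number of concurrent lineages is reached
    and then all pending edges are extended by one further exponential
    waiting time, so the returned ultrametric tree has exactly ``ntips``
    tips at a uniformly random point of the holding interval.  With
    ``death > 0`` and ``extant_only`` extinct lineages are pruned; total
    extinction triggers a retry up to ``max_tries`` before
    :class:`ExtinctionError` is raised.
    """
    if birth <= 0 or death < 0:
        raise ValueError("need birth > 0 and death >= 0")
    if (ntips is None) == (time is None):
        raise ValueError("give exactly one of ntips or time")
    if ntips is not None and ntips < 2:
        raise ValueError("ntips must be >= 2")
    rng = np.random.default_rng(seed)
    rate = birth + death
    pb = birth / rate

    for _ in range(max_tries):
        # lineages: list of (accumulated pendant length); children structure
        # built as nested records [children, length]
        root_kids = [[[], 0.0], [[], 0.0]]
        alive: list[list] = list(root_kids)
        dead_count = 0
        ok = True
        if ntips is not None:
            while len(alive) < ntips:
                if not alive:
                    ok = False
                    break
                dt = rng.exponential(1.0 / (len(alive) * rate))
                for nd in alive:
                    nd[1] += dt
                k = rng.integers(len(alive))
                nd = alive.pop(int(k))
                if rng.random() < pb:
                    nd[0] = [[[], 0.0], [[], 0.0]]
                    alive.extend(nd[0])
                else:
                    dead_count += 1
            if ok:
                dt = rng.exponential(1.0 / (len(alive) * rate))
                for nd in alive:
                    nd[1] += dt
        else:
            t = 0.0
            while True:
                if not alive:
                    ok = False
                    break
                dt = rng.exponential(1.0 / (len(alive) * rate))
                if t + dt >= time:
                    for nd in alive:
                        nd[1] += time - t
                    break
                t += dt
                for nd in alive:
                    nd[1] += dt
                k = rng.integers(len(alive))
                nd = alive.pop(int(k))
                if rng.random() < pb:
                    nd[0] = [[[], 0.0], [[], 0.0]]
                    alive.extend(nd[0])
                else:
                    dead_count += 1
        if not ok:
            continue

        alive_set = {id(nd) for nd in alive}

        def build(children_recs):
            """Convert nested records to (label-or-children, length) tuples."""
            out = []
            for nd in children_recs:
                kids, length = nd
                if kids:
                    out.append((build(kids), length, id(nd) in alive_set))
                else:
                    out.append((None, length, id(nd) in alive_set))
            return out

        top = build(root_kids)

        # serialize and reuse the parser's id-assignment machinery
        counter = {"tip": 0}

        def serialize(nodes) -> str:
            parts = []
            for sub, length, is_alive in nodes:
                if sub is None:
                    counter["tip"] += 1
                    name = f"t{counter['tip']}"
                    if not is_alive:
                        name = f"x{counter['tip']}"
                    parts.append(f"{name}:{length!r}")
                else:
                    parts.append(f"{serialize(sub)}:{length!r}")
            return "(" + ",".join(parts) + ")"

        txt = serialize(top) + ";"
        tr = parse_tree(txt, "newick")
        if death > 0 and extant_only:
            extinct = [lab for lab in tr.labels if lab.startswith("x")]
            if len(tr.labels) - len(extinct) < 2:
                continue
            if extinct:
                tr = drop_tips(tr, extinct)
            tr = Tree(tr.parent, tr.edge_length,
                      [f"t{i+1}" for i in range(tr.n_tips)])
        return tr
    raise ExtinctionError(
        f"no surviving tree in {max_tries} attempts (birth={birth}, death={death})")
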