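"""Self-contained synthetic fixtures: trees plus discrete/continuous traits.

The generator wraps the package's own simulators (birth-death trees, Mk
tip states with full histories, Brownian traits) and writes plain-text
files (Newick/SIMMAP, CSV) together with a JSON "truth" record of the
generating parameters, so a complete analysis can be exercised with no
external data.  Outputs are deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mk import DiscreteTrait, QMatrix, build_design, sim_mk
from .cont import sim_bm
from .tree import Tree, sim_bd_tree, write_tree

__all__ = ["FixtureSpec", "make_fixture"]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults describe a comparative study of moderate size: a pure-birth
    tree rescaled to unit height, a binary equal-rates character with one
    expected change per tree height, and a unit-rate Brownian trait.
    """

    n_tips: int = 100
    birth: float = 1.0
    death: float = 0.0
    scale_height: float | None = 1.0
    mk_model: str = "ER"
    mk_levels: tuple[str, ...] = ("a", "b")
    mk_rates: tuple[float, ...] = (1.0,)
    root_state: str = "a"
    bm_sig2: float = 1.0
    bm_root: float = 0.0
    seed: int = 0


def _scaled(tree: Tree, height: float | None) -> Tree:
    if height is None:
        return tree
    t = tree.copy()
    t.edge_length[1:] *= height / t.max_height()
    return Tree(t.parent, t.edge_length, t.labels)


def make_fixture(spec: FixtureSpec, outdir=None):
    """Simulate one dataset; optionally write it under ``outdir``.

    Returns a dict with the tree, the mapped true history, the discrete
    trait, the continuous trait and the truth record.  When ``outdir`` is
    given, writes ``tree.nwk``, ``history.simmap``, ``discrete.csv``,
    ``continuous.csv`` and ``truth.json``.
    """
    rng = np.random.default_rng(spec.seed)
    tree = sim_bd_tree(spec.birth, spec.death, ntips=spec.n_tips,
                       seed=rng.integers(2 ** 31))
    tree = _scaled(tree, spec.scale_height)
    design = build_design(len(spec.mk_levels), spec.mk_model, spec.mk_levels)
    Q = design.q_from_rates(np.asarray(spec.mk_rates, dtype=float))
    trait, history = sim_mk(tree, Q, root_state=spec.root_state,
                            seed=rng.integers(2 ** 31), history=True)
    cont = sim_bm(tree, spec.bm_sig2, spec.bm_root,
                  seed=rng.integers(2 ** 31))
    truth = {
        "n_tips": spec.n_tips, "birth": spec.birth, "death": spec.death,
        "scale_height": spec.scale_height, "mk_model": spec.mk_model,
        "mk_levels": list(spec.mk_levels), "mk_rates": list(spec.mk_rates),
        "root_state": spec.root_state, "bm_sig2": spec.bm_sig2,
        "bm_root": spec.bm_root, "seed": spec.seed,
    }
    out = {"tree": tree, "history": history, "discrete": trait,
           "continuous": cont, "truth": truth}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tree.nwk").write_text(write_tree(tree) + "\n")
        (outdir / "history.simmap").write_text(write_tree(history) + "\n")
        with open(outdir / "discrete.csv", "w") as fh:
            fh.write("tip,state\n")
            for lab in tree.labels:
                fh.write(f"{lab},{'+'.join(sorted(trait.values[lab]))}\n")
        with open(outdir / "continuous.csv", "w") as fh:
            fh.write("tip,x\n")
            for lab in tree.labels:
                fh.write(f"{lab},{cont[lab]!r}\n")
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")
    return out
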