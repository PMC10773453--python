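"""Polymorphic and hidden-rates state spaces and their fits."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import pcmkit
from pcmkit import (DiscreteTrait, build_hrm_space, build_poly_space,
                    canonical_condition, fit_hrm, fit_mk, fit_polymk,
                    mk_loglik, parse_tree)


class TestPolySpace:
    def test_binary_space(self):
        sp = build_poly_space(["a", "b"], model="ER")
        assert sp.states == ("a", "b", "a+b")
        # 4 allowed moves, one shared class
        assert sp.design.n_classes == 1
        assert (sp.design.matrix > 0).sum() == 4

    def test_three_level_unordered_has_all_subsets(self):
        sp = build_poly_space(["forest", "fringe", "open"], model="ARD")
        assert len(sp.states) == 7
        assert "forest+open" in sp.states
        assert "forest+fringe+open" in sp.states
        assert sp.design.n_classes == 18

    def test_three_level_ordered_contiguous_runs_only(self):
        sp = build_poly_space(["forest", "fringe", "open"], ordered=True,
                              order=["forest", "fringe", "open"], model="ARD")
        assert "forest+open" not in sp.states
        assert "forest+fringe+open" in sp.states
        assert sp.design.n_classes == 12

    def test_transient_two_classes(self):
        sp = build_poly_space(["a", "b", "c"], model="transient")
        assert sp.design.n_classes == 2
        m, states = sp.design.matrix, sp.states
        sizes = [s.count("+") for s in states]
        for i in range(len(states)):
            for j in range(len(states)):
                if m[i, j]:
                    assert m[i, j] == (1 if sizes[j] > sizes[i] else 2)

    def test_single_step_moves_only(self):
        sp = build_poly_space(["a", "b", "c"], model="ARD")
        sets = [frozenset(s.split("+")) for s in sp.states]
        for i, j in zip(*np.nonzero(sp.design.matrix)):
            assert len(sets[i] ^ sets[j]) == 1

    def test_canonicalization_order_insensitive(self):
        assert canonical_condition("b+a") == "a+b"
        sp = build_poly_space(["a", "b"])
        assert sp.canonical("b+a") == "a+b"


class TestPolyFit:
    def test_plus_order_gives_identical_fits(self, fixture20):
        tree = fixture20["tree"]
        rng = np.random.default_rng(0)
        conds = ["a", "b", "a+b"]
        vals1 = {lab: conds[rng.integers(3)] for lab in tree.labels}
        vals2 = {lab: ("b+a" if v == "a+b" else v) for lab, v in vals1.items()}
        f1 = fit_polymk(tree, vals1, model="ER")
        f2 = fit_polymk(tree, vals2, model="ER")
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-9)

    def test_transient_nested_in_ard(self, fixture20):
        tree = fixture20["tree"]
        rng = np.random.default_rng(1)
        conds = ["a", "b", "a+b"]
        vals = {lab: conds[rng.integers(3)] for lab in tree.labels}
        tr = fit_polymk(tree, vals, model="transient", nstarts=3, seed=2)
        ard = fit_polymk(tree, vals, model="ARD", nstarts=5, seed=3)
        assert ard.loglik >= tr.loglik - 1e-6

    def test_poly_likelihood_matches_enumeration(self):
        t = parse_tree("((A:0.3,B:0.7):0.5,(C:0.2,D:0.9):0.4);")
        vals = {"A": "a", "B": "a+b", "C": "b", "D": "a"}
        fit = fit_polymk(t, vals, model="ER")
        k = len(fit.Q.levels)
        P = {v: expm(fit.Q.matrix * t.edge_length[v])
             for v in range(1, t.n_nodes + 1) if v != t.root}
        obs = {t.tip_index(lab): fit.Q.levels.index(fit.space.canonical(c))
               for lab, c in vals.items()}
        total = 0.0
        for assign in itertools.product(range(k), repeat=3):
            st = dict(zip(t.internals(), assign))
            st.update(obs)
            p = 1.0 / k
            for v in range(1, t.n_nodes + 1):
                if v != t.root:
                    p *= P[v][st[t.parent[v]], st[v]]
            total += p
        assert fit.loglik == pytest.approx(np.log(total), abs=1e-6)


class TestHRMSpace:
    def test_umbral_binary_layout(self):
        sp = build_hrm_space(["O", "V"], 2, umbral=True)
        assert sp.states == ("O", "O*", "V", "V*")
        np.testing.assert_array_equal(sp.design.matrix,
                                      [[0, 1, 2, 0],
                                       [3, 0, 0, 0],
                                       [4, 0, 0, 5],
                                       [0, 0, 6, 0]])

    def test_full_binary_has_eight_classes(self):
        assert build_hrm_space(["O", "V"], 2).design.n_classes == 8

    def test_ncat_one_is_plain_ard(self):
        sp = build_hrm_space(["a", "b", "c"], 1)
        ard = pcmkit.build_design(3, "ARD", ("a", "b", "c"))
        np.testing.assert_array_equal(sp.design.matrix, ard.matrix)


class TestHRMFit:
    def test_ncat1_equals_ard_fit(self, fixture20):
        tree, trait = fixture20["tree"], fixture20["discrete"]
        hrm = fit_hrm(tree, trait, ncat=1, prior="equal", nstarts=3, seed=1)
        ard = fit_mk(tree, trait, "ARD", nstarts=3, seed=1)
        assert hrm.loglik == pytest.approx(ard.loglik, abs=1e-5)

    def test_umbral_nests_ard(self, fixture20):
        tree, trait = fixture20["tree"], fixture20["discrete"]
        ard = fit_hrm(tree, trait, ncat=1, prior="fitzjohn", nstarts=3, seed=2)
        um = fit_hrm(tree, trait, ncat=2, umbral=True, prior="fitzjohn",
                     nstarts=6, seed=3)
        assert um.loglik >= ard.loglik - 1e-5

    def test_hrm_likelihood_matches_enumeration(self):
        t = parse_tree("((A:0.3,B:0.7):0.5,(C:0.2,D:0.9):0.4);")
        vals = {"A": "O", "B": "V", "C": "V", "D": "O"}
        sp = build_hrm_space(["O", "V"], 2, umbral=True)
        rng = np.random.default_rng(5)
        Q = sp.design.q_from_rates(rng.exponential(1.0, 6))
        expanded = DiscreteTrait({lab: sp.hidden_of(v) for lab, v in vals.items()},
                                 sp.states)
        k = 4
        P = {v: expm(Q.matrix * t.edge_length[v])
             for v in range(1, t.n_nodes + 1) if v != t.root}
        allowed = {t.tip_index(lab): [sp.states.index(h) for h in sp.hidden_of(v)]
                   for lab, v in vals.items()}
        total = 0.0
        for assign in itertools.product(range(k), repeat=3):
            st = dict(zip(t.internals(), assign))
            for tips_assign in itertools.product(*[allowed[v] for v in t.tips()]):
                stt = dict(st)
                stt.update(dict(zip(t.tips(), tips_assign)))
                p = 1.0 / k
                for v in range(1, t.n_nodes + 1):
                    if v != t.root:
                        p *= P[v][stt[t.parent[v]], stt[v]]
                total += p
        assert mk_loglik(t, expanded, Q) == pytest.approx(np.log(total), abs=1e-8)

    def test_recovers_rate_ordering_in_simulation(self):
        """Simulated umbral data: fitted labile rates exceed inert ones."""
        sp = build_hrm_space(["a", "b"], 2, umbral=True)
        # truth: fast observed switching from labile, slow hidden moves
        true_rates = np.array([0.3, 2.0, 0.3, 2.0, 0.3, 0.3])
        Q = sp.design.q_from_rates(true_rates)
        wins = 0
        reps = 8
        for i in range(reps):
            fx_tree = pcmkit.sim_bd_tree(1.0, 0.0, ntips=200, seed=50 + i)
            fx_tree.edge_length[1:] *= 1.0 / fx_tree.max_height()
            tree = pcmkit.Tree(fx_tree.parent, fx_tree.edge_length, fx_tree.labels)
            hidden = pcmkit.sim_mk(tree, Q, root_state="a", seed=60 + i)
            observed = {lab: next(iter(v)).rstrip("*")
                        for lab, v in hidden.values.items()}
            if len(set(observed.values())) < 2:
                continue
            fit = fit_hrm(tree, observed, ncat=2, umbral=True, nstarts=3,
                          seed=70 + i)
            labile = fit.rates[np.array([2, 4]) - 1].mean()   # a->b, b->a
            inert = fit.rates[np.array([1, 5]) - 1].mean()    # a->a*, b->b*
            if labile > inert:
                wins += 1
        assert wins >= int(0.7 * reps)
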