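"""Mk likelihoods against enumeration, fitting, model comparison, ancr."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

import pcmkit
from pcmkit import (DiscreteTrait, RootPrior, ancr, build_design,
                    compare_models, fit_mk, mk_loglik, parse_tree, sim_mk)

FOUR_TIP_SHAPES = [
    "((A:0.3,B:0.7):0.5,(C:0.2,D:0.9):0.4);",     # balanced
    "(((A:0.3,B:0.7):0.5,C:0.2):0.4,D:0.9);",     # pectinate
]


def _enumerate_loglik(tree, obs, Q, pi):
    """Brute-force sum over all internal-node state assignments."""
    k = Q.shape[0]
    P = {v: expm(Q * tree.edge_length[v])
         for v in range(1, tree.n_nodes + 1) if v != tree.root}
    internals = list(tree.internals())
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        st = dict(zip(internals, assign))
        st.update(obs)
        p = pi[st[tree.root]]
        for v in range(1, tree.n_nodes + 1):
            if v != tree.root:
                p *= P[v][st[tree.parent[v]], st[v]]
        total += p
    return np.log(total)


def _enumerate_marginals(tree, obs, Q, pi):
    k = Q.shape[0]
    P = {v: expm(Q * tree.edge_length[v])
         for v in range(1, tree.n_nodes + 1) if v != tree.root}
    internals = list(tree.internals())
    M = {v: np.zeros(k) for v in internals}
    for assign in itertools.product(range(k), repeat=len(internals)):
        st = dict(zip(internals, assign))
        st.update(obs)
        p = pi[st[tree.root]]
        for v in range(1, tree.n_nodes + 1):
            if v != tree.root:
                p *= P[v][st[tree.parent[v]], st[v]]
        for v in internals:
            M[v][st[v]] += p
    return {v: m / m.sum() for v, m in M.items()}


class TestDesign:
    def test_er_binary(self):
        d = build_design(2, "ER")
        np.testing.assert_array_equal(d.matrix, [[0, 1], [1, 0]])

    def test_irreversible_explicit(self):
        d = build_design(2, np.array([[0, 1], [0, 0]]), ("non", "pisc"))
        assert d.matrix[0, 1] == 1 and d.matrix[1, 0] == 0
        Q = d.q_from_rates([2.0]).matrix
        assert Q[1, 1] == 0 and Q[0, 0] == -2.0

    def test_ard_three_states(self):
        assert build_design(3, "ARD").n_classes == 6
        assert build_design(3, "SYM").n_classes == 3

    def test_bad_design_rejected(self):
        with pytest.raises(ValueError):
            build_design(2, np.array([[1, 1], [0, 0]]))


class TestLoglik:
    def test_no_change_process(self):
        t = parse_tree("(A:1,B:1);")
        d = build_design(2, "ER", ("a", "b"))
        Q = d.q_from_rates([1e-300])
        trait = DiscreteTrait({"A": "a", "B": "a"}, ("a", "b"))
        assert np.exp(mk_loglik(t, trait, Q)) == pytest.approx(0.5)

    def test_two_tip_closed_form(self):
        # binary ER, q=0.5, t=1: L = (1 - e^-2)/4
        t = parse_tree("(A:1,B:1);")
        Q = build_design(2, "ER", ("a", "b")).q_from_rates([0.5])
        trait = DiscreteTrait({"A": "a", "B": "b"}, ("a", "b"))
        assert np.exp(mk_loglik(t, trait, Q)) == pytest.approx((1 - np.exp(-2)) / 4)

    @pytest.mark.parametrize("shape", FOUR_TIP_SHAPES)
    def test_matches_enumeration(self, shape):
        rng = np.random.default_rng(10)
        t = parse_tree(shape)
        for k in (2, 3):
            levels = tuple(f"s{i}" for i in range(k))
            d = build_design(k, "ARD", levels)
            for _ in range(100):
                Q = d.q_from_rates(rng.exponential(1.0, d.n_classes))
                obs = {v: int(rng.integers(k)) for v in t.tips()}
                trait = DiscreteTrait(
                    {t.labels[v - 1]: levels[s] for v, s in obs.items()}, levels)
                ref = _enumerate_loglik(t, obs, Q.matrix, np.full(k, 1 / k))
                assert mk_loglik(t, trait, Q) == pytest.approx(ref, abs=1e-8)

    def test_invariant_to_rotation_and_tip_order(self):
        rng = np.random.default_rng(11)
        Q = build_design(3, "ARD").q_from_rates(rng.exponential(1.0, 6))
        vals = {"A": "s1", "B": "s2", "C": "s3", "D": "s1"}
        trait = DiscreteTrait(vals, Q.levels)
        a = mk_loglik(parse_tree("((A:0.3,B:0.7):0.5,(C:0.2,D:0.9):0.4);"), trait, Q)
        b = mk_loglik(parse_tree("((D:0.9,C:0.2):0.4,(B:0.7,A:0.3):0.5);"), trait, Q)
        assert a == pytest.approx(b, abs=1e-10)

    def test_ambiguous_tip_is_partial_one(self):
        t = parse_tree("(A:1,B:1);")
        Q = build_design(2, "ER", ("a", "b")).q_from_rates([0.5])
        amb = DiscreteTrait({"A": ("a", "b"), "B": "b"}, ("a", "b"))
        la = np.exp(mk_loglik(t, amb, Q))
        ref = sum(np.exp(mk_loglik(
            t, DiscreteTrait({"A": s, "B": "b"}, ("a", "b")), Q))
            for s in ("a", "b"))
        assert la == pytest.approx(ref)

    def test_rows_of_transition_matrix_sum_to_one(self):
        from pcmkit.mk import _Propagator
        rng = np.random.default_rng(12)
        Q = build_design(3, "ARD").q_from_rates(rng.exponential(1.0, 6)).matrix
        prop = _Propagator(Q)
        for t in (0.0, 1e-3, 1.0, 100.0):
            P = prop(t)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(prop(0.0), np.eye(3), atol=1e-12)


class TestFitting:
    def test_er_nested_in_ard(self, fixture20):
        tree, trait = fixture20["tree"], fixture20["discrete"]
        er = fit_mk(tree, trait, "ER")
        ard = fit_mk(tree, trait, "ARD", nstarts=3, seed=0)
        assert ard.loglik >= er.loglik - 1e-6

    def test_rate_recovery_er(self):
        # ER q=1 on 500-tip unit-height trees: median q-hat within 25%
        rng = np.random.default_rng(13)
        d = build_design(2, "ER", ("a", "b"))
        Q = d.q_from_rates([1.0])
        qhats = []
        for i in range(20):
            fx = pcmkit.make_fixture(pcmkit.FixtureSpec(
                n_tips=500, seed=100 + i, mk_rates=(1.0,)))
            fit = fit_mk(fx["tree"], fx["discrete"], "ER")
            qhats.append(fit.rates[0])
        assert abs(np.median(qhats) - 1.0) < 0.25

    def test_aic_identity(self, fixture20):
        fit = fit_mk(fixture20["tree"], fixture20["discrete"], "ER")
        assert fit.aic == pytest.approx(2 * fit.df - 2 * fit.loglik, abs=1e-8)


class TestCompareModels:
    def test_single_model_weight_one(self, fixture20):
        fit = fit_mk(fixture20["tree"], fixture20["discrete"], "ER")
        assert compare_models([fit]).weights[0] == pytest.approx(1.0)

    def test_equal_aic_splits_even(self):
        class Stub:
            def __init__(self, l, d, n):
                self.loglik, self.df, self.name = l, d, n
            @property
            def aic(self):
                return 2 * self.df - 2 * self.loglik
        tab = compare_models([Stub(-10, 1, "a"), Stub(-10, 1, "b")])
        np.testing.assert_allclose(tab.weights, [0.5, 0.5])

    def test_weights_invariant_to_loglik_shift(self):
        class Stub:
            def __init__(self, l, d, n):
                self.loglik, self.df, self.name = l, d, n
            @property
            def aic(self):
                return 2 * self.df - 2 * self.loglik
        t1 = compare_models([Stub(-10, 1, "a"), Stub(-12, 2, "b")])
        t2 = compare_models([Stub(-110, 1, "a"), Stub(-112, 2, "b")])
        np.testing.assert_allclose(t1.weights, t2.weights)
        assert t1.weights.sum() == pytest.approx(1.0, abs=1e-10)


class TestAncr:
    @pytest.mark.parametrize("shape", FOUR_TIP_SHAPES)
    def test_marginals_match_enumeration(self, shape):
        rng = np.random.default_rng(14)
        t = parse_tree(shape)
        k = 3
        levels = tuple(f"s{i}" for i in range(k))
        d = build_design(k, "ARD", levels)
        for _ in range(20):
            Q = d.q_from_rates(rng.exponential(1.0, d.n_classes))
            obs = {v: int(rng.integers(k)) for v in t.tips()}
            trait = DiscreteTrait(
                {t.labels[v - 1]: levels[s] for v, s in obs.items()}, levels)
            fit = pcmkit.MkFit(d, np.zeros(d.n_classes), Q, RootPrior("equal"),
                               mk_loglik(t, trait, Q), t, trait)
            M = ancr(fit)
            ref = _enumerate_marginals(t, obs, Q.matrix, np.full(k, 1 / k))
            for v in t.internals():
                np.testing.assert_allclose(M.loc[v].to_numpy(), ref[v], atol=1e-8)

    def test_rows_sum_to_one_and_degenerate_average(self, fixture20):
        tree, trait = fixture20["tree"], fixture20["discrete"]
        er = fit_mk(tree, trait, "ER", name="ER")
        ard = fit_mk(tree, trait, "ARD", name="ARD")
        M1 = ancr(er)
        np.testing.assert_allclose(M1.sum(axis=1), 1.0, atol=1e-8)

        class Weighted(pcmkit.ModelTable):
            @property
            def weights(self):
                return np.array([1.0, 0.0])
        M2 = ancr(Weighted([er, ard]))
        np.testing.assert_allclose(M1.to_numpy(), M2.to_numpy(), atol=1e-12)

    def test_joint_reconstruction_agrees_with_exhaustive(self):
        rng = np.random.default_rng(15)
        t = parse_tree(FOUR_TIP_SHAPES[0])
        levels = ("a", "b")
        d = build_design(2, "ER", levels)
        Q = d.q_from_rates([0.7])
        obs = {1: 0, 2: 1, 3: 1, 4: 0}
        trait = DiscreteTrait({t.labels[v - 1]: levels[s] for v, s in obs.items()},
                              levels)
        fit = fit_mk(t, trait, d)
        got = ancr(fit, method="joint")
        # exhaustive joint search
        P = {v: expm(fit.Q.matrix * t.edge_length[v])
             for v in range(1, t.n_nodes + 1) if v != t.root}
        best, best_p = None, -1
        for assign in itertools.product(range(2), repeat=3):
            st = dict(zip(t.internals(), assign))
            st.update(obs)
            p = 0.5
            for v in range(1, t.n_nodes + 1):
                if v != t.root:
                    p *= P[v][st[t.parent[v]], st[v]]
            if p > best_p:
                best_p, best = p, dict(st)
        for v in t.internals():
            assert got[v] == levels[best[v]]


class TestSimMk:
    def test_zero_rate_keeps_root_state(self, fixture20):
        tree = fixture20["tree"]
        Q = build_design(2, "ER", ("a", "b")).q_from_rates([1e-300])
        trait = sim_mk(tree, Q, root_state="b", seed=1)
        assert all(v == frozenset(["b"]) for v in trait.values.values())

    def test_stationary_frequency_high_rate(self):
        tree = pcmkit.sim_bd_tree(1.0, 0.0, ntips=2000, seed=3)
        t = tree.copy()
        t.edge_length[1:] *= 5.0 / t.max_height()
        t = pcmkit.Tree(t.parent, t.edge_length, t.labels)
        Q = build_design(2, "ER", ("a", "b")).q_from_rates([10.0])
        trait = sim_mk(t, Q, root_state="a", seed=4)
        freq = np.mean([v == frozenset(["a"]) for v in trait.values.values()])
        # stationary freq 0.5; tips correlated, allow a generous band
        assert 0.4 < freq < 0.6

    def test_realized_transition_rate_on_long_edge(self):
        t = parse_tree("(A:200,B:200);")
        Q = build_design(2, "ARD", ("a", "b")).q_from_rates([0.5, 1.5])
        n_ab = n_ba = t_a = t_b = 0.0
        for i in range(40):
            _, hist = sim_mk(t, Q, root_state="a", seed=i, history=True)
            for v in (1, 2):
                segs = hist.maps[v]
                for (s1, d1), (s2, _) in zip(segs[:-1], segs[1:]):
                    if s1 == "a":
                        n_ab += 1
                    else:
                        n_ba += 1
                for s, dd in segs:
                    if s == "a":
                        t_a += dd
                    else:
                        t_b += dd
        assert n_ab / t_a == pytest.approx(0.5, rel=0.1)
        assert n_ba / t_b == pytest.approx(1.5, rel=0.1)
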