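"""Brownian-motion machinery: covariance, signal statistics, ancestral states."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import pcmkit
from pcmkit import (MCMCControl, anc_bayes, blomberg_k, bm_loglik, fast_anc,
                    gls_mean, pagel_lambda, parse_tree, phylo_vcv, sim_bm)


class TestVCV:
    def test_three_tip_matrix(self, three_tip):
        np.testing.assert_allclose(phylo_vcv(three_tip).C,
                                   [[1, 0, 0], [0, 1, 0.5], [0, 0.5, 1]])

    def test_star_tree_is_diagonal(self):
        t = parse_tree("(A:1,B:1,C:1,D:1);")
        np.testing.assert_allclose(phylo_vcv(t).C, np.eye(4))

    def test_matches_pairwise_mrca_heights(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            t = pcmkit.sim_bd_tree(1.0, 0.0, ntips=int(rng.integers(4, 25)),
                                   seed=rng)
            C = phylo_vcv(t).C
            h = t.node_heights()
            for i in range(1, t.n_tips + 1):
                for j in range(i + 1, t.n_tips + 1):
                    # walk up from i collecting ancestors
                    anc = set()
                    u = i
                    while u:
                        anc.add(u)
                        u = t.parent[u]
                    u = j
                    while u not in anc:
                        u = t.parent[u]
                    assert C[i - 1, j - 1] == pytest.approx(h[u])


class TestBMLoglik:
    def test_matches_dense_mvn(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = pcmkit.sim_bd_tree(1.0, 0.0, ntips=6, seed=rng)
            x = rng.normal(size=6)
            sig2, a = rng.uniform(0.5, 2.0), rng.normal()
            C = phylo_vcv(t).C
            ref = multivariate_normal(mean=np.full(6, a), cov=sig2 * C)
            assert bm_loglik(t, x, sig2, a) == pytest.approx(
                ref.logpdf(x), abs=1e-9)

    def test_translation_invariance(self, three_tip):
        x = np.array([0.3, -0.2, 1.1])
        a = bm_loglik(three_tip, x, 1.0, 0.1)
        b = bm_loglik(three_tip, x + 5.0, 1.0, 5.1)
        assert a == pytest.approx(b, abs=1e-10)


class TestBlombergK:
    def test_affine_invariance(self, fixture20):
        tree = fixture20["tree"]
        x = np.array([fixture20["continuous"][l] for l in tree.labels])
        k1 = blomberg_k(tree, x, nperm=10, seed=0).value
        k2 = blomberg_k(tree, 3.0 * x + 7.0, nperm=10, seed=0).value
        assert k1 == pytest.approx(k2, abs=1e-10)

    def test_mean_k_is_one_under_bm(self):
        # E[K] = 1 under Brownian motion on the generating tree
        rng = np.random.default_rng(2)
        ks = []
        for i in range(300):
            t = pcmkit.sim_bd_tree(1.0, 0.0, ntips=100, seed=rng)
            x = sim_bm(t, 1.0, 0.0, seed=rng)
            ks.append(blomberg_k(t, x, nperm=1).value)
        se = np.std(ks) / np.sqrt(len(ks))
        assert abs(np.mean(ks) - 1.0) < 3 * se

    def test_constant_data_rejected(self, fixture20):
        with pytest.raises(ValueError):
            blomberg_k(fixture20["tree"],
                       np.ones(fixture20["tree"].n_tips), nperm=5)


class TestPagelLambda:
    def test_identity_transform_at_lambda_one(self, fixture20):
        tree = fixture20["tree"]
        from pcmkit.cont import _lambda_transform
        C = tree.mrca_heights()
        np.testing.assert_allclose(_lambda_transform(C, 1.0), C)

    def test_mle_beats_endpoints_and_profile_smooth(self, fixture20):
        tree = fixture20["tree"]
        x = fixture20["continuous"]
        res = pagel_lambda(tree, x, profile=True)
        from pcmkit.cont import _lambda_profile_loglik
        C = tree.mrca_heights()
        xv = np.array([x[l] for l in tree.labels])
        assert res.loglik >= _lambda_profile_loglik(0.0, C, xv) - 1e-8
        assert res.loglik >= _lambda_profile_loglik(1.0, C, xv) - 1e-8
        grid, prof = res.profile
        # continuous away from the singular upper boundary
        interior = prof[grid <= 0.98 * grid[-1]]
        assert np.all(np.isfinite(interior))
        assert np.all(np.abs(np.diff(interior)) < 2.0)
        assert res.lr >= 0 and 0 < res.pvalue <= 1

    def test_recovers_generating_lambda(self):
        # data simulated with lambda-rescaled covariance, n=300
        rng = np.random.default_rng(3)
        lams = []
        from pcmkit.cont import _lambda_transform
        for i in range(10):
            t = pcmkit.sim_bd_tree(1.0, 0.0, ntips=300, seed=rng)
            C = _lambda_transform(t.mrca_heights(), 0.5)
            x = rng.multivariate_normal(np.zeros(300), C)
            lams.append(pagel_lambda(t, x).value)
        assert abs(np.median(lams) - 0.5) < 0.15


class TestFastAnc:
    def test_two_tip_root_is_mean(self):
        t = parse_tree("(A:1,B:1);")
        est = fast_anc(t, {"A": 2.0, "B": 4.0})
        assert est.loc[3, "estimate"] == pytest.approx(3.0)

    def test_root_equals_gls_phylogenetic_mean(self, fixture20):
        tree = fixture20["tree"]
        x = fixture20["continuous"]
        xv = np.array([x[l] for l in tree.labels])
        est = fast_anc(tree, x)
        assert est.loc[tree.root, "estimate"] == pytest.approx(
            gls_mean(tree.mrca_heights(), xv), abs=1e-10)

    def test_equals_rerooting_oracle(self):
        """Node estimates equal the GLS mean of the tree re-rooted there."""
        rng = np.random.default_rng(4)
        for _ in range(15):
            t = pcmkit.sim_bd_tree(1.0, 0.0, ntips=10, seed=rng)
            x = sim_bm(t, 1.0, 0.0, seed=rng)
            xv = np.array([x[l] for l in t.labels])
            est = fast_anc(t, x)
            C_full, order = pcmkit.cont.phylo_vcv_with_internals(t)
            h = t.node_heights()
            for v in t.internals():
                if v == t.root:
                    continue
                # re-rooted covariance: distance-based kernel from node v
                i = order.index(v)
                # C_v[a,b] = h[a] + h[v] - 2*h[mrca] relative to v:
                # use distances d(v,·) to build the re-rooted C
                n = t.n_tips
                Cv = np.empty((n, n))
                for a in range(n):
                    for b in range(n):
                        da = h[a + 1] + h[v] - 2 * C_full[a, i] if a != b else 0
                        Cv[a, b] = 0.5 * ((h[a + 1] + h[v] - 2 * C_full[a, i])
                                          + (h[b + 1] + h[v] - 2 * C_full[b, i])
                                          - (h[a + 1] + h[b + 1]
                                             - 2 * C_full[a, b]))
                np.fill_diagonal(Cv, [h[a + 1] + h[v] - 2 * C_full[a, i]
                                      for a in range(n)])
                assert est.loc[v, "estimate"] == pytest.approx(
                    gls_mean(Cv, xv), abs=1e-8)


class TestAncBayes:
    def test_chain_bookkeeping(self, fixture20):
        tree = fixture20["tree"]
        x = fixture20["continuous"]
        chain, means = anc_bayes(tree, x, ngen=2000,
                                 control=MCMCControl(sample=100, seed=0))
        assert len(chain) == 2000 // 100 + 1
        assert chain["gen"].iloc[0] == 0
        kept = chain[chain["gen"] >= 0.2 * 2000]
        assert len(kept) == (2000 - 0.2 * 2000) // 100 + 1

    def test_acceptance_rate_moderate_with_matched_proposals(self, fixture20):
        tree = fixture20["tree"]
        x = fixture20["continuous"]
        chain, _ = anc_bayes(tree, x, ngen=20000,
                             control=MCMCControl(prop=0.05, seed=1))
        assert 0.05 < chain.attrs["acceptance_rate"] < 0.8

    def test_posterior_means_near_ml_states(self, fixture20):
        tree = fixture20["tree"]
        x = fixture20["continuous"]
        chain, means = anc_bayes(tree, x, ngen=200000,
                                 control=MCMCControl(seed=2))
        ml = fast_anc(tree, x)["estimate"]
        # compare at non-root internal nodes; diffuse priors, so near-ML
        common = [v for v in ml.index if v in means.index]
        dev = np.abs(means[common].to_numpy() - ml[common].to_numpy())
        assert np.max(dev) < 0.25

    def test_sig2_recovered_on_simulated_data(self):
        t = pcmkit.sim_bd_tree(1.0, 0.0, ntips=200, seed=7)
        x = sim_bm(t, sig2=2.0, a=0.0, seed=8)
        chain, _ = anc_bayes(t, x, ngen=100000, control=MCMCControl(seed=9))
        post = chain[chain["gen"] >= 20000]["sig2"].mean()
        assert abs(post - 2.0) / 2.0 < 0.3

    def test_invalid_control_rejected(self, fixture20):
        with pytest.raises(ValueError):
            anc_bayes(fixture20["tree"], fixture20["continuous"], ngen=1001,
                      control=MCMCControl(sample=100))
        with pytest.raises(ValueError):
            anc_bayes(fixture20["tree"], fixture20["continuous"], ngen=1000,
                      control=MCMCControl(prop=-1.0))


class TestSimBM:
    def test_zero_rate_is_constant(self, fixture20):
        vals = sim_bm(fixture20["tree"], 0.0, 1.5, seed=0)
        assert all(v == 1.5 for v in vals.values())

    def test_tip_variance_and_sister_covariance(self):
        t = parse_tree("((A:0.5,B:0.5):0.5,C:1);")
        rng = np.random.default_rng(5)
        X = np.array([[v for v in sim_bm(t, 2.0, 0.0, seed=rng).values()]
                      for _ in range(5000)])
        # order A, B, C; var = sig2 * height = 2; cov(A,B) = 2 * 0.5
        np.testing.assert_allclose(X.var(axis=0), 2.0, rtol=0.05)
        cab = np.cov(X[:, 0], X[:, 1])[0, 1]
        assert cab == pytest.approx(1.0, rel=0.1)
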