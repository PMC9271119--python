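"""REML engine: closed forms, dense oracles, BLUPs and the mixture LRT."""

import numpy as np
import pytest

from wgnam.lmm import (
    GroupTerm,
    MixedModelSpec,
    RandomTerm,
    build_marker_kernel,
    blup_marker_effects,
    fit_reml,
    lrt_variance_component,
    mixture_chi2_pvalue,
)
from wgnam.types import DataError

from .conftest import random_prob_cube
from .oracles import balanced_oneway_reml, dense_reml_fit, dense_reml_loglik


def _incidence(li, n):
    Z = np.zeros((li.size, n))
    Z[np.arange(li.size), li] = 1.0
    return Z


class TestClosedForms:
    def test_ols_limit(self):
        rng = np.random.default_rng(1)
        N = 40
        X = np.column_stack([np.ones(N), rng.normal(size=N)])
        y = X @ [2.0, -1.0] + rng.normal(0, 1.5, N)
        spec = MixedModelSpec(y=y, X=X, line_index=np.zeros(N, dtype=int),
                              n_lines=1, terms=[])
        fit = fit_reml(spec)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        s2 = float(resid @ resid) / (N - 2)
        assert fit.varcomps.residual == pytest.approx(s2, rel=1e-10)
        V = s2 * np.eye(N)
        assert fit.loglik == pytest.approx(dense_reml_loglik(y, X, V), abs=1e-8)

    @pytest.mark.parametrize("seed,shift", [(2, 0.0), (3, 2.0)])
    def test_balanced_oneway_matches_anova_reml(self, seed, shift):
        rng = np.random.default_rng(seed)
        a, n = 10, 5
        u = rng.normal(0, np.sqrt(0.8), a) * (1 if shift == 0 else 0.05)
        yg = 4.0 + u[:, None] + rng.normal(0, 1, (a, n))
        s2b, s2w = balanced_oneway_reml(yg)
        li = np.repeat(np.arange(a), n)
        spec = MixedModelSpec(y=yg.ravel(), X=np.ones((a * n, 1)),
                              line_index=li, n_lines=a,
                              terms=[RandomTerm("group")])
        fit = fit_reml(spec)
        assert fit.varcomps.components["group"] == pytest.approx(s2b, abs=1e-6)
        assert fit.varcomps.residual == pytest.approx(s2w, rel=1e-6)


class TestDenseOracle:
    def _instance(self, seed, n_g=20, n_m=5, n_f=3, r=2):
        rng = np.random.default_rng(seed)
        probs = random_prob_cube(rng, n_g, n_m, n_f)
        K, c = build_marker_kernel(probs)
        li = np.repeat(np.arange(n_g), r)
        N = n_g * r
        X = np.column_stack([np.ones(N), rng.normal(size=N)])
        u = rng.multivariate_normal(np.zeros(n_g), 0.6 * K + 0.3 * np.eye(n_g))
        y = X @ [5.0, 0.5] + u[li] + rng.normal(0, 1, N)
        return probs, K, c, li, X, y

    def test_matches_dense_reml(self):
        probs, K, c, li, X, y = self._instance(4)
        n_g = probs.n_lines
        spec = MixedModelSpec(
            y=y, X=X, line_index=li, n_lines=n_g,
            terms=[RandomTerm("poly"), RandomTerm("kernel", kernel=K)])
        fit = fit_reml(spec)
        Z = _incidence(li, n_g)
        covs = [Z @ Z.T, Z @ K @ Z.T, np.eye(y.size)]
        s2, ll = dense_reml_fit(y, X, covs)
        assert fit.loglik == pytest.approx(ll, abs=1e-6)
        assert fit.varcomps.components["poly"] == pytest.approx(s2[0], abs=1e-5)
        assert fit.varcomps.components["kernel"] == pytest.approx(s2[1], abs=1e-5)
        assert fit.varcomps.residual == pytest.approx(s2[2], rel=1e-4)

    def test_group_term_matches_dense_reml(self):
        probs, K, c, li, X, y = self._instance(5)
        n_g = probs.n_lines
        rng = np.random.default_rng(55)
        codes = rng.integers(0, 4, size=y.size)
        spec = MixedModelSpec(
            y=y, X=X, line_index=li, n_lines=n_g,
            terms=[RandomTerm("poly")],
            group_terms=[GroupTerm("block", codes)])
        fit = fit_reml(spec)
        Z = _incidence(li, n_g)
        Zb = _incidence(codes, 4)
        covs = [Z @ Z.T, Zb @ Zb.T, np.eye(y.size)]
        s2, ll = dense_reml_fit(y, X, covs)
        assert fit.loglik == pytest.approx(ll, abs=1e-5)

    def test_nested_fits_are_likelihood_ordered(self):
        probs, K, c, li, X, y = self._instance(6)
        n_g = probs.n_lines
        red = fit_reml(MixedModelSpec(y=y, X=X, line_index=li, n_lines=n_g,
                                      terms=[RandomTerm("poly")]))
        comp = fit_reml(MixedModelSpec(
            y=y, X=X, line_index=li, n_lines=n_g,
            terms=[RandomTerm("poly"), RandomTerm("kernel", kernel=K)]),
            start=red.varcomps)
        assert comp.loglik >= red.loglik - 1e-8


class TestKernel:
    def test_single_marker_indicator_algebra(self):
        rng = np.random.default_rng(7)
        probs = random_prob_cube(rng, 12, 1, 3)
        K, c = build_marker_kernel(probs)
        Q = probs.marker_slab(0)
        same = (Q @ Q.T)  # 1 iff same founder origin for 0/1 rows
        assert np.allclose(K, c * same)
        assert np.allclose(np.diag(K), c)

    def test_founder_permutation_invariance(self):
        rng = np.random.default_rng(8)
        probs = random_prob_cube(rng, 10, 4, 3)
        K, _ = build_marker_kernel(probs)
        perm = [1, 2, 0]
        from wgnam.probs import FounderProbabilities

        probs2 = FounderProbabilities(
            p=probs.p[:, :, perm], line_ids=probs.line_ids,
            marker_ids=probs.marker_ids,
            founder_ids=tuple(probs.founder_ids[k] for k in perm))
        K2, _ = build_marker_kernel(probs2)
        assert np.allclose(K, K2)

    def test_matches_explicit_column_product(self):
        rng = np.random.default_rng(9)
        probs = random_prob_cube(rng, 20, 5, 3)
        K, c = build_marker_kernel(probs)
        # dense oracle: explicit n_g x (n_m * n_f) design product
        cols = np.hstack([probs.marker_slab(j) for j in range(5)])
        assert np.allclose(K, c * cols @ cols.T, atol=1e-12)

    def test_empty_marker_set_rejected(self):
        rng = np.random.default_rng(10)
        probs = random_prob_cube(rng, 5, 2, 3)
        with pytest.raises(DataError):
            build_marker_kernel(probs, exclude={"m0", "m1"})


class TestMarkerBlups:
    def test_zero_variance_gives_zero_blups(self):
        rng = np.random.default_rng(11)
        probs = random_prob_cube(rng, 15, 3, 3)
        K, c = build_marker_kernel(probs)
        li = np.repeat(np.arange(15), 2)
        y = rng.normal(7, 1, li.size)  # no genetic signal
        spec = MixedModelSpec(y=y, X=np.ones((li.size, 1)), line_index=li,
                              n_lines=15,
                              terms=[RandomTerm("poly"),
                                     RandomTerm("kernel", kernel=K)])
        fit = fit_reml(spec)
        if fit.varcomps.components["kernel"] == 0.0:
            blup = blup_marker_effects(fit, probs, "m0", "common",
                                       kernel_scale=c)
            assert np.all(blup.effects == 0.0)
            assert np.all(blup.pev == 0.0)

    def test_matches_mixed_model_equations(self):
        # MME oracle on the 20-line instance: explicit a_j random effects
        from .oracles import mme_blups

        rng = np.random.default_rng(12)
        n_g, n_m, n_f, r = 20, 5, 3, 2
        probs = random_prob_cube(rng, n_g, n_m, n_f)
        K, c = build_marker_kernel(probs)
        li = np.repeat(np.arange(n_g), r)
        N = n_g * r
        X = np.ones((N, 1))
        u = rng.multivariate_normal(np.zeros(n_g), 0.8 * K + 0.2 * np.eye(n_g))
        y = 7.0 + u[li] + rng.normal(0, 1, N)
        spec = MixedModelSpec(y=y, X=X, line_index=li, n_lines=n_g,
                              terms=[RandomTerm("poly"),
                                     RandomTerm("kernel", kernel=K)])
        fit = fit_reml(spec)
        s2p = fit.varcomps.components["poly"]
        s2a = c * fit.varcomps.components["kernel"]  # per-effect variance
        s2e = fit.varcomps.residual
        if s2a == 0.0 or s2p == 0.0:
            pytest.skip("boundary solution; BLUP comparison undefined")
        Z = _incidence(li, n_g)
        Za = Z @ np.hstack([probs.marker_slab(j) for j in range(n_m)])
        _, us, pevs = mme_blups(y, X, [Z, Za], [s2p, s2a], s2e)
        for j in range(n_m):
            blup = blup_marker_effects(fit, probs, f"m{j}", "common",
                                       kernel_scale=c)
            sl = slice(j * n_f, (j + 1) * n_f)
            assert np.allclose(blup.effects, us[1][sl], atol=1e-6)
            assert np.allclose(blup.pev, pevs[1][sl, sl], atol=1e-6)
        # line BLUPs: polygenic + sum of marker contributions
        u_engine = fit.blup_lines()
        Qall = np.hstack([probs.marker_slab(j) for j in range(n_m)])
        u_oracle = us[0] + Qall @ us[1]
        assert np.allclose(u_engine, u_oracle, atol=1e-6)

    def test_pev_plus_blup_variance_decomposition(self):
        rng = np.random.default_rng(13)
        probs = random_prob_cube(rng, 25, 4, 3)
        K, c = build_marker_kernel(probs)
        li = np.repeat(np.arange(25), 2)
        u = rng.multivariate_normal(np.zeros(25), K)
        y = 7.0 + u[li] + rng.normal(0, 1, li.size)
        spec = MixedModelSpec(y=y, X=np.ones((li.size, 1)), line_index=li,
                              n_lines=25,
                              terms=[RandomTerm("poly"),
                                     RandomTerm("kernel", kernel=K)])
        fit = fit_reml(spec)
        for j in range(4):
            blup = blup_marker_effects(fit, probs, f"m{j}", "common",
                                       kernel_scale=c)
            total = blup.blup_variance + blup.pev
            assert np.allclose(total, blup.sigma2 * np.eye(3),
                               atol=1e-8 * max(blup.sigma2, 1.0))
            diag = np.diag(blup.pev)
            assert np.all(diag >= -1e-10)
            assert np.all(diag <= blup.sigma2 + 1e-10)


class TestLRT:
    def test_printed_iteration_statistics(self):
        # published iteration summary: Lambda 2.83 -> p 0.0462 and
        # Lambda 1.96 -> p 0.0808; both columns are independently rounded,
        # so agreement is to one unit in the fourth decimal
        assert mixture_chi2_pvalue(2.83) == pytest.approx(0.0462, abs=1e-4)
        assert mixture_chi2_pvalue(1.96) == pytest.approx(0.0808, abs=1e-4)
        assert mixture_chi2_pvalue(0.0) == 1.0

    def test_lrt_from_fit_pair(self):
        rng = np.random.default_rng(14)
        n_g = 30
        li = np.repeat(np.arange(n_g), 2)
        K = np.eye(n_g)
        y = 7 + rng.normal(0, 1, li.size)
        red = fit_reml(MixedModelSpec(y=y, X=np.ones((li.size, 1)),
                                      line_index=li, n_lines=n_g,
                                      terms=[RandomTerm("poly")]))
        comp = fit_reml(MixedModelSpec(y=y, X=np.ones((li.size, 1)),
                                       line_index=li, n_lines=n_g,
                                       terms=[RandomTerm("poly"),
                                              RandomTerm("dup", kernel=K)]))
        lam, p = lrt_variance_component(red, comp)
        assert lam >= 0.0
        assert 0 < p <= 1.0
        if lam == 0.0:
            assert p == 1.0

    def test_negative_statistic_rejected(self):
        with pytest.raises(DataError):
            mixture_chi2_pvalue(-1.0)


class TestScalingInvariance:
    def test_kernel_scale_does_not_move_likelihood_or_blups(self):
        rng = np.random.default_rng(15)
        probs = random_prob_cube(rng, 20, 4, 3)
        K, c = build_marker_kernel(probs)
        li = np.repeat(np.arange(20), 2)
        u = rng.multivariate_normal(np.zeros(20), 0.5 * K + 0.2 * np.eye(20))
        y = 7.0 + u[li] + rng.normal(0, 1, li.size)
        X = np.ones((li.size, 1))

        results = []
        for mult in (1.0, 10.0):
            spec = MixedModelSpec(
                y=y, X=X, line_index=li, n_lines=20,
                terms=[RandomTerm("poly"),
                       RandomTerm("kernel", kernel=mult * K)])
            fit = fit_reml(spec)
            blup = blup_marker_effects(fit, probs, "m1", "common",
                                       kernel_scale=mult * c)
            results.append((fit, blup))
        (f1, b1), (f2, b2) = results
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
        # sigma2_kernel rescales to compensate
        assert f1.varcomps.components["kernel"] == pytest.approx(
            10 * f2.varcomps.components["kernel"], rel=1e-4)
        assert np.allclose(b1.effects, b2.effects, atol=1e-7)
        assert np.allclose(b1.blup_variance, b2.blup_variance, atol=1e-7)
        assert np.allclose(b1.pev, b2.pev, atol=1e-7)
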