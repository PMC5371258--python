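"""AI-REML variance components, heritabilities, GBLUP, SNP back-solving."""
import numpy as np
import pytest

from snpherit import (GBLUPRegressor, backsolve_snp_effects, build_grms,
                      design_matrix, fit_greml, gblup, heritabilities)
from snpherit.greml import MixedModelSpec, VarianceComponents, reml_loglik
from tests.conftest import make_genotype_matrix


def toy_additive_spec(n=40, m=60, h2=0.5, seed=0):
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 3, (n, m))
    pair = build_grms(make_genotype_matrix(codes))
    L = np.linalg.cholesky(pair.A + 1e-6 * np.eye(n))
    a = L @ rng.standard_normal(n)
    a *= np.sqrt(h2 / a.var())
    e = rng.standard_normal(n)
    e *= np.sqrt((1 - h2) / e.var())
    y = 3.0 + a + e
    X = np.ones((n, 1))
    return MixedModelSpec(y=y, X=X, A=pair.A, D=None,
                          include_dominance=False), pair


class TestFitGreml:
    def test_loglik_maximum_matches_grid_oracle(self):
        """REML solution sits in the same cell as a 50x50 direct
        likelihood-evaluation grid over (sigma2_a, sigma2_e)."""
        spec, _ = toy_additive_spec(n=40, seed=1)
        vc = fit_greml(spec)
        grid = np.linspace(0.02, 2.0, 50)
        best, argbest = -np.inf, None
        for sa in grid:
            for se in grid:
                ll = reml_loglik(spec, {"additive": sa, "residual": se})
                if ll > best:
                    best, argbest = ll, (sa, se)
        cell = grid[1] - grid[0]
        assert abs(vc.components["additive"] - argbest[0]) <= cell
        assert abs(vc.components["residual"] - argbest[1]) <= cell
        assert vc.loglik >= best - 1e-6

    def test_permuted_phenotype_estimates_near_zero(self):
        """Breaking the genotype-phenotype link should collapse the
        additive component in at least 19/20 seeds."""
        spec, _ = toy_additive_spec(n=600, m=100, h2=0.5, seed=2)
        ok = 0
        rng = np.random.default_rng(3)
        for _ in range(20):
            yp = rng.permutation(spec.y)
            pspec = MixedModelSpec(y=yp, X=spec.X, A=spec.A, D=None,
                                   include_dominance=False)
            vc = fit_greml(pspec)
            h = heritabilities(vc)
            if h.h2_add < 0.05:
                ok += 1
        assert ok >= 19

    def test_shift_invariance_and_scale_equivariance(self):
        spec, _ = toy_additive_spec(n=80, seed=4)
        vc0 = fit_greml(spec)
        shifted = MixedModelSpec(y=spec.y + 100.0, X=spec.X, A=spec.A,
                                 include_dominance=False)
        vc1 = fit_greml(shifted)
        for k in vc0.components:
            assert vc1.components[k] == pytest.approx(vc0.components[k],
                                                      rel=1e-5)
        scaled = MixedModelSpec(y=3.0 * spec.y, X=spec.X, A=spec.A,
                                include_dominance=False)
        vc9 = fit_greml(scaled)
        for k in vc0.components:
            assert vc9.components[k] == pytest.approx(9.0 * vc0.components[k],
                                                      rel=1e-4)

    def test_additive_only_close_to_full_model_without_dominance(
            self, small_dataset, fitted_model):
        """With little simulated dominance the additive-only fit tracks
        the additive+dominance fit (the published pattern: 0.368 vs
        0.365)."""
        d = small_dataset
        pair = fitted_model["pair"]
        X, _ = design_matrix(batch=d["batch"])
        spec_a = MixedModelSpec(y=d["y"], X=X, A=pair.A, include_dominance=False)
        h_a = heritabilities(fit_greml(spec_a))
        h_full = fitted_model["herit"]
        tol = 2 * np.hypot(h_a.se_add, h_full.se_add)
        assert abs(h_a.h2_add - h_full.h2_add) <= tol


class TestHeritabilities:
    def test_published_component_ratios(self):
        vc = VarianceComponents(
            components={"additive": 0.365, "dominance": 0.035,
                        "residual": 0.600},
            se={}, cov=np.zeros((3, 3)), loglik=0.0, n_iter=1,
            converged=True, boundary={})
        h = heritabilities(vc)
        assert h.h2_add == pytest.approx(0.365)
        assert h.h2_dom == pytest.approx(0.035)
        assert h.h2_total == pytest.approx(0.400)
        assert h.h2_total == pytest.approx(h.h2_add + h.h2_dom)

    def test_all_residual_and_scale_invariance(self):
        base = {"additive": 1e-9, "dominance": 1e-9, "residual": 2.0}
        vc = VarianceComponents(components=base, se={}, cov=np.zeros((3, 3)),
                                loglik=0, n_iter=1, converged=True, boundary={})
        h = heritabilities(vc)
        assert h.h2_add == pytest.approx(0.0, abs=1e-8)
        assert h.h2_total == pytest.approx(0.0, abs=1e-8)
        doubled = VarianceComponents(
            components={k: 2 * v for k, v in base.items()}, se={},
            cov=np.zeros((3, 3)), loglik=0, n_iter=1, converged=True,
            boundary={})
        h2 = heritabilities(doubled)
        assert h2.h2_add == pytest.approx(h.h2_add)


class TestGblup:
    def test_interpolation_limit_reproduces_adjusted_phenotype(self):
        spec, _ = toy_additive_spec(n=25, m=80, seed=5)
        vc = VarianceComponents(
            components={"additive": 1.0, "residual": 1e-9}, se={},
            cov=np.eye(2), loglik=0, n_iter=1, converged=True, boundary={})
        res = gblup(spec, vc)
        adj = spec.y - spec.X @ res.beta
        assert np.abs(res.g_hat - adj).max() < 1e-5

    def test_matches_dense_henderson_solver(self):
        """Independent oracle: solve Henderson's mixed-model equations
        with an explicit GRM inverse on a small well-conditioned system."""
        spec, pair = toy_additive_spec(n=30, m=120, seed=6)
        vc = fit_greml(spec)
        res = gblup(spec, vc)
        s2a, s2e = vc.components["additive"], vc.components["residual"]
        n = len(spec.y)
        A = pair.A + 1e-10 * np.eye(n)
        Ainv = np.linalg.inv(A)
        X = spec.X
        lam = s2e / s2a
        top = np.hstack([X.T @ X, X.T])
        bottom = np.hstack([X, np.eye(n) + lam * Ainv])
        lhs = np.vstack([top, bottom])
        rhs = np.concatenate([X.T @ spec.y, spec.y])
        sol = np.linalg.solve(lhs, rhs)
        a_hat_mme = sol[X.shape[1]:]
        assert np.abs(a_hat_mme - res.a_hat).max() < 1e-6

    def test_masked_predictions_consistent_with_full_training(self, fitted_model):
        spec, vc = fitted_model["spec"], fitted_model["vc"]
        res_all = gblup(spec, vc, mask=None)
        res_empty = gblup(spec, vc, mask=np.zeros(len(spec.y), dtype=bool))
        assert np.allclose(res_all.a_hat, res_empty.a_hat)
        mask = np.zeros(len(spec.y), dtype=bool)
        mask[:50] = True
        res_m = gblup(spec, vc, mask=mask)
        assert res_m.train_mask.sum() == len(spec.y) - 50
        assert np.all((res_m.rel_total >= 0) & (res_m.rel_total <= 1))

    def test_predictions_shrink_as_additive_variance_vanishes(self, fitted_model):
        spec = fitted_model["spec"]
        vc_small = VarianceComponents(
            components={"additive": 1e-8, "dominance": 1e-8, "residual": 3.0},
            se={}, cov=np.eye(3), loglik=0, n_iter=1, converged=True,
            boundary={})
        res = gblup(spec, vc_small)
        assert np.abs(res.a_hat).max() < 1e-4


class TestBacksolve:
    def test_reconstruction_identity(self, fitted_model):
        pair, spec, vc = (fitted_model["pair"], fitted_model["spec"],
                          fitted_model["vc"])
        res = gblup(spec, vc)
        eff = backsolve_snp_effects(pair, vc, res)
        assert np.abs(pair.W_a @ eff.alpha_hat - res.a_hat).max() < 1e-8
        assert eff.h2_add.sum() <= 1.0
        # per-SNP heritabilities decompose the additive component
        h = fitted_model["herit"]
        assert eff.h2_add.sum() == pytest.approx(h.h2_add, rel=1e-6)

    def test_single_qtl_carries_top_per_snp_heritability(self):
        """One large-effect QTL in a low-LD panel should rank first in
        per-SNP heritability in at least 9/10 seeds."""
        from snpherit import SimConfig, simulate_dataset

        hits = 0
        for seed in range(10):
            cfg = SimConfig(n_sires=20, n_litters=150, litter_size_range=(2, 2),
                            n_snps=120, n_chromosomes=2, ld_decay=0.0,
                            n_qtl=1, h2_add=0.45, h2_dom=0.0, batch_sd=0.0,
                            discretize=False, seed=300 + seed)
            G, st, pheno, truth = simulate_dataset(cfg)
            pair = build_grms(G)
            X = np.ones((G.n_individuals, 1))
            spec = MixedModelSpec(y=pheno["y"].to_numpy(float), X=X,
                                  A=pair.A, include_dominance=False)
            vc = fit_greml(spec)
            res = gblup(spec, vc)
            eff = backsolve_snp_effects(pair, vc, res, snp_ids=G.snp_ids)
            top = eff.snp_ids[np.argmax(eff.h2_add)]
            if top == truth.qtl["snp_id"].iloc[0]:
                hits += 1
        assert hits >= 9


class TestGBLUPRegressorEstimator:
    def test_fit_predict_surface(self, small_dataset):
        d = small_dataset
        est = GBLUPRegressor(include_dominance=True)
        est.fit(d["G"].codes, d["y"], batch=d["batch"])
        assert 0 <= est.heritability_.h2_add <= 1
        preds = est.predict(d["G"].codes)
        # in-sample predictions equal the GBLUP genetic values
        assert np.abs(preds - est.gblup_.g_hat).max() < 1e-8
        assert est.score(d["G"].codes, d["y"]) > 0.3

    def test_get_set_params(self):
        est = GBLUPRegressor(include_dominance=False)
        assert est.get_params()["include_dominance"] is False
        est.set_params(max_iter=50)
        assert est.max_iter == 50
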