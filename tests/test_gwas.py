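"""Single-SNP scans: GLS with family effects, LS with MDS covariates,
inflation factor, Bonferroni threshold, significant-set algebra."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from snpherit import (FamilyGWAS, ScanConfig, StratifiedGWAS,
                      bonferroni_threshold, gls_family_scan, inflation_factor,
                      ls_mds_scan, significant_snps)
from snpherit.gwas import CHI2_MEDIAN_1DF, family_whitening
from tests.conftest import make_genotype_matrix


def dense_gls_oracle(y, Xfull, V):
    """Direct (X'V^-1X)^-1 X'V^-1 y with explicit inverse; returns
    (beta, cov_beta_unit_scale, df, s2)."""
    Vinv = np.linalg.inv(V)
    XtVinvX = Xfull.T @ Vinv @ Xfull
    C = np.linalg.inv(XtVinvX)
    beta = C @ (Xfull.T @ Vinv @ y)
    resid = y - Xfull @ beta
    df = len(y) - np.linalg.matrix_rank(Xfull)
    s2 = float(resid @ Vinv @ resid) / df
    return beta, C, df, s2


def simulate_family_data(n_fam=20, fam_size=3, m=8, s2f=0.3, s2e=1.0,
                         seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    n = n_fam * fam_size
    fam = np.repeat(np.arange(n_fam), fam_size)
    codes = rng.integers(0, 3, (n, m))
    f = rng.normal(0, np.sqrt(s2f), n_fam)[fam]
    y = 2.0 + f + rng.normal(0, np.sqrt(s2e), n) + effect * codes[:, 0]
    return y, fam, codes


class TestGlsFamilyScan:
    def test_zero_family_variance_reduces_to_ols(self):
        y, fam, codes = simulate_family_data(seed=1)
        G = make_genotype_matrix(codes)
        X = np.ones((len(y), 1))
        gls = gls_family_scan(y, X, fam, G, variances=(0.0, 1.0))
        ols = gls_family_scan(y, X, np.arange(len(y)), G, variances=(0.0, 1.0))
        for col in ("a_est", "d_est", "t_add", "t_dom"):
            assert np.allclose(gls.table[col].astype(float),
                               ols.table[col].astype(float),
                               atol=1e-10, equal_nan=True)

    def test_matches_dense_v_inverse_oracle(self):
        """n=60, 20 families of 3: whitened-OLS statistics equal the
        explicit V^-1 GLS solution."""
        y, fam, codes = simulate_family_data(n_fam=20, fam_size=3, m=6,
                                             seed=2, effect=0.4)
        G = make_genotype_matrix(codes)
        s2f, s2e = 0.3, 1.0
        X = np.ones((len(y), 1))
        res = gls_family_scan(y, X, fam, G, variances=(s2f, s2e))
        Z = np.zeros((len(y), fam.max() + 1))
        Z[np.arange(len(y)), fam] = 1
        V = s2f * (Z @ Z.T) + s2e * np.eye(len(y))
        for j in range(6):
            het = (codes[:, j] == 1).astype(float)
            hom2 = (codes[:, j] == 2).astype(float)
            if het.sum() < 5 or hom2.sum() < 5 or (codes[:, j] == 0).sum() < 5:
                continue
            Xf = np.column_stack([X, het, hom2])
            beta, C, df, s2 = dense_gls_oracle(y, Xf, V)
            a = beta[2] / 2
            d = beta[1] - beta[2] / 2
            cvec_a = np.array([0, 0, 0.5])
            var_a = s2 * cvec_a @ C @ cvec_a
            t_a = a / np.sqrt(var_a)
            p_a = 2 * sps.t.sf(abs(t_a), df)
            row = res.table.iloc[j]
            assert row["a_est"] == pytest.approx(a, abs=1e-10)
            assert row["d_est"] == pytest.approx(d, abs=1e-10)
            assert row["t_add"] == pytest.approx(t_a, abs=1e-8)
            assert row["p_add"] == pytest.approx(p_a, abs=1e-10)

    def test_sparse_genotype_class_falls_back_to_additive(self):
        rng = np.random.default_rng(3)
        col = np.concatenate([np.zeros(50), np.ones(48), np.full(2, 2)])
        rng.shuffle(col)
        G = make_genotype_matrix(col[:, None])
        y = rng.standard_normal(100)
        res = gls_family_scan(y, np.ones((100, 1)), np.arange(100), G,
                              variances=(0.0, 1.0))
        assert res.table["flag"][0] == "additive_only"
        assert np.isnan(res.table["p_dom"][0])
        assert np.isfinite(res.table["p_add"][0])

    def test_whitening_matches_cholesky_inverse_sqrt(self):
        fam = np.array([0, 0, 0, 1, 1, 2])
        s2f, s2e = 0.4, 0.9
        Z = np.zeros((6, 3))
        Z[np.arange(6), fam] = 1
        V = s2f * (Z @ Z.T) + s2e * np.eye(6)
        whiten = family_whitening(fam, s2f, s2e)
        M = whiten(np.eye(6))
        assert np.abs(M @ V @ M.T - np.eye(6)).max() < 1e-10


class TestLsMdsScan:
    def test_zero_mds_equals_covariate_regression(self):
        y, _, codes = simulate_family_data(seed=4, effect=0.5)
        G = make_genotype_matrix(codes)
        X = np.ones((len(y), 1))
        res = ls_mds_scan(y, X, np.zeros((len(y), 5)),
                          G, ScanConfig(method="ls_mds_additive", n_mds=0))
        # oracle: plain OLS slope of y on allele count
        for j in range(codes.shape[1]):
            x = codes[:, j].astype(float)
            Xf = np.column_stack([np.ones(len(y)), x])
            beta, C, df, s2 = dense_gls_oracle(y, Xf, np.eye(len(y)))
            t = beta[1] / np.sqrt(s2 * C[1, 1])
            assert res.table["a_est"][j] == pytest.approx(beta[1], abs=1e-10)
            assert res.table["t_add"][j] == pytest.approx(t, abs=1e-8)

    def test_genotypic_variant_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        n = 50
        codes = rng.integers(0, 3, (n, 4))
        mds = rng.standard_normal((n, 3))
        y = rng.standard_normal(n) + 0.6 * codes[:, 1]
        G = make_genotype_matrix(codes)
        X = np.ones((n, 1))
        res = ls_mds_scan(y, X, mds, G,
                          ScanConfig(method="ls_mds_genotypic", n_mds=3))
        for j in range(4):
            counts = [(codes[:, j] == c).sum() for c in (0, 1, 2)]
            if min(counts) < 5:
                continue
            het = (codes[:, j] == 1).astype(float)
            hom2 = (codes[:, j] == 2).astype(float)
            Xf = np.column_stack([X, mds, het, hom2])
            beta, C, df, s2 = dense_gls_oracle(y, Xf, np.eye(n))
            assert res.table["a_est"][j] == pytest.approx(beta[-1] / 2,
                                                          abs=1e-10)
            d = beta[-2] - beta[-1] / 2
            assert res.table["d_est"][j] == pytest.approx(d, abs=1e-10)

    def test_stratification_correction_lowers_lambda(self):
        """Two diverged subpopulations with a mean shift: lambda with 10
        MDS covariates below lambda without, in 10/10 seeds."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            n, m = 200, 400
            p1 = rng.uniform(0.1, 0.9, m)
            p2 = np.clip(p1 + rng.choice([-0.25, 0.25], m), 0.05, 0.95)
            pop = np.repeat([0, 1], n // 2)
            codes = np.where(pop[:, None] == 0, rng.binomial(2, p1, (n, m)),
                             rng.binomial(2, p2, (n, m)))
            y = 0.8 * pop + rng.standard_normal(n)
            G = make_genotype_matrix(codes)
            from snpherit import ibs_matrix, mds_components
            mds = mds_components(ibs_matrix(G), 10)
            X = np.ones((n, 1))
            lam0 = ls_mds_scan(y, X, mds.coords, G,
                               ScanConfig(method="ls_mds_additive",
                                          n_mds=0)).inflation
            lam10 = ls_mds_scan(y, X, mds.coords, G,
                                ScanConfig(method="ls_mds_additive",
                                           n_mds=10)).inflation
            if lam10 < lam0:
                wins += 1
        assert wins == 10

    def test_allele_flip_symmetry(self):
        y, fam, codes = simulate_family_data(seed=6, effect=0.5, m=5)
        G1 = make_genotype_matrix(codes)
        G2 = make_genotype_matrix(2 - codes)
        X = np.ones((len(y), 1))
        cfg = ScanConfig(method="ls_mds_genotypic", n_mds=0)
        r1 = ls_mds_scan(y, X, np.zeros((len(y), 1)), G1, cfg).table
        r2 = ls_mds_scan(y, X, np.zeros((len(y), 1)), G2, cfg).table
        ok = r1["flag"] == "ok"
        assert np.allclose(r1.loc[ok, "a_est"], -r2.loc[ok, "a_est"], atol=1e-10)
        assert np.allclose(r1.loc[ok, "d_est"], r2.loc[ok, "d_est"], atol=1e-10)
        assert np.allclose(r1.loc[ok, "p_add"], r2.loc[ok, "p_add"], atol=1e-10)
        assert np.allclose(r1.loc[ok, "p_dom"], r2.loc[ok, "p_dom"], atol=1e-10)

    def test_gls_with_singleton_families_equals_ls(self):
        y, _, codes = simulate_family_data(seed=7, m=6)
        G = make_genotype_matrix(codes)
        X = np.ones((len(y), 1))
        gls = gls_family_scan(y, X, np.arange(len(y)), G,
                              ScanConfig(method="gls_family"))
        ls = ls_mds_scan(y, X, np.zeros((len(y), 1)), G,
                         ScanConfig(method="ls_mds_genotypic", n_mds=0))
        ok = gls.table["flag"] == "ok"
        # identical estimates; t statistics agree up to the GLS variance
        # scaling, hence identical after the same residual normalization
        assert np.allclose(gls.table.loc[ok, "a_est"],
                           ls.table.loc[ok, "a_est"], atol=1e-8)
        assert np.allclose(gls.table.loc[ok, "t_add"],
                           ls.table.loc[ok, "t_add"], atol=1e-6)

    def test_power_ranks_with_effect_size(self):
        """Larger simulated additive effects get smaller p-values
        (rank correlation > 0.8 across 50 QTL)."""
        rng = np.random.default_rng(8)
        n, m = 800, 50
        codes = rng.integers(0, 3, (n, m))
        effects = np.linspace(0.05, 0.6, m)
        y = codes @ effects + rng.standard_normal(n) * 2.0
        G = make_genotype_matrix(codes)
        res = ls_mds_scan(y, np.ones((n, 1)), np.zeros((n, 1)), G,
                          ScanConfig(method="ls_mds_additive", n_mds=0))
        rho = sps.spearmanr(effects, res.table["p_add"]).statistic
        assert rho < -0.8


class TestInflationAndThreshold:
    def test_lambda_on_null_chi2_draws(self):
        rng = np.random.default_rng(9)
        draws = rng.chisquare(1, 100_000)
        lam = inflation_factor(draws, kind="chi2")
        assert 0.98 <= lam <= 1.02

    def test_lambda_scale_equivariance_and_unit_point(self):
        rng = np.random.default_rng(10)
        t = rng.standard_normal(5000)
        lam = inflation_factor(t)
        assert inflation_factor(np.sqrt(2) * t) == pytest.approx(2 * lam)
        with pytest.warns(UserWarning):
            assert inflation_factor([CHI2_MEDIAN_1DF],
                                    kind="chi2") == pytest.approx(1.0)

    def test_bonferroni_published_panel_size(self):
        thr, neglog = bonferroni_threshold(41108, 0.05)
        assert round(neglog, 2) == 5.91
        assert bonferroni_threshold(1, 0.05)[0] == 0.05
        assert bonferroni_threshold(100, 0.05)[0] == pytest.approx(5e-4)

    def test_bonferroni_rejects_zero_tests(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestSignificantSet:
    def _fake_scan(self, method, pvals):
        from snpherit.gwas import ScanResult

        m = len(pvals)
        table = pd.DataFrame({
            "snp": [f"s{i}" for i in range(m)], "chr": 1, "pos": range(m),
            "maf": 0.3, "a_est": 0.0, "d_est": np.nan, "t_add": 1.0,
            "p_add": pvals, "t_dom": np.nan, "p_dom": np.nan,
            "flag": "ok", "method": method,
        })
        return ScanResult(table=table, method=method, inflation=1.0,
                          bonferroni_p=0.05, n_tests=m)

    def test_single_method_union(self):
        scan = self._fake_scan("gls_family", [0.001, 0.2, 0.03])
        sig = significant_snps([scan], 0.05)
        assert sig.union == ["s0", "s2"]

    def test_disjoint_sets_overlap_zero(self):
        a = self._fake_scan("m1", [0.001, 0.001, 0.5])
        b = self._fake_scan("m2", [0.5, 0.9, 0.01])
        sig = significant_snps([a, b], 0.05)
        assert len(sig.union) == 3
        assert sig.overlap.loc["m1", "m2"] == 0
        assert sig.overlap.loc["m1", "m1"] == 2

    def test_union_superset_and_overlap_match_set_algebra(self):
        rng = np.random.default_rng(11)
        scans = [self._fake_scan(f"m{i}", rng.uniform(0, 0.2, 30))
                 for i in range(3)]
        sig = significant_snps(scans, 0.05)
        sets = [set(s.table.loc[s.table.p_add < 0.05, "snp"]) for s in scans]
        assert set(sig.union) == sets[0] | sets[1] | sets[2]
        for i in range(3):
            for j in range(3):
                assert sig.overlap.iloc[i, j] == len(sets[i] & sets[j])


class TestScanEstimators:
    def test_family_gwas_estimator(self, small_dataset):
        d = small_dataset
        G = d["G"].subset_snps(np.arange(60))
        est = FamilyGWAS().fit(G, d["y"], families=d["litter"],
                               batch=d["batch"])
        assert len(est.results_) == 60
        assert est.inflation_ > 0
        assert 0 < est.bonferroni_p_ < 1

    def test_stratified_gwas_estimator(self, small_dataset):
        d = small_dataset
        G = d["G"].subset_snps(np.arange(60)).subset_individuals(np.arange(150))
        est = StratifiedGWAS(n_mds=5).fit(G, d["y"][:150], batch=d["batch"][:150])
        assert len(est.results_) == 60
        est2 = StratifiedGWAS(n_mds=5, genotypic=True).fit(
            G, d["y"][:150], batch=d["batch"][:150])
        assert np.isfinite(est2.results_["p_dom"].astype(float)).any()
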