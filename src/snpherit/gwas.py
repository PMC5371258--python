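"""Single-SNP association scans with three model variants.

- ``gls_family_scan``: generalized least squares with a random family
  effect (common intraclass correlation for sibs in a family); the
  family and residual variances are estimated once under the no-SNP
  model and held fixed across SNPs.
- ``ls_mds_scan``: ordinary least squares with leading MDS coordinates
  of the IBS distance matrix as stratification covariates; an additive
  (allele-count regression) variant and a genotypic (3-level factor)
  variant that also tests the dominance contrast.

Genotype-class values are tested through the additive contrast
a = (mu_AA - mu_aa)/2 and the dominance contrast
d = mu_Aa - (mu_AA + mu_aa)/2, each by a t test with
df = n - rank(fixed design).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .greml import MixedModelSpec, fit_greml

logger = logging.getLogger(__name__)

CHI2_MEDIAN_1DF = 0.4549364231195728  # median of chi-square(1)


@dataclass
class ScanConfig:
    method: str = "gls_family"  # gls_family | ls_mds_additive | ls_mds_genotypic
    n_mds: int = 35
    alpha: float = 0.05
    min_class: int = 5
    family_grouping: str = "litter"  # or "sire"

    def __post_init__(self):
        if self.method not in ("gls_family", "ls_mds_additive", "ls_mds_genotypic"):
            raise ValueError(f"unknown scan method {self.method!r}")
        if self.n_mds < 0:
            raise ValueError("n_mds must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")


@dataclass
class ScanResult:
    table: pd.DataFrame
    # columns: snp chr pos maf a_est d_est t_add p_add t_dom p_dom flag
    method: str
    inflation: float
    bonferroni_p: float
    n_tests: int

    def significant(self, threshold: float | None = None) -> pd.DataFrame:
        thr = self.bonferroni_p if threshold is None else threshold
        t = self.table
        return t[(t["p_add"] < thr) | (t["p_dom"] < thr)]


def _snp_frame(G):
    if isinstance(G, GenotypeMatrix):
        return (G.codes, G.snp_meta["id"].to_numpy(),
                G.snp_meta["chrom"].to_numpy(), G.snp_meta["pos"].to_numpy())
    codes = np.asarray(G)
    m = codes.shape[1]
    return (codes, np.array([f"snp{j}" for j in range(m)]),
            np.ones(m, dtype=int), np.arange(1, m + 1))


def estimate_family_variance(y, X_b, family_labels, max_iter: int = 200):
    """One-time REML of (sigma2_f, sigma2_e) under y = X_b b + Z f + e
    with Var(f) = I sigma2_f."""
    fam = pd.factorize(np.asarray(family_labels))[0]
    n = len(y)
    Z = np.zeros((n, fam.max() + 1))
    Z[np.arange(n), fam] = 1.0
    K = Z @ Z.T
    spec = MixedModelSpec(y=y, X=X_b, A=K, D=None, include_dominance=False)
    vc = fit_greml(spec, max_iter=max_iter)
    return float(vc.components["additive"]), float(vc.components["residual"])


def family_whitening(family_labels, sigma_f2: float, sigma_e2: float):
    """Rows of V^-1/2 applied per family block: within a family of size
    k, V = s2e I + s2f J has the analytic inverse square root
    (1/sqrt(s2e)) (I - c J / k) with c = 1 - sqrt(s2e/(s2e + k s2f)).
    Returns a function whitening vectors/matrices row-wise."""
    fam = pd.factorize(np.asarray(family_labels))[0]
    order = np.argsort(fam, kind="stable")
    inv_order = np.argsort(order)
    sizes = np.bincount(fam)

    def whiten(M):
        M = np.asarray(M, dtype=np.float64)
        one_d = M.ndim == 1
        M2 = M[order].reshape(len(fam), -1)
        out = np.empty_like(M2)
        pos = 0
        for k in sizes:
            block = M2[pos: pos + k]
            c = 1.0 - np.sqrt(sigma_e2 / (sigma_e2 + k * sigma_f2))
            out[pos: pos + k] = (block - (c / k) * block.sum(axis=0, keepdims=True))
            pos += k
        out /= np.sqrt(sigma_e2)
        out = out[inv_order]
        return out.ravel() if one_d else out

    return whiten


def _contrast_tests(Xf, yw, add_vec, dom_vec, df):
    """OLS on (whitened) data; t tests of two contrast vectors on the
    coefficients. Returns (a, d, t_a, p_a, t_d, p_d)."""
    XtX = Xf.T @ Xf
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ (Xf.T @ yw)
    resid = yw - Xf @ beta
    s2 = float(resid @ resid) / df
    out = []
    for cvec in (add_vec, dom_vec):
        if cvec is None:
            out.extend([np.nan, np.nan, np.nan])
            continue
        est = float(cvec @ beta)
        var = s2 * float(cvec @ XtX_inv @ cvec)
        tstat = est / np.sqrt(var) if var > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(tstat), df) if np.isfinite(tstat) else np.nan
        out.extend([est, tstat, p])
    a_est, t_a, p_a, d_est, t_d, p_d = out
    return a_est, d_est, t_a, p_a, t_d, p_d


def _scan_factor_model(codes, covariates, yw, whiten=None, min_class: int = 5):
    """Per-SNP genotype-factor fit with additive/dominance contrasts.

    ``covariates`` must include the intercept; genotype enters as
    heterozygote and alt-homozygote indicator columns (baseline =
    ref-homozygote), whitened alongside when a whitener is given.
    """
    n, m = codes.shape
    C = covariates
    rows = np.empty((m, 6))
    flags = np.empty(m, dtype=object)
    for j in range(m):
        x = codes[:, j].astype(np.float64)
        called = x >= 0
        counts = [(x == c).sum() for c in (0, 1, 2)]
        present = sum(c > 0 for c in counts)
        if present < 2:
            rows[j] = np.nan
            flags[j] = "monomorphic"
            continue
        small = min(c for c in counts if c > 0) < min_class or present < 3
        if small:
            # additive allele-count regression only
            Xf = np.column_stack([C, x])
            Xw = whiten(Xf) if whiten is not None else Xf
            df = n - np.linalg.matrix_rank(Xw)
            add_vec = np.zeros(Xw.shape[1])
            add_vec[-1] = 1.0
            a, d, ta, pa, td, pd_ = _contrast_tests(Xw, yw, add_vec, None, df)
            rows[j] = (a, np.nan, ta, pa, np.nan, np.nan)
            flags[j] = "additive_only"
            continue
        het = (x == 1).astype(np.float64)
        hom2 = (x == 2).astype(np.float64)
        Xf = np.column_stack([C, het, hom2])
        Xw = whiten(Xf) if whiten is not None else Xf
        df = n - np.linalg.matrix_rank(Xw)
        p_cols = Xw.shape[1]
        add_vec = np.zeros(p_cols)
        add_vec[-1] = 0.5  # (mu_AA - mu_aa)/2 = b_hom2 / 2
        dom_vec = np.zeros(p_cols)
        dom_vec[-2] = 1.0  # mu_Aa - (mu_AA+mu_aa)/2 = b_het - b_hom2/2
        dom_vec[-1] = -0.5
        rows[j] = _contrast_tests(Xw, yw, add_vec, dom_vec, df)
        flags[j] = "ok"
    return rows, flags


def _finish_scan(rows, flags, G, method, alpha):
    codes, ids, chrom, pos = _snp_frame(G)
    with np.errstate(invalid="ignore"):
        p_alt = np.where(codes >= 0, codes, np.nan)
    freq = np.nanmean(p_alt, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    table = pd.DataFrame({
        "snp": ids, "chr": chrom, "pos": pos, "maf": maf,
        "a_est": rows[:, 0], "d_est": rows[:, 1],
        "t_add": rows[:, 2], "p_add": rows[:, 3],
        "t_dom": rows[:, 4], "p_dom": rows[:, 5],
        "flag": flags, "method": method,
    })
    tested = table["t_add"].to_numpy()
    tested = tested[np.isfinite(tested)]
    lam = inflation_factor(tested) if len(tested) else np.nan
    n_tests = int(np.isfinite(rows[:, 3]).sum())
    thr = bonferroni_threshold(max(n_tests, 1), alpha)[0]
    return ScanResult(table=table, method=method, inflation=lam,
                      bonferroni_p=thr, n_tests=n_tests)


def gls_family_scan(y, X_b, family_labels, G, config: ScanConfig | None = None,
                    variances: tuple | None = None) -> ScanResult:
    """GLS scan accounting for sib intraclass correlation via a random
    family effect; variances estimated once then held fixed."""
    config = config or ScanConfig(method="gls_family")
    y = np.asarray(y, dtype=np.float64)
    codes, _, _, _ = _snp_frame(G)
    if variances is None:
        s2f, s2e = estimate_family_variance(y, X_b, family_labels)
    else:
        s2f, s2e = variances
    if s2f <= 0:
        whiten = None
        yw = y.copy()
    else:
        whiten = family_whitening(family_labels, s2f, s2e)
        yw = whiten(y)
    # whiten=None means plain OLS, which equals GLS at s2f = 0 up to scale
    rows, flags = _scan_factor_model(codes, np.asarray(X_b, dtype=np.float64),
                                     yw, whiten=whiten,
                                     min_class=config.min_class)
    return _finish_scan(rows, flags, G, "gls_family", config.alpha)


def ls_mds_scan(y, X_b, mds_coords, G, config: ScanConfig | None = None) -> ScanResult:
    """LS scan with MDS stratification covariates.

    ``ls_mds_additive`` regresses y on the allele count (t test of the
    additive SNP effect); ``ls_mds_genotypic`` fits the 3-level genotype
    factor and tests both contrasts.
    """
    config = config or ScanConfig(method="ls_mds_additive")
    y = np.asarray(y, dtype=np.float64)
    codes, _, _, _ = _snp_frame(G)
    X_b = np.asarray(X_b, dtype=np.float64)
    mds_coords = np.asarray(mds_coords, dtype=np.float64)
    if mds_coords.ndim == 1:
        mds_coords = mds_coords[:, None]
    if config.n_mds > mds_coords.shape[1]:
        raise ValueError("requested more MDS dimensions than available")
    C = np.column_stack([X_b, mds_coords[:, : config.n_mds]]) if config.n_mds else X_b
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        warnings.warn("dropping collinear stratification covariates")
        from scipy.linalg import qr as sqr
        _, _, piv = sqr(C, mode="economic", pivoting=True)
        C = C[:, np.sort(piv[:rank])]

    if config.method == "ls_mds_genotypic":
        rows, flags = _scan_factor_model(codes, C, y, whiten=None,
                                         min_class=config.min_class)
        return _finish_scan(rows, flags, G, "ls_mds_genotypic", config.alpha)

    # additive variant, vectorized: residualize y and genotype columns on C
    Q, _ = np.linalg.qr(C)
    ey = y - Q @ (Q.T @ y)
    Xc = codes.astype(np.float64)
    miss = codes < 0
    if miss.any():
        col_mean = np.where(miss, np.nan, Xc).astype(float)
        col_mean = np.nanmean(col_mean, axis=0)
        ii, jj = np.nonzero(miss)
        Xc[ii, jj] = col_mean[jj]
    Ex = Xc - Q @ (Q.T @ Xc)
    sxx = (Ex * Ex).sum(axis=0)
    sxy = Ex.T @ ey
    n = len(y)
    df = n - rank - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        rss = float(ey @ ey) - beta ** 2 * sxx
        se = np.sqrt(np.maximum(rss, 0.0) / df / np.where(sxx > 0, sxx, np.nan))
        tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    m = codes.shape[1]
    nan_col = np.full(m, np.nan)
    # the allele-count slope is the additive SNP effect
    rows = np.column_stack([beta, nan_col, tstat, pval, nan_col, nan_col])
    flags = np.where(sxx > 0, "ok", "monomorphic").astype(object)
    return _finish_scan(rows, flags, G, "ls_mds_additive", config.alpha)


def inflation_factor(statistics, kind: str = "t") -> float:
    """Genomic inflation factor lambda = median(chi-square)/0.4549.

    ``kind='t'`` squares the inputs (t or z statistics);
    ``kind='chi2'`` takes them as 1-df chi-square values already.
    """
    s = np.asarray(statistics, dtype=np.float64)
    s = s[np.isfinite(s)]
    if len(s) == 0:
        return float("nan")
    if len(s) < 100:
        warnings.warn("fewer than 100 test statistics; lambda is noisy")
    if kind == "t":
        chi = s ** 2
    elif kind == "chi2":
        chi = s
    else:
        raise ValueError("kind must be 't' or 'chi2'")
    return float(np.median(chi) / CHI2_MEDIAN_1DF)


def bonferroni_threshold(m: int, alpha: float = 0.05):
    """Family-wise threshold alpha/m and its -log10."""
    if m < 1:
        raise ValueError("m must be >= 1")
    thr = alpha / m
    return thr, float(-np.log10(thr))


@dataclass
class SignificantSet:
    flags: pd.DataFrame  # snp + one bool column per method
    union: list
    overlap: pd.DataFrame  # method x method pairwise overlap counts


def significant_snps(results, threshold: float) -> SignificantSet:
    """Union of SNPs passing ``threshold`` in any scan, with per-method
    flags and pairwise overlap counts."""
    methods = []
    sets = {}
    all_snps = None
    for res in results:
        t = res.table
        if all_snps is None:
            all_snps = t["snp"].to_numpy()
        hits = set(t.loc[(t["p_add"] < threshold)
                         | (t["p_dom"].fillna(1.0) < threshold), "snp"])
        sets[res.method] = hits
        methods.append(res.method)
    union = sorted(set().union(*sets.values())) if sets else []
    flags = pd.DataFrame({"snp": union})
    for m in methods:
        flags[m] = flags["snp"].isin(sets[m])
    overlap = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in methods] for a in methods],
        index=methods, columns=methods,
    )
    return SignificantSet(flags=flags, union=union, overlap=overlap)


class _ScanEstimator:
    """Shared sklearn-style surface for the scan estimators."""

    _param_names: tuple = ()

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self


class FamilyGWAS(_ScanEstimator):
    """GLS single-SNP scan with a random family effect.

    fit(X, y, families=..., batch=...) -> self with results_ (ScanResult
    table), inflation_, bonferroni_p_.
    """

    _param_names = ("alpha", "min_class")

    def __init__(self, alpha: float = 0.05, min_class: int = 5):
        self.alpha = alpha
        self.min_class = min_class

    def fit(self, X, y, families=None, batch=None):
        from .greml import design_matrix

        if families is None:
            raise ValueError("families labels are required")
        Xb, _ = design_matrix(batch=batch, n=len(y))
        cfg = ScanConfig(method="gls_family", alpha=self.alpha,
                         min_class=self.min_class)
        res = gls_family_scan(y, Xb, families, X, cfg)
        self.results_ = res.table
        self.scan_ = res
        self.inflation_ = res.inflation
        self.bonferroni_p_ = res.bonferroni_p
        return self


class StratifiedGWAS(_ScanEstimator):
    """LS single-SNP scan with MDS stratification covariates.

    fit(X, y, batch=...) computes IBS-MDS coordinates from X itself and
    scans; genotypic=True fits the 3-level genotype factor and also
    tests dominance.
    """

    _param_names = ("n_mds", "genotypic", "alpha", "min_class")

    def __init__(self, n_mds: int = 35, genotypic: bool = False,
                 alpha: float = 0.05, min_class: int = 5):
        self.n_mds = n_mds
        self.genotypic = genotypic
        self.alpha = alpha
        self.min_class = min_class

    def fit(self, X, y, batch=None, mds_coords=None):
        from .greml import design_matrix
        from .relationship import MDSStratifier

        if mds_coords is None and self.n_mds > 0:
            mds_coords = MDSStratifier(n_components=self.n_mds).fit_transform(X)
        elif mds_coords is None:
            codes = X.codes if isinstance(X, GenotypeMatrix) else np.asarray(X)
            mds_coords = np.zeros((codes.shape[0], 0))
        Xb, _ = design_matrix(batch=batch, n=len(y))
        method = "ls_mds_genotypic" if self.genotypic else "ls_mds_additive"
        cfg = ScanConfig(method=method, n_mds=min(self.n_mds, np.asarray(mds_coords).shape[1]),
                         alpha=self.alpha, min_class=self.min_class)
        res = ls_mds_scan(y, Xb, mds_coords, X, cfg)
        self.results_ = res.table
        self.scan_ = res
        self.inflation_ = res.inflation
        self.bonferroni_p_ = res.bonferroni_p
        return self
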