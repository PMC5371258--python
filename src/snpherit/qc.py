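"""SNP quality control: allele statistics, Hardy-Weinberg test, filters.

The retained panel keeps a SNP iff MAF > maf_min (strict), the frequency
of the least frequent homozygous genotype >= hom_min, and the 1-df
Pearson chi-square HWE p-value >= hwe_min.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)


def hwe_test(n_AA, n_Aa, n_aa):
    """Hardy-Weinberg equilibrium p-value: 1-df Pearson chi-square on
    expected genotype counts at the estimated allele frequency, no
    continuity correction. Monomorphic SNPs return p = 1 by convention.
    Accepts scalars or equal-length arrays."""
    n_AA = np.asarray(n_AA, dtype=np.float64)
    n_Aa = np.asarray(n_Aa, dtype=np.float64)
    n_aa = np.asarray(n_aa, dtype=np.float64)
    n = n_AA + n_Aa + n_aa
    if np.any(n <= 0):
        raise ValueError("total genotype count must be positive")
    p = (2.0 * n_AA + n_Aa) / (2.0 * n)
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.stack([n * p * p, 2.0 * n * p * q, n * q * q])
        o = np.stack([n_AA, n_Aa, n_aa])
        chi2 = np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0).sum(axis=0)
    pval = stats.chi2.sf(chi2, df=1)
    mono = (p == 0) | (p == 1)
    pval = np.where(mono, 1.0, pval)
    return float(pval) if pval.ndim == 0 else pval


def hwe_exact_test(n_AA, n_Aa, n_aa) -> float:
    """Exact mid-p HWE test (single SNP) — optional alternative to the
    chi-square default."""
    n_Aa = int(n_Aa)
    n_AA = int(n_AA)
    n_aa = int(n_aa)
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_AA + n_Aa  # minor-allele count wlog
    n_a = min(n_a, 2 * n - n_a)
    if n_a == 0:
        return 1.0
    # probabilities of heterozygote counts given n and minor-allele count
    hets = np.arange(n_a % 2, n_a + 1, 2)
    from scipy.special import gammaln

    def logprob(h):
        hom_min = (n_a - h) // 2
        hom_maj = n - h - hom_min
        return (h * np.log(2) + gammaln(n + 1)
                - gammaln(h + 1) - gammaln(hom_min + 1) - gammaln(hom_maj + 1)
                + gammaln(n_a + 1) + gammaln(2 * n - n_a + 1) - gammaln(2 * n + 1))

    lp = np.array([logprob(h) for h in hets])
    pr = np.exp(lp - lp.max())
    pr /= pr.sum()
    obs = pr[hets == n_Aa][0]
    return float(pr[pr <= obs].sum() - 0.5 * obs)


@dataclass
class SnpStats:
    """Per-SNP allele and genotype statistics on the counted (alt) allele."""

    table: pd.DataFrame
    # columns: id, p, maf, n_AA, n_Aa, n_aa, hom_min_freq, hwe_p

    def __getitem__(self, col):
        return self.table[col].to_numpy()


def allele_stats(G: GenotypeMatrix) -> SnpStats:
    """Counted-allele frequency p = (2 n_AA + n_Aa)/(2n), MAF, genotype
    counts and HWE p per SNP. Missing genotypes are excluded from the
    tallies (n_AA + n_Aa + n_aa = called individuals)."""
    if G.n_individuals < 1:
        raise ValueError("need at least one individual")
    codes = G.codes
    n_AA = (codes == 2).sum(axis=0).astype(np.float64)
    n_Aa = (codes == 1).sum(axis=0).astype(np.float64)
    n_aa = (codes == 0).sum(axis=0).astype(np.float64)
    n = n_AA + n_Aa + n_aa
    n_safe = np.where(n > 0, n, 1.0)
    p = (2.0 * n_AA + n_Aa) / (2.0 * n_safe)
    maf = np.minimum(p, 1.0 - p)
    hom_min = np.minimum(n_AA, n_aa) / n_safe
    hwe_p = np.ones(G.n_snps)
    called = n > 0
    if called.any():
        hwe_p[called] = np.atleast_1d(hwe_test(n_AA[called], n_Aa[called], n_aa[called]))
    table = pd.DataFrame({
        "id": G.snp_ids,
        "p": p,
        "maf": maf,
        "n_AA": n_AA.astype(np.int64),
        "n_Aa": n_Aa.astype(np.int64),
        "n_aa": n_aa.astype(np.int64),
        "hom_min_freq": hom_min,
        "hwe_p": hwe_p,
    })
    return SnpStats(table=table)


@dataclass
class FilterReport:
    n_input: int
    n_fail_maf: int
    n_fail_hom: int
    n_fail_hwe: int
    n_pass: int
    pass_flags: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rule": ["maf", "hom_freq", "hwe", "pass"],
            "count": [self.n_fail_maf, self.n_fail_hom, self.n_fail_hwe, self.n_pass],
        })


def filter_snps(G: GenotypeMatrix, maf_min: float = 0.05, hom_min: float = 0.01,
                hwe_min: float = 1e-6):
    """Apply the three QC rules; returns (filtered GenotypeMatrix,
    FilterReport). MAF uses strict '>', homozygote frequency and HWE
    use '>='."""
    st = allele_stats(G)
    ok_maf = st["maf"] > maf_min
    ok_hom = st["hom_min_freq"] >= hom_min
    ok_hwe = st["hwe_p"] >= hwe_min
    keep = ok_maf & ok_hom & ok_hwe
    report = FilterReport(
        n_input=G.n_snps,
        n_fail_maf=int((~ok_maf).sum()),
        n_fail_hom=int((~ok_hom).sum()),
        n_fail_hwe=int((~ok_hwe).sum()),
        n_pass=int(keep.sum()),
        pass_flags=keep,
    )
    logger.info("QC: %d/%d SNPs pass (maf fails %d, hom fails %d, hwe fails %d)",
                report.n_pass, report.n_input, report.n_fail_maf,
                report.n_fail_hom, report.n_fail_hwe)
    return G.subset_snps(keep), report


class SNPQCFilter:
    """Sklearn-style transformer applying the SNP QC rules to a codes matrix.

    fit(X) computes per-SNP statistics on X (individuals x SNPs alt-allele
    counts, -1 missing); transform(X) keeps the passing columns.
    """

    def __init__(self, maf_min: float = 0.05, hom_min: float = 0.01,
                 hwe_min: float = 1e-6):
        self.maf_min = maf_min
        self.hom_min = hom_min
        self.hwe_min = hwe_min

    def get_params(self, deep: bool = True) -> dict:
        return {"maf_min": self.maf_min, "hom_min": self.hom_min,
                "hwe_min": self.hwe_min}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def _as_matrix(self, X) -> GenotypeMatrix:
        if isinstance(X, GenotypeMatrix):
            return X
        X = np.asarray(X)
        meta = pd.DataFrame({
            "chrom": 1, "pos": np.arange(1, X.shape[1] + 1),
            "id": [f"snp{j}" for j in range(X.shape[1])],
            "ref": "A", "alt": "G",
        })
        return GenotypeMatrix(codes=X, snp_meta=meta,
                              ind_ids=np.array([f"i{j}" for j in range(X.shape[0])]))

    def fit(self, X, y=None):
        G = self._as_matrix(X)
        self.stats_ = allele_stats(G)
        _, report = filter_snps(G, self.maf_min, self.hom_min, self.hwe_min)
        self.report_ = report
        self.keep_mask_ = report.pass_flags
        self.n_features_in_ = G.n_snps
        return self

    def transform(self, X):
        if not hasattr(self, "keep_mask_"):
            raise RuntimeError("SNPQCFilter is not fitted")
        if isinstance(X, GenotypeMatrix):
            return X.subset_snps(self.keep_mask_)
        return np.asarray(X)[:, self.keep_mask_]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
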