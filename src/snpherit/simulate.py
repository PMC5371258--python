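"""Synthetic family-structured genotype/phenotype generator.

Emulates a paternal half-sib nucleus-herd design: a few dozen sires each
mated to many dams, one litter per dam with one to three recorded
offspring, genotyped at a dense autosomal SNP panel with local linkage
disequilibrium, and scored for a near-bell-shaped integer trait (for
example a count such as teat number) with additive, dominance and batch
(year-month) components. Every downstream stage of the package can be
exercised against the known truth this module returns.

Founder haplotypes follow a first-order Markov chain along each
chromosome (Gaussian-copula AR(1) with latent correlation ``ld_decay``
thresholded at the marker's allele frequency), and offspring genotypes
are produced by gene dropping with recombination between adjacent
markers, so nearby markers tag each other the way a real dense panel
does.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import GenotypeMatrix, PopulationStructure


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters for one simulated dataset.

    Defaults reproduce the design of the motivating pig dataset: 79
    sires, 1456 litters of 1-3 offspring, ~41k autosomal SNPs with
    MAF > 0.05, narrow-sense heritability 0.365, dominance heritability
    0.035, and an integer phenotype with mean 10.72 and SD 1.72 over 24
    year-month batches.
    """

    n_sires: int = 79
    n_litters: int = 1456
    litter_size_range: tuple = (1, 3)
    n_snps: int = 41108
    n_chromosomes: int = 18
    maf_range: tuple = (0.05, 0.5)
    ld_decay: float = 0.9
    n_qtl: int = 200
    h2_add: float = 0.365
    h2_dom: float = 0.035
    n_batches: int = 24
    batch_sd: float = 0.1  # in phenotypic-SD units
    pheno_mean: float = 10.72
    pheno_sd: float = 1.72
    discretize: bool = True
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_sires, self.n_litters, self.n_snps,
               self.n_chromosomes, self.n_batches) < 1:
            raise ConfigurationError("counts must be positive")
        lo, hi = self.litter_size_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("litter sizes must satisfy 1 <= min <= max")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.ld_decay < 1):
            raise ConfigurationError("ld_decay must be in [0, 1)")
        if self.h2_add < 0 or self.h2_dom < 0 or self.h2_add + self.h2_dom >= 1:
            raise ConfigurationError("need h2_add + h2_dom < 1 with both >= 0")
        if self.n_qtl > self.n_snps:
            raise ConfigurationError("n_qtl cannot exceed n_snps")


@dataclass
class TruthRecord:
    """Per-individual true genetic values and per-QTL effects."""

    a: np.ndarray  # true additive (breeding) values
    d: np.ndarray  # true dominance deviations
    g: np.ndarray  # total genetic value a + d
    qtl: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: snp_id, snp_index, add_effect, dom_effect, freq

    def to_frame(self, ind_ids) -> pd.DataFrame:
        return pd.DataFrame({"iid": ind_ids, "a": self.a, "d": self.d, "g": self.g})


def simulate_pedigree(config: SimConfig) -> PopulationStructure:
    """Assign litters to sires, one unique dam per litter, litter sizes
    uniform within the configured range, and a year-month batch label
    per litter."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # Every sire gets at least one litter when possible; the rest at random.
    litter_sire = np.empty(config.n_litters, dtype=np.int64)
    base = min(config.n_sires, config.n_litters)
    litter_sire[:base] = np.arange(base)
    if config.n_litters > base:
        litter_sire[base:] = rng.integers(0, config.n_sires, config.n_litters - base)
    rng.shuffle(litter_sire)

    lo, hi = config.litter_size_range
    sizes = rng.integers(lo, hi + 1, config.n_litters)
    litter_batch = rng.integers(0, config.n_batches, config.n_litters)

    sire_ids = np.array([f"SIRE{i:03d}" for i in range(config.n_sires)], dtype=object)
    dam_ids = np.array([f"DAM{i:04d}" for i in range(config.n_litters)], dtype=object)

    rows = []
    k = 0
    for lit in range(config.n_litters):
        for _ in range(sizes[lit]):
            rows.append(
                (f"IND{k:05d}", sire_ids[litter_sire[lit]], dam_ids[lit],
                 f"LIT{lit:04d}", f"B{litter_batch[lit]:02d}")
            )
            k += 1
    table = pd.DataFrame(rows, columns=["iid", "sire", "dam", "litter", "batch"])
    return PopulationStructure(table=table, sire_ids=sire_ids, dam_ids=dam_ids)


def _chromosome_sizes(n_snps: int, n_chrom: int) -> np.ndarray:
    sizes = np.full(n_chrom, n_snps // n_chrom, dtype=np.int64)
    sizes[: n_snps % n_chrom] += 1
    return sizes


def _founder_haplotypes(rng, n_haps: int, freqs: np.ndarray, ld: float) -> np.ndarray:
    """AR(1) Gaussian latent process thresholded at each marker's allele
    frequency: adjacent markers share latent correlation ``ld``."""
    m = len(freqs)
    z = np.empty((n_haps, m), dtype=np.float32)
    z[:, 0] = rng.standard_normal(n_haps)
    if m > 1:
        innov = rng.standard_normal((n_haps, m - 1)).astype(np.float32)
        w = np.sqrt(1.0 - ld * ld)
        for k in range(1, m):
            z[:, k] = ld * z[:, k - 1] + w * innov[:, k - 1]
    thresh = norm.ppf(freqs).astype(np.float32)
    return (z < thresh[None, :]).astype(np.uint8)


def _transmit(rng, parent_haps: np.ndarray, recomb: float, n_gametes: int) -> np.ndarray:
    """Gene dropping: each gamete copies one of the parent's two
    haplotypes, switching between them with probability ``recomb`` in
    each adjacent-marker interval."""
    m = parent_haps.shape[1]
    start = rng.integers(0, 2, n_gametes)
    if m > 1:
        switches = rng.random((n_gametes, m - 1)) < recomb
        hap_idx = np.empty((n_gametes, m), dtype=np.int8)
        hap_idx[:, 0] = start
        hap_idx[:, 1:] = switches
        np.cumsum(hap_idx, axis=1, out=hap_idx)
        hap_idx &= 1
    else:
        hap_idx = start[:, None].astype(np.int8)
    cols = np.arange(m)
    return parent_haps[hap_idx, cols[None, :]]


def simulate_genotypes(structure: PopulationStructure, config: SimConfig,
                       return_founders: bool = False):
    """Draw founder haplotypes with local LD, then drop genes through the
    pedigree with recombination. Returns offspring genotypes (the
    phenotyped study individuals); with ``return_founders`` also a dict
    of sire and dam genotype-code arrays for transmission checks."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    n_sires = len(structure.sire_ids)
    n_dams = len(structure.dam_ids)
    n_off = structure.n_individuals

    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], config.n_snps)
    sizes = _chromosome_sizes(config.n_snps, config.n_chromosomes)

    sire_lookup = {s: i for i, s in enumerate(structure.sire_ids)}
    dam_lookup = {d: i for i, d in enumerate(structure.dam_ids)}
    off_sire = structure.table["sire"].map(sire_lookup).to_numpy()
    off_dam = structure.table["dam"].map(dam_lookup).to_numpy()

    codes = np.empty((n_off, config.n_snps), dtype=np.int8)
    sire_codes = np.empty((n_sires, config.n_snps), dtype=np.int8)
    dam_codes = np.empty((n_dams, config.n_snps), dtype=np.int8)
    meta_chrom, meta_pos = [], []
    offset = 0
    for c, mc in enumerate(sizes):
        fc = freqs[offset: offset + mc]
        sire_h = _founder_haplotypes(rng, 2 * n_sires, fc, config.ld_decay)
        sire_h = sire_h.reshape(n_sires, 2, mc)
        dam_h = _founder_haplotypes(rng, 2 * n_dams, fc, config.ld_decay)
        dam_h = dam_h.reshape(n_dams, 2, mc)
        recomb = min(0.5, 1.0 / mc) if mc > 1 else 0.0

        pat = np.empty((n_off, mc), dtype=np.uint8)
        mat = np.empty((n_off, mc), dtype=np.uint8)
        # group offspring by parent so each parent's gametes are drawn at once
        for parent_idx, haps, out in ((off_sire, sire_h, pat), (off_dam, dam_h, mat)):
            order = np.argsort(parent_idx, kind="stable")
            grouped = parent_idx[order]
            bounds = np.flatnonzero(np.diff(grouped)) + 1
            for block in np.split(order, bounds):
                p = parent_idx[block[0]]
                out[block] = _transmit(rng, haps[p], recomb, len(block))
        codes[:, offset: offset + mc] = (pat + mat).astype(np.int8)
        sire_codes[:, offset: offset + mc] = sire_h.sum(axis=1).astype(np.int8)
        dam_codes[:, offset: offset + mc] = dam_h.sum(axis=1).astype(np.int8)
        meta_chrom.extend([c + 1] * mc)
        meta_pos.extend(((np.arange(mc) + 1) * 50_000).tolist())
        offset += mc

    meta = pd.DataFrame({
        "chrom": np.asarray(meta_chrom, dtype=np.int64),
        "pos": np.asarray(meta_pos, dtype=np.int64),
        "id": [f"S{c}_{p}" for c, p in zip(meta_chrom, meta_pos)],
        "ref": "A",
        "alt": "G",
    })
    G = GenotypeMatrix(codes=codes, snp_meta=meta,
                       ind_ids=structure.table["iid"].to_numpy())
    if return_founders:
        return G, {"sire": sire_codes, "dam": dam_codes,
                   "off_sire_index": off_sire, "off_dam_index": off_dam}
    return G


def _dominance_column(x: np.ndarray, p: float) -> np.ndarray:
    """Statistical dominance-deviation coding at allele frequency p:
    orthogonal to the allele-count regression under HWE."""
    q = 1.0 - p
    out = np.empty_like(x, dtype=np.float64)
    out[x == 0] = -2.0 * p * p
    out[x == 1] = 2.0 * p * q
    out[x == 2] = -2.0 * q * q
    return out


def simulate_phenotypes(genotypes: GenotypeMatrix, structure: PopulationStructure,
                        config: SimConfig):
    """Build y = mean + batch + a + d + e with realized variance ratios
    rescaled to hit the target heritabilities on this sample.

    Heritabilities are defined against sigma2_y = var(a)+var(d)+var(e)
    (batch is a fixed effect, excluded from the denominator, matching
    the mixed-model definition used downstream). Returns
    (phenotype table, TruthRecord).
    """
    config.validate()
    if genotypes.n_individuals != structure.n_individuals:
        raise ConfigurationError("genotypes and structure disagree on n")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = genotypes.n_individuals

    qtl_idx = np.sort(rng.choice(genotypes.n_snps, size=config.n_qtl, replace=False))
    X = genotypes.codes[:, qtl_idx].astype(np.float64)
    p = X.mean(axis=0) / 2.0

    alpha = rng.standard_normal(config.n_qtl)
    a_raw = (X - 2.0 * p) @ alpha

    delta = rng.standard_normal(config.n_qtl)
    Wd = np.column_stack([
        _dominance_column(X[:, k], p[k]) for k in range(config.n_qtl)
    ]) if config.n_qtl else np.zeros((n, 0))
    d_raw = Wd @ delta if config.n_qtl else np.zeros(n)

    sigma2_y = config.pheno_sd ** 2

    def _rescale(v: np.ndarray, eff: np.ndarray, target_var: float):
        var = v.var()
        if target_var == 0 or var == 0:
            if target_var > 0 and var == 0:
                raise ConfigurationError("no genetic variance to rescale")
            return np.zeros_like(v), np.zeros_like(eff)
        s = np.sqrt(target_var / var)
        return v * s, eff * s

    a, alpha = _rescale(a_raw, alpha, config.h2_add * sigma2_y)
    d, delta = _rescale(d_raw, delta, config.h2_dom * sigma2_y)

    e = rng.standard_normal(n)
    e_target = (1.0 - config.h2_add - config.h2_dom) * sigma2_y
    e = e * np.sqrt(e_target / e.var())
    e -= e.mean()

    batch_levels = np.unique(structure.table["batch"])
    batch_eff = rng.normal(0.0, config.batch_sd * config.pheno_sd, len(batch_levels))
    lut = dict(zip(batch_levels, batch_eff))
    b = structure.table["batch"].map(lut).to_numpy()

    y = config.pheno_mean + b + a + d + e
    if config.discretize:
        y = np.rint(y)

    pheno = structure.table[["iid", "sire", "litter", "batch"]].copy()
    pheno["y"] = y

    truth = TruthRecord(
        a=a, d=d, g=a + d,
        qtl=pd.DataFrame({
            "snp_id": genotypes.snp_meta["id"].to_numpy()[qtl_idx],
            "snp_index": qtl_idx,
            "add_effect": alpha,
            "dom_effect": delta,
            "freq": p,
        }),
    )
    return pheno, truth


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: pedigree -> genotypes -> phenotypes.

    Returns (GenotypeMatrix, PopulationStructure, phenotype DataFrame,
    TruthRecord).
    """
    structure = simulate_pedigree(config)
    G = simulate_genotypes(structure, config)
    pheno, truth = simulate_phenotypes(G, structure, config)
    return G, structure, pheno, truth


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
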