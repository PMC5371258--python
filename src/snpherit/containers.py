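"""Core in-memory containers shared across the package.

Genotypes are held as an individuals x SNPs matrix of alternate-allele
counts (0/1/2, -1 for missing) together with per-SNP metadata, mirroring
the layout of a PLINK fileset after loading.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SNP_META_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for a panel of individuals.

    Parameters
    ----------
    codes : ndarray of shape (n_individuals, n_snps), int8
        Count of the alternate allele per genotype: 0, 1 or 2;
        ``MISSING`` (-1) marks an uncalled genotype.
    snp_meta : DataFrame with columns chrom, pos, id, ref, alt
        One row per SNP, positions 1-based.
    ind_ids : array of str
        Ordered unique individual identifiers.
    """

    codes: np.ndarray
    snp_meta: pd.DataFrame
    ind_ids: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.ind_ids = np.asarray(self.ind_ids, dtype=object)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x SNPs)")
        if self.codes.shape[0] != len(self.ind_ids):
            raise ValueError("ind_ids length does not match codes rows")
        if self.codes.shape[1] != len(self.snp_meta):
            raise ValueError("snp_meta rows do not match codes columns")
        if len(set(self.ind_ids)) != len(self.ind_ids):
            raise ValueError("individual ids are not unique")
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes outside {0,1,2,missing}")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["id"].to_numpy()

    def subset_snps(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            codes=self.codes[:, idx],
            snp_meta=self.snp_meta.iloc[idx],
            ind_ids=self.ind_ids,
        )

    def subset_individuals(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            codes=self.codes[idx, :],
            snp_meta=self.snp_meta,
            ind_ids=self.ind_ids[idx],
        )

    def snp_index(self, snp_ids) -> np.ndarray:
        """Map SNP ids to column indices; raises listing unknown ids."""
        lookup = pd.Index(self.snp_meta["id"])
        idx = lookup.get_indexer(list(snp_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"unknown SNP ids: {missing}")
        return idx

    def imputed_dosages(self) -> np.ndarray:
        """Codes as float with missing genotypes mean-imputed to 2p."""
        x = self.codes.astype(np.float64)
        miss = self.codes == MISSING
        if miss.any():
            x[miss] = np.nan
            col_mean = np.nanmean(x, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            ii, jj = np.nonzero(miss)
            x[ii, jj] = col_mean[jj]
        return x


@dataclass
class PopulationStructure:
    """Per-individual family structure: sire, dam, litter and batch labels.

    ``table`` has one row per (phenotyped) individual with columns
    iid, sire, dam, litter, batch. Founders (sires/dams) are listed
    separately; they carry no phenotype.
    """

    table: pd.DataFrame
    sire_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    dam_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        required = {"iid", "sire", "dam", "litter", "batch"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"structure table needs columns {sorted(required)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    def family_labels(self, grouping: str = "litter") -> np.ndarray:
        """Family grouping for sib models: 'litter' (full sibs, default)
        or 'sire' (paternal half-sib families)."""
        if grouping not in ("litter", "sire"):
            raise ValueError("grouping must be 'litter' or 'sire'")
        return self.table[grouping].to_numpy()
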