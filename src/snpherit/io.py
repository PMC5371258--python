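"""Readers and writers for standard genotype formats.

PLINK binary (bed/bim/fam, v1.00 SNP-major) is decoded/encoded directly
from the bit-packed payload; VCF reading uses cyvcf2, VCF writing emits
plain-text VCF 4.2. GRMs are written in the GCTA grm.gz + grm.id dialect.

Genotype codes are counts of the alternate allele. When writing PLINK,
A1 is set to the alternate allele and A2 to the reference, so bed code
00 (hom A1) maps to 2, 10 (het) to 1, 11 (hom A2) to 0 and 01 to
missing; reading reverses the mapping.
"""
from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# two-bit PLINK code -> alt-allele count (A1 = alt)
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_CODE_TO_BITS = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

# 256-entry lookup: byte -> 4 genotype codes (low bits first)
_BYTE_LUT = np.zeros((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _BYTE_LUT[_b, _k] = _BED_DECODE[(_b >> (2 * _k)) & 0b11]


class FormatError(ValueError):
    pass


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK v1.00 SNP-major bed/bim/fam fileset."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype=str)
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(
            f"{prefix}.bed: bad magic bytes at offset 0: {raw[:3].tobytes()!r}")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if raw.size != expected:
        raise FormatError(
            f"{prefix}.bed: payload is {raw.size} bytes, expected {expected} "
            f"(truncated at byte offset {min(raw.size, expected)})")
    body = raw[3:].reshape(m, bytes_per_snp)
    codes = _BYTE_LUT[body].reshape(m, bytes_per_snp * 4)[:, :n]
    meta = pd.DataFrame({
        "chrom": bim["chrom"].to_numpy(),
        "pos": bim["pos"].to_numpy(),
        "id": bim["id"].to_numpy(),
        "ref": bim["a2"].to_numpy(),
        "alt": bim["a1"].to_numpy(),
    })
    return GenotypeMatrix(codes=codes.T.copy(), snp_meta=meta,
                          ind_ids=fam["iid"].to_numpy())


def write_plink(G: GenotypeMatrix, prefix) -> None:
    """Write bed/bim/fam (v1.00 SNP-major). A1 = alt, A2 = ref."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = G.n_individuals, G.n_snps
    bytes_per_snp = (n + 3) // 4
    bits = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for code, b in _CODE_TO_BITS.items():
        lut[np.int8(code).view(np.uint8)] = b
    # pad the last partial byte with hom-A2 (code 0 -> bits 11)
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.int8)
    padded[:, :n] = G.codes.T
    bits = lut[padded.view(np.uint8)]
    packed = (bits[:, 0::4] | (bits[:, 1::4] << 2)
              | (bits[:, 2::4] << 4) | (bits[:, 3::4] << 6)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    bim = pd.DataFrame({
        "chrom": G.snp_meta["chrom"], "id": G.snp_meta["id"], "cm": 0,
        "pos": G.snp_meta["pos"], "a1": G.snp_meta["alt"], "a2": G.snp_meta["ref"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": G.ind_ids, "iid": G.ind_ids, "father": 0, "mother": 0,
        "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_vcf(path) -> GenotypeMatrix:
    """Read diploid biallelic SNP records from a VCF (gzip accepted).
    Multi-allelic or non-diploid records are skipped with a warning."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ind_ids = np.asarray(vcf.samples, dtype=object)
    rows, chroms, poss, ids, refs, alts = [], [], [], [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        gts = var.genotype.array()
        if gts.shape[1] < 2:
            skipped += 1
            continue
        a = gts[:, 0].astype(np.int64)
        b = gts[:, 1].astype(np.int64)
        codes = np.where((a < 0) | (b < 0), MISSING, a + b).astype(np.int8)
        if codes.max(initial=0) > 2:
            skipped += 1
            continue
        rows.append(codes)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID if var.ID else f"S{var.CHROM}_{var.POS}")
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if skipped:
        logger.warning("read_vcf: skipped %d multi-allelic/non-diploid records", skipped)
    if not rows:
        raise FormatError(f"{path}: no usable biallelic SNP records")
    meta = pd.DataFrame({"chrom": chroms, "pos": poss, "id": ids,
                         "ref": refs, "alt": alts})
    return GenotypeMatrix(codes=np.vstack(rows).T, snp_meta=meta, ind_ids=ind_ids)


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write genotypes as uncompressed VCF 4.2 with GT fields."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, G.ind_ids)) + "\n")
        meta = G.snp_meta
        for j in range(G.n_snps):
            gts = "\t".join(gt_map[int(c)] for c in G.codes[:, j])
            fh.write(f"{meta.chrom[j]}\t{meta.pos[j]}\t{meta.id[j]}\t"
                     f"{meta.ref[j]}\t{meta.alt[j]}\t.\t.\t.\tGT\t{gts}\n")


def read_genotypes(path, format: str = "plink_bed") -> GenotypeMatrix:
    """Dispatch reader: format in {'plink_bed', 'vcf'}. For plink_bed,
    pass the fileset prefix (with or without .bed)."""
    if format == "plink_bed":
        p = Path(path)
        if p.suffix == ".bed":
            p = p.with_suffix("")
        return read_plink(p)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def write_grm_gcta(grm: np.ndarray, ids, n_snps: int, prefix) -> None:
    """GCTA text dialect: lower triangle rows (i, j, n_snps, value) in
    grm.gz plus grm.id."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = grm.shape[0]
    with gzip.open(str(prefix) + ".grm.gz", "wt") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{n_snps}\t{grm[i, j]:.8g}\n")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for iid in ids:
            fh.write(f"{iid}\t{iid}\n")


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    """Phenotype/covariate table as TSV with header iid sire litter batch y."""
    cols = ["iid", "sire", "litter", "batch", "y"]
    pheno[cols].to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"iid": str, "sire": str,
                                            "litter": str, "batch": str})
    missing = {"iid", "batch", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: phenotype table lacks columns {sorted(missing)}")
    return df
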