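"""Genomic relationship matrices, IBS/MDS stratification and pairwise LD.

The additive matrix is the VanRaden-type A_g = W_a W_a' / sum_k 2 p_k q_k
with W_a[i,k] = x_ik - 2 p_k; the dominance matrix uses the matched
statistical coding W_d in {-2q^2, 2pq, -2p^2} normalized by
sum_k (2 p_k q_k)^2. Allele frequencies are always estimated from the
analysis sample. MDS follows the PLINK convention: classical scaling of
the distance matrix 1 - IBS.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    pass


def _dosages_and_freqs(G):
    if isinstance(G, GenotypeMatrix):
        X = G.imputed_dosages()
    else:
        X = np.asarray(G, dtype=np.float64)
    p = X.mean(axis=0) / 2.0
    return X, p


def centered_dosages(G):
    """W_a = X - 2p with p from the sample; also returns p."""
    X, p = _dosages_and_freqs(G)
    return X - 2.0 * p, p


def dominance_coded(G):
    """W_d: -2q^2 for code 2, 2pq for code 1, -2p^2 for code 0 (with
    mean-imputed dosages interpolated linearly between the class codes);
    also returns p."""
    X, p = _dosages_and_freqs(G)
    q = 1.0 - p
    # exact class codes at 0/1/2; piecewise-linear in between for
    # mean-imputed dosages
    w = np.where(
        X <= 1.0,
        -2.0 * p * p + X * (2.0 * p * q + 2.0 * p * p),
        2.0 * p * q + (X - 1.0) * (-2.0 * q * q - 2.0 * p * q),
    )
    return w, p


def additive_grm(G) -> np.ndarray:
    """A_g = W_a W_a' / sum_k 2 p_k q_k."""
    W, p = centered_dosages(G)
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0:
        raise DegenerateInputError("all SNPs monomorphic; additive GRM undefined")
    return (W @ W.T) / denom


def dominance_grm(G) -> np.ndarray:
    """D_g = W_d W_d' / sum_k (2 p_k q_k)^2."""
    W, p = dominance_coded(G)
    denom = float(np.sum((2.0 * p * (1.0 - p)) ** 2))
    if denom <= 0:
        raise DegenerateInputError("all SNPs monomorphic; dominance GRM undefined")
    return (W @ W.T) / denom


@dataclass
class GRMPair:
    """Additive and dominance GRMs with their normalizers."""

    A: np.ndarray
    D: np.ndarray
    sum_2pq: float
    sum_2pq_sq: float
    n_snps: int
    W_a: np.ndarray | None = None
    W_d: np.ndarray | None = None


def build_grms(G, keep_loadings: bool = True) -> GRMPair:
    """Compute A_g and D_g together, optionally retaining the centered
    marker matrices needed for back-solving SNP effects."""
    Wa, p = centered_dosages(G)
    Wd, _ = dominance_coded(G)
    s_a = float(np.sum(2.0 * p * (1.0 - p)))
    s_d = float(np.sum((2.0 * p * (1.0 - p)) ** 2))
    if s_a <= 0 or s_d <= 0:
        raise DegenerateInputError("all SNPs monomorphic; GRMs undefined")
    pair = GRMPair(
        A=(Wa @ Wa.T) / s_a,
        D=(Wd @ Wd.T) / s_d,
        sum_2pq=s_a,
        sum_2pq_sq=s_d,
        n_snps=Wa.shape[1],
        W_a=Wa if keep_loadings else None,
        W_d=Wd if keep_loadings else None,
    )
    return pair


def ibs_matrix(G) -> np.ndarray:
    """Identity-by-state similarity: S[i,j] = mean_k (2 - |x_ik - x_jk|)/2.

    Computed from genotype-class indicator matmuls, so cost is a few
    n x m by m x n products.
    """
    if isinstance(G, GenotypeMatrix):
        codes = G.codes
    else:
        codes = np.asarray(G)
    n, m = codes.shape
    I0 = (codes == 0).astype(np.float64)
    I1 = (codes == 1).astype(np.float64)
    I2 = (codes == 2).astype(np.float64)
    # |a-b| = 2*(opposite homozygotes) + 1*(het vs homozygote)
    opp = I0 @ I2.T
    hethom = I1 @ (I0 + I2).T
    absdiff = 2.0 * (opp + opp.T) + hethom + hethom.T
    return (2.0 * m - absdiff) / (2.0 * m)


@dataclass
class MdsCoordinates:
    """Classical-MDS stratification coordinates, ordered by eigenvalue."""

    coords: np.ndarray  # n x d, columns centered at 0
    eigenvalues: np.ndarray


def mds_components(S: np.ndarray, d: int) -> MdsCoordinates:
    """Classical MDS of distance D = 1 - S: double-centered Gram matrix
    B = -1/2 J D^2 J, top-d eigenpairs, coordinates eigenvector*sqrt(eig).

    If fewer than d eigenvalues are positive, returns fewer columns with
    a warning.
    """
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[0]
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be a symmetric similarity matrix")
    if d >= n:
        raise ValueError("d must be smaller than n")
    D2 = (1.0 - S) ** 2
    row = D2.mean(axis=0)
    B = -0.5 * (D2 - row[None, :] - row[:, None] + D2.mean())
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-9 * abs(vals[0]))
    n_pos = int(pos[:d].sum())
    if n_pos < d:
        warnings.warn(f"only {n_pos} positive MDS eigenvalues; returning fewer "
                      f"columns than requested ({d})")
    keep = min(d, n_pos) if n_pos > 0 else 0
    coords = vecs[:, :keep] * np.sqrt(vals[:keep])[None, :]
    return MdsCoordinates(coords=coords, eigenvalues=vals[:max(keep, 1)])


class MDSStratifier:
    """Sklearn-style transformer: genotype codes -> leading MDS
    stratification coordinates of the IBS distance matrix.

    Like sklearn.manifold.MDS, only fit_transform is meaningful
    (classical MDS does not project unseen individuals).
    """

    def __init__(self, n_components: int = 35):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        S = ibs_matrix(X)
        mds = mds_components(S, self.n_components)
        self.ibs_ = S
        self.embedding_ = mds.coords
        self.eigenvalues_ = mds.eigenvalues
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def transform(self, X):
        raise NotImplementedError(
            "classical MDS cannot embed new individuals; use fit_transform")


class EMConvergenceError(RuntimeError):
    def __init__(self, msg, last_estimate=None):
        super().__init__(msg)
        self.last_estimate = last_estimate


@dataclass
class LdEstimate:
    """Pairwise linkage disequilibrium between two SNPs."""

    D: float
    Dprime: float
    r2: float
    hap_freqs: np.ndarray  # (p_AB, p_Ab, p_aB, p_ab)
    n_iter: int


def _ld_from_hapfreq(p_AB: float, p_A: float, p_B: float) -> tuple:
    D = p_AB - p_A * p_B
    q_A, q_B = 1.0 - p_A, 1.0 - p_B
    if D > 0:
        d_max = min(p_A * q_B, q_A * p_B)
    else:
        d_max = min(p_A * p_B, q_A * q_B)
    dprime = abs(D) / d_max if d_max > 0 else 0.0
    denom = p_A * q_A * p_B * q_B
    r2 = D * D / denom if denom > 0 else 0.0
    return D, min(dprime, 1.0), min(r2, 1.0)


def pairwise_ld(G, snp_i: int, snp_j: int, tol: float = 1e-10,
                max_iter: int = 1000) -> LdEstimate:
    """EM haplotype-frequency estimation over unphased genotypes, then
    D, Lewontin's D' and r^2.

    Only the double heterozygote is phase-ambiguous; the EM splits its
    count between coupling (AB/ab) and repulsion (Ab/aB) in proportion
    to the current haplotype-frequency products.
    """
    if isinstance(G, GenotypeMatrix):
        xi = G.codes[:, snp_i].astype(np.int64)
        xj = G.codes[:, snp_j].astype(np.int64)
    else:
        G = np.asarray(G)
        xi, xj = G[:, snp_i].astype(np.int64), G[:, snp_j].astype(np.int64)
    ok = (xi >= 0) & (xj >= 0)
    xi, xj = xi[ok], xj[ok]
    n = len(xi)
    if n == 0:
        raise ValueError("no called genotype pairs")
    p_A = xi.mean() / 2.0
    p_B = xj.mean() / 2.0
    if p_A in (0.0, 1.0) or p_B in (0.0, 1.0):
        raise DegenerateInputError("both SNPs must be polymorphic")

    # 3x3 genotype table, A = alt allele of snp_i, B = alt of snp_j
    table = np.zeros((3, 3), dtype=np.float64)
    np.add.at(table, (xi, xj), 1.0)

    # haplotype counts are certain for every cell except the double
    # heterozygote (1,1); haplotypes ordered (AB, Ab, aB, ab)
    certain = np.zeros(4)
    phase = {
        (0, 0): (0, 0, 0, 2), (0, 1): (0, 0, 1, 1), (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1), (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0), (2, 1): (1, 1, 0, 0), (2, 2): (2, 0, 0, 0),
    }
    for (gi, gj), hap in phase.items():
        certain += table[gi, gj] * np.array(hap, dtype=np.float64)
    n_dh = table[1, 1]

    f = np.full(4, 0.25)
    n_hap = 2.0 * n
    last = f
    for it in range(1, max_iter + 1):
        # E: split double hets between AB/ab and Ab/aB
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        tot = coupling + repulsion
        w = 0.5 if tot == 0 else coupling / tot
        counts = certain + n_dh * np.array([w, 1 - w, 1 - w, w])
        new = counts / n_hap
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f, last = new, new
    else:
        raise EMConvergenceError(
            f"LD EM did not converge in {max_iter} iterations", last_estimate=last)
    D, dprime, r2 = _ld_from_hapfreq(f[0], p_A, p_B)
    return LdEstimate(D=D, Dprime=dprime, r2=r2, hap_freqs=f, n_iter=it)


def ld_table(G, pairs) -> "pd.DataFrame":
    """Pairwise LD for a list of (i, j) SNP index pairs, as a tidy table."""
    import pandas as pd

    ids = G.snp_ids if isinstance(G, GenotypeMatrix) else None
    rows = []
    for i, j in pairs:
        est = pairwise_ld(G, i, j)
        rows.append({
            "snp_i": ids[i] if ids is not None else i,
            "snp_j": ids[j] if ids is not None else j,
            "D": est.D, "Dprime": est.Dprime, "r2": est.r2,
        })
    return pd.DataFrame(rows)
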