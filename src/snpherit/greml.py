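"""AI-REML variance-component estimation and GBLUP prediction.

Model: y = X_b b + Z a + Z d + e with
Var(y) = V = Z A_g Z' s2_a + Z D_g Z' s2_d + I s2_e.
The dominance term is dropped when ``include_dominance`` is False.

The restricted likelihood is maximized by average-information updates
with an EM fallback whenever an AI step would leave the parameter
space; components that collapse are pinned at a small positive boundary
(1e-6 of the phenotypic variance) and flagged. Standard errors come
from the inverse AI matrix at convergence; heritability SEs by the
delta method.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

BOUNDARY_FRACTION = 1e-6


class ConvergenceError(RuntimeError):
    def __init__(self, msg, trajectory=None):
        super().__init__(msg)
        self.trajectory = trajectory


def design_matrix(batch=None, n: int | None = None, snp_codes: np.ndarray | None = None,
                  genotypic: bool = False):
    """Fixed-effect design: intercept + batch factor (first level dropped)
    + optional fixed-SNP columns.

    SNPs fitted as fixed effects enter as allele-count covariates by
    default; ``genotypic=True`` adds a heterozygote indicator per SNP
    (2-df genotype coding). Returns (X, column names).
    """
    if batch is not None:
        batch = np.asarray(batch)
        n = len(batch)
    if n is None:
        raise ValueError("need batch labels or n")
    cols = [np.ones(n)]
    names = ["intercept"]
    if batch is not None:
        levels = pd.unique(batch)
        for lev in levels[1:]:
            cols.append((batch == lev).astype(np.float64))
            names.append(f"batch[{lev}]")
    if snp_codes is not None:
        snp_codes = np.atleast_2d(np.asarray(snp_codes, dtype=np.float64))
        if snp_codes.shape[0] != n:
            snp_codes = snp_codes.T
        for k in range(snp_codes.shape[1]):
            cols.append(snp_codes[:, k])
            names.append(f"snp{k}_add")
            if genotypic:
                cols.append((snp_codes[:, k] == 1).astype(np.float64))
                names.append(f"snp{k}_het")
    X = np.column_stack(cols)
    # drop collinear columns (keeps full column rank)
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    tol = np.abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
    rank = int((np.abs(np.diag(r)) > tol).sum())
    if rank < X.shape[1]:
        keep = np.sort(piv[:rank])
        dropped = [names[i] for i in piv[rank:]]
        warnings.warn(f"dropping collinear fixed-effect columns: {dropped}")
        X = X[:, keep]
        names = [names[i] for i in keep]
    return X, names


@dataclass
class MixedModelSpec:
    """Inputs to one GREML/GBLUP analysis.

    ``obs_to_ind`` maps each phenotype record to its row in the GRMs
    (identity by default — one record per genotyped individual).
    """

    y: np.ndarray
    X: np.ndarray  # fixed design incl. intercept (+ batch, + fixed SNPs)
    A: np.ndarray
    D: np.ndarray | None = None
    include_dominance: bool = True
    obs_to_ind: np.ndarray | None = None
    x_names: list = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        n = len(self.y)
        if self.X.shape[0] != n:
            raise ValueError("X rows must match y")
        if self.obs_to_ind is None:
            if self.A.shape[0] != n:
                raise ValueError("GRM size must match y without obs_to_ind")
            self.obs_to_ind = np.arange(n)
        self.obs_to_ind = np.asarray(self.obs_to_ind)
        if self.include_dominance and self.D is None:
            raise ValueError("include_dominance requires D")

    def kernels(self, ind_subset=None):
        """Observation-level covariance kernels [Z K Z' ...] restricted to
        a subset of observation indices."""
        idx = self.obs_to_ind if ind_subset is None else self.obs_to_ind[ind_subset]
        ks = [self.A[np.ix_(idx, idx)]]
        names = ["additive"]
        if self.include_dominance:
            ks.append(self.D[np.ix_(idx, idx)])
            names.append("dominance")
        return ks, names


@dataclass
class VarianceComponents:
    components: dict  # name -> estimate (includes 'residual')
    se: dict
    cov: np.ndarray  # sampling covariance of estimates (inverse AI)
    loglik: float
    n_iter: int
    converged: bool
    boundary: dict  # name -> bool, pinned at lower boundary

    @property
    def sigma2_y(self) -> float:
        return float(sum(self.components.values()))

    def order(self):
        return list(self.components.keys())


def _full_rank_columns(X):
    """Indices of a maximal linearly independent column subset (QR with
    pivoting). Keeps original order."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = (diag[0] if diag.size else 0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return np.sort(piv[:rank])


def _reml_pieces(y, X, V):
    """Cholesky-based P matrix, Py and restricted log-likelihood parts."""
    n = len(y)
    cf = linalg.cho_factor(V, lower=True, check_finite=False)
    logdet_V = 2.0 * np.log(np.diag(cf[0])).sum()
    Vinv = linalg.cho_solve(cf, np.eye(n), check_finite=False)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    cfx = linalg.cho_factor(XtVinvX, lower=True, check_finite=False)
    logdet_X = 2.0 * np.log(np.diag(cfx[0])).sum()
    beta = linalg.cho_solve(cfx, X.T @ (Vinv @ y), check_finite=False)
    P = Vinv - VinvX @ linalg.cho_solve(cfx, VinvX.T, check_finite=False)
    Py = P @ y
    yPy = float(y @ Py)
    ll = -0.5 * (logdet_V + logdet_X + yPy)
    return P, Py, beta, ll


def fit_greml(spec: MixedModelSpec, max_iter: int = 200, tol: float = 1e-8,
              verbose: bool = False) -> VarianceComponents:
    """Average-information REML with EM fallback and boundary pinning.

    Convergence: relative change of every component below ``tol``.
    """
    y, X = spec.y, spec.X
    keep_cols = _full_rank_columns(X)
    if len(keep_cols) < X.shape[1]:
        X = X[:, keep_cols]
    n = len(y)
    if n < X.shape[1] + 2:
        raise ValueError("too few records for the fixed design")
    Ks, names = spec.kernels()
    Ks = Ks + [np.eye(n)]
    names = names + ["residual"]
    q = len(Ks)

    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    vary = float(resid.var())
    if vary <= 0:
        raise ValueError("phenotype has zero residual variance")
    sigma = np.full(q, vary / q)
    floor = BOUNDARY_FRACTION * vary

    trajectory = [sigma.copy()]
    converged = False
    ai_inv = np.eye(q)
    ll = -np.inf
    ll_prev = -np.inf
    for it in range(1, max_iter + 1):
        V = sum(s * K for s, K in zip(sigma, Ks))
        try:
            P, Py, _, ll = _reml_pieces(y, X, V)
        except linalg.LinAlgError:
            # ridge the GRM part and retry once
            V = V + np.eye(n) * (1e-8 * vary)
            P, Py, _, ll = _reml_pieces(y, X, V)

        KPy = [K @ Py for K in Ks]
        score = np.array([
            -0.5 * (float(np.sum(P * K)) - float(Py @ KPy_i))
            for K, KPy_i in zip(Ks, KPy)
        ])
        AI = 0.5 * np.array([[float(KPy[i] @ (P @ KPy[j])) for j in range(q)]
                             for i in range(q)])
        try:
            delta = np.linalg.solve(AI, score)
            ai_inv = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            delta = None

        if delta is None or not np.all(np.isfinite(delta)) or it > 100:
            new = None
        else:
            # project components that an AI step would push out of the
            # parameter space onto the boundary; the others move freely
            new = np.maximum(sigma + delta, floor)
        if new is None:
            # EM update: s_i' = s_i + s_i^2 (y'P K P y - tr(P K)) / n
            new = np.array([
                max(s + (s * s) * (float(Py @ KPy_i) - float(np.sum(P * K))) / n,
                    floor)
                for s, K, KPy_i in zip(sigma, Ks, KPy)
            ])
        new = np.maximum(new, floor)

        rel = np.abs(new - sigma) / np.maximum(np.abs(sigma), floor)
        # a component sitting on the lower boundary is treated as settled
        pinned = (new <= floor * (1 + 1e-9)) & (sigma <= floor * 2)
        rel[pinned] = 0.0
        ll_change = ll - ll_prev if it > 1 else np.inf
        sigma = new
        ll_prev = ll
        trajectory.append(sigma.copy())
        if verbose:
            logger.info("AI-REML iter %d: ll=%.6f sigma=%s", it, ll, sigma)
        if np.all(rel < tol) or (it > 10 and abs(ll_change) < 1e-10 * max(1.0, abs(ll))):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"AI-REML did not converge in {max_iter} iterations",
            trajectory=np.array(trajectory))

    # final SEs from the AI matrix at the solution
    V = sum(s * K for s, K in zip(sigma, Ks))
    P, Py, _, ll = _reml_pieces(y, X, V)
    KPy = [K @ Py for K in Ks]
    AI = 0.5 * np.array([[float(KPy[i] @ (P @ KPy[j])) for j in range(q)]
                         for i in range(q)])
    try:
        ai_inv = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        ai_inv = np.linalg.pinv(AI)
    se = np.sqrt(np.maximum(np.diag(ai_inv), 0.0))
    boundary = {nm: bool(s <= floor * (1 + 1e-12)) for nm, s in zip(names, sigma)}
    if any(boundary.values()):
        logger.info("components pinned at boundary: %s",
                    [k for k, v in boundary.items() if v])
    return VarianceComponents(
        components=dict(zip(names, map(float, sigma))),
        se=dict(zip(names, map(float, se))),
        cov=ai_inv,
        loglik=float(ll),
        n_iter=it,
        converged=converged,
        boundary=boundary,
    )


def reml_loglik(spec: MixedModelSpec, sigma: dict) -> float:
    """Restricted log-likelihood at a given parameter point (for
    profiling / grid checks)."""
    Ks, names = spec.kernels()
    Ks = Ks + [np.eye(len(spec.y))]
    names = names + ["residual"]
    V = sum(sigma[nm] * K for nm, K in zip(names, Ks))
    _, _, _, ll = _reml_pieces(spec.y, spec.X, V)
    return ll


@dataclass
class HeritabilityEstimates:
    h2_add: float
    h2_dom: float
    h2_total: float
    se_add: float
    se_dom: float
    se_total: float
    sigma2_y: float


def heritabilities(vc: VarianceComponents) -> HeritabilityEstimates:
    """Heritability ratios h2_j = s2_j / s2_y with delta-method SEs from
    the variance-component sampling covariance."""
    names = vc.order()
    s = np.array([vc.components[nm] for nm in names])
    tot = s.sum()
    if tot <= 0:
        raise ValueError("total variance must be positive")

    def ratio_se(idx_set):
        num = s[list(idx_set)].sum()
        h = num / tot
        grad = np.array([
            (1.0 - h) / tot if i in idx_set else -h / tot
            for i in range(len(s))
        ])
        return h, float(np.sqrt(max(grad @ vc.cov @ grad, 0.0)))

    i_add = names.index("additive") if "additive" in names else None
    i_dom = names.index("dominance") if "dominance" in names else None
    h_a, se_a = ratio_se({i_add}) if i_add is not None else (0.0, 0.0)
    h_d, se_d = ratio_se({i_dom}) if i_dom is not None else (0.0, 0.0)
    gen = {i for i in (i_add, i_dom) if i is not None}
    h_t, se_t = ratio_se(gen) if gen else (0.0, 0.0)
    return HeritabilityEstimates(h2_add=h_a, h2_dom=h_d, h2_total=h_t,
                                 se_add=se_a, se_dom=se_d, se_total=se_t,
                                 sigma2_y=float(tot))


@dataclass
class GblupResult:
    ind_index: np.ndarray  # GRM row per prediction
    a_hat: np.ndarray
    d_hat: np.ndarray
    g_hat: np.ndarray
    rel_add: np.ndarray
    rel_dom: np.ndarray
    rel_total: np.ndarray
    beta: np.ndarray
    x_names: list
    train_mask: np.ndarray  # over observations
    Py_train: np.ndarray  # V^-1 (y - X beta) on training records

    def to_frame(self, ids=None) -> pd.DataFrame:
        df = pd.DataFrame({
            "a_hat": self.a_hat, "d_hat": self.d_hat, "g_hat": self.g_hat,
            "rel_a": self.rel_add, "rel_d": self.rel_dom, "rel_t": self.rel_total,
        })
        if ids is not None:
            df.insert(0, "iid", np.asarray(ids)[self.ind_index])
        return df


def gblup(spec: MixedModelSpec, vc: VarianceComponents,
          mask: np.ndarray | None = None) -> GblupResult:
    """BLUP of additive and dominance values for every individual in the
    GRMs, with phenotypes of ``mask``-ed observations omitted.

    Predictions use the covariance route a_hat = s2_a A[:,t] Vt^-1
    (y_t - X_t b_hat); reliabilities come from the prediction-error
    variance rel = 1 - PEV_ii / (K_ii s2), computed against A (additive),
    D (dominance) and s2_a A + s2_d D (total).
    """
    n_obs = len(spec.y)
    train = np.ones(n_obs, dtype=bool)
    if mask is not None:
        mask = np.asarray(mask)
        if mask.dtype == bool:
            train = ~mask
        else:
            train[mask] = False
    if train.sum() < spec.X.shape[1] + 1:
        raise ValueError("not enough training records")

    t_idx = np.flatnonzero(train)
    y_t = spec.y[t_idx]
    X_t = spec.X[t_idx]
    keep_cols = _full_rank_columns(X_t)
    beta_full = np.zeros(spec.X.shape[1])
    if len(keep_cols) < X_t.shape[1]:
        X_t = X_t[:, keep_cols]
    Ks_t, names = spec.kernels(ind_subset=t_idx)
    s2 = vc.components
    V_t = sum(s2[nm] * K for nm, K in zip(names, Ks_t))
    V_t = V_t + s2["residual"] * np.eye(len(t_idx))
    try:
        P, Py, beta, _ = _reml_pieces(y_t, X_t, V_t)
    except linalg.LinAlgError:
        warnings.warn("singular coefficient matrix; applying 1e-8 ridge to V")
        V_t = V_t + np.eye(len(t_idx)) * (1e-8 * float(np.trace(V_t)) / len(t_idx))
        P, Py, beta, _ = _reml_pieces(y_t, X_t, V_t)
    beta_full[keep_cols] = beta
    beta = beta_full

    ind_all = np.arange(spec.A.shape[0])
    ind_t = spec.obs_to_ind[t_idx]

    A_cross = spec.A[np.ix_(ind_all, ind_t)]
    s2a = s2.get("additive", 0.0)
    a_hat = s2a * (A_cross @ Py)
    # PEV diag: s2 K_ii - s2^2 diag(K[:,t] P K[t,:])
    quadA = np.einsum("ij,jk,ik->i", A_cross, P, A_cross)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_a = np.where(np.diag(spec.A) > 0,
                         s2a * quadA / np.maximum(np.diag(spec.A), 1e-30), 0.0)
    rel_a = np.clip(rel_a, 0.0, 1.0)

    if spec.include_dominance:
        D_cross = spec.D[np.ix_(ind_all, ind_t)]
        s2d = s2.get("dominance", 0.0)
        d_hat = s2d * (D_cross @ Py)
        quadD = np.einsum("ij,jk,ik->i", D_cross, P, D_cross)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_d = np.where(np.diag(spec.D) > 0,
                             s2d * quadD / np.maximum(np.diag(spec.D), 1e-30), 0.0)
        rel_d = np.clip(rel_d, 0.0, 1.0)
        K_tot_diag = s2a * np.diag(spec.A) + s2d * np.diag(spec.D)
        K_cross = s2a * A_cross + s2d * D_cross
        quadT = np.einsum("ij,jk,ik->i", K_cross, P, K_cross)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_t = np.where(K_tot_diag > 0, quadT / np.maximum(K_tot_diag, 1e-30), 0.0)
        rel_t = np.clip(rel_t, 0.0, 1.0)
    else:
        d_hat = np.zeros_like(a_hat)
        rel_d = np.zeros_like(rel_a)
        rel_t = rel_a
    g_hat = a_hat + d_hat

    return GblupResult(
        ind_index=ind_all, a_hat=a_hat, d_hat=d_hat, g_hat=g_hat,
        rel_add=rel_a, rel_dom=rel_d, rel_total=rel_t,
        beta=beta, x_names=list(spec.x_names), train_mask=train, Py_train=Py,
    )


@dataclass
class SnpEffectEstimates:
    snp_ids: np.ndarray
    alpha_hat: np.ndarray
    delta_hat: np.ndarray
    h2_add: np.ndarray  # per-SNP narrow-sense heritability
    h2_dom: np.ndarray
    m: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp": self.snp_ids, "alpha_hat": self.alpha_hat,
            "delta_hat": self.delta_hat, "h2_k_add": self.h2_add,
            "h2_k_dom": self.h2_dom,
        })


def backsolve_snp_effects(grm_pair, vc: VarianceComponents, result: GblupResult,
                          snp_ids=None) -> SnpEffectEstimates:
    """Back-solve per-SNP additive/dominance effects from the GBLUP
    solutions: alpha = s2_a W_a' V^-1 (y - Xb) / sum 2pq, which satisfies
    W_a alpha = a_hat exactly. Per-SNP heritability is the sample
    variance of the SNP's fitted genetic values over s2_y.
    """
    if grm_pair.W_a is None:
        raise ValueError("GRMPair must keep marker loadings (keep_loadings=True)")
    t = np.flatnonzero(result.train_mask)
    Wa_t = grm_pair.W_a[t]
    Wd_t = grm_pair.W_d[t]
    s2 = vc.components
    alpha = s2.get("additive", 0.0) * (Wa_t.T @ result.Py_train) / grm_pair.sum_2pq
    if "dominance" in s2:
        delta = s2["dominance"] * (Wd_t.T @ result.Py_train) / grm_pair.sum_2pq_sq
    else:
        delta = np.zeros_like(alpha)
    s2y = vc.sigma2_y

    def per_snp_h2(effects, W, total_var):
        # raw per-SNP variances Var_i(W[:,k] e_k) understate the component
        # (BLUP shrinkage, LD cross-terms), so they are used as weights
        # normalized to decompose the REML component estimate exactly:
        # sum_k h2_k = sigma2_component / sigma2_y
        w = (effects ** 2) * W.var(axis=0)
        tot = w.sum()
        if tot <= 0:
            return np.zeros_like(w)
        return (total_var / s2y) * w / tot

    h2a = per_snp_h2(alpha, grm_pair.W_a, s2.get("additive", 0.0))
    h2d = per_snp_h2(delta, grm_pair.W_d, s2.get("dominance", 0.0))
    if snp_ids is None:
        snp_ids = np.array([f"snp{k}" for k in range(len(alpha))])
    return SnpEffectEstimates(snp_ids=np.asarray(snp_ids), alpha_hat=alpha,
                              delta_hat=delta, h2_add=h2a, h2_dom=h2d,
                              m=len(alpha))


class GBLUPRegressor:
    """Sklearn-style genomic prediction estimator.

    fit(X, y, batch=..., fixed_snps=...) builds additive (and optionally
    dominance) GRMs from the genotype-code matrix X, estimates variance
    components by AI-REML, computes GBLUP values and back-solved SNP
    effects. predict(X_new) maps new genotype rows through the
    back-solved SNP effects using the training-sample allele
    frequencies.

    Fitted attributes: varcomp_, heritability_, gblup_, snp_effects_,
    allele_freq_.
    """

    def __init__(self, include_dominance: bool = True, max_iter: int = 200,
                 tol: float = 1e-8, genotypic_fixed: bool = False):
        self.include_dominance = include_dominance
        self.max_iter = max_iter
        self.tol = tol
        self.genotypic_fixed = genotypic_fixed

    def get_params(self, deep: bool = True) -> dict:
        return {"include_dominance": self.include_dominance,
                "max_iter": self.max_iter, "tol": self.tol,
                "genotypic_fixed": self.genotypic_fixed}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, batch=None, fixed_snp_index=None, mask=None):
        from .relationship import build_grms

        X = np.asarray(X)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.shape[0] != len(y):
            raise ValueError("X rows must match y length")
        self.n_features_in_ = X.shape[1]
        self.allele_freq_ = X.mean(axis=0) / 2.0
        pair = build_grms(X, keep_loadings=True)
        fixed = X[:, fixed_snp_index].astype(np.float64) if fixed_snp_index is not None else None
        Xd, names = design_matrix(batch=batch, n=len(y), snp_codes=fixed,
                                  genotypic=self.genotypic_fixed)
        spec = MixedModelSpec(y=y, X=Xd, A=pair.A, D=pair.D,
                              include_dominance=self.include_dominance,
                              x_names=names)
        self.varcomp_ = fit_greml(spec, max_iter=self.max_iter, tol=self.tol)
        self.heritability_ = heritabilities(self.varcomp_)
        self.gblup_ = gblup(spec, self.varcomp_, mask=mask)
        self.snp_effects_ = backsolve_snp_effects(pair, self.varcomp_, self.gblup_)
        self.grm_pair_ = pair
        self.spec_ = spec
        return self

    def predict(self, X):
        if not hasattr(self, "snp_effects_"):
            raise RuntimeError("GBLUPRegressor is not fitted")
        X = np.asarray(X, dtype=np.float64)
        Wa = X - 2.0 * self.allele_freq_
        g = Wa @ self.snp_effects_.alpha_hat
        if self.include_dominance:
            p = self.allele_freq_
            q = 1.0 - p
            Wd = np.where(X <= 1.0,
                          -2.0 * p * p + X * (2.0 * p * q + 2.0 * p * p),
                          2.0 * p * q + (X - 1.0) * (-2.0 * q * q - 2.0 * p * q))
            g = g + Wd @ self.snp_effects_.delta_hat
        return g

    def score(self, X, y):
        """Pearson correlation between predicted genetic values and y."""
        yhat = self.predict(X)
        return float(np.corrcoef(yhat, np.asarray(y, dtype=float))[0, 1])
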