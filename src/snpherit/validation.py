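"""Tenfold cross-validation and the three prediction-accuracy measures.

For genetic-effect type j in {additive (a), dominance (d), total (t)}:

- observed phenotypic accuracy  R_hat_0jp = corr(g_hat_0j, y_0),
- expected genetic accuracy     R_0j = mean sqrt(reliability) over the
  validation individuals,
- expected phenotypic accuracy  R_0jp = R_0j * sqrt(h2_j),

pooled as the mean across folds with the SD across folds as the
printed +/-. Variance components are re-estimated within each training
fold to avoid information leakage.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .greml import MixedModelSpec, fit_greml, gblup, heritabilities

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    folds: list  # list of index arrays, disjoint, covering range(n)
    seed: int | None = None

    @property
    def k(self) -> int:
        return len(self.folds)

    def sizes(self) -> list:
        return [len(f) for f in self.folds]

    def to_frame(self, ids=None) -> pd.DataFrame:
        rows = []
        for f, idx in enumerate(self.folds):
            for i in idx:
                rows.append((ids[i] if ids is not None else i, f))
        return pd.DataFrame(rows, columns=["iid", "fold"])


def make_folds(n: int, k: int = 10, sizes=None, seed: int | None = None) -> FoldPlan:
    """Random disjoint partition of range(n) into k folds. Default sizes
    are floor(n/k) with the remainder added to the last fold (e.g.
    n=2936, k=10 gives nine folds of 293 and a tenth of 299)."""
    if k > n:
        raise ValueError("k cannot exceed n")
    if sizes is None:
        base = n // k
        sizes = [base] * (k - 1) + [n - base * (k - 1)]
    if sum(sizes) != n:
        raise ValueError("fold sizes must sum to n")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds, pos = [], 0
    for s in sizes:
        folds.append(np.sort(perm[pos: pos + s]))
        pos += s
    return FoldPlan(folds=folds, seed=seed)


def observed_phenotypic_accuracy(predictions, phenotypes) -> float:
    """Pearson correlation between predicted genetic values and raw
    phenotypes of validation individuals."""
    g = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(phenotypes, dtype=np.float64)
    if len(g) != len(y) or len(g) < 3:
        raise ValueError("need at least 3 paired values")
    if g.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(np.corrcoef(g, y)[0, 1])


def expected_phenotypic_accuracy(R_0j: float, h2_j: float) -> float:
    """R_0jp = R_0j * sqrt(h2_j): the expected accuracy of predicting
    phenotypes from the expected genetic accuracy and the heritability."""
    if not (0 <= R_0j <= 1 and 0 <= h2_j <= 1):
        raise ValueError("inputs must lie in [0, 1]")
    return R_0j * np.sqrt(h2_j)


@dataclass
class AccuracyReport:
    per_fold: pd.DataFrame
    # columns: fold, j, observed (R_hat_0jp), expected_genetic (R_0j),
    #          expected_phenotypic (R_0jp), h2_j, n_validation
    pooled: pd.DataFrame
    # columns: j, observed, observed_sd, expected_genetic,
    #          expected_genetic_sd, expected_phenotypic, expected_phenotypic_sd

    def value(self, j: str = "t", measure: str = "observed") -> float:
        row = self.pooled.set_index("j").loc[j]
        return float(row[measure])


def _fold_accuracies(res, herit, y, val_idx, truth_g=None):
    rows = []
    comps = [("a", res.a_hat, res.rel_add, herit.h2_add)]
    if res.rel_dom.any() or herit.h2_dom > 0:
        comps.append(("d", res.d_hat, res.rel_dom, herit.h2_dom))
    comps.append(("t", res.g_hat, res.rel_total, herit.h2_total))
    for j, ghat, rel, h2 in comps:
        g0 = ghat[val_idx]
        try:
            obs = observed_phenotypic_accuracy(g0, y[val_idx])
        except ValueError:
            obs = np.nan
        r0j = float(np.sqrt(np.clip(rel[val_idx], 0, 1)).mean())
        rows.append({
            "j": j, "observed": obs, "expected_genetic": r0j,
            "expected_phenotypic": expected_phenotypic_accuracy(r0j, h2),
            "h2_j": h2, "n_validation": len(val_idx),
        })
        if truth_g is not None and j == "t":
            rows[-1]["observed_vs_truth"] = observed_phenotypic_accuracy(
                g0, truth_g[val_idx])
    return rows


def cross_validate(spec: MixedModelSpec, plan: FoldPlan,
                   truth_g=None, max_iter: int = 200) -> AccuracyReport:
    """Refit GREML per training fold, run GBLUP with the fold's
    phenotypes masked, and collect the three accuracy measures."""
    y = spec.y
    records = []
    for f, val_idx in enumerate(plan.folds):
        if len(val_idx) < 2:
            warnings.warn(f"fold {f} has fewer than 2 individuals; skipped")
            continue
        mask = np.zeros(len(y), dtype=bool)
        mask[val_idx] = True
        train_spec = MixedModelSpec(
            y=y[~mask], X=spec.X[~mask], A=spec.A, D=spec.D,
            include_dominance=spec.include_dominance,
            obs_to_ind=spec.obs_to_ind[~mask], x_names=spec.x_names,
        )
        vc = fit_greml(train_spec, max_iter=max_iter)
        herit = heritabilities(vc)
        res = gblup(spec, vc, mask=mask)
        for row in _fold_accuracies(res, herit, y, val_idx, truth_g):
            row["fold"] = f
            records.append(row)
    per_fold = pd.DataFrame(records)
    pooled_rows = []
    for j, grp in per_fold.groupby("j"):
        pooled_rows.append({
            "j": j,
            "observed": grp["observed"].mean(),
            "observed_sd": grp["observed"].std(ddof=1),
            "expected_genetic": grp["expected_genetic"].mean(),
            "expected_genetic_sd": grp["expected_genetic"].std(ddof=1),
            "expected_phenotypic": grp["expected_phenotypic"].mean(),
            "expected_phenotypic_sd": grp["expected_phenotypic"].std(ddof=1),
        })
        if "observed_vs_truth" in grp:
            pooled_rows[-1]["observed_vs_truth"] = grp["observed_vs_truth"].mean()
    pooled = pd.DataFrame(pooled_rows)
    return AccuracyReport(per_fold=per_fold, pooled=pooled)
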