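"""Contribution of a SNP set to genomic heritability and prediction accuracy.

Three approaches:

- Method I  (``method1_sum``): sum of the per-SNP heritabilities of the
  set under the full model. The sum scales as ~1/m with the panel size,
  so it is reported with that caveat and no accuracy value.
- Method II (``method2_removal``): rebuild the GRMs without the target
  SNPs, refit, optionally re-run cross-validation; the drop is a lower
  bound because SNPs in LD with the removed set absorb their signal.
- Method III (``method3_fixed``, "partial heritability"/"partial
  accuracy"): keep all SNPs in the GRMs but fit the target SNPs as
  fixed-effect covariates; the drop is an upper bound because the fixed
  SNPs also absorb the signal of correlated markers.

Relative contributions: c_h2 = 1 - h2_reduced/h2_full and
c_r = 1 - R_reduced/R_full (positive when the reduced model is lower;
the conventional table prints decreases with a minus sign).
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .greml import (MixedModelSpec, design_matrix, fit_greml, gblup,
                    heritabilities)
from .relationship import build_grms
from .validation import FoldPlan, cross_validate

logger = logging.getLogger(__name__)


@dataclass
class SnpSet:
    """Named set of SNP ids with a provenance note."""

    name: str
    snp_ids: list
    note: str = ""

    def __post_init__(self):
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids in set")

    @classmethod
    def from_region(cls, G: GenotypeMatrix, region: str, note: str = "") -> "SnpSet":
        """Resolve a 'chr:start-end' string (1-based, inclusive) against
        SNP positions."""
        m = re.fullmatch(r"(\w+):([\d_.]+)-([\d_.]+)", region.strip())
        if not m:
            raise ValueError(f"bad region string {region!r}; expected chr:start-end")
        chrom, start, end = m.group(1), float(m.group(2)), float(m.group(3))
        meta = G.snp_meta
        sel = (meta["chrom"].astype(str) == chrom) & \
              (meta["pos"] >= start) & (meta["pos"] <= end)
        return cls(name=region, snp_ids=meta.loc[sel, "id"].tolist(),
                   note=note or f"region {region}")


@dataclass
class AnalysisData:
    """One trait analysis bundle: genotypes, phenotype, batch labels."""

    G: GenotypeMatrix
    y: np.ndarray
    batch: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        if self.G.n_individuals != len(self.y):
            raise ValueError("genotypes and phenotypes disagree on n")
        if self.batch is not None:
            self.batch = np.asarray(self.batch)


@dataclass
class ContributionReport:
    method: str  # I_sum | II_removal | III_fixed
    set_name: str
    full_h2: dict  # component -> full-model heritability
    reduced_h2: dict
    c_h2: dict  # component -> 1 - reduced/full
    full_accuracy: dict = field(default_factory=dict)  # measure -> value
    reduced_accuracy: dict = field(default_factory=dict)
    c_r: dict = field(default_factory=dict)
    notes: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp in self.full_h2:
            rows.append({
                "quantity": f"h2_{comp}", "full": self.full_h2[comp],
                "reduced": self.reduced_h2.get(comp),
                "c_percent": 100.0 * self.c_h2[comp] if comp in self.c_h2 else None,
            })
        for meas in self.full_accuracy:
            rows.append({
                "quantity": meas, "full": self.full_accuracy[meas],
                "reduced": self.reduced_accuracy.get(meas),
                "c_percent": 100.0 * self.c_r[meas] if meas in self.c_r else None,
            })
        return pd.DataFrame(rows)


def contribution_stats(full_value: float, reduced_value: float) -> float:
    """c = 1 - reduced/full (fraction; multiply by 100 for the percent
    the tables print, decreases conventionally shown negative)."""
    if full_value == 0:
        raise ValueError("full-model value is zero; contribution undefined")
    return 1.0 - reduced_value / full_value


def _fit_full(data: AnalysisData, include_dominance: bool = True,
              fixed_snp_ids=None, genotypic: bool = False,
              G: GenotypeMatrix | None = None):
    """Fit GREML on (optionally substituted) genotypes; returns
    (spec, vc, herit, grm_pair)."""
    Gm = data.G if G is None else G
    pair = build_grms(Gm, keep_loadings=True)
    fixed = None
    if fixed_snp_ids is not None:
        idx = Gm.snp_index(fixed_snp_ids)
        fixed = Gm.codes[:, idx].astype(np.float64)
    X, names = design_matrix(batch=data.batch, n=len(data.y),
                             snp_codes=fixed, genotypic=genotypic)
    spec = MixedModelSpec(y=data.y, X=X, A=pair.A, D=pair.D,
                          include_dominance=include_dominance, x_names=names)
    vc = fit_greml(spec)
    return spec, vc, heritabilities(vc), pair


def _herit_dict(h) -> dict:
    return {"additive": h.h2_add, "dominance": h.h2_dom, "total": h.h2_total}


def _accuracy_dict(report) -> dict:
    out = {}
    for _, row in report.pooled.iterrows():
        out[f"observed_{row['j']}"] = row["observed"]
        out[f"expected_phenotypic_{row['j']}"] = row["expected_phenotypic"]
        out[f"expected_genetic_{row['j']}"] = row["expected_genetic"]
    return out


def _c_dict(full: dict, reduced: dict) -> dict:
    return {k: contribution_stats(full[k], reduced[k])
            for k in full if k in reduced and full[k] != 0}


def method1_sum(per_snp, snp_set: SnpSet) -> dict:
    """Method I: sum the per-SNP heritabilities of the set (computed
    under the full model). Output carries the m-dependency caveat and no
    accuracy value."""
    ids = pd.Index(per_snp.snp_ids)
    idx = ids.get_indexer(snp_set.snp_ids)
    if (idx < 0).any():
        missing = [s for s, i in zip(snp_set.snp_ids, idx) if i < 0]
        raise KeyError(f"unknown SNP ids: {missing}")
    return {
        "set": snp_set.name,
        "h2_add_sum": float(per_snp.h2_add[idx].sum()),
        "h2_dom_sum": float(per_snp.h2_dom[idx].sum()),
        "m": per_snp.m,
        "note": "per-SNP heritabilities scale ~1/m with panel size",
    }


def method2_removal(data: AnalysisData, snp_set: SnpSet,
                    include_dominance: bool = True,
                    plan: FoldPlan | None = None,
                    min_remaining: int = 10) -> ContributionReport:
    """Method II: drop the target SNPs from the GRMs and refit (and
    re-validate when a fold plan is given)."""
    idx = data.G.snp_index(snp_set.snp_ids)
    keep = np.ones(data.G.n_snps, dtype=bool)
    keep[idx] = False
    if keep.sum() < min_remaining:
        raise ValueError(f"removal leaves {int(keep.sum())} SNPs (<{min_remaining})")
    G_red = data.G.subset_snps(keep)

    spec_f, vc_f, h_f, _ = _fit_full(data, include_dominance)
    spec_r, vc_r, h_r, _ = _fit_full(data, include_dominance, G=G_red)
    full_h2, red_h2 = _herit_dict(h_f), _herit_dict(h_r)
    report = ContributionReport(
        method="II_removal", set_name=snp_set.name,
        full_h2=full_h2, reduced_h2=red_h2, c_h2=_c_dict(full_h2, red_h2),
        notes="lower bound: SNPs in LD with the removed set absorb its signal",
    )
    if plan is not None:
        acc_f = _accuracy_dict(cross_validate(spec_f, plan))
        acc_r = _accuracy_dict(cross_validate(spec_r, plan))
        report.full_accuracy, report.reduced_accuracy = acc_f, acc_r
        report.c_r = _c_dict(acc_f, acc_r)
    return report


def method3_fixed(data: AnalysisData, snp_set: SnpSet,
                  include_dominance: bool = True,
                  plan: FoldPlan | None = None,
                  genotypic: bool = False) -> ContributionReport:
    """Method III ("partial heritability"/"partial accuracy"): keep all
    SNPs in the GRMs, add the set as fixed-effect covariates, refit.

    In cross-validation the fixed SNP effects are estimated within each
    training fold and reach validation individuals through their
    genotypes (the design matrix covers everyone)."""
    if len(snp_set.snp_ids) >= data.G.n_snps:
        raise ValueError("cannot fit every SNP as a fixed effect (rank)")
    data.G.snp_index(snp_set.snp_ids)  # validates ids

    spec_f, vc_f, h_f, _ = _fit_full(data, include_dominance)
    spec_r, vc_r, h_r, _ = _fit_full(data, include_dominance,
                                     fixed_snp_ids=snp_set.snp_ids,
                                     genotypic=genotypic)
    full_h2, red_h2 = _herit_dict(h_f), _herit_dict(h_r)
    report = ContributionReport(
        method="III_fixed", set_name=snp_set.name,
        full_h2=full_h2, reduced_h2=red_h2, c_h2=_c_dict(full_h2, red_h2),
        notes="upper bound: fixed SNPs also absorb signal of markers in LD",
    )
    if plan is not None:
        acc_f = _accuracy_dict(cross_validate(spec_f, plan))
        acc_r = _accuracy_dict(cross_validate(spec_r, plan))
        report.full_accuracy, report.reduced_accuracy = acc_f, acc_r
        report.c_r = _c_dict(acc_f, acc_r)
    return report


def partial_heritability_stability(data: AnalysisData, snp_set: SnpSet,
                                   panel_fractions=(0.5, 1.0),
                                   include_dominance: bool = True,
                                   seed: int = 0) -> pd.DataFrame:
    """Method III partial heritability recomputed on subsampled panels
    (the target set always retained); the spread across fractions
    measures how insensitive partial heritability is to panel size."""
    rng = np.random.default_rng(seed)
    set_idx = set(data.G.snp_index(snp_set.snp_ids).tolist())
    rows = []
    for frac in panel_fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        n_keep = int(round(frac * data.G.n_snps))
        others = np.array(sorted(set(range(data.G.n_snps)) - set_idx))
        n_extra = max(n_keep - len(set_idx), 0)
        extra = rng.choice(others, size=min(n_extra, len(others)), replace=False)
        keep = np.sort(np.concatenate([np.fromiter(set_idx, dtype=int), extra]))
        sub = AnalysisData(G=data.G.subset_snps(keep), y=data.y, batch=data.batch)
        rep = method3_fixed(sub, snp_set, include_dominance=include_dominance)
        rows.append({
            "fraction": frac, "n_snps": len(keep),
            "c_h2_additive": rep.c_h2.get("additive"),
            "c_h2_total": rep.c_h2.get("total"),
            "full_h2_additive": rep.full_h2["additive"],
            "reduced_h2_additive": rep.reduced_h2["additive"],
        })
    table = pd.DataFrame(rows)
    table.attrs["max_spread_c_h2_additive"] = float(
        table["c_h2_additive"].max() - table["c_h2_additive"].min())
    return table
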