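"""End-to-end orchestration: QC -> GRM/MDS -> GREML -> GWAS -> CV -> contributions.

A run is driven by one ``RunConfig`` (YAML-loadable) that supplies either
input file paths or a simulator configuration, and writes every stage's
tabular output plus a JSON manifest with checksums under the output
directory.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .contribution import AnalysisData, SnpSet, method2_removal, method3_fixed
from .greml import (MixedModelSpec, backsolve_snp_effects, design_matrix,
                    fit_greml, gblup, heritabilities)
from .gwas import (ScanConfig, bonferroni_threshold, gls_family_scan,
                   ls_mds_scan, significant_snps)
from .qc import filter_snps
from .relationship import build_grms, ibs_matrix, mds_components
from .simulate import SimConfig, simulate_dataset
from .validation import cross_validate, make_folds

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genotypes: str | None = None  # PLINK prefix or VCF path
    genotype_format: str = "plink_bed"
    phenotypes: str | None = None  # TSV iid sire litter batch y
    simulate: dict | None = None  # SimConfig fields
    maf_min: float = 0.05
    hom_min: float = 0.01
    hwe_min: float = 1e-6
    n_mds: int = 35
    methods: list = field(default_factory=lambda: ["gls", "ls-add", "ls-geno"])
    folds: int = 10
    include_dominance: bool = True
    snp_sets: dict = field(default_factory=dict)  # name -> list of ids or "chr:a-b"
    seed: int = 0
    out: str = "snpherit_out"
    family_grouping: str = "litter"

    def validate(self):
        has_files = self.genotypes is not None or self.phenotypes is not None
        if has_files == (self.simulate is not None):
            raise ValueError("supply exactly one of input paths or a "
                             "simulate: block")
        if has_files and (self.genotypes is None or self.phenotypes is None):
            raise ValueError("both genotypes and phenotypes paths are required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependence order; returns the manifest dict
    (also written to <out>/manifest.json)."""
    config.validate()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "stages": {}, "files": {}}
    t_all = time.time()

    def stage(name):
        manifest["stages"][name] = {"status": "running", "t0": time.time()}

        def done(**info):
            st = manifest["stages"][name]
            st.update(status="ok", wall_s=round(time.time() - st.pop("t0"), 3), **info)
        return done

    def emit(path: Path):
        manifest["files"][str(path.relative_to(out))] = _sha256(path)

    # ---- load or simulate -------------------------------------------------
    done = stage("input")
    if config.simulate is not None:
        sim = SimConfig(**{**config.simulate, "seed": config.seed})
        G, structure, pheno, truth = simulate_dataset(sim)
        truth_path = out / "truth.tsv"
        truth.to_frame(G.ind_ids).to_csv(truth_path, sep="\t", index=False)
        emit(truth_path)
        sio.write_plink(G, out / "genotypes")
        sio.write_phenotypes(pheno, out / "phenotypes.tsv")
        for suffix in (".bed", ".bim", ".fam"):
            emit((out / "genotypes").with_suffix(suffix))
        emit(out / "phenotypes.tsv")
    else:
        G = sio.read_genotypes(config.genotypes, config.genotype_format)
        pheno = sio.read_phenotypes(config.phenotypes)
        order = pd.Index(G.ind_ids).get_indexer(pheno["iid"])
        if (order < 0).any():
            raise ValueError("phenotype iids missing from genotypes")
        G = G.subset_individuals(order)
    y = pheno["y"].to_numpy(dtype=float)
    batch = pheno["batch"].to_numpy()
    families = pheno[config.family_grouping].to_numpy() \
        if config.family_grouping in pheno else pheno["litter"].to_numpy()
    done(n_individuals=G.n_individuals, n_snps=G.n_snps)

    # ---- QC ---------------------------------------------------------------
    done = stage("qc")
    G, report = filter_snps(G, config.maf_min, config.hom_min, config.hwe_min)
    qc_path = out / "qc_report.tsv"
    report.to_frame().to_csv(qc_path, sep="\t", index=False)
    emit(qc_path)
    done(n_pass=report.n_pass, n_input=report.n_input)

    # ---- relationships ----------------------------------------------------
    done = stage("grm")
    pair = build_grms(G, keep_loadings=True)
    sio.write_grm_gcta(pair.A, G.ind_ids, pair.n_snps, out / "additive")
    sio.write_grm_gcta(pair.D, G.ind_ids, pair.n_snps, out / "dominance")
    S = ibs_matrix(G)
    mds = mds_components(S, min(config.n_mds, G.n_individuals - 1))
    mds_path = out / "mds.tsv"
    pd.DataFrame(mds.coords, index=G.ind_ids).to_csv(mds_path, sep="\t",
                                                     header=False)
    emit(mds_path)
    done(n_mds=mds.coords.shape[1])

    # ---- GREML ------------------------------------------------------------
    done = stage("greml")
    X, names = design_matrix(batch=batch, n=len(y))
    spec = MixedModelSpec(y=y, X=X, A=pair.A, D=pair.D,
                          include_dominance=config.include_dominance,
                          x_names=names)
    vc = fit_greml(spec)
    herit = heritabilities(vc)
    greml_out = {
        "components": vc.components, "se": vc.se, "loglik": vc.loglik,
        "n_iter": vc.n_iter,
        "h2": {"additive": herit.h2_add, "dominance": herit.h2_dom,
               "total": herit.h2_total},
        "h2_se": {"additive": herit.se_add, "dominance": herit.se_dom,
                  "total": herit.se_total},
    }
    greml_path = out / "greml.json"
    greml_path.write_text(json.dumps(greml_out, indent=2))
    emit(greml_path)
    res = gblup(spec, vc)
    gblup_path = out / "gblup.tsv"
    res.to_frame(G.ind_ids).to_csv(gblup_path, sep="\t", index=False)
    emit(gblup_path)
    eff = backsolve_snp_effects(pair, vc, res, snp_ids=G.snp_ids)
    eff_path = out / "snp_effects.tsv"
    eff.to_frame().to_csv(eff_path, sep="\t", index=False)
    emit(eff_path)
    done(**{"h2_add": herit.h2_add, "h2_dom": herit.h2_dom})

    # ---- GWAS -------------------------------------------------------------
    sig = None
    scans = []
    if config.methods:
        done = stage("gwas")
        method_map = {"gls": "gls_family", "ls-add": "ls_mds_additive",
                      "ls-geno": "ls_mds_genotypic"}
        for meth in config.methods:
            tag = method_map.get(meth, meth)
            cfg = ScanConfig(method=tag, n_mds=min(config.n_mds, mds.coords.shape[1]))
            if tag == "gls_family":
                scan = gls_family_scan(y, X, families, G, cfg)
            else:
                scan = ls_mds_scan(y, X, mds.coords, G, cfg)
            path = out / f"gwas_{tag}.tsv"
            scan.table.to_csv(path, sep="\t", index=False)
            emit(path)
            scans.append(scan)
        thr, neglog = bonferroni_threshold(G.n_snps)
        sig = significant_snps(scans, thr)
        sig_path = out / "significant_snps.tsv"
        sig.flags.to_csv(sig_path, sep="\t", index=False)
        emit(sig_path)
        summary = {"bonferroni_p": thr, "neg_log10_threshold": neglog,
                   "lambda": {s.method: s.inflation for s in scans},
                   "n_significant_union": len(sig.union)}
        (out / "gwas_summary.json").write_text(json.dumps(summary, indent=2))
        emit(out / "gwas_summary.json")
        done(n_significant=len(sig.union))

    # ---- cross-validation -------------------------------------------------
    plan = None
    if config.folds and config.folds >= 2:
        done = stage("cv")
        plan = make_folds(len(y), k=config.folds, seed=config.seed)
        plan_path = out / "folds.tsv"
        plan.to_frame(G.ind_ids).to_csv(plan_path, sep="\t", index=False)
        emit(plan_path)
        acc = cross_validate(spec, plan)
        acc_path = out / "accuracy.tsv"
        acc.pooled.to_csv(acc_path, sep="\t", index=False)
        emit(acc_path)
        done(observed_t=float(acc.pooled.set_index("j")["observed"].get("t", np.nan)))

    # ---- contributions (optional stage) ------------------------------------
    sets = dict(config.snp_sets)
    if not sets and sig is not None and sig.union:
        sets["significant"] = list(sig.union)
    if sets:
        done = stage("contrib")
        data = AnalysisData(G=G, y=y, batch=batch)
        try:
            for name, spec_ids in sets.items():
                if isinstance(spec_ids, str):
                    sset = SnpSet.from_region(G, spec_ids)
                    sset.name = name
                else:
                    sset = SnpSet(name=name, snp_ids=list(spec_ids))
                for fn, tag in ((method2_removal, "II"), (method3_fixed, "III")):
                    rep = fn(data, sset, include_dominance=config.include_dominance,
                             plan=plan)
                    path = out / f"contribution_{name}_method{tag}.tsv"
                    rep.to_frame().to_csv(path, sep="\t", index=False)
                    emit(path)
            done(n_sets=len(sets))
        except Exception as exc:  # optional stage must not abort the run
            manifest["stages"]["contrib"].update(status="failed", error=str(exc))
            logger.exception("contribution stage failed")

    manifest["wall_s"] = round(time.time() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
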