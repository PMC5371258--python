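# snpherit

Genomic heritability, GBLUP prediction accuracy and SNP-set
contribution analysis for family-structured populations.

Breeding programs for livestock routinely estimate how much of a
trait's variation is genetic, predict each animal's genetic merit from
dense SNP panels, and ask which genomic regions drive both. `snpherit`
packages that workflow for quantitative geneticists working with
half-sib/full-sib family designs (the motivating case is a nucleus pig
herd scored for a counted trait such as teat number): SNP quality
control, additive and dominance genomic relationship matrices, GREML /
GBLUP, three single-SNP GWAS variants with stratification control,
tenfold validation, and the "partial heritability / partial accuracy"
framework for quantifying a SNP set's contribution.

## The model

Phenotypes follow the mixed model

    y = X_b b + Z a + Z d + e,   Var(y) = Z A_g Z' σ²_α + Z D_g Z' σ²_δ + I σ²_e

with batch fixed effects b, genomic breeding values a ~ (0, A_g σ²_α)
and dominance deviations d ~ (0, D_g σ²_δ). The relationship matrices
come from centered allele counts: A_g = W_a W_a'/Σ 2p_k q_k and the
matched dominance form. Variance components are estimated by
average-information REML; heritabilities are h²_α = σ²_α/σ²_y,
h²_δ = σ²_δ/σ²_y and h²_t = h²_α + h²_δ with σ²_y the sum of the
components. Prediction accuracy in validation is measured three ways:

  - observed phenotypic accuracy  R̂_0jp = corr(ĝ_0j, y_0)
  - expected genetic accuracy     R_0j = mean √(reliability)
  - expected phenotypic accuracy  R_0jp = R_0j √(h²_j)

and the contribution of a SNP set i is c²_hi = 1 − ĥ²_i/ĥ² (likewise
c_ri = 1 − R_0i/R_0), where the reduced model either drops the set from
the GRMs (Method II, a lower bound) or fits it as fixed-effect
covariates (Method III, "partial heritability", an upper bound).
See `docs/methods.md` for the full account.

## Worked example

No suitable public dataset accompanies the motivating study, so the
package ships a calibrated simulator (`snpherit.simulate`) whose
defaults mirror that design; here a smaller panel keeps the example
quick:

```python
import numpy as np
from snpherit import (SimConfig, simulate_dataset, build_grms, design_matrix,
                      fit_greml, heritabilities, make_folds, cross_validate,
                      method3_fixed, AnalysisData, SnpSet)
from snpherit.greml import MixedModelSpec

cfg = SimConfig(n_sires=30, n_litters=250, litter_size_range=(2, 2),
                n_snps=800, n_chromosomes=5, n_qtl=80, seed=3)
G, structure, pheno, truth = simulate_dataset(cfg)
y = pheno["y"].to_numpy(float)

pair = build_grms(G)
X, _ = design_matrix(batch=pheno["batch"].to_numpy())
spec = MixedModelSpec(y=y, X=X, A=pair.A, D=pair.D)
h = heritabilities(fit_greml(spec))
print(f"h2_additive = {h.h2_add:.3f} +/- {h.se_add:.3f}")
print(f"h2_dominance = {h.h2_dom:.3f} +/- {h.se_dom:.3f}")
print(f"h2_broad = {h.h2_total:.3f} +/- {h.se_total:.3f}")

plan = make_folds(len(y), k=10, seed=3)
report = cross_validate(spec, plan)
print(f"observed accuracy (total) = {report.value('t', 'observed'):.3f}")
print(f"expected phenotypic accuracy = "
      f"{report.value('t', 'expected_phenotypic'):.3f}")

data = AnalysisData(G=G, y=y, batch=pheno["batch"].to_numpy())
top = truth.qtl.reindex(
    truth.qtl.add_effect.abs().sort_values(ascending=False).index)
rep = method3_fixed(data, SnpSet(name="top10-qtl",
                                 snp_ids=list(top.snp_id[:10])))
print(f"partial heritability drop c_h2(additive) = "
      f"{100 * rep.c_h2['additive']:.2f}%")
```

prints

```
h2_additive = 0.362 +/- 0.065
h2_dominance = 0.017 +/- 0.049
h2_broad = 0.379 +/- 0.075
observed accuracy (total) = 0.412
expected phenotypic accuracy = 0.413
partial heritability drop c_h2(additive) = 22.36%
```

The simulator targeted h²_α = 0.365 and h²_δ = 0.035: GREML recovers
the additive component within one standard error at n = 500. The
correlation between GBLUP predictions and the phenotypes of masked
validation animals (0.412) agrees with the model-expected phenotypic
accuracy (0.413) — on well-specified data the two measures coincide.
Fitting the ten largest simulated QTL as fixed effects removes 22% of
the additive heritability: those ten loci (plus whatever their
neighbours tag) carry that share of the genetic variance.

The same workflow runs from the shell against PLINK or VCF inputs, or a
simulation block, via the `snpherit` CLI
(`snpherit all --config run.yaml`, with per-stage subcommands
`simulate`, `qc`, `grm`, `greml`, `gwas`, `cv`, `contrib`).

Estimator-style interfaces (`GBLUPRegressor`, `SNPQCFilter`,
`MDSStratifier`, `FamilyGWAS`, `StratifiedGWAS`) expose the fit-shaped
cores with sklearn conventions (`fit`/`predict`/`transform`,
`get_params`, trailing-underscore attributes) for use in composite
pipelines.

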