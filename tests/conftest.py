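import numpy as np
import pandas as pd
import pytest

from snpherit import SimConfig, simulate_dataset
from snpherit.containers import GenotypeMatrix


def make_genotype_matrix(codes, chrom=None, pos=None):
    """Wrap a raw codes array in a GenotypeMatrix with generic metadata."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    meta = pd.DataFrame({
        "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "id": [f"snp{j}" for j in range(m)],
        "ref": "A",
        "alt": "G",
    })
    return GenotypeMatrix(codes=codes, snp_meta=meta,
                          ind_ids=np.array([f"i{j}" for j in range(n)]))


SMALL_SIM = SimConfig(
    n_sires=25, n_litters=200, litter_size_range=(2, 2), n_snps=600,
    n_chromosomes=5, n_qtl=60, h2_add=0.365, h2_dom=0.035, n_batches=8,
    seed=20,
)


@pytest.fixture(scope="session")
def small_dataset():
    """One family-structured dataset shared by read-only tests:
    500 offspring in 250 full-sib pairs, 600 SNPs with local LD."""
    G, structure, pheno, truth = simulate_dataset(SMALL_SIM)
    return {
        "G": G, "structure": structure, "pheno": pheno, "truth": truth,
        "y": pheno["y"].to_numpy(dtype=float),
        "batch": pheno["batch"].to_numpy(),
        "litter": pheno["litter"].to_numpy(),
    }


@pytest.fixture(scope="session")
def fitted_model(small_dataset):
    """Full additive+dominance GREML fit on the shared dataset."""
    from snpherit import build_grms, design_matrix, fit_greml, heritabilities
    from snpherit.greml import MixedModelSpec

    d = small_dataset
    pair = build_grms(d["G"], keep_loadings=True)
    X, names = design_matrix(batch=d["batch"])
    spec = MixedModelSpec(y=d["y"], X=X, A=pair.A, D=pair.D,
                          include_dominance=True, x_names=names)
    vc = fit_greml(spec)
    return {"pair": pair, "spec": spec, "vc": vc,
            "herit": heritabilities(vc)}
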