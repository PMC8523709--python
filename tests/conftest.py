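import numpy as np
import pandas as pd
import pytest

from funcprs.dataio import GenotypePanel, Phenotype, SummaryStats
from funcprs.simulate import SimConfig, simulate_study


def make_variants(m, chrom="1", spacing=1000, alleles=("A", "G"), maf=None):
    return pd.DataFrame(
        {
            "id": [f"snp{i + 1:04d}" for i in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1, dtype=np.int64) * spacing,
            "a1": alleles[0],
            "a2": alleles[1],
            "maf": np.full(m, 0.3) if maf is None else np.asarray(maf, dtype=float),
        }
    )


def make_panel(dosages, **kw):
    dosages = np.asarray(dosages, dtype=np.float64)
    n, m = dosages.shape
    variants = make_variants(m, **kw)
    variants["maf"] = np.minimum(dosages.mean(axis=0) / 2, 1 - dosages.mean(axis=0) / 2)
    return GenotypePanel(variants, dosages, [f"s{j}" for j in range(n)])


@pytest.fixture(scope="session")
def small_study():
    """One moderately sized synthetic study shared across read-only tests."""
    return simulate_study(SimConfig(n_train=1500, n_val=600, M=400, seed=7))


@pytest.fixture
def toy_panel():
    rng = np.random.default_rng(42)
    dosages = rng.integers(0, 3, size=(30, 8)).astype(float)
    return make_panel(dosages)


@pytest.fixture
def toy_pheno(toy_panel):
    rng = np.random.default_rng(1)
    return Phenotype(list(toy_panel.sample_ids), rng.standard_normal(toy_panel.n_samples))


def make_sumstats(variants, beta, p, n=1000.0, pheno_var=1.0):
    m = len(variants)
    return SummaryStats(
        variants.reset_index(drop=True),
        np.asarray(beta, dtype=float),
        np.asarray(p, dtype=float),
        np.full(m, float(n)),
        pheno_var=pheno_var,
    )
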