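"""Synthetic data generator: LD-structured diploid genotypes, functional
annotations, annotation-dependent causal effects, phenotypes with a target
SNP-heritability, and marginal GWAS summary statistics.

Haplotypes are drawn from a latent-Gaussian model: within an LD block, latent
variables follow an AR(1) process with correlation ``ld_rho`` and each SNP's
allele indicator thresholds the latent value at its MAF quantile; the two
haplotypes of an individual are independent, so genotypes are in
Hardy-Weinberg equilibrium with tunable LD decay along the chromosome. This
emulates the LD structure of a real panel without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataio import AnnotationMatrix, GenotypePanel, Phenotype, SummaryStats
from .funct_prior import PriorSpec
from .ldtools import annotation_ld_scores

import pandas as pd


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror the simulation design the methods were developed under:
    heritability 0.5 split over a 10% causal fraction, moderate block-wise LD.
    """

    n_train: int = 1000
    n_val: int = 500
    M: int = 2000
    p_causal: float = 0.1
    h2g: float = 0.5
    ld_rho: float = 0.6
    block_size_mean: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    annotation_spec: list[tuple[str, float]] = field(
        default_factory=lambda: [("binary", 0.1), ("ldscore", 25.0)]
    )
    seed: int = 0
    spacing_bp: int = 1000  # physical distance between adjacent SNPs

    def __post_init__(self) -> None:
        if not (0.0 < self.p_causal <= 1.0):
            raise ValueError("p_causal must lie in (0, 1]")
        if not (0.0 < self.h2g < 1.0):
            raise ValueError("h2g must lie in (0, 1)")
        if self.maf_range[0] < 0.01:
            raise ValueError("minimum MAF must be >= 0.01")


def _block_starts(m: int, mean_size: int, rng: np.random.Generator) -> np.ndarray:
    """Random LD-block boundaries with geometric block sizes."""
    starts = [0]
    while starts[-1] < m:
        starts.append(starts[-1] + int(rng.geometric(1.0 / mean_size)))
    is_start = np.zeros(m, dtype=bool)
    is_start[[s for s in starts if s < m]] = True
    return is_start


def synth_genotypes(config: SimConfig, n: int | None = None, seed: int | None = None) -> GenotypePanel:
    """Draw a diploid dosage panel of ``n`` samples (default ``n_train``).

    Deterministic given (config, seed); ``seed`` defaults to ``config.seed``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_train if n is None else n
    m = config.M
    mafs = rng.uniform(*config.maf_range, size=m)
    thresholds = stats.norm.ppf(mafs)
    new_block = _block_starts(m, config.block_size_mean, rng)
    new_block[0] = True
    rho = config.ld_rho
    innov_sd = np.sqrt(1.0 - rho**2)
    dosages = np.empty((n, m), dtype=np.float64)
    starts = list(np.flatnonzero(new_block)) + [m]
    from scipy.signal import lfilter

    for a, b in zip(starts[:-1], starts[1:]):
        e = rng.standard_normal((2 * n, b - a), dtype=np.float32)
        if b - a > 1 and rho != 0.0:
            e[:, 1:] *= innov_sd
            z = lfilter([1.0], [1.0, -rho], e, axis=1)
        else:
            z = e
        alleles = (z < thresholds[a:b]).astype(np.float64)
        dosages[:, a:b] = alleles[:n] + alleles[n:]
    freq = dosages.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "id": [f"snp{j + 1:06d}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1, dtype=np.int64) * config.spacing_bp,
            "a1": "A",
            "a2": "G",
            "maf": np.minimum(freq, 1.0 - freq),
        }
    )
    return GenotypePanel(variants, dosages, [f"s{j + 1:06d}" for j in range(n)])


def synth_annotations(
    panel: GenotypePanel,
    annotation_spec: list[tuple[str, float]],
    seed: int = 0,
) -> AnnotationMatrix:
    """Annotation matrix with a base column of ones plus the requested
    columns: ``("binary", q)`` gives Bernoulli(q) indicators, ``("ldscore",
    radius_kb)`` gives the SNP's base LD score within the radius (an
    LD-related continuous annotation)."""
    rng = np.random.default_rng(seed)
    m = panel.n_variants
    cols = [np.ones(m)]
    names = ["base"]
    base_annot = AnnotationMatrix(panel.variants, np.ones((m, 1)), ["base"])
    for k, (kind, param) in enumerate(annotation_spec):
        if kind == "binary":
            cols.append(rng.binomial(1, param, size=m).astype(float))
            names.append(f"binary_{k}")
        elif kind == "ldscore":
            # a few hundred samples estimate r2 well enough for an annotation
            ref = panel
            if panel.n_samples > 500:
                ref = GenotypePanel(
                    panel.variants, panel.dosages[:500], panel.sample_ids[:500]
                )
                base_ref = AnnotationMatrix(ref.variants, np.ones((m, 1)), ["base"])
            else:
                base_ref = base_annot
            l = annotation_ld_scores(ref, base_ref, radius_kb=int(param))[:, 0]
            cols.append(l)
            names.append(f"ldscore_{k}")
        else:
            raise ValueError(f"unknown annotation type {kind!r}")
    return AnnotationMatrix(panel.variants, np.column_stack(cols), names)


def sample_causal_effects(
    prior: PriorSpec,
    panel: GenotypePanel,
    p_causal: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw sparse causal effects under the functional prior.

    A uniform random ``round(p_causal * M)`` SNPs are causal; a causal SNP i
    gets a normalized effect ``beta_i ~ N(0, c * sigma2_i / p_causal)`` so the
    expected summed squared effect equals h2g. Per-allele effects are
    ``b_i = beta_i / sqrt(2 p_i (1 - p_i))`` with panel MAF ``p_i``.
    """
    if not (0.0 < p_causal <= 1.0):
        raise ValueError("p_causal must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    m = len(prior.sigma2)
    n_causal = int(round(p_causal * m))
    if n_causal == 0:
        raise ValueError("p_causal * M rounds to zero causal SNPs")
    causal = rng.choice(m, size=n_causal, replace=False)
    var = prior.prior_variance()[causal] / p_causal
    beta = np.zeros(m)
    beta[causal] = rng.standard_normal(n_causal) * np.sqrt(var)
    maf = panel.variants["maf"].to_numpy(dtype=np.float64)
    het = 2.0 * maf * (1.0 - maf)
    if np.any(het[causal] <= 0):
        raise ValueError("causal SNP with zero heterozygosity")
    b = np.where(het > 0, beta / np.sqrt(np.where(het > 0, het, 1.0)), 0.0)
    return beta, b


def simulate_phenotype(
    panel: GenotypePanel,
    b: np.ndarray,
    h2g: float,
    seed: int = 0,
    exact_h2: bool = False,
) -> Phenotype:
    """Phenotype ``Y_j = sum_i b_i g_ij + eps_j`` with ``eps ~ N(0, 1 - h2g)``.

    With ``exact_h2`` the noise is residualized on the genetic value and
    rescaled so the realized var(G)/var(Y) equals ``h2g`` exactly.
    """
    rng = np.random.default_rng(seed)
    g = panel.dosages @ np.asarray(b, dtype=np.float64)
    eps = rng.standard_normal(panel.n_samples) * np.sqrt(1.0 - h2g)
    if exact_h2:
        var_g = np.var(g)
        if var_g == 0:
            raise ValueError("exact_h2 requires a non-degenerate genetic value")
        gc = g - g.mean()
        eps = eps - eps.mean() - (eps @ gc / (gc @ gc)) * gc  # orthogonal to G
        eps *= np.sqrt(var_g * (1.0 - h2g) / h2g / np.var(eps))
    y = g + eps
    return Phenotype(list(panel.sample_ids), y)


def marginal_gwas(panel: GenotypePanel, pheno: Phenotype) -> SummaryStats:
    """Per-SNP simple linear regression of the phenotype on each standardized
    genotype (normal-approximation p-values), reported on the per-allele
    scale with the training phenotypic variance attached."""
    n = panel.n_samples
    if n < 3:
        raise ValueError("marginal GWAS needs at least 3 samples")
    X = panel.dosages
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("monomorphic variant in GWAS panel")
    y = pheno.values
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    slope_std = (Xc / sd).T @ yc / (n - 1)  # slope on standardized genotype
    tss = yc @ yc
    rss = tss - (n - 1) * slope_std**2
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / (n - 1))
    with np.errstate(divide="ignore"):
        z = np.where(se > 0, slope_std / se, np.inf * np.sign(slope_std))
    pval = 2.0 * stats.norm.sf(np.abs(z))
    return SummaryStats(
        panel.variants.copy(),
        beta_hat=slope_std / sd,
        pvalue=pval,
        n_train=np.full(panel.n_variants, float(n)),
        pheno_var=float(np.var(y, ddof=1)),
    )


def simulate_study(
    config: SimConfig,
) -> dict:
    """Full study draw: disjoint training and validation cohorts, annotations,
    a functional prior on causal variances, effects, phenotypes and training
    summary statistics.

    The generative prior uses the annotation matrix itself: binary columns
    get an enrichment bump, so annotation-informed methods have signal to
    find. Returns a dict with keys train_panel, val_panel, annotations,
    prior, beta, b, pheno_train, pheno_val, sumstats.
    """
    base = np.random.SeedSequence(config.seed)
    s_train, s_val, s_annot, s_eff, s_ptrain, s_pval = [
        int(s.generate_state(1)[0] % (2**31)) for s in base.spawn(6)
    ]
    train = synth_genotypes(config, n=config.n_train, seed=s_train)
    val = synth_genotypes(config, n=config.n_val, seed=s_val)
    annotations = synth_annotations(train, config.annotation_spec, seed=s_annot)
    prior = generative_prior(annotations, config.h2g)
    beta, b = sample_causal_effects(prior, train, config.p_causal, seed=s_eff)
    pheno_train = simulate_phenotype(train, b, config.h2g, seed=s_ptrain)
    # validation effects converted with validation MAF so scoring is consistent
    maf_v = val.variants["maf"].to_numpy(dtype=np.float64)
    maf_v = np.clip(maf_v, 1.0 / (4.0 * config.n_val), 0.5)
    b_val = beta / np.sqrt(2.0 * maf_v * (1.0 - maf_v))
    pheno_val = simulate_phenotype(val, b_val, config.h2g, seed=s_pval)
    sumstats = marginal_gwas(train, pheno_train)
    return {
        "train_panel": train,
        "val_panel": val,
        "annotations": annotations,
        "prior": prior,
        "beta": beta,
        "b": b,
        "pheno_train": pheno_train,
        "pheno_val": pheno_val,
        "sumstats": sumstats,
    }


def generative_prior(annotations: AnnotationMatrix, h2g: float) -> PriorSpec:
    """A ground-truth functional prior: binary annotations are 3x enriched,
    continuous annotations contribute in proportion to their standardized
    value; normalized so masked variances sum to h2g."""
    from .funct_prior import normalize_prior

    A = annotations.values
    m, c = A.shape
    tau = np.zeros(c)
    tau[0] = 1.0
    for j in range(1, c):
        col = A[:, j]
        if set(np.unique(col)) <= {0.0, 1.0}:
            tau[j] = 2.0  # binary: carriers get 3x the base rate
        else:
            sd = col.std()
            if sd > 0:
                # standardized continuous contribution, folded into tau so
                # sigma2 == A @ tau holds exactly; may push some sigma2 < 0
                tau[j] = 0.5 / sd
                tau[0] -= 0.5 * col.mean() / sd
    sigma2 = A @ tau
    return normalize_prior(sigma2, h2g, tau=tau)
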