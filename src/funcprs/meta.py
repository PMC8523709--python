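"""Multi-cohort combination of polygenic scores and posterior mean causal
effect sizes (PMCES)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import GenotypePanel, Phenotype
from .predictors import PosteriorEffects, PRSModel, bin_effects, choose_K, fit_bin_weights_cv, score


@dataclass
class MetaWeights:
    """Per-cohort combination weights gamma_i.

    ``fixed`` mode weights by training sample size (gamma_i = N_i / sum N);
    ``optimized`` fits the weights on validation data by least squares (with
    intercept) and reports adjusted R^2 to account for in-sample fitting.
    """

    gamma: np.ndarray
    mode: str
    intercept: float = 0.0
    adj_r2: float | None = None


def combine_meta(
    prs_list: list[np.ndarray],
    n_list: list[float] | None = None,
    pheno: Phenotype | None = None,
    mode: str = "fixed",
) -> tuple[np.ndarray, MetaWeights]:
    """Combine per-cohort scores for the same validation samples."""
    P = np.column_stack([np.asarray(p, dtype=np.float64) for p in prs_list])
    n, k = P.shape
    if mode == "fixed":
        if n_list is None:
            raise ValueError("fixed-effect combination needs cohort sizes")
        gamma = np.asarray(n_list, dtype=np.float64)
        gamma = gamma / gamma.sum()
        return P @ gamma, MetaWeights(gamma, "fixed")
    if mode != "optimized":
        raise ValueError("mode must be 'fixed' or 'optimized'")
    if pheno is None:
        raise ValueError("validation-optimized combination needs a phenotype")
    y = pheno.values
    X = np.column_stack([np.ones(n), P])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        import logging

        logging.getLogger(__name__).warning(
            "collinear cohort scores; reporting a minimum-norm pseudo-solution"
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    combined = X @ coef
    r = np.corrcoef(y, combined)[0, 1]
    r2 = r * r
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return combined, MetaWeights(coef[1:], "optimized", float(coef[0]), float(adj))


def combine_meta_cv(
    prs_list: list[np.ndarray],
    pheno: Phenotype,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Cross-validated cohort weighting: gamma fit on nine folds, scores
    composed on the held-out fold; returns the held-out combined score and
    the mean held-out R^2 across folds."""
    P = np.column_stack([np.asarray(p, dtype=np.float64) for p in prs_list])
    n = P.shape[0]
    y = pheno.values
    rng = np.random.default_rng(seed)
    folds = rng.permutation(np.arange(n) % min(n_folds, n))
    combined = np.empty(n)
    r2s = []
    for f in np.unique(folds):
        hold = folds == f
        X = np.column_stack([np.ones((~hold).sum()), P[~hold]])
        coef, *_ = np.linalg.lstsq(X, y[~hold], rcond=None)
        pred = coef[0] + P[hold] @ coef[1:]
        combined[hold] = pred
        r = np.corrcoef(y[hold], pred)[0, 1]
        r2s.append(float(r * r))
    return combined, float(np.mean(r2s))


def meta_ldpred_funct(
    post_list: list[PosteriorEffects],
    panel: GenotypePanel,
    pheno: Phenotype,
    h2g: float,
    seed: int = 0,
    n_folds: int = 10,
    K: int | None = None,
) -> tuple[PRSModel, MetaWeights]:
    """Meta-analysis with bin regularization: fit cohort weights gamma_i from
    the cohorts' infinitesimal functional scores, combine PMCES as
    ``sum_i gamma_i PMCES_i``, then bin and cross-validate bin weights."""
    m = panel.n_variants
    for post in post_list:
        if len(post.effects) != m:
            raise ValueError("posterior effects are not aligned to a common variant set")
    if len(post_list) == 1:
        gamma = MetaWeights(np.array([1.0]), "optimized")
        combined_effects = post_list[0].effects
    else:
        prs_list = [score(post.effects, panel) for post in post_list]
        _, gamma = combine_meta(prs_list, pheno=pheno, mode="optimized")
        combined_effects = np.sum(
            [g * post.effects for g, post in zip(gamma.gamma, post_list)], axis=0
        )
    combined = PosteriorEffects(combined_effects, "meta-pmces")
    k = K if K is not None else choose_K(panel.n_samples, h2g)
    bins = bin_effects(combined, k)
    model = fit_bin_weights_cv(bins, combined, panel, pheno, n_folds=n_folds, seed=seed)
    return model, gamma
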