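"""Core prediction operations: posterior mean causal effects under
infinitesimal and functionally informed priors, LASSO-style winner's-curse
shrinkage, effect-size binning, cross-validated bin weights, and scoring.

All effect sizes here live on the normalized (standardized-genotype,
standardized-phenotype) scale; :func:`score` applies them to standardized
validation genotypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .dataio import GenotypePanel, Phenotype, SummaryStats, normalize_genotypes
from .funct_prior import PriorSpec
from .ldtools import LDBlocks, clump

logger = logging.getLogger(__name__)

# parameter grids for clumping + thresholding
DEFAULT_R2_GRID = (0.1, 0.2, 0.5, 0.8)
DEFAULT_PT_GRID = (
    1.0, 0.3, 0.1, 0.03, 0.01, 3e-3, 1e-3, 3e-4, 1e-4, 3e-5, 1e-5, 1e-6, 1e-7, 1e-8,
)


@dataclass
class PosteriorEffects:
    """Posterior mean causal effects, one per analysis SNP (zeros where the
    prior removed the SNP)."""

    effects: np.ndarray
    method: str
    window_provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=np.float64)
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("posterior mean effects must be finite")


@dataclass
class BinPartition:
    """Greedy partition of SNPs into K bins of roughly equal squared mass.

    ``assignment[i]`` is the 1-based bin of SNP i; bins are defined on
    descending squared posterior effects, so bin 1 holds the largest effects.
    """

    assignment: np.ndarray
    K: int
    S: float
    empty_bins: list[int] = field(default_factory=list)


@dataclass
class PRSModel:
    """Cross-validated bin-weight model and the per-sample scores it yields."""

    bin_prs: np.ndarray  # n x K per-bin scores
    alpha: np.ndarray  # final bin weights (refit on all validation samples)
    intercept: float
    folds: np.ndarray  # fold index per validation sample
    r2_cv: float  # mean held-out R^2 across folds
    alpha_folds: np.ndarray | None = None  # (n_folds, K)
    cv_predictions: np.ndarray | None = None  # held-out predictions, per sample
    scores: np.ndarray | None = None  # final-model predictions

    @property
    def K(self) -> int:
        return self.bin_prs.shape[1]


# ---------------------------------------------------------------------------
# posterior means


def posterior_mean_inf(
    beta_tilde: np.ndarray,
    ld: LDBlocks,
    n_train: float,
    h2g: float,
    m_total: int | None = None,
) -> PosteriorEffects:
    """Infinitesimal-prior posterior means: per LD window solve
    ``(N D + I / sigma2) E = N beta_tilde`` with ``sigma2 = h2g / M``.

    The residual-heritability factor multiplying N is approximated as 1,
    appropriate when each window holds a small share of total heritability.
    """
    beta_tilde = np.asarray(beta_tilde, dtype=np.float64)
    m = m_total if m_total is not None else len(beta_tilde)
    sigma2 = h2g / m
    if sigma2 <= 0:
        raise ValueError("h2g / M must be positive")
    if ld.n_variants != len(beta_tilde):
        raise ValueError("LD blocks do not cover the effect vector")
    prior = np.full(len(beta_tilde), sigma2)
    effects = _solve_windows(beta_tilde, ld, n_train, prior, "ldpred-inf")
    return PosteriorEffects(effects, "ldpred-inf", ld.window_of())


def posterior_mean_funct_inf(
    beta_tilde: np.ndarray,
    ld: LDBlocks,
    n_train: float,
    prior: PriorSpec,
) -> PosteriorEffects:
    """Functionally informed posterior means (heterogeneous prior variances).

    ``beta_tilde`` has one entry per analysis SNP; SNPs outside the prior's
    positive mask get effect 0 and take no part in the solve. ``ld`` must be
    estimated on the masked subset (``ld.n_variants == prior.m_pos``).
    """
    beta_tilde = np.asarray(beta_tilde, dtype=np.float64)
    if len(beta_tilde) != len(prior.sigma2):
        raise ValueError("beta_tilde is not aligned to the prior")
    mask = prior.mask_pos
    if ld.n_variants != int(mask.sum()):
        raise ValueError("LD blocks must cover exactly the positive-prior SNPs")
    prior_var = prior.c_norm * prior.sigma2[mask]
    sub = _solve_windows(beta_tilde[mask], ld, n_train, prior_var, "ldpred-funct-inf")
    effects = np.zeros(len(beta_tilde))
    effects[mask] = sub
    prov = np.full(len(beta_tilde), -1, dtype=np.int64)
    prov[mask] = ld.window_of()
    return PosteriorEffects(effects, "ldpred-funct-inf", prov)


def _solve_windows(
    beta_tilde: np.ndarray,
    ld: LDBlocks,
    n_train: float,
    prior_var: np.ndarray,
    label: str,
) -> np.ndarray:
    out = np.empty_like(beta_tilde)
    for w, ((a, b), D) in enumerate(zip(ld.windows, ld.matrices)):
        A = n_train * D + np.diag(1.0 / prior_var[a:b])
        try:
            sol = linalg.solve(A, n_train * beta_tilde[a:b], assume_a="pos")
        except linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ValueError(f"{label}: linear solve failed in window {w}") from exc
        if not np.all(np.isfinite(sol)):
            raise ValueError(f"{label}: non-finite posterior means in window {w}")
        out[a:b] = sol
    return out


# ---------------------------------------------------------------------------
# shrinkage and scoring


def lasso_shrink(
    beta_tilde: np.ndarray,
    pvalue: np.ndarray,
    p_threshold: float,
    sd_ref: float,
    soft: bool = False,
) -> np.ndarray:
    """Winner's-curse correction: shrink marginal effects by
    ``lambda(P_T) = Phi^{-1}(1 - P_T/2) * sd_ref`` and zero out SNPs at or
    above the significance threshold.

    By default the shrunk magnitude is ``| |beta| - lambda |`` (the printed
    form); with ``soft`` it is ``max(|beta| - lambda, 0)`` (soft
    thresholding), which differs for sub-threshold magnitudes.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError("p_threshold must lie in (0, 1]")
    if sd_ref < 0:
        raise ValueError("sd_ref must be non-negative")
    lam = stats.norm.isf(p_threshold / 2.0) * sd_ref
    mag = np.abs(beta_tilde) - lam
    mag = np.maximum(mag, 0.0) if soft else np.abs(mag)
    return np.sign(beta_tilde) * mag * (pvalue < p_threshold)


def score(effects: np.ndarray, panel: GenotypePanel) -> np.ndarray:
    """Per-sample PRS: standardized genotypes dotted with normalized effects."""
    effects = np.asarray(effects, dtype=np.float64)
    if len(effects) != panel.n_variants:
        raise ValueError("effects are not aligned to the panel")
    X = normalize_genotypes(panel)
    return X @ effects


# ---------------------------------------------------------------------------
# clumping + thresholding predictors


@dataclass
class GridFit:
    """Best clump+threshold grid point and the model it selects."""

    effects: np.ndarray
    scores: np.ndarray
    r2: float
    r2_ld: float
    p_threshold: float


def prs_pt(
    sumstats: SummaryStats,
    panel: GenotypePanel,
    pheno: Phenotype,
    r2_grid: tuple[float, ...] = DEFAULT_R2_GRID,
    p_grid: tuple[float, ...] = DEFAULT_PT_GRID,
    kb_window: int = 250,
) -> GridFit:
    """Clumping + thresholding with the (R2_LD, P_T) grid tuned on validation
    R^2. Scores use normalized marginal effects on standardized genotypes."""
    if not r2_grid or not p_grid:
        raise ValueError("parameter grids must be non-empty")
    y = pheno.values
    best: GridFit | None = None
    for r2_ld in r2_grid:
        kept = clump(sumstats, panel, r2_ld, kb_window).kept
        kept_mask = np.zeros(panel.n_variants, dtype=bool)
        kept_mask[kept] = True
        for p_t in p_grid:
            sel = kept_mask & (sumstats.pvalue < p_t)
            if not sel.any():
                continue
            effects = np.where(sel, sumstats.beta_tilde, 0.0)
            s = score(effects, panel)
            if np.var(s) == 0:
                continue
            r2 = _r2(y, s)
            if best is None or r2 > best.r2:
                best = GridFit(effects, s, r2, r2_ld, p_t)
    if best is None:
        raise ValueError("every grid point produced an empty model")
    return best


def prs_pt_funct_lasso(
    sumstats: SummaryStats,
    panel: GenotypePanel,
    pheno: Phenotype,
    prior: PriorSpec,
    hp_fraction: float = 0.10,
    weighted: bool = False,
    soft: bool = False,
    r2_grid: tuple[float, ...] = DEFAULT_R2_GRID,
    p_grid: tuple[float, ...] = DEFAULT_PT_GRID,
    kb_window: int = 250,
) -> GridFit:
    """Clumping + thresholding with LASSO shrinkage, run separately on a
    high-prior SNP set (top ``hp_fraction`` of raw per-SNP prior heritability)
    and its complement, each with its own tuned grid.

    The two component scores are summed, or combined with least-squares
    weights when ``weighted``.
    """
    if not (0.0 < hp_fraction < 1.0):
        raise ValueError("hp_fraction must lie in (0, 1)")
    m = sumstats.n_variants
    n_hp = max(1, int(round(hp_fraction * m)))
    # rank on raw sigma2 (pre-masking); ties broken by position order
    order = np.argsort(-prior.sigma2, kind="stable")
    hp_mask = np.zeros(m, dtype=bool)
    hp_mask[order[:n_hp]] = True
    sd_ref = float(np.std(sumstats.beta_tilde, ddof=1))
    y = pheno.values

    parts: list[GridFit | None] = []
    for set_mask in (hp_mask, ~hp_mask):
        idx = np.where(set_mask)[0]
        if idx.size == 0:
            parts.append(None)
            continue
        ss_sub, panel_sub = sumstats.subset(idx), panel.subset(idx)
        best: GridFit | None = None
        for r2_ld in r2_grid:
            kept = clump(ss_sub, panel_sub, r2_ld, kb_window).kept
            kept_mask = np.zeros(len(idx), dtype=bool)
            kept_mask[kept] = True
            for p_t in p_grid:
                shrunk = lasso_shrink(ss_sub.beta_tilde, ss_sub.pvalue, p_t, sd_ref, soft=soft)
                shrunk = np.where(kept_mask, shrunk, 0.0)
                if not np.any(shrunk):
                    continue
                full = np.zeros(m)
                full[idx] = shrunk
                s = score(full, panel)
                if np.var(s) == 0:
                    continue
                r2 = _r2(y, s)
                if best is None or r2 > best.r2:
                    best = GridFit(full, s, r2, r2_ld, p_t)
        if best is None:
            logger.warning("one P+T-funct-LASSO component is empty; contributes 0")
        parts.append(best)

    live = [p for p in parts if p is not None]
    if not live:
        raise ValueError("both HP and LP components are empty")
    if weighted and len(live) == 2:
        X = np.column_stack([np.ones(len(y)), live[0].scores, live[1].scores])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        effects = coef[1] * live[0].effects + coef[2] * live[1].effects
        scores = coef[0] + coef[1] * live[0].scores + coef[2] * live[1].scores
    else:
        effects = np.sum([p.effects for p in live], axis=0)
        scores = np.sum([p.scores for p in live], axis=0)
    return GridFit(effects, scores, _r2(y, scores), live[0].r2_ld, live[0].p_threshold)


# ---------------------------------------------------------------------------
# binning and cross-validated regularization


def choose_K(n_val: int, h2g: float) -> int:
    """Bin count rule ``K = min(100, ceil(0.9 N h2g / 100))``, at least 1.

    Keeps the per-fold estimation sample at least 100 times larger than K; for
    small validation sets K = 1 and the method reduces to its uniform-weight
    (infinitesimal) parent.
    """
    if n_val < 1:
        raise ValueError("n_val must be >= 1")
    if not (0.0 < h2g <= 1.0):
        raise ValueError("h2g must lie in (0, 1]")
    return max(1, min(100, math.ceil(0.9 * n_val * h2g / 100.0)))


def bin_effects(post: PosteriorEffects, K: int) -> BinPartition:
    """Partition SNPs into K bins of roughly equal summed squared posterior
    effect: rank by descending squared effect, then bin k is the smallest
    prefix extension whose cumulative squared mass reaches k S / K."""
    if K < 1:
        raise ValueError("K must be >= 1")
    e2 = post.effects**2
    S = float(e2.sum())
    if S == 0:
        raise ValueError("all posterior effects are zero; nothing to bin")
    order = np.argsort(-e2, kind="stable")
    cum = np.cumsum(e2[order])
    targets = S * np.arange(1, K + 1) / K
    # first index reaching each target; tiny tolerance absorbs roundoff
    bounds = np.searchsorted(cum, targets - 1e-12 * S, side="left") + 1
    bounds[-1] = len(e2)  # last bin takes every remaining SNP
    assignment = np.empty(len(e2), dtype=np.int64)
    prev = 0
    empty: list[int] = []
    for k, b in enumerate(bounds, start=1):
        if b <= prev:
            empty.append(k)
        assignment[order[prev:b]] = k
        prev = max(prev, b)
    if empty:
        logger.warning("bins %s are empty", empty)
    return BinPartition(assignment, K, S, empty)


def fit_bin_weights_cv(
    bins: BinPartition,
    post: PosteriorEffects,
    panel: GenotypePanel,
    pheno: Phenotype,
    n_folds: int = 10,
    seed: int = 0,
) -> PRSModel:
    """Estimate per-bin weights alpha_k by 10-fold cross-validation on the
    validation cohort.

    Each fold's weights are least squares of the phenotype on the K per-bin
    scores (with intercept) over the other folds; held-out R^2 is averaged
    across folds. The deployable weights are refit on all validation samples.
    Bins whose score column is constant (empty bins) get alpha = 0.
    """
    n = panel.n_samples
    if len(pheno.values) != n:
        raise ValueError("phenotype is not aligned to the panel")
    n_folds = min(n_folds, n)
    X = normalize_genotypes(panel)
    K = bins.K
    bin_prs = np.empty((n, K))
    for k in range(1, K + 1):
        e = np.where(bins.assignment == k, post.effects, 0.0)
        bin_prs[:, k - 1] = X @ e
    live = bin_prs.std(axis=0) > 0

    rng = np.random.default_rng(seed)
    folds = rng.permutation(np.arange(n) % n_folds)
    y = pheno.values
    alpha_folds = np.zeros((n_folds, K))
    cv_pred = np.empty(n)
    r2s = []
    for f in range(n_folds):
        hold = folds == f
        a, b0 = _ols_alpha(bin_prs[~hold][:, live], y[~hold])
        alpha = np.zeros(K)
        alpha[live] = a
        alpha_folds[f] = alpha
        pred = b0 + bin_prs[hold] @ alpha
        cv_pred[hold] = pred
        if np.var(pred) > 0 and np.var(y[hold]) > 0:
            r2s.append(_r2(y[hold], pred))
        else:
            r2s.append(0.0)
    a, b0 = _ols_alpha(bin_prs[:, live], y)
    alpha = np.zeros(K)
    alpha[live] = a
    scores = b0 + bin_prs @ alpha
    return PRSModel(
        bin_prs=bin_prs,
        alpha=alpha,
        intercept=float(b0),
        folds=folds,
        r2_cv=float(np.mean(r2s)),
        alpha_folds=alpha_folds,
        cv_predictions=cv_pred,
        scores=scores,
    )


def _ols_alpha(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef[1:], float(coef[0])


def _r2(y: np.ndarray, s: np.ndarray) -> float:
    r = np.corrcoef(y, s)[0, 1]
    return float(r * r)
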