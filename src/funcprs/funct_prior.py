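"""Functionally informed priors on causal effect-size variance.

Annotation coefficients tau_c are estimated by regressing GWAS chi-square
statistics on per-annotation LD scores (the stratified LD-score regression
model E[chi2_i] = N * sum_c tau_c l(i,c) + 1). Per-SNP prior variances
sigma2_i = sum_c a_c(i) tau_c may come out negative for some SNPs; those are
removed and the remainder rescaled so the prior variances sum to the
SNP-heritability h2_g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import AnnotationMatrix


class CollinearityError(ValueError):
    """The LD-score design matrix is rank deficient."""


class DegeneratePriorError(ValueError):
    """No SNP has a positive prior variance."""


@dataclass
class PriorSpec:
    """Normalized per-SNP prior on causal effect variances.

    The effective prior variance of SNP i is ``c_norm * sigma2[i]`` on the
    positive mask, chosen so the masked prior variances sum to ``h2g``.
    """

    tau: np.ndarray
    sigma2: np.ndarray
    c_norm: float
    mask_pos: np.ndarray
    h2g: float

    @property
    def m_pos(self) -> int:
        return int(self.mask_pos.sum())

    def prior_variance(self) -> np.ndarray:
        """c_norm * sigma2 on the positive mask, 0 elsewhere."""
        out = np.where(self.mask_pos, self.c_norm * self.sigma2, 0.0)
        return out


def flat_prior(m: int, h2g: float) -> PriorSpec:
    """Infinitesimal prior sigma2_i = h2g / M for all SNPs."""
    sigma2 = np.full(m, h2g / m)
    return PriorSpec(
        tau=np.array([h2g / m]),
        sigma2=sigma2,
        c_norm=1.0,
        mask_pos=np.ones(m, dtype=bool),
        h2g=h2g,
    )


def estimate_tau(
    chisq: np.ndarray,
    ld_scores: np.ndarray,
    n_train: float,
    weighted: bool = False,
) -> np.ndarray:
    """Least-squares fit of (chi2_i - 1) on N * l(i, c), no intercept.

    With ``weighted``, rows are downweighted by 1/max(l_base, 1) as a crude
    heteroskedasticity correction (l_base = first LD-score column).
    """
    chisq = np.asarray(chisq, dtype=np.float64)
    L = np.atleast_2d(np.asarray(ld_scores, dtype=np.float64))
    if np.any(chisq < 0):
        raise ValueError("chi-square statistics must be non-negative")
    if n_train <= 0:
        raise ValueError("sample size must be positive")
    X = n_train * L
    y = chisq - 1.0
    if weighted:
        w = 1.0 / np.sqrt(np.maximum(L[:, 0], 1.0))
        X = X * w[:, None]
        y = y * w
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns: those whose removal restores full rank
        bad = [
            c
            for c in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, c, axis=1)) == rank
        ]
        raise CollinearityError(f"LD-score columns are collinear (columns {bad})")
    tau, *_ = np.linalg.lstsq(X, y, rcond=None)
    return tau


def per_snp_variance(annotations: AnnotationMatrix, tau: np.ndarray) -> np.ndarray:
    """sigma2_i = sum_c a_c(i) tau_c (may be negative)."""
    tau = np.asarray(tau, dtype=np.float64)
    if annotations.values.shape[1] != tau.shape[0]:
        raise ValueError("tau length != annotation column count")
    return annotations.values @ tau


def normalize_prior(sigma2: np.ndarray, h2g: float, tau: np.ndarray | None = None) -> PriorSpec:
    """Mask non-positive variances and rescale so the rest sum to ``h2g``."""
    sigma2 = np.asarray(sigma2, dtype=np.float64)
    if not (0.0 < h2g <= 1.0):
        raise ValueError("h2g must lie in (0, 1]")
    mask = sigma2 > 0
    total = sigma2[mask].sum()
    if not mask.any() or total <= 0:
        raise DegeneratePriorError("all per-SNP prior variances are non-positive")
    c_norm = h2g / total
    return PriorSpec(
        tau=np.asarray(tau) if tau is not None else np.array([]),
        sigma2=sigma2,
        c_norm=float(c_norm),
        mask_pos=mask,
        h2g=float(h2g),
    )


def fit_prior(
    chisq: np.ndarray,
    ld_scores: np.ndarray,
    annotations: AnnotationMatrix,
    n_train: float,
    h2g: float,
    weighted: bool = False,
) -> PriorSpec:
    """Convenience composition: estimate tau, map to sigma2, normalize."""
    tau = estimate_tau(chisq, ld_scores, n_train, weighted=weighted)
    sigma2 = per_snp_variance(annotations, tau)
    return normalize_prior(sigma2, h2g, tau=tau)


def h2g_fallback(sigma2: np.ndarray) -> float:
    """Crude SNP-heritability fallback: sum of positive fitted variances.

    Offered only when no external heritability estimate is supplied; callers
    should prefer a mixed-model or LD-score estimate.
    """
    return float(np.maximum(sigma2, 0.0).sum())
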