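"""Prediction accuracy and calibration metrics with genomic block-jackknife
standard errors."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd


@dataclass
class JackknifeEstimate:
    """Delete-one-block jackknife of a genome-wide statistic.

    ``se`` uses the standard jackknife variance
    ``(B - 1)/B * sum_b (theta_b - theta_bar)^2`` over the B delete-one
    statistics; this accounts for variation across a finite number of SNPs,
    which per-sample standard errors ignore.
    """

    estimate: float
    se: float
    n_blocks: int
    leave_one_out: np.ndarray


def prediction_r2(y: np.ndarray, prs: np.ndarray) -> float:
    """Squared Pearson correlation between phenotype and score."""
    y = np.asarray(y, dtype=np.float64)
    prs = np.asarray(prs, dtype=np.float64)
    if len(y) != len(prs) or len(y) < 3:
        raise ValueError("need equal-length vectors with at least 3 samples")
    if np.var(y) == 0 or np.var(prs) == 0:
        raise ValueError("prediction R^2 undefined for a constant input")
    r = np.corrcoef(y, prs)[0, 1]
    return float(r * r)


def calibration_slope(y: np.ndarray, prs: np.ndarray) -> float:
    """Slope of the regression of true phenotype on predicted score;
    1 indicates a calibrated predictor."""
    y = np.asarray(y, dtype=np.float64)
    prs = np.asarray(prs, dtype=np.float64)
    v = np.var(prs)
    if v == 0:
        raise ValueError("calibration slope undefined for a constant score")
    return float(np.cov(y, prs)[0, 1] / np.cov(prs)[()])


def jackknife_se(leave_one_out: np.ndarray) -> float:
    theta = np.asarray(leave_one_out, dtype=np.float64)
    b = len(theta)
    return float(np.sqrt((b - 1) / b * np.sum((theta - theta.mean()) ** 2)))


def make_blocks(n_variants: int, n_blocks: int = 200) -> list[np.ndarray]:
    """Contiguous variant-index blocks of near-equal size (the variant order
    is assumed sorted by chrom, pos; chromosome boundaries may fall inside a
    block)."""
    if n_blocks > n_variants:
        raise ValueError("more blocks than variants")
    return [np.asarray(b) for b in np.array_split(np.arange(n_variants), n_blocks)]


def block_jackknife(
    stat_fn: Callable[[np.ndarray], float],
    n_variants: int,
    n_blocks: int = 200,
) -> JackknifeEstimate:
    """Block-jackknife a statistic over genomic SNP blocks.

    ``stat_fn`` receives a boolean keep-mask over the variant order and must
    recompute the statistic using only the kept SNPs; any tuning parameters
    should already be frozen at their genome-wide values. The full-data
    estimate uses the all-true mask.
    """
    blocks = make_blocks(n_variants, n_blocks)
    full = stat_fn(np.ones(n_variants, dtype=bool))
    loo = np.empty(len(blocks))
    for b, idx in enumerate(blocks):
        mask = np.ones(n_variants, dtype=bool)
        mask[idx] = False
        try:
            loo[b] = stat_fn(mask)
        except Exception as exc:
            raise RuntimeError(f"statistic failed on delete-block {b}") from exc
    return JackknifeEstimate(float(full), jackknife_se(loo), len(blocks), loo)


def paired_difference_jackknife(
    stat_fn_a: Callable[[np.ndarray], float],
    stat_fn_b: Callable[[np.ndarray], float],
    n_variants: int,
    n_blocks: int = 200,
) -> JackknifeEstimate:
    """Jackknife of the difference of two statistics on paired delete-one
    blocks (supports method-difference z-tests)."""
    ja = block_jackknife(stat_fn_a, n_variants, n_blocks)
    jb = block_jackknife(stat_fn_b, n_variants, n_blocks)
    diff = ja.leave_one_out - jb.leave_one_out
    return JackknifeEstimate(
        ja.estimate - jb.estimate, jackknife_se(diff), ja.n_blocks, diff
    )


def metrics_report(rows: list[dict], path=None) -> pd.DataFrame:
    """Assemble (and optionally write) a per-method metrics table."""
    df = pd.DataFrame(rows, columns=["method", "r2", "slope", "se", "n_blocks"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
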