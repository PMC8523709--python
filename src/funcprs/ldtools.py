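"""Linkage-disequilibrium machinery: window partitions, per-window correlation
matrices, greedy clumping, per-annotation LD scores and long-range-LD masks."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import AnnotationMatrix, FormatError, GenotypePanel, SummaryStats, normalize_genotypes


@dataclass
class LDBlocks:
    """Non-overlapping variant windows with their sample correlation matrices.

    ``windows`` holds (start, stop) index ranges into the retained variant
    order; each ``matrices[w]`` is the symmetric unit-diagonal correlation
    matrix of the standardized genotypes inside window ``w``.
    """

    windows: list[tuple[int, int]]
    matrices: list[np.ndarray]

    @property
    def n_variants(self) -> int:
        return self.windows[-1][1] if self.windows else 0

    def window_of(self) -> np.ndarray:
        """Window index for every variant (provenance)."""
        out = np.empty(self.n_variants, dtype=np.int64)
        for w, (a, b) in enumerate(self.windows):
            out[a:b] = w
        return out


@dataclass
class ClumpResult:
    kept: np.ndarray  # variant indices, in processing order
    removed_by: dict[int, int]  # removed index -> kept index that removed it


def window_size_inf(m: int) -> int:
    """Default window size for the infinitesimal solver: round(M / 3000), >= 1."""
    return max(1, round(m / 3000))


def window_size_funct(m_pos: int) -> int:
    """Window size for the functional-prior solver: round(0.15% of M+), >= 1."""
    return max(1, round(0.0015 * m_pos))


def window_partition(
    chroms: np.ndarray | list[str], window_snps: int
) -> list[tuple[int, int]]:
    """Split variants (ordered, chromosome-contiguous) into consecutive windows
    of ``window_snps`` SNPs; the last window on each chromosome holds the
    remainder. Windows never span chromosomes."""
    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    chroms = np.asarray(chroms)
    windows: list[tuple[int, int]] = []
    start = 0
    m = len(chroms)
    while start < m:
        chrom_end = start
        while chrom_end < m and chroms[chrom_end] == chroms[start]:
            chrom_end += 1
        for a in range(start, chrom_end, window_snps):
            windows.append((a, min(a + window_snps, chrom_end)))
        start = chrom_end
    return windows


def estimate_ld(panel: GenotypePanel, windows: list[tuple[int, int]]) -> LDBlocks:
    """Per-window sample correlation matrices of standardized genotypes."""
    if panel.n_samples < 2:
        raise ValueError("LD estimation needs at least 2 samples")
    X = normalize_genotypes(panel)
    n = X.shape[0]
    mats = []
    for a, b in windows:
        W = X[:, a:b]
        D = (W.T @ W) / (n - 1)
        np.fill_diagonal(D, 1.0)
        D = (D + D.T) / 2.0
        mats.append(D)
    return LDBlocks(list(windows), mats)


def clump(
    sumstats: SummaryStats,
    panel: GenotypePanel,
    r2_threshold: float,
    kb_window: int = 250,
) -> ClumpResult:
    """Greedy LD clumping: process SNPs by ascending p-value; each kept SNP
    removes every not-yet-processed SNP within ``kb_window`` kb whose squared
    correlation with it exceeds ``r2_threshold``.

    Ties in p-value are broken by (chrom, pos) so the result is deterministic
    and invariant to input row order.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must lie in (0, 1]")
    if sumstats.n_variants != panel.n_variants:
        raise ValueError("sumstats and panel are not aligned")
    X = normalize_genotypes(panel)
    n = X.shape[0]
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()
    order = np.lexsort((pos, chrom, sumstats.pvalue))
    removed = np.zeros(panel.n_variants, dtype=bool)
    kept: list[int] = []
    removed_by: dict[int, int] = {}
    bp_window = kb_window * 1000
    for i in order:
        if removed[i]:
            continue
        kept.append(int(i))
        near = np.where(
            (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= bp_window)
            & ~removed
        )[0]
        near = near[near != i]
        if near.size:
            r = (X[:, near].T @ X[:, i]) / (n - 1)
            hits = near[r**2 > r2_threshold]
            for j in hits:
                removed[j] = True
                removed_by[int(j)] = int(i)
    return ClumpResult(np.asarray(kept, dtype=np.int64), removed_by)


def annotation_ld_scores(
    ref_panel: GenotypePanel,
    annotations: AnnotationMatrix,
    radius_kb: int = 1000,
) -> np.ndarray:
    """Per-annotation LD scores l(i, c) = sum_j r2(i, j) a_c(j) over SNPs j
    within ``radius_kb`` of SNP i on the same chromosome, including j = i.

    r2 is the plain squared sample correlation from the reference panel.
    """
    if radius_kb <= 0:
        raise ValueError("radius_kb must be positive")
    if annotations.values.shape[0] != ref_panel.n_variants:
        raise ValueError("annotations are not aligned to the panel")
    X = normalize_genotypes(ref_panel)
    n, m = X.shape
    A = annotations.values
    pos = ref_panel.variants["pos"].to_numpy()
    chrom = ref_panel.variants["chrom"].to_numpy()
    bp = radius_kb * 1000
    out = np.zeros((m, A.shape[1]))
    # process in chromosome-contiguous chunks; neighbours found by sorted pos
    start = 0
    while start < m:
        end = start
        while end < m and chrom[end] == chrom[start]:
            end += 1
        cpos = pos[start:end]
        lo = np.searchsorted(cpos, cpos - bp, side="left") + start
        hi = np.searchsorted(cpos, cpos + bp, side="right") + start
        for i in range(start, end):
            j0, j1 = lo[i - start], hi[i - start]
            r = (X[:, j0:j1].T @ X[:, i]) / (n - 1)
            out[i] = (r**2) @ A[j0:j1]
        start = end
    return out


def read_bed_regions(path: str | Path) -> pd.DataFrame:
    """Read a BED interval file (0-based half-open) of exclusion regions."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: BED line needs chrom, start, end")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: non-integer BED coordinates") from exc
        if end < start:
            raise FormatError(f"{path}:{ln}: end < start")
        rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def long_range_ld_mask(variants: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Boolean mask, True where a variant falls inside any exclusion region.

    Regions are half-open [start, end): a variant whose position equals a
    region's start coordinate is masked, one at the end coordinate is not.
    """
    mask = np.zeros(len(variants), dtype=bool)
    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].to_numpy().astype(str)
    for _, reg in regions.iterrows():
        mask |= (chrom == str(reg["chrom"])) & (pos >= reg["start"]) & (pos < reg["end"])
    return mask


def write_window_partition(
    windows: list[tuple[int, int]], chroms: np.ndarray, path: str | Path
) -> None:
    df = pd.DataFrame(
        [(chroms[a], a, b) for a, b in windows], columns=["chrom", "start_idx", "end_idx"]
    )
    df.to_csv(path, sep="\t", index=False)
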