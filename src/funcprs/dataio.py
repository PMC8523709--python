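"""Input/output, harmonization and QC for genotypes, summary statistics,
annotations and phenotypes.

Variant metadata is carried as a pandas DataFrame with columns
``id, chrom, pos, a1, a2, maf`` (``a1`` is the effect allele, positions are
1-based as in PLINK BIM files). Genotype dosages are an ``n x M`` float array
with values in [0, 2] counting copies of ``a1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2", "maf"]

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class FormatError(ValueError):
    """A file does not conform to its expected layout."""


class EmptyInputError(ValueError):
    """An input file or an intersection of inputs is empty."""


class MonomorphicVariantError(ValueError):
    """A variant has zero dosage variance and cannot be standardized."""


@dataclass
class GenotypePanel:
    """Diploid dosage panel: ``n`` samples by ``M`` variants.

    ``dosages[j, i]`` counts copies of ``variants.a1[i]`` carried by sample
    ``j`` and lies in [0, 2]. Variants are sorted by (chrom, pos).
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise FormatError("dosages must be a 2-D samples x variants array")
        if self.dosages.shape[1] != len(self.variants):
            raise FormatError(
                f"dosage columns ({self.dosages.shape[1]}) != variant rows "
                f"({len(self.variants)})"
            )
        if self.dosages.size and (
            np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2
        ):
            raise FormatError("dosage entries must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset(self, index: np.ndarray) -> "GenotypePanel":
        """Panel restricted to the variant positions in ``index`` (kept order)."""
        return GenotypePanel(
            self.variants.iloc[index].reset_index(drop=True),
            self.dosages[:, index],
            self.sample_ids,
        )


@dataclass
class SummaryStats:
    """Marginal GWAS association statistics, one row per variant.

    ``beta_hat`` is the per-allele effect of ``a1`` in phenotype units;
    ``beta_tilde`` is the normalized (correlation-scale, ~Z/sqrt(N)) effect
    filled by :func:`normalized_effects`.
    """

    variants: pd.DataFrame
    beta_hat: np.ndarray
    pvalue: np.ndarray
    n_train: np.ndarray
    beta_tilde: np.ndarray | None = None
    pheno_var: float | None = None
    info: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta_hat = np.asarray(self.beta_hat, dtype=np.float64)
        self.pvalue = np.asarray(self.pvalue, dtype=np.float64)
        self.n_train = np.asarray(self.n_train, dtype=np.float64)
        m = len(self.variants)
        for name in ("beta_hat", "pvalue", "n_train"):
            if len(getattr(self, name)) != m:
                raise FormatError(f"{name} length != variant count")
        if np.any((self.pvalue < 0) | (self.pvalue > 1)):
            raise FormatError("p-values must lie in [0, 1]")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, index: np.ndarray) -> "SummaryStats":
        return SummaryStats(
            self.variants.iloc[index].reset_index(drop=True),
            self.beta_hat[index],
            self.pvalue[index],
            self.n_train[index],
            None if self.beta_tilde is None else self.beta_tilde[index],
            self.pheno_var,
            None if self.info is None else self.info[index],
        )


@dataclass
class Phenotype:
    """Quantitative trait values (binary traits coded 0/1)."""

    sample_ids: list[str]
    values: np.ndarray
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != len(self.sample_ids):
            raise FormatError("phenotype length != sample count")
        if len(self.values) > 1 and np.var(self.values) == 0:
            raise FormatError("phenotype has zero variance")


@dataclass
class AnnotationMatrix:
    """Per-SNP functional annotation values, M x C, first column 'base' = 1."""

    variants: pd.DataFrame
    values: np.ndarray
    names: list[str] = field(default_factory=lambda: ["base"])

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[0] != len(self.variants):
            raise FormatError("annotation rows != variant count")
        if self.values.shape[1] != len(self.names):
            raise FormatError("annotation columns != name count")
        if self.names[0] != "base" or not np.allclose(self.values[:, 0], 1.0):
            raise FormatError("first annotation must be 'base' and identically 1")

    def subset(self, index: np.ndarray) -> "AnnotationMatrix":
        return AnnotationMatrix(
            self.variants.iloc[index].reset_index(drop=True),
            self.values[index],
            list(self.names),
        )


# ---------------------------------------------------------------------------
# readers


DEFAULT_SUMSTATS_DIALECT = {
    "id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "beta": "BETA",
    "p": "P",
    "N": "N",
}


def read_summary_stats(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    pheno_var: float | None = None,
) -> SummaryStats:
    """Read a summary-statistics TSV.

    ``dialect`` maps the canonical keys (id, chrom, pos, a1, a2, beta, p, N,
    optionally maf and info) to the column names used in the file. Rows with
    unparseable numeric fields are dropped with a logged count.
    """
    dialect = {**DEFAULT_SUMSTATS_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[0] == 0:
        raise EmptyInputError(f"summary statistics file {path} has no data rows")
    for key in ("id", "chrom", "pos", "a1", "a2", "beta", "p", "N"):
        col = dialect[key]
        if col not in df.columns:
            raise FormatError(f"summary statistics missing required column {col!r}")
    out = pd.DataFrame(
        {
            "id": df[dialect["id"]].astype(str),
            "chrom": df[dialect["chrom"]].astype(str),
            "pos": pd.to_numeric(df[dialect["pos"]], errors="coerce"),
            "a1": df[dialect["a1"]].str.upper(),
            "a2": df[dialect["a2"]].str.upper(),
            "beta": pd.to_numeric(df[dialect["beta"]], errors="coerce"),
            "p": pd.to_numeric(df[dialect["p"]], errors="coerce"),
            "N": pd.to_numeric(df[dialect["N"]], errors="coerce"),
        }
    )
    for opt in ("maf", "info"):
        col = dialect.get(opt)
        if col is not None and col in df.columns:
            out[opt] = pd.to_numeric(df[col], errors="coerce")
    ok = out[["pos", "beta", "p", "N"]].notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d summary-statistic rows with unparseable numerics", n_dropped)
    out = out[ok].reset_index(drop=True)
    if out.shape[0] == 0:
        raise EmptyInputError(f"no parseable rows in {path}")
    variants = pd.DataFrame(
        {
            "id": out["id"],
            "chrom": out["chrom"],
            "pos": out["pos"].astype(np.int64),
            "a1": out["a1"],
            "a2": out["a2"],
            "maf": out["maf"].to_numpy() if "maf" in out else np.full(len(out), np.nan),
        }
    )
    return SummaryStats(
        variants,
        out["beta"].to_numpy(),
        out["p"].to_numpy(),
        out["N"].to_numpy(),
        pheno_var=pheno_var,
        info=out["info"].to_numpy() if "info" in out else None,
    )


def _maf_from_dosages(dosages: np.ndarray) -> np.ndarray:
    freq = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def read_dosage_tsv(path: str | Path, variant_meta: pd.DataFrame | None = None) -> GenotypePanel:
    """Read the plain-text dosage dialect: header of variant IDs, first column
    sample ID, one row per sample, entries in [0, 2] ('NA' = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise EmptyInputError(f"dosage file {path} is empty")
    dosages = df.to_numpy(dtype=np.float64)
    dosages, keep = _impute_missing(dosages, list(df.columns))
    ids = [df.columns[i] for i in keep]
    if variant_meta is not None:
        variants = variant_meta.set_index("id").loc[ids].reset_index()
    else:
        variants = pd.DataFrame(
            {
                "id": ids,
                "chrom": "0",
                "pos": np.arange(1, len(ids) + 1, dtype=np.int64),
                "a1": "A",
                "a2": "G",
                "maf": np.nan,
            }
        )
    variants = variants.copy()
    variants["maf"] = _maf_from_dosages(dosages)
    panel = GenotypePanel(variants.reset_index(drop=True), dosages, [str(s) for s in df.index])
    return _sort_panel(panel)


def _impute_missing(
    dosages: np.ndarray, ids: list[str]
) -> tuple[np.ndarray, list[int]]:
    """Mean-impute missing calls per variant; drop all-missing variants."""
    keep: list[int] = []
    for i in range(dosages.shape[1]):
        col = dosages[:, i]
        miss = np.isnan(col)
        if miss.all():
            logger.warning("variant %s has no observed genotypes; dropped", ids[i])
            continue
        if miss.any():
            col[miss] = col[~miss].mean()
        keep.append(i)
    return dosages[:, keep], keep


def _sort_panel(panel: GenotypePanel) -> GenotypePanel:
    key = panel.variants.assign(_chrom_num=pd.to_numeric(panel.variants["chrom"], errors="coerce"))
    order = np.lexsort((panel.variants["pos"].to_numpy(), key["_chrom_num"].fillna(1e9).to_numpy(),
                        panel.variants["chrom"].to_numpy()))
    if np.array_equal(order, np.arange(len(order))):
        return panel
    return panel.subset(order)


# PLINK BED: v1.00 magic 0x6c 0x1b, variant-major 0x01; 2 bits per genotype,
# 00=hom a1 (2 copies of BIM allele 1), 01=missing, 10=het, 11=hom a2.
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK BED/BIM/FAM triple given the shared path prefix."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed lacks the PLINK v1.00 variant-major magic bytes")
    n, m = len(fam), len(bim)
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_variant * m:
        raise FormatError(
            f"{prefix}.bed encodes {body.size // max(bytes_per_variant, 1)} variants "
            f"but BIM lists {m}"
        )
    codes = body.reshape(m, bytes_per_variant)
    # unpack 2-bit genotypes, sample index advances within each byte LSB-first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    geno = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    geno = geno.reshape(m, -1)[:, :n]
    dosages = _BED_CODE_TO_DOSAGE[geno].T.copy()  # n x m, counts of BIM a1
    dosages, keep = _impute_missing(dosages, list(bim["id"]))
    bim = bim.iloc[keep].reset_index(drop=True)
    variants = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(np.int64),
            "a1": bim["a1"].str.upper(),
            "a2": bim["a2"].str.upper(),
            "maf": _maf_from_dosages(dosages),
        }
    )
    panel = GenotypePanel(variants, dosages, list(fam["iid"]))
    return _sort_panel(panel)


def read_genotypes(path: str | Path) -> GenotypePanel:
    """Dispatch on extension: PLINK prefix / .bed -> BED triple, else dosage TSV."""
    p = Path(path)
    if p.suffix == ".bed" or p.with_suffix(".bed").exists():
        return read_plink(p.with_suffix("") if p.suffix == ".bed" else p)
    return read_dosage_tsv(p)


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as a PLINK BED/BIM/FAM triple (dosages rounded to calls)."""
    prefix = Path(prefix)
    v = panel.variants
    bim = pd.DataFrame(
        {"chrom": v["chrom"], "id": v["id"], "cm": 0, "pos": v["pos"], "a1": v["a1"], "a2": v["a2"]}
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.sample_ids,
            "iid": panel.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    n = panel.n_samples
    calls = np.rint(panel.dosages).astype(np.int64)  # copies of a1
    code = np.array([3, 2, 0], dtype=np.uint8)[calls]  # dosage 0/1/2 -> BED code
    pad = (-n) % 4
    if pad:
        code = np.vstack([code, np.ones((pad, code.shape[1]), dtype=np.uint8)])
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    grouped = code.T.reshape(panel.n_variants, -1, 4)
    packed = (grouped << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def write_dosage_tsv(panel: GenotypePanel, path: str | Path) -> None:
    df = pd.DataFrame(panel.dosages, index=panel.sample_ids, columns=panel.variants["id"])
    df.to_csv(path, sep="\t", index_label="sample")


def read_phenotype(path: str | Path) -> Phenotype:
    """Read a two-column (sample ID, value) TSV, with or without a header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"phenotype file {path} needs two columns")
    first_val = pd.to_numeric(df.columns[1], errors="coerce")
    if not np.isnan(first_val):  # headerless file: the header row is data
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    ok = values.notna()
    return Phenotype(list(df.iloc[:, 0][ok].astype(str)), values[ok].to_numpy())


def write_phenotype(pheno: Phenotype, path: str | Path) -> None:
    pd.DataFrame({"sample": pheno.sample_ids, "value": pheno.values}).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path: str | Path, variants: pd.DataFrame) -> AnnotationMatrix:
    """Read an annotation TSV (variant ID + C named columns) aligned to ``variants``."""
    df = pd.read_csv(path, sep="\t")
    id_col = df.columns[0]
    df = df.set_index(id_col)
    missing = set(variants["id"]) - set(df.index)
    if missing:
        raise FormatError(f"annotation file lacks {len(missing)} panel variants")
    aligned = df.loc[variants["id"]]
    return AnnotationMatrix(variants, aligned.to_numpy(dtype=np.float64), list(aligned.columns))


def write_annotations(annot: AnnotationMatrix, path: str | Path) -> None:
    df = pd.DataFrame(annot.values, columns=annot.names)
    df.insert(0, "id", annot.variants["id"].to_numpy())
    df.to_csv(path, sep="\t", index=False)


def write_summary_stats(ss: SummaryStats, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "SNP": ss.variants["id"],
            "CHR": ss.variants["chrom"],
            "BP": ss.variants["pos"],
            "A1": ss.variants["a1"],
            "A2": ss.variants["a2"],
            "MAF": ss.variants["maf"],
            "BETA": ss.beta_hat,
            "P": ss.pvalue,
            "N": ss.n_train,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonization and normalization


def harmonize(
    sumstats: SummaryStats,
    panel: GenotypePanel,
    maf_min: float = 0.01,
    info_min: float = 0.9,
    drop_ambiguous: bool = True,
) -> tuple[SummaryStats, GenotypePanel]:
    """Intersect summary statistics with a genotype panel on (chrom, pos).

    Allele orders are reconciled: when the sumstats (a1, a2) match the panel's
    (a2, a1), effect signs are flipped so both refer to the panel's a1. A/T and
    C/G pairs are removed when ``drop_ambiguous`` (strand cannot be resolved),
    variants with panel MAF below ``maf_min`` are removed, and rows with an
    INFO column value below ``info_min`` are removed. Duplicate positions are
    dropped entirely. Outputs share one variant order.
    """
    if sumstats.n_variants == 0 or panel.n_variants == 0:
        raise EmptyInputError("harmonize requires non-empty inputs")
    sv = sumstats.variants.copy()
    pv = panel.variants.copy()
    sv["_row"] = np.arange(len(sv))
    pv["_row"] = np.arange(len(pv))
    for df in (sv, pv):
        df["_key"] = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
        dup = df["_key"].duplicated(keep=False)
        if dup.any():
            logger.warning("dropping %d variants at duplicated positions", int(dup.sum()))
        df.drop(df.index[dup], inplace=True)
    merged = sv.merge(pv, on="_key", suffixes=("_s", "_p"))
    if merged.empty:
        raise EmptyInputError("no variants shared between summary statistics and panel")

    same = (merged["a1_s"] == merged["a1_p"]) & (merged["a2_s"] == merged["a2_p"])
    swapped = (merged["a1_s"] == merged["a2_p"]) & (merged["a2_s"] == merged["a1_p"])
    merged = merged[same | swapped]
    flip = (merged["a1_s"] == merged["a2_p"]).to_numpy()

    if drop_ambiguous:
        amb = [
            (a, b) in _AMBIGUOUS_PAIRS
            for a, b in zip(merged["a1_p"], merged["a2_p"])
        ]
        keep = ~np.asarray(amb)
        merged, flip = merged[keep], flip[keep]

    keep = (merged["maf_p"] >= maf_min).to_numpy()
    merged, flip = merged[keep], flip[keep]

    s_rows = merged["_row_s"].to_numpy()
    if sumstats.info is not None:
        keep = sumstats.info[s_rows] >= info_min
        merged, flip, s_rows = merged[keep], flip[keep], s_rows[keep]
    if merged.empty:
        raise EmptyInputError("no variants survive harmonization filters")

    p_rows = merged["_row_p"].to_numpy()
    out_panel = panel.subset(p_rows)
    out_ss = sumstats.subset(s_rows)
    sign = np.where(flip, -1.0, 1.0)
    out_ss.beta_hat = out_ss.beta_hat * sign
    if out_ss.beta_tilde is not None:
        out_ss.beta_tilde = out_ss.beta_tilde * sign
    # adopt the panel's allele orientation and MAF
    out_ss.variants = out_panel.variants.copy()
    order = np.lexsort(
        (out_panel.variants["pos"].to_numpy(), out_panel.variants["chrom"].to_numpy())
    )
    return out_ss.subset(order), out_panel.subset(order)


def normalize_genotypes(panel: GenotypePanel, dtype=np.float64) -> np.ndarray:
    """Column-standardize dosages to mean 0, sample variance 1 (ddof=1)."""
    X = panel.dosages.astype(dtype, copy=True)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        ids = panel.variants["id"].iloc[bad[:5]].tolist()
        raise MonomorphicVariantError(f"monomorphic variants cannot be standardized: {ids}")
    X -= mean
    X /= sd
    return X


def normalized_effects(sumstats: SummaryStats) -> SummaryStats:
    """Fill ``beta_tilde`` from p-values: sign(beta_hat) * |Z| / sqrt(N).

    When a p-value underflows to exactly zero the quantile is infinite, so the
    per-allele effect is rescaled instead:
    ``beta_hat * sqrt(2 p_i (1 - p_i)) / sqrt(pheno_var)`` with ``p_i`` the
    minor allele frequency.
    """
    p = sumstats.pvalue
    z = stats.norm.isf(p / 2.0)
    beta_tilde = np.sign(sumstats.beta_hat) * z / np.sqrt(sumstats.n_train)
    under = p == 0.0
    if under.any():
        maf = sumstats.variants["maf"].to_numpy(dtype=np.float64)
        if np.any(np.isnan(maf[under])) or sumstats.pheno_var is None:
            raise ValueError(
                "p-value underflow requires variant MAF and training phenotypic "
                "variance for the fallback normalization"
            )
        beta_tilde[under] = (
            sumstats.beta_hat[under]
            * np.sqrt(2.0 * maf[under] * (1.0 - maf[under]))
            / np.sqrt(sumstats.pheno_var)
        )
    out = replace(sumstats)
    out.beta_tilde = beta_tilde
    return out
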