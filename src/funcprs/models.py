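"""Model/Results interface over the prediction methods.

Each model class is built from harmonized data (summary statistics aligned to
a validation genotype panel, plus whatever the method needs: a phenotype, an
SNP-heritability estimate, a functional prior). ``fit()`` runs the method and
returns a :class:`PRSResults` carrying the per-SNP effects, per-sample
scores, accuracy and calibration diagnostics, and a ``summary()`` table.

Typical use::

    sim = simulate.simulate_study(SimConfig(seed=1))
    prior = funct_prior.fit_prior(...)          # or sim["prior"] as the truth
    res = LDpredFunct(sim["sumstats"], sim["val_panel"], prior,
                      sim["pheno_val"]).fit(seed=1)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import predictors
from .dataio import GenotypePanel, Phenotype, SummaryStats, normalized_effects
from .evaluate import calibration_slope, prediction_r2
from .funct_prior import PriorSpec, flat_prior, normalize_prior
from .ldtools import estimate_ld, window_partition, window_size_funct, window_size_inf


@dataclass
class PRSResults:
    """Fitted polygenic score: estimates, diagnostics, provenance."""

    method: str
    effects: np.ndarray  # normalized-scale per-SNP effects, aligned to the panel
    scores: np.ndarray  # per-sample predictions on the validation panel
    params: dict[str, Any] = field(default_factory=dict)
    r2: float | None = None  # validation squared correlation
    r2_cv: float | None = None  # mean held-out R^2 (cross-validated methods)
    slope: float | None = None  # calibration slope on held-out predictions
    alpha: np.ndarray | None = None  # bin weights
    K: int | None = None
    cv_predictions: np.ndarray | None = None
    model: Any = None

    def per_allele_effects(self, panel: GenotypePanel) -> np.ndarray:
        """Convert normalized effects to the per-allele scale via panel MAF."""
        maf = panel.variants["maf"].to_numpy(dtype=np.float64)
        het = 2.0 * maf * (1.0 - maf)
        return np.where(het > 0, self.effects / np.sqrt(np.where(het > 0, het, 1.0)), 0.0)

    def summary(self) -> str:
        lines = [
            f"{'Polygenic score results':^58}",
            "=" * 58,
            f"Method:              {self.method}",
            f"Analysis SNPs:       {len(self.effects)}",
            f"Non-zero effects:    {int(np.count_nonzero(self.effects))}",
            f"Validation samples:  {len(self.scores)}",
        ]
        if self.K is not None:
            lines.append(f"Bins (K):            {self.K}")
        if self.r2 is not None:
            lines.append(f"Validation R2:       {self.r2:.4f}")
        if self.r2_cv is not None:
            lines.append(f"Held-out R2 (CV):    {self.r2_cv:.4f}")
        if self.slope is not None:
            lines.append(f"Calibration slope:   {self.slope:.4f}")
        for key, val in self.params.items():
            lines.append(f"{key + ':':<21}{val}")
        lines.append("=" * 58)
        return "\n".join(lines)


class _BaseModel:
    """Shared construction: align inputs, fill normalized effects."""

    method = "base"

    def __init__(
        self,
        sumstats: SummaryStats,
        panel: GenotypePanel,
        pheno: Phenotype | None = None,
        exclude_mask: np.ndarray | None = None,
    ) -> None:
        if sumstats.n_variants != panel.n_variants:
            raise ValueError(
                "sumstats and panel are not aligned; run dataio.harmonize first"
            )
        if pheno is not None and len(pheno.values) != panel.n_samples:
            raise ValueError("phenotype is not aligned to the panel samples")
        if sumstats.beta_tilde is None:
            sumstats = normalized_effects(sumstats)
        self.sumstats = sumstats
        self.panel = panel
        self.pheno = pheno
        self.exclude_mask = (
            np.zeros(panel.n_variants, dtype=bool) if exclude_mask is None else exclude_mask
        )
        self.n_train = float(np.median(sumstats.n_train))

    def _evaluate(self, scores: np.ndarray) -> float | None:
        if self.pheno is None:
            return None
        return prediction_r2(self.pheno.values, scores)


class PTModel(_BaseModel):
    """Clumping + thresholding, grid-tuned on validation accuracy."""

    method = "pt"

    def __init__(self, sumstats, panel, pheno: Phenotype, **kw) -> None:
        super().__init__(sumstats, panel, pheno, **kw)

    def fit(
        self,
        r2_grid=predictors.DEFAULT_R2_GRID,
        p_grid=predictors.DEFAULT_PT_GRID,
        kb_window: int = 250,
    ) -> PRSResults:
        fitres = predictors.prs_pt(
            self.sumstats, self.panel, self.pheno, r2_grid, p_grid, kb_window
        )
        return PRSResults(
            self.method,
            fitres.effects,
            fitres.scores,
            params={"r2_ld": fitres.r2_ld, "p_threshold": fitres.p_threshold},
            r2=fitres.r2,
            slope=calibration_slope(self.pheno.values, fitres.scores),
            model=self,
        )


class PTFunctLasso(_BaseModel):
    """Clumping + thresholding with winner's-curse LASSO shrinkage and a
    high-prior / low-prior SNP-set split from a functional prior."""

    method = "pt-funct-lasso"

    def __init__(self, sumstats, panel, prior: PriorSpec, pheno: Phenotype, **kw) -> None:
        super().__init__(sumstats, panel, pheno, **kw)
        self.prior = prior

    def fit(
        self,
        hp_fraction: float = 0.10,
        weighted: bool = False,
        soft: bool = False,
        r2_grid=predictors.DEFAULT_R2_GRID,
        p_grid=predictors.DEFAULT_PT_GRID,
        kb_window: int = 250,
    ) -> PRSResults:
        fitres = predictors.prs_pt_funct_lasso(
            self.sumstats,
            self.panel,
            self.pheno,
            self.prior,
            hp_fraction=hp_fraction,
            weighted=weighted,
            soft=soft,
            r2_grid=r2_grid,
            p_grid=p_grid,
            kb_window=kb_window,
        )
        return PRSResults(
            self.method + ("-weighted" if weighted else ""),
            fitres.effects,
            fitres.scores,
            params={"hp_fraction": hp_fraction},
            r2=fitres.r2,
            slope=calibration_slope(self.pheno.values, fitres.scores),
            model=self,
        )


class LDpredInf(_BaseModel):
    """Posterior mean causal effects under the infinitesimal prior."""

    method = "ldpred-inf"

    def __init__(self, sumstats, panel, h2g: float, pheno=None, **kw) -> None:
        super().__init__(sumstats, panel, pheno, **kw)
        self.h2g = h2g

    def _posterior(self) -> predictors.PosteriorEffects:
        keep = ~self.exclude_mask
        idx = np.where(keep)[0]
        sub_panel = self.panel.subset(idx)
        chroms = sub_panel.variants["chrom"].to_numpy()
        windows = window_partition(chroms, window_size_inf(len(idx)))
        ld = estimate_ld(sub_panel, windows)
        post = predictors.posterior_mean_inf(
            self.sumstats.beta_tilde[idx], ld, self.n_train, self.h2g, m_total=len(idx)
        )
        effects = np.zeros(self.panel.n_variants)
        effects[idx] = post.effects
        return predictors.PosteriorEffects(effects, self.method)

    def fit(self) -> PRSResults:
        post = self._posterior()
        scores = predictors.score(post.effects, self.panel)
        return PRSResults(
            self.method,
            post.effects,
            scores,
            params={"h2g": self.h2g, "window_snps": window_size_inf(int((~self.exclude_mask).sum()))},
            r2=self._evaluate(scores),
            slope=None if self.pheno is None else calibration_slope(self.pheno.values, scores),
            model=self,
        )


class LDpredFunctInf(_BaseModel):
    """Posterior mean causal effects under a functionally informed prior."""

    method = "ldpred-funct-inf"

    def __init__(self, sumstats, panel, prior: PriorSpec, pheno=None, **kw) -> None:
        super().__init__(sumstats, panel, pheno, **kw)
        if len(prior.sigma2) != panel.n_variants:
            raise ValueError("prior is not aligned to the panel")
        if self.exclude_mask.any():
            # re-normalize after zeroing excluded SNPs so masked variances
            # still sum to h2g
            sigma2 = np.where(self.exclude_mask, 0.0, prior.sigma2)
            prior = normalize_prior(sigma2, prior.h2g, tau=prior.tau)
        self.prior = prior

    def _posterior(self) -> predictors.PosteriorEffects:
        mask = self.prior.mask_pos
        idx = np.where(mask)[0]
        sub_panel = self.panel.subset(idx)
        chroms = sub_panel.variants["chrom"].to_numpy()
        windows = window_partition(chroms, window_size_funct(len(idx)))
        ld = estimate_ld(sub_panel, windows)
        return predictors.posterior_mean_funct_inf(
            self.sumstats.beta_tilde, ld, self.n_train, self.prior
        )

    def fit(self) -> PRSResults:
        post = self._posterior()
        scores = predictors.score(post.effects, self.panel)
        return PRSResults(
            self.method,
            post.effects,
            scores,
            params={
                "h2g": self.prior.h2g,
                "m_pos": self.prior.m_pos,
                "window_snps": window_size_funct(self.prior.m_pos),
            },
            r2=self._evaluate(scores),
            slope=None if self.pheno is None else calibration_slope(self.pheno.values, scores),
            model=self,
        )


class LDpredFunct(LDpredFunctInf):
    """Functionally informed posterior means with cross-validated bin
    regularization: rank posterior effects, partition into K bins of equal
    squared mass, and fit per-bin weights by 10-fold CV on validation data."""

    method = "ldpred-funct"

    def __init__(self, sumstats, panel, prior: PriorSpec, pheno: Phenotype, **kw) -> None:
        super().__init__(sumstats, panel, prior, pheno, **kw)

    def fit(self, seed: int = 0, K: int | None = None, n_folds: int = 10) -> PRSResults:
        post = self._posterior()
        k = K if K is not None else predictors.choose_K(self.panel.n_samples, self.prior.h2g)
        if k == 1:
            # reduces to the uniform-weight infinitesimal parent
            inf_res = super().fit()
            return PRSResults(
                self.method,
                inf_res.effects,
                inf_res.scores,
                params={**inf_res.params, "K": 1, "reduced_to": "ldpred-funct-inf"},
                r2=inf_res.r2,
                slope=inf_res.slope,
                K=1,
                model=self,
            )
        bins = predictors.bin_effects(post, k)
        model = predictors.fit_bin_weights_cv(
            bins, post, self.panel, self.pheno, n_folds=n_folds, seed=seed
        )
        # deployable effects: bin weights folded into the posterior means
        effects = post.effects * model.alpha[bins.assignment - 1]
        slope = calibration_slope(self.pheno.values, model.cv_predictions)
        return PRSResults(
            self.method,
            effects,
            model.scores,
            params={"h2g": self.prior.h2g, "m_pos": self.prior.m_pos, "n_folds": n_folds, "seed": seed},
            r2=self._evaluate(model.scores),
            r2_cv=model.r2_cv,
            slope=slope,
            alpha=model.alpha,
            K=k,
            cv_predictions=model.cv_predictions,
            model=model,
        )


class LDpredInfSparsity(LDpredFunct):
    """Composition variant: bin regularization applied on top of the
    flat (infinitesimal) prior — no functional information."""

    method = "ldpred-inf-sparsity"

    def __init__(self, sumstats, panel, h2g: float, pheno: Phenotype, **kw) -> None:
        prior = flat_prior(panel.n_variants, h2g)
        super().__init__(sumstats, panel, prior, pheno, **kw)


class LDpredFunctConstantPrior(LDpredFunct):
    """Composition variant: keep the functional prior's SNP selection
    (sigma2 > 0) but impose a constant prior variance on the retained SNPs."""

    method = "ldpred-funct-constant"

    def __init__(self, sumstats, panel, prior: PriorSpec, pheno: Phenotype, **kw) -> None:
        sigma2 = np.where(prior.mask_pos, 1.0, 0.0)
        const = normalize_prior(sigma2, prior.h2g)
        super().__init__(sumstats, panel, const, pheno, **kw)
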