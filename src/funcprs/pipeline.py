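"""Configuration-driven end-to-end runs: load or simulate data, build the
prior, fit a method, evaluate, and write a reproducible manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import dataio, evaluate, funct_prior, ldtools, models, simulate

logger = logging.getLogger(__name__)

METHODS = {
    "pt": models.PTModel,
    "pt-funct-lasso": models.PTFunctLasso,
    "ldpred-inf": models.LDpredInf,
    "ldpred-funct-inf": models.LDpredFunctInf,
    "ldpred-funct": models.LDpredFunct,
    "ldpred-inf-sparsity": models.LDpredInfSparsity,
    "ldpred-funct-constant": models.LDpredFunctConstantPrior,
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    method = config.get("method")
    if method not in METHODS:
        raise ConfigError(
            f"unknown method {method!r}; allowed: {sorted(METHODS)}"
        )
    if "seed" not in config:
        raise ConfigError("config must set an explicit seed")
    if "out_dir" not in config:
        raise ConfigError("config must set out_dir")
    needs_h2 = method in (
        "ldpred-inf", "ldpred-funct-inf", "ldpred-funct",
        "ldpred-inf-sparsity", "ldpred-funct-constant",
    )
    if needs_h2 and "h2g" not in config and "simulate" not in config:
        raise ConfigError(f"method {method} requires h2g")
    return config


def _load_inputs(config: dict[str, Any]) -> dict[str, Any]:
    if "simulate" in config:
        sim_cfg = simulate.SimConfig(**{**config["simulate"], "seed": config["seed"]})
        study = simulate.simulate_study(sim_cfg)
        return {
            "sumstats": study["sumstats"],
            "panel": study["val_panel"],
            "pheno": study["pheno_val"],
            "annotations": study["annotations"],
            "h2g": config.get("h2g", sim_cfg.h2g),
            "sim_config": asdict(sim_cfg),
        }
    sumstats = dataio.read_summary_stats(
        config["sumstats"], config.get("sumstats_dialect"),
        pheno_var=config.get("pheno_var"),
    )
    panel = dataio.read_genotypes(config["genotypes"])
    pheno = dataio.read_phenotype(config["pheno"]) if "pheno" in config else None
    qc = config.get("qc", {})
    sumstats, panel = dataio.harmonize(
        sumstats, panel,
        maf_min=qc.get("maf_min", 0.01),
        info_min=qc.get("info_min", 0.9),
        drop_ambiguous=qc.get("drop_ambiguous", True),
    )
    if pheno is not None:
        order = {s: i for i, s in enumerate(pheno.sample_ids)}
        idx = [order[s] for s in panel.sample_ids if s in order]
        if len(idx) != panel.n_samples:
            raise ConfigError("phenotype does not cover all panel samples")
        pheno = dataio.Phenotype(list(panel.sample_ids), pheno.values[idx])
    annotations = (
        dataio.read_annotations(config["annotations"], panel.variants)
        if "annotations" in config
        else None
    )
    return {
        "sumstats": sumstats,
        "panel": panel,
        "pheno": pheno,
        "annotations": annotations,
        "h2g": config.get("h2g"),
    }


def _build_prior(inputs: dict[str, Any], config: dict[str, Any]) -> funct_prior.PriorSpec:
    annotations = inputs["annotations"]
    if annotations is None:
        raise ConfigError("this method requires an annotation matrix")
    sumstats = inputs["sumstats"]
    if sumstats.beta_tilde is None:
        sumstats = dataio.normalized_effects(sumstats)
        inputs["sumstats"] = sumstats
    chisq = (sumstats.beta_tilde * np.sqrt(sumstats.n_train)) ** 2
    radius = config.get("ld_score_radius_kb", 1000)
    lsc = ldtools.annotation_ld_scores(inputs["panel"], annotations, radius_kb=radius)
    n = float(np.median(sumstats.n_train))
    return funct_prior.fit_prior(chisq, lsc, annotations, n, inputs["h2g"])


def run(config: dict[str, Any]) -> dict[str, Any]:
    """Execute one configured run; returns the manifest (also written to
    ``out_dir/manifest.json``)."""
    config = validate_config(dict(config))
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": {k: v for k, v in config.items()}, "stages": []}
    method = config["method"]
    seed = int(config["seed"])
    try:
        stage = "load"
        inputs = _load_inputs(config)
        manifest["stages"].append(stage)
        manifest["n_variants"] = inputs["panel"].n_variants
        manifest["n_samples"] = inputs["panel"].n_samples

        exclude = None
        if "exclude_regions" in config:
            regions = ldtools.read_bed_regions(config["exclude_regions"])
            exclude = ldtools.long_range_ld_mask(inputs["panel"].variants, regions)
            manifest["n_excluded_long_range_ld"] = int(exclude.sum())

        stage = "prior"
        needs_prior = method in ("pt-funct-lasso", "ldpred-funct-inf", "ldpred-funct",
                                 "ldpred-funct-constant")
        prior = _build_prior(inputs, config) if needs_prior else None
        if prior is not None:
            manifest["m_pos"] = prior.m_pos
            manifest["c_norm"] = prior.c_norm
            pd.DataFrame({"id": inputs["panel"].variants["id"], "sigma2": prior.sigma2}).to_csv(
                out_dir / "sigma2.tsv", sep="\t", index=False
            )
        manifest["stages"].append(stage)

        stage = "fit"
        cls = METHODS[method]
        kw: dict[str, Any] = {}
        fit_kw: dict[str, Any] = {}
        if exclude is not None:
            kw["exclude_mask"] = exclude
        if method == "pt":
            model = cls(inputs["sumstats"], inputs["panel"], inputs["pheno"], **kw)
        elif method == "pt-funct-lasso":
            model = cls(inputs["sumstats"], inputs["panel"], prior, inputs["pheno"], **kw)
            fit_kw = {
                "hp_fraction": config.get("hp_fraction", 0.10),
                "weighted": config.get("weighted", False),
            }
        elif method in ("ldpred-inf", "ldpred-inf-sparsity"):
            args = [inputs["sumstats"], inputs["panel"], inputs["h2g"]]
            if method == "ldpred-inf-sparsity":
                args.append(inputs["pheno"])
                fit_kw = {"seed": seed}
            else:
                kw["pheno"] = inputs["pheno"]
            model = cls(*args, **kw)
        elif method == "ldpred-funct-inf":
            model = cls(inputs["sumstats"], inputs["panel"], prior, pheno=inputs["pheno"], **kw)
        else:  # ldpred-funct, ldpred-funct-constant
            model = cls(inputs["sumstats"], inputs["panel"], prior, inputs["pheno"], **kw)
            fit_kw = {"seed": seed}
            if "K" in config:
                fit_kw["K"] = config["K"]
        results = model.fit(**fit_kw)
        manifest["stages"].append(stage)
        manifest["params"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in results.params.items()
        }
        if results.K is not None:
            manifest["K"] = results.K
        if results.alpha is not None:
            manifest["alpha"] = results.alpha.tolist()

        stage = "write"
        panel = inputs["panel"]
        eff = pd.DataFrame(
            {
                "id": panel.variants["id"],
                "a1": panel.variants["a1"],
                "a2": panel.variants["a2"],
                "effect_normalized": results.effects,
                "effect_per_allele": results.per_allele_effects(panel),
            }
        )
        eff.to_csv(out_dir / "effects.tsv", sep="\t", index=False)
        pd.DataFrame({"sample": panel.sample_ids, "score": results.scores}).to_csv(
            out_dir / "prs.tsv", sep="\t", index=False
        )
        manifest["stages"].append(stage)

        stage = "evaluate"
        if inputs["pheno"] is not None:
            rows = [
                {
                    "method": results.method,
                    "r2": results.r2,
                    "slope": results.slope,
                    "se": None,
                    "n_blocks": None,
                }
            ]
            evaluate.metrics_report(rows, out_dir / "metrics.tsv")
            manifest["r2"] = results.r2
            if results.r2_cv is not None:
                manifest["r2_cv"] = results.r2_cv
            manifest["slope"] = results.slope
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    manifest["method"] = results.method
    manifest["seed"] = seed
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
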