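import json

import numpy as np
import pytest

import funcprs
from funcprs import meta, pipeline
from funcprs.dataio import Phenotype, normalized_effects
from funcprs.funct_prior import flat_prior
from funcprs.meta import combine_meta, meta_ldpred_funct
from funcprs.models import (
    LDpredFunct,
    LDpredFunctInf,
    LDpredInf,
    LDpredInfSparsity,
    PTFunctLasso,
    PTModel,
)
from funcprs.predictors import PosteriorEffects, bin_effects, choose_K, fit_bin_weights_cv
from funcprs.simulate import SimConfig, simulate_study


@pytest.fixture(scope="module")
def study():
    return simulate_study(SimConfig(n_train=1200, n_val=500, M=300, seed=31))


@pytest.fixture(scope="module")
def inputs(study):
    ss = normalized_effects(study["sumstats"])
    return ss, study["val_panel"], study["pheno_val"], study["prior"]


class TestModels:
    def test_ldpred_inf_fit(self, inputs):
        ss, panel, pheno, _ = inputs
        res = LDpredInf(ss, panel, h2g=0.5, pheno=pheno).fit()
        assert res.method == "ldpred-inf"
        assert 0 <= res.r2 <= 1
        assert np.count_nonzero(res.effects) == panel.n_variants

    def test_funct_inf_masks_nonpositive(self, inputs):
        ss, panel, pheno, prior = inputs
        res = LDpredFunctInf(ss, panel, prior, pheno=pheno).fit()
        off = ~prior.mask_pos
        if off.any():
            np.testing.assert_array_equal(res.effects[off], 0.0)
        assert res.params["m_pos"] == prior.m_pos

    def test_ldpred_funct_full_fit(self, inputs):
        ss, panel, pheno, prior = inputs
        res = LDpredFunct(ss, panel, prior, pheno).fit(seed=5)
        assert res.K == choose_K(panel.n_samples, prior.h2g)
        assert res.alpha is not None and len(res.alpha) == res.K
        assert res.r2_cv is not None
        text = res.summary()
        assert "ldpred-funct" in text and "Held-out R2" in text

    def test_k1_reduces_to_funct_inf(self, inputs):
        ss, panel, pheno, prior = inputs
        res = LDpredFunct(ss, panel, prior, pheno).fit(seed=5, K=1)
        ref = LDpredFunctInf(ss, panel, prior, pheno=pheno).fit()
        np.testing.assert_allclose(res.effects, ref.effects)
        assert res.params["reduced_to"] == "ldpred-funct-inf"

    def test_composition_variants_run(self, inputs):
        ss, panel, pheno, prior = inputs
        res_sp = LDpredInfSparsity(ss, panel, 0.5, pheno).fit(seed=2)
        assert res_sp.method == "ldpred-inf-sparsity"
        assert res_sp.K is not None  # binning machinery engaged
        from funcprs.models import LDpredFunctConstantPrior

        res_cp = LDpredFunctConstantPrior(ss, panel, prior, pheno).fit(seed=2)
        assert np.isfinite(res_cp.r2_cv or res_cp.r2)

    def test_sparsity_variant_matches_manual_composition(self, inputs):
        """Binning applied to infinitesimal posterior means equals the
        dedicated composition class."""
        ss, panel, pheno, _ = inputs
        res = LDpredInfSparsity(ss, panel, 0.5, pheno).fit(seed=7)
        base = LDpredInf(ss, panel, h2g=0.5, pheno=pheno)
        post = base._posterior()
        k = choose_K(panel.n_samples, 0.5)
        manual = fit_bin_weights_cv(
            bin_effects(PosteriorEffects(post.effects, "x"), k),
            PosteriorEffects(post.effects, "x"),
            panel,
            pheno,
            seed=7,
        )
        assert res.r2_cv == pytest.approx(manual.r2_cv)

    def test_pt_and_lasso_models(self, inputs):
        ss, panel, pheno, prior = inputs
        grids = dict(r2_grid=(0.2, 0.8), p_grid=(1.0, 1e-3))
        res_pt = PTModel(ss, panel, pheno).fit(**grids)
        assert "r2_ld" in res_pt.params
        res_l = PTFunctLasso(ss, panel, prior, pheno).fit(hp_fraction=0.10, **grids)
        assert np.isfinite(res_l.r2)

    def test_exclude_mask_zeroes_region(self, inputs):
        ss, panel, pheno, _ = inputs
        mask = np.zeros(panel.n_variants, dtype=bool)
        mask[:50] = True
        res = LDpredInf(ss, panel, h2g=0.5, pheno=pheno, exclude_mask=mask).fit()
        np.testing.assert_array_equal(res.effects[:50], 0.0)

    def test_per_allele_conversion(self, inputs):
        ss, panel, pheno, _ = inputs
        res = LDpredInf(ss, panel, h2g=0.5, pheno=pheno).fit()
        maf = panel.variants["maf"].to_numpy()
        expected = res.effects / np.sqrt(2 * maf * (1 - maf))
        np.testing.assert_allclose(res.per_allele_effects(panel), expected)

    def test_misaligned_inputs_rejected(self, inputs):
        ss, panel, pheno, _ = inputs
        with pytest.raises(ValueError, match="harmonize"):
            LDpredInf(ss.subset(np.arange(100)), panel, h2g=0.5)


class TestCombineMeta:
    def test_fixed_effect_symmetric(self):
        a, b = np.arange(5.0), np.ones(5)
        combined, w = combine_meta([a, b], n_list=[100, 100])
        np.testing.assert_allclose(w.gamma, [0.5, 0.5])
        np.testing.assert_allclose(combined, (a + b) / 2)

    def test_fixed_effect_cohort_sizes(self):
        _, w = combine_meta(
            [np.arange(4.0), np.ones(4)], n_list=[408_092, 698_430]
        )
        np.testing.assert_allclose(w.gamma, [0.36884, 0.63116], atol=5e-5)

    def test_optimized_identity(self):
        rng = np.random.default_rng(2)
        prs1 = rng.standard_normal(200)
        prs2 = rng.standard_normal(200)
        pheno = Phenotype([f"s{i}" for i in range(200)], prs1.copy())
        combined, w = combine_meta([prs1, prs2], pheno=pheno, mode="optimized")
        assert w.gamma[0] == pytest.approx(1.0, abs=1e-8)
        assert w.gamma[1] == pytest.approx(0.0, abs=1e-8)
        assert w.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_optimized_beats_fixed_in_sample(self):
        rng = np.random.default_rng(3)
        prs1, prs2 = rng.standard_normal(300), rng.standard_normal(300)
        y = 2 * prs1 + 0.5 * prs2 + rng.standard_normal(300)
        pheno = Phenotype([f"s{i}" for i in range(300)], y)
        fixed, _ = combine_meta([prs1, prs2], n_list=[1, 1])
        opt, _ = combine_meta([prs1, prs2], pheno=pheno, mode="optimized")
        r2 = lambda s: np.corrcoef(y, s)[0, 1] ** 2
        assert r2(opt) >= r2(fixed) - 1e-12

    def test_cross_validated_weights_near_in_sample(self):
        from funcprs.meta import combine_meta_cv

        rng = np.random.default_rng(4)
        prs1, prs2 = rng.standard_normal(400), rng.standard_normal(400)
        y = prs1 + 0.3 * prs2 + 0.5 * rng.standard_normal(400)
        pheno = Phenotype([f"s{i}" for i in range(400)], y)
        combined, r2_cv = combine_meta_cv([prs1, prs2], pheno, seed=1)
        _, w = combine_meta([prs1, prs2], pheno=pheno, mode="optimized")
        assert len(combined) == 400
        # held-out accuracy is close to (and not above noise of) in-sample
        assert r2_cv == pytest.approx(w.adj_r2, abs=0.08)

    def test_modes_validated(self):
        with pytest.raises(ValueError):
            combine_meta([np.ones(3)], mode="optimized")
        with pytest.raises(ValueError):
            combine_meta([np.ones(3)], mode="bogus")


class TestMetaLDpredFunct:
    def test_single_cohort_reduces_to_ldpred_funct(self, inputs):
        ss, panel, pheno, prior = inputs
        direct = LDpredFunct(ss, panel, prior, pheno).fit(seed=9)
        post = LDpredFunctInf(ss, panel, prior)._posterior()
        model, gamma = meta_ldpred_funct([post], panel, pheno, h2g=prior.h2g, seed=9)
        assert model.r2_cv == pytest.approx(direct.r2_cv)
        np.testing.assert_allclose(gamma.gamma, [1.0])

    def test_identical_cohorts_symmetric(self, inputs):
        ss, panel, pheno, prior = inputs
        post = LDpredFunctInf(ss, panel, prior)._posterior()
        model2, gamma = meta_ldpred_funct(
            [post, post], panel, pheno, h2g=prior.h2g, seed=9
        )
        single, _ = meta_ldpred_funct([post], panel, pheno, h2g=prior.h2g, seed=9)
        # duplicated cohorts: combined PMCES proportional to either cohort's,
        # so bins and cross-validated accuracy coincide
        assert model2.r2_cv == pytest.approx(single.r2_cv, abs=1e-6)

    def test_higher_heritability_cohort_upweighted(self):
        """Two cohorts with the same N but different true heritability: the
        optimized weights favour the informative cohort beyond its N share."""
        study_hi = simulate_study(SimConfig(n_train=1500, n_val=600, M=200, h2g=0.5, seed=41))
        cfg_lo = SimConfig(n_train=1500, n_val=600, M=200, h2g=0.1, seed=41)
        study_lo = simulate_study(cfg_lo)
        panel, pheno = study_hi["val_panel"], study_hi["pheno_val"]
        prior = study_hi["prior"]
        ss_hi = normalized_effects(study_hi["sumstats"])
        ss_lo = normalized_effects(study_lo["sumstats"])
        post_hi = LDpredFunctInf(ss_hi, panel, prior)._posterior()
        post_lo = LDpredFunctInf(ss_lo, panel, prior)._posterior()
        _, gamma = meta_ldpred_funct(
            [post_hi, post_lo], panel, pheno, h2g=0.5, seed=1
        )
        assert abs(gamma.gamma[0]) > abs(gamma.gamma[1])


class TestPipeline:
    def _config(self, tmp_path, **overrides):
        cfg = {
            "method": "ldpred-funct",
            "seed": 11,
            "out_dir": str(tmp_path / "run"),
            "h2g": 0.5,
            "simulate": {"n_train": 500, "n_val": 300, "M": 150},
        }
        cfg.update(overrides)
        return cfg

    def test_deterministic_outputs(self, tmp_path):
        m1 = pipeline.run(self._config(tmp_path / "a"))
        m2 = pipeline.run(self._config(tmp_path / "b"))
        assert m1["r2"] == m2["r2"]
        f1 = (tmp_path / "a" / "run" / "metrics.tsv").read_text()
        f2 = (tmp_path / "b" / "run" / "metrics.tsv").read_text()
        assert f1 == f2

    def test_small_validation_falls_back_to_k1(self, tmp_path):
        cfg = self._config(tmp_path, simulate={"n_train": 500, "n_val": 150, "M": 150})
        manifest = pipeline.run(cfg)
        assert manifest["K"] == 1
        assert manifest["params"]["reduced_to"] == "ldpred-funct-inf"

    def test_invalid_method_lists_choices(self, tmp_path):
        with pytest.raises(pipeline.ConfigError, match="ldpred-funct"):
            pipeline.run(self._config(tmp_path, method="nope"))

    def test_manifest_records_parameters(self, tmp_path):
        pipeline.run(self._config(tmp_path))
        manifest = json.loads((tmp_path / "run" / "manifest.json").read_text())
        assert manifest["seed"] == 11
        assert "alpha" in manifest and "K" in manifest
        assert (tmp_path / "run" / "effects.tsv").exists()
        assert (tmp_path / "run" / "prs.tsv").exists()

    def test_file_roundtrip_run(self, tmp_path):
        """Write a study to disk with the generator, then run the pipeline
        through the real file-based loaders."""
        from funcprs import dataio
        from funcprs.simulate import simulate_study

        study = simulate_study(SimConfig(n_train=400, n_val=250, M=120, seed=13))
        data = tmp_path / "data"
        data.mkdir()
        dataio.write_plink(study["val_panel"], data / "val")
        dataio.write_summary_stats(study["sumstats"], data / "ss.tsv")
        dataio.write_annotations(study["annotations"], data / "annot.tsv")
        dataio.write_phenotype(study["pheno_val"], data / "pheno.tsv")
        cfg = {
            "method": "ldpred-funct-inf",
            "seed": 3,
            "out_dir": str(tmp_path / "out"),
            "h2g": 0.5,
            "sumstats": str(data / "ss.tsv"),
            "sumstats_dialect": {"maf": "MAF"},
            "genotypes": str(data / "val"),
            "pheno": str(data / "pheno.tsv"),
            "annotations": str(data / "annot.tsv"),
            "qc": {"maf_min": 0.01},
            "pheno_var": 1.0,
        }
        manifest = pipeline.run(cfg)
        assert manifest["r2"] is not None and manifest["r2"] > 0


class TestCLI:
    def test_cli_simulate_and_evaluate(self, tmp_path):
        from click.testing import CliRunner

        from funcprs.cli import main

        runner = CliRunner()
        out = tmp_path / "sim"
        res = runner.invoke(
            main,
            ["simulate", "--out", str(out), "--seed", "5"],
            catch_exceptions=False,
        )
        assert res.exit_code == 0
        assert (out / "sumstats.tsv").exists() and (out / "train.bed").exists()

    def test_cli_run_roundtrip(self, tmp_path):
        import yaml
        from click.testing import CliRunner

        from funcprs.cli import main

        cfg = {
            "method": "ldpred-inf",
            "seed": 2,
            "out_dir": str(tmp_path / "out"),
            "h2g": 0.5,
            "simulate": {"n_train": 300, "n_val": 200, "M": 100},
        }
        cfg_path = tmp_path / "c.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        runner = CliRunner()
        res = runner.invoke(main, ["run", "--config", str(cfg_path)], catch_exceptions=False)
        assert res.exit_code == 0
        assert "r2" in res.output
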