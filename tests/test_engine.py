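"""Scenario catalogue, generation loop, reproducibility and reporting."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from polledsim import cli, engine
from polledsim.pedigree import inbreeding_coefficients
from polledsim.selection import GENO, NONE, PHENO, WeightingScheme

TINY = dict(scale_factor=250, n_replicates=1, n_polled_generations=5, base_seed=17)


def tiny_config(name="CONTROL", **kw):
    return engine.scenario_config(name, **{**TINY, **kw})


class TestCatalogue:
    def test_names_and_schemes(self):
        cat = engine.scenario_catalogue()
        assert set(cat) == {
            "CONTROL", "GENO-ALL", "GENO-M", "GENO-F", "PHENO-ALL",
            "PHENO-M", "PHENO-F", "GENO-M-PHENO-F", "wf-M-0.1", "wf-M-0.5",
        }
        s = cat["CONTROL"].scheme
        assert s.strategy_male == NONE and s.strategy_female == NONE
        s = cat["wf-M-0.1"].scheme
        assert (s.strategy_male, s.wf_male) == (GENO, 0.1)
        assert (s.strategy_female, s.wf_female) == (PHENO, 0.5)
        s = cat["GENO-F"].scheme
        assert s.strategy_male == NONE
        assert (s.strategy_female, s.wf_female) == (GENO, 0.5)
        assert cat["wf-M-0.5"].scheme == cat["GENO-M-PHENO-F"].scheme

    def test_unknown_scenario(self):
        with pytest.raises(KeyError):
            engine.scenario_config("GENO-XXL")


class TestPopulationStructure:
    def test_dam_growth_schedule_full_scale(self):
        cfg = engine.scenario_config("CONTROL")
        # 12.5 % growth from 50,000, capped at 75,000 when first exceeded
        assert cfg.dam_targets() == [56250, 63281, 71191, 75000, 75000]

    def test_scaled_sizes_preserve_ratios(self):
        cfg = engine.scenario_config("CONTROL", scale_factor=25)
        assert cfg.n_sires_scaled == 10
        assert cfg.n_dams_scaled == 3000
        assert cfg.n_founder_females_scaled == 2000

    def test_active_sizes_constant_after_growth(self):
        rep = engine.run_replicate(tiny_config(), 0, keep_pedigree=False)
        m = rep.metrics
        sires = m[m.group == "active_sires"]
        assert (sires.n == tiny_config().n_sires_scaled).all()
        dams = m[(m.group == "active_dams") & (m.generation >= 0)]
        assert (dams.n == tiny_config().n_dams_scaled).all()

    def test_generation_labels(self):
        assert engine.scenario_config("CONTROL").generation_labels()[0] == -4
        assert engine.scenario_config("CONTROL").generation_labels()[-1] == 25


class TestReproducibility:
    def test_same_seed_is_bit_identical(self):
        r1 = engine.run_replicate(tiny_config(), 0, keep_pedigree=False)
        r2 = engine.run_replicate(tiny_config(), 0, keep_pedigree=False)
        pd.testing.assert_frame_equal(r1.metrics, r2.metrics)

    def test_replicates_differ(self):
        r0 = engine.run_replicate(tiny_config(), 0, keep_pedigree=False)
        r1 = engine.run_replicate(tiny_config(), 1, keep_pedigree=False)
        assert not r0.metrics.equals(r1.metrics)

    def test_control_equals_geno_all_with_zero_weight(self):
        base = tiny_config("CONTROL")
        zero = dataclasses.replace(
            base, name="CONTROL", scheme=WeightingScheme(GENO, GENO, 0.0, 0.0)
        )
        r1 = engine.run_replicate(base, 0, keep_pedigree=False)
        r2 = engine.run_replicate(zero, 0, keep_pedigree=False)
        pd.testing.assert_frame_equal(r1.metrics, r2.metrics)


@pytest.fixture(scope="module")
def result():
    return engine.run_replicate(tiny_config("GENO-ALL"), 0)


class TestGenerationLoop:

    def test_gen0_frequency_rounding_rule(self, result):
        ped = result.pedigree
        cohort = ped.ids[ped.generation == 0]
        n = cohort.size
        freq = ped.n_polled[cohort - 1].sum() / (2 * n)
        assert freq == round(2 * n * 0.03) / (2 * n)

    def test_metrics_frequency_identities(self, result):
        m = result.metrics
        cohorts = m[m.generation >= 0]
        np.testing.assert_allclose(
            cohorts.f_pp + cohorts.f_Pp + cohorts.f_PP, 1.0, atol=1e-12
        )
        np.testing.assert_allclose(
            cohorts.freq_P, cohorts.f_Pp / 2 + cohorts.f_PP, atol=1e-12
        )

    def test_engine_inbreeding_matches_meuwissen_luo(self, result):
        ped = result.pedigree
        np.testing.assert_allclose(ped.f, inbreeding_coefficients(ped), atol=1e-10)

    def test_mean_inbreeding_nondecreasing_in_closed_population(self, result):
        f = [
            result.active_summary(g)["mean_F"]
            for g in sorted(result.metrics.generation.unique())
        ]
        assert np.all(np.diff(f) > -1e-9)

    def test_phenotypes_female_only(self, result):
        ped = result.pedigree
        assert np.isnan(ped.phenotype[ped.sex == 0]).all()
        assert not np.isnan(ped.phenotype[ped.sex == 1]).any()

    def test_progeny_sex_ratio(self, result):
        m = result.metrics
        males = m[m.group == "progeny_males"].n.sum()
        females = m[m.group == "progeny_females"].n.sum()
        total = males + females
        assert abs(males / total - 0.5) < 3 * np.sqrt(0.25 / total)


class TestScenarioAggregation:
    def test_single_replicate_sd_flagged(self):
        res = engine.run_scenario(tiny_config())
        s = res.summary()
        assert s["n_replicates"] == 1
        assert np.isnan(s["freq_P_sd"])

    def test_control_allele_frequency_supermartingale(self):
        # selection ignores the locus but carriers start genetically inferior,
        # so the replicate-mean endpoint frequency stays at or below 0.03
        cfg = engine.scenario_config(
            "CONTROL", scale_factor=100, n_replicates=3, base_seed=23,
            n_polled_generations=10,
        )
        res = engine.run_scenario(cfg)
        assert res.endpoints["freq_P"].mean() <= 0.03

    def test_trajectory_table_shape(self):
        cfg = tiny_config(n_replicates=2)
        res = engine.run_scenario(cfg)
        traj = res.trajectory
        assert {"generation", "group", "freq_P_mean", "freq_P_std"} <= set(traj.columns)
        gens = cfg.generation_labels()
        assert traj.generation.max() == gens[-1]

    def test_blup_window_runs(self):
        cfg = tiny_config(blup_window=2)
        rep = engine.run_replicate(cfg, 0, keep_pedigree=False)
        assert rep.metrics.generation.max() == 5


def test_cli_catalogue_and_run(tmp_path):
    runner = CliRunner()
    out = runner.invoke(cli.main, ["catalogue"])
    assert out.exit_code == 0 and "GENO-M-PHENO-F" in out.output
    out = runner.invoke(
        cli.main,
        [
            "run", "--scenario", "GENO-ALL", "--replicates", "1",
            "--seed", "3", "--scale", "250", "--generations", "3",
            "--out", str(tmp_path), "--pedigrees",
        ],
    )
    assert out.exit_code == 0, out.output
    assert (tmp_path / "endpoints_GENO-ALL.csv").exists()
    assert (tmp_path / "metrics_GENO-ALL_rep0.csv").exists()
    assert (tmp_path / "pedigree_GENO-ALL_rep0.tsv").exists()
    out = runner.invoke(cli.main, ["report", str(tmp_path)])
    assert out.exit_code == 0 and "GENO-ALL" in out.output
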