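"""Generator structure: panels, Mendelian pedigrees, calibrated phenotypes."""

import numpy as np
import pandas as pd
import pytest

from introgress_stock._rng import substream
from introgress_stock.parentage import count_mismatches
from introgress_stock.simulate import (
    EffectConfig,
    PanelSpec,
    simulate_adult_table,
    simulate_crosses,
    simulate_family_table,
    simulate_individual,
    simulate_panel,
    simulate_run_years,
)


class TestPanel:
    def test_default_layout(self, panel):
        assert panel.n_nuclear == 81
        assert panel.n_diagnostic == 48
        assert panel.n_mt == 15
        assert np.all((panel.wild_freq > 0) & (panel.wild_freq < 1))
        assert np.all((panel.farmed_freq > 0) & (panel.farmed_freq < 1))

    def test_zero_divergence_collapses_references(self):
        p = simulate_panel(PanelSpec(fst_like_divergence=0.0, seed=4), calibrate=False)
        np.testing.assert_allclose(p.wild_freq, p.farmed_freq)
        np.testing.assert_allclose(p.mt_wild_freq, p.mt_farmed_freq)

    def test_divergence_ordering(self, panel):
        diff = np.abs(panel.farmed_freq - panel.wild_freq)
        assert diff[panel.diagnostic].min() > diff[~panel.diagnostic].max()

    def test_seeded_reproducibility(self):
        spec = PanelSpec(seed=9)
        p1, p2 = simulate_panel(spec), simulate_panel(spec)
        np.testing.assert_array_equal(p1.wild_freq, p2.wild_freq)
        assert p1.p_w == p2.p_w and p1.p_d == p2.p_d

    def test_calibrated_scaling_constants(self, panel):
        # pure-reference averages sit near, not at, the boundaries
        assert 0.0 < panel.p_w < 0.15
        assert 0.85 < panel.p_d < 1.0

    def test_invalid_divergence_rejected(self):
        with pytest.raises(ValueError, match="divergence"):
            PanelSpec(fst_like_divergence=1.5)


class TestIndividual:
    def test_fixation_limits(self):
        panel = simulate_panel(PanelSpec(seed=2), calibrate=False)
        from dataclasses import replace

        fixed = replace(
            panel,
            wild_freq=np.full(81, 1e-4),
            farmed_freq=np.full(81, 1 - 1e-4),
        )
        ind = simulate_individual(fixed, 1.0, seed=5)
        assert np.all(ind.genotypes == 2.0)
        ind0 = simulate_individual(fixed, 0.0, seed=5)
        assert np.all(ind0.genotypes == 0.0)

    def test_mixture_dosage_expectation(self):
        """At q=0.5 with 0.1/0.9 references, mean dosage is 1 (Monte Carlo)."""
        panel = simulate_panel(PanelSpec(seed=2), calibrate=False)
        from dataclasses import replace

        p = replace(panel, wild_freq=np.full(81, 0.1), farmed_freq=np.full(81, 0.9))
        rng = substream(6, "mc")
        dosages = [simulate_individual(p, 0.5, rng).genotypes.mean() for _ in range(300)]
        assert np.mean(dosages) == pytest.approx(1.0, abs=0.02)

    def test_invalid_true_d(self, panel):
        with pytest.raises(ValueError):
            simulate_individual(panel, 1.2)


class TestFamilyTable:
    def test_mean_family_size_near_study_value(self, config):
        _, crosses = simulate_family_table(config, n_pairs=2000, seed=3)
        assert crosses["n_offspring"].mean() == pytest.approx(10.33, abs=1.0)
        assert crosses["n_offspring"].min() >= 1

    def test_null_configuration_recovers_zero_slope(self):
        cfg = EffectConfig(
            beta_dam_hatchery=0.0,
            beta_introgression_wild_dam=0.0,
            beta_introgression_hatchery_dam=0.0,
            beta_log_eggs=0.0,
            beta_intercept=2.3,
            sigma_year=0.0,
        )
        _, crosses = simulate_family_table(cfg, n_pairs=1500, seed=8)
        slope = np.polyfit(
            crosses["pair_introgression_true"], np.log(crosses["n_offspring"]), 1
        )[0]
        assert slope == pytest.approx(0.0, abs=0.25)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError, match="sigma_resid"):
            EffectConfig(sigma_resid=-1.0)


class TestCrosses:
    def test_mendelian_consistency_without_error(self, clean_config):
        study = simulate_crosses(clean_config, n_pairs=12, seed=21)
        geno = study.offspring_genotypes
        for rec in study.offspring.itertuples():
            mism, compared = count_mismatches(
                geno.loc[rec.individual_id],
                study.broodstock_genotypes.loc[rec.dam_id],
                study.broodstock_genotypes.loc[rec.sire_id],
            )
            assert mism == 0
            assert compared == 81

    def test_mt_maternal_inheritance(self, clean_config):
        study = simulate_crosses(clean_config, n_pairs=8, seed=22)
        for rec in study.offspring.itertuples():
            np.testing.assert_array_equal(
                study.offspring_mt.loc[rec.individual_id],
                study.broodstock_mt.loc[rec.dam_id],
            )

    def test_seeded_determinism(self, config):
        s1 = simulate_crosses(config, n_pairs=10, seed=33)
        s2 = simulate_crosses(config, n_pairs=10, seed=33)
        pd.testing.assert_frame_equal(s1.offspring, s2.offspring)
        pd.testing.assert_frame_equal(s1.offspring_genotypes, s2.offspring_genotypes)
        pd.testing.assert_frame_equal(s1.crosses, s2.crosses)

    def test_smolt_length_group_separation(self, config):
        """Hatchery-reared offspring centre near 232 mm, wild adults near 152 mm."""
        study = simulate_crosses(config, n_pairs=60, seed=34)
        hatchery_mean = study.offspring["smolt_length_true_mm"].mean()
        wild = simulate_adult_table(config, n_adults=800, origin="wild", seed=35)
        assert hatchery_mean == pytest.approx(232.0, rel=0.05)
        assert wild["smolt_length_true_mm"].mean() == pytest.approx(152.0, rel=0.05)


class TestRunYears:
    def test_group_means_recovered_at_large_n(self, config):
        table = simulate_run_years(config, n_years=40, n_per_group_per_year=200, seed=41)
        logit = lambda p: np.log(p / (1 - p))
        for origin, target in (("wild", 0.092), ("hatchery", 0.27)):
            sub = table[table["origin"] == origin]
            year_means = sub.groupby("run_year")["p_ind"].apply(lambda p: logit(p).mean())
            recovered = 1 / (1 + np.exp(-year_means.mean()))
            assert recovered == pytest.approx(target, rel=0.15)

    def test_equal_means_give_null_contrast(self):
        cfg = EffectConfig(run_year_means=(0.2, 0.2))
        table = simulate_run_years(cfg, n_years=30, n_per_group_per_year=100, seed=42)
        gm = table.groupby("origin")["p_ind"].mean()
        assert abs(gm["wild"] - gm["hatchery"]) < 0.05

    def test_noise_free_groups_are_constant(self):
        cfg = EffectConfig(run_year_logit_sd_year=0.0, run_year_logit_sd_ind=0.0)
        table = simulate_run_years(cfg, n_years=1, n_per_group_per_year=10, seed=43)
        assert table.groupby("origin")["p_ind"].nunique().max() == 1

    def test_invalid_means_rejected(self):
        with pytest.raises(ValueError, match="run_year_means"):
            EffectConfig(run_year_means=(0.0, 0.3))
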