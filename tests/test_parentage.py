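"""Mendelian exclusion, maternity verification and family tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introgress_stock.parentage import (
    assign_all,
    assign_offspring,
    build_family_table,
    count_mismatches,
    verify_maternity,
)
from introgress_stock.simulate import simulate_crosses


from oracles import brute_force_mismatches


genotype_vec = st.lists(
    st.sampled_from([0.0, 1.0, 2.0, np.nan]), min_size=1, max_size=30
)


class TestCountMismatches:
    def test_impossible_transmission(self):
        assert count_mismatches([2.0], [0.0], [0.0]) == (1, 1)

    def test_heterozygous_parents_permit_all(self):
        for o in (0.0, 1.0, 2.0):
            assert count_mismatches([o], [1.0], [1.0]) == (0, 1)

    def test_engineered_fixture_trio(self):
        rng = np.random.default_rng(5)
        dam = rng.integers(0, 3, 81).astype(float)
        sire = rng.integers(0, 3, 81).astype(float)
        # draw a compatible offspring, then corrupt two loci to be impossible
        kid = np.array(
            [
                np.random.default_rng(i).choice(
                    sorted({a + b for a in ((0, 0), (0, 1), (1, 1))[int(d)]
                            for b in ((0, 0), (0, 1), (1, 1))[int(s)]})
                )
                for i, (d, s) in enumerate(zip(dam, sire))
            ],
            dtype=float,
        )
        dam[:2] = 0.0
        sire[:2] = 0.0
        kid[:2] = 2.0
        assert count_mismatches(kid, dam, sire) == (2, 81)
        assert brute_force_mismatches(kid, dam, sire) == (2, 81)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_mismatches([0.0], [0.0, 1.0], [0.0])

    @given(genotype_vec, genotype_vec, genotype_vec)
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_bruteforce_oracle(self, off, dam, sire):
        n = min(len(off), len(dam), len(sire))
        off, dam, sire = off[:n], dam[:n], sire[:n]
        assert count_mismatches(off, dam, sire) == brute_force_mismatches(off, dam, sire)


class TestVerifyMaternity:
    def test_identical_consistent(self):
        h = np.array([0.0, 1.0] * 7 + [0.0])
        assert verify_maternity(h, h.copy()) == "consistent"

    def test_single_difference_inconsistent(self):
        h = np.zeros(15)
        h2 = h.copy()
        h2[3] = 1.0
        assert verify_maternity(h, h2) == "inconsistent"

    def test_all_missing_untestable(self):
        assert verify_maternity(np.full(15, np.nan), np.zeros(15)) == "untestable"


def _study(clean=True, **kwargs):
    from introgress_stock.simulate import EffectConfig

    cfg = EffectConfig(genotyping_error_rate=0.0, missing_rate=0.0) if clean else EffectConfig()
    return simulate_crosses(cfg, **kwargs)


class TestAssignment:
    def test_perfect_data_assigns_true_parents(self):
        study = _study(n_pairs=15, seed=51)
        asg = assign_all(
            study.offspring, study.offspring_genotypes,
            study.broodstock, study.broodstock_genotypes,
            study.offspring_mt, study.broodstock_mt,
        )
        assert (asg["status"] == "assigned").all()
        truth = study.offspring.set_index("individual_id")
        for row in asg.itertuples():
            assert row.dam_id == truth.loc[row.individual_id, "dam_id"]
            assert row.sire_id == truth.loc[row.individual_id, "sire_id"]
            assert row.mismatch_count == 0
            assert row.mt_consistent == "consistent"

    def test_high_missingness_excluded(self, panel):
        study = _study(n_pairs=4, seed=52)
        oid = study.offspring["individual_id"].iloc[0]
        g = study.offspring_genotypes.loc[oid].to_numpy().copy()
        g[:17] = np.nan  # 17/81 = 21% missing
        res = assign_offspring(
            oid, g, int(study.offspring["brood_year"].iloc[0]),
            study.broodstock, study.broodstock_genotypes,
        )
        assert res.status == "excluded_missingness"

    def test_duplicate_parents_tie_is_ambiguous(self):
        study = _study(n_pairs=4, seed=53)
        roster = study.broodstock.copy()
        geno = study.broodstock_genotypes.copy()
        # clone the true dam under a new id: two pairs now tie exactly
        oid = study.offspring["individual_id"].iloc[0]
        dam = study.offspring["dam_id"].iloc[0]
        clone = dam + "_copy"
        roster = pd.concat(
            [roster, roster[roster["individual_id"] == dam].assign(individual_id=clone)],
            ignore_index=True,
        )
        geno.loc[clone] = geno.loc[dam]
        res = assign_offspring(
            oid,
            study.offspring_genotypes.loc[oid].to_numpy(),
            int(study.offspring["brood_year"].iloc[0]),
            roster, geno,
        )
        assert res.status == "ambiguous"

    def test_unrelated_offspring_unassigned(self):
        study = _study(n_pairs=4, seed=54)
        rng = np.random.default_rng(0)
        fake = rng.integers(0, 3, 81).astype(float)
        res = assign_offspring(
            "stranger", fake, int(study.offspring["brood_year"].iloc[0]),
            study.broodstock, study.broodstock_genotypes, max_mismatch=2,
        )
        assert res.status == "unassigned"


class TestFamilyTable:
    def test_counts_match_generator_truth(self):
        study = _study(n_pairs=10, seed=55)
        asg = assign_all(
            study.offspring, study.offspring_genotypes,
            study.broodstock, study.broodstock_genotypes,
        )
        fam = build_family_table(asg, study.broodstock)
        merged = fam.merge(study.crosses, on=["dam_id", "sire_id"], suffixes=("", "_true"))
        assert (merged["n_offspring"] == merged["n_offspring_true"]).all()
        assert fam["n_offspring"].sum() == (asg["status"] == "assigned").sum()
        # pair introgression is the dam-sire average of the ancestry column
        np.testing.assert_allclose(
            merged["pair_introgression"],
            0.5 * (merged["dam_true_d"] + merged["sire_true_d"]),
        )

    def test_no_assignments_empty_table(self):
        asg = pd.DataFrame({"status": [], "dam_id": [], "sire_id": [],
                            "brood_year": [], "individual_id": []})
        assert build_family_table(asg).empty
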