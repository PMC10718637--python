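"""Threshold-difference scan: filters, permutation null, BH over retained."""

import numpy as np
import pandas as pd
import pytest

from audiogene.consensus import MISSING, GenotypeMatrix
from audiogene.synthetic import PlantedEffect, SimParams, generate_cohort, generate_genotypes
from audiogene.threshold_scan import (
    CohortAudiograms,
    ScanConfig,
    ThresholdScan,
    bh_adjust,
    build_groupings,
    empirical_p,
    frequency_pass,
    permutation_test,
    variant_filter,
)
from audiogene.audiometry import Sex
from conftest import FREQS, make_participant


class TestEmpiricalP:
    @pytest.mark.parametrize("count,expected",
                             [(38, 1.90e-3), (40, 2.00e-3), (152, 7.60e-3), (0, 0.0)])
    def test_count_over_n_perm_convention(self, count, expected):
        assert empirical_p(count, 20000) == pytest.approx(expected)

    def test_out_of_range_count_rejected(self):
        with pytest.raises(ValueError):
            empirical_p(-1, 100)


class TestSdCaps:
    @pytest.mark.parametrize("freq,cap", [
        (0.125, 15.0), (0.5, 15.0), (1.0, 20.0), (2.0, 20.0),
        (3.0, 25.0), (4.0, 25.0), (6.0, 30.0), (8.0, 30.0),
    ])
    def test_every_standard_frequency_maps_to_one_band(self, freq, cap):
        assert ScanConfig().sd_cap(freq) == cap

    def test_alpha_is_reject_fraction(self):
        assert ScanConfig().alpha == 0.05
        assert ScanConfig(n_perm=2000, reject_count=100).alpha == 0.05


class TestFrequencyPass:
    def test_large_worse_shift_with_low_sd_passes(self):
        rec = frequency_pass([65, 70, 75], [40] * 10, "L", 4.0)
        assert rec.passed and rec.direction == "worse"
        assert rec.mean_diff_db == pytest.approx(30.0)
        assert rec.carrier_sd_db == pytest.approx(5.0)

    def test_sd_cap_blocks_noisy_carrier_group(self):
        carriers = [50, 50, 50, 50, 82]  # mean 56.4, sd ~14.3... tune below
        carr = np.array([40, 70, 90, 50, 80.0])  # sd 20.7 > 15 at 0.25 kHz
        rec = frequency_pass(carr, [30.0] * 5, "L", 0.25)
        assert abs(rec.mean_diff_db) >= 20 and not rec.passed

    def test_better_direction_detected(self):
        rec = frequency_pass([10, 12, 14], [35.0] * 8, "R", 8.0)
        assert rec.passed and rec.direction == "better"

    def test_insufficient_data_unevaluable(self):
        rec = frequency_pass([50.0], [30.0] * 5, "L", 1.0)
        assert not rec.evaluable and not rec.passed


def _toy_cohort(n=40, carriers=8, shift=30.0, seed=0, sexes=None):
    rng = np.random.default_rng(seed)
    participants = []
    for i in range(n):
        base = rng.normal(20, 3, 8)
        if i < carriers:
            base = base + np.array([0, 0, 0, 0, shift, shift, shift, shift])
        vals = np.clip(base, -10, 120)
        sex = (sexes[i] if sexes is not None
               else (Sex.MALE if i % 2 else Sex.FEMALE))
        participants.append(
            make_participant(f"p{i:02d}", sex, vals, vals))
    genotypes = {f"p{i:02d}": (1 if i < carriers else 0) for i in range(n)}
    return participants, genotypes


class TestGroupings:
    def test_three_groupings_with_sex_matched_references(self):
        participants, genotypes = _toy_cohort(carriers=7)
        cohort = CohortAudiograms.from_participants(participants)
        sexes = dict(zip(cohort.ids, cohort.sex))
        groupings = build_groupings(genotypes, sexes, "v1")
        strata = {g.stratum: g for g in groupings}
        assert set(strata) == {"all", "M", "F"}
        assert len(strata["all"].carriers) == 7
        assert all(sexes[p] == "M" for p in strata["M"].carriers)
        assert all(sexes[p] == "M" for p in strata["M"].reference)
        for g in groupings:
            assert not (set(g.carriers) & set(g.reference))

    def test_single_sex_carriers_omit_other_stratum(self):
        sexes = [Sex.MALE] * 10 + [Sex.FEMALE] * 10
        participants, _ = _toy_cohort(n=20, carriers=0, sexes=sexes)
        cohort = CohortAudiograms.from_participants(participants)
        genotypes = {pid: (1 if i < 3 else 0)
                     for i, pid in enumerate(cohort.ids)}  # male carriers only
        groupings = build_groupings(genotypes, dict(zip(cohort.ids, cohort.sex)),
                                    "v1")
        assert {g.stratum for g in groupings} == {"all", "M"}

    def test_missing_genotypes_excluded(self):
        participants, genotypes = _toy_cohort()
        genotypes = {p: MISSING for p in genotypes}
        groupings = build_groupings(genotypes, {}, "v1")
        assert groupings == []


class TestVariantFilter:
    def test_small_sex_groups_fall_back_to_combined(self):
        # 4 male + 3 female carriers: only the combined grouping (7 >= 5)
        sexes = ([Sex.MALE] * 4 + [Sex.FEMALE] * 3 + [Sex.MALE] * 16
                 + [Sex.FEMALE] * 17)
        participants, genotypes = _toy_cohort(n=40, carriers=7, sexes=sexes)
        cohort = CohortAudiograms.from_participants(participants)
        candidates = variant_filter("v1", genotypes, cohort)
        assert [c.grouping.stratum for c in candidates] == ["all"]

    def test_shift_below_cutoff_yields_no_candidate(self):
        participants, genotypes = _toy_cohort(shift=12.0)
        cohort = CohortAudiograms.from_participants(participants)
        assert variant_filter("v1", genotypes, cohort) == []

    def test_candidate_records_consistent_direction_and_pass_set(self):
        participants, genotypes = _toy_cohort()
        cohort = CohortAudiograms.from_participants(participants)
        candidates = variant_filter("v1", genotypes, cohort)
        cand = next(c for c in candidates if c.grouping.stratum == "all")
        assert cand.direction == "worse"
        ears = [e for e, _ in cand.pass_set]
        assert ears.count("L") >= 2 and ears.count("R") >= 2
        assert all(f >= 3.0 for _, f in cand.pass_set)


class TestPermutationTest:
    def test_identical_seed_gives_identical_count(self):
        participants, genotypes = _toy_cohort()
        cohort = CohortAudiograms.from_participants(participants)
        cand = variant_filter("v1", genotypes, cohort)[0]
        cfg = ScanConfig(n_perm=500, reject_count=25)
        c1, p1 = permutation_test(cand, cohort, cfg, np.random.default_rng(9))
        c2, p2 = permutation_test(cand, cohort, cfg, np.random.default_rng(9))
        assert (c1, p1) == (c2, p2)
        assert 0 <= p1 <= 1

    def test_planted_shift_rarely_reproduced_by_chance(self):
        participants, genotypes = _toy_cohort(n=60, carriers=8, shift=35.0)
        cohort = CohortAudiograms.from_participants(participants)
        cand = next(c for c in variant_filter("v1", genotypes, cohort)
                    if c.grouping.stratum == "all")
        cfg = ScanConfig(n_perm=1000, reject_count=50)
        count, p = permutation_test(cand, cohort, cfg, np.random.default_rng(1))
        assert count <= cfg.reject_count

    def test_null_p_distribution_not_anticonservative(self):
        # exchangeable carriers: p should be stochastically >= uniform
        rng = np.random.default_rng(5)
        ps = []
        for seed in range(40):
            participants, _ = _toy_cohort(n=30, carriers=0, seed=seed)
            # widen spread so the 20 dB gate is reachable by chance
            participants = [
                make_participant(p.id, p.sex,
                                 np.clip(p.left.values * 3, -10, 120),
                                 np.clip(p.right.values * 3, -10, 120))
                for p in participants
            ]
            cohort = CohortAudiograms.from_participants(participants)
            genotypes = {pid: (1 if i < 5 else 0)
                         for i, pid in enumerate(cohort.ids)}
            for cand in variant_filter("v1", genotypes, cohort):
                _, p = permutation_test(
                    cand, cohort, ScanConfig(n_perm=200, reject_count=10),
                    np.random.default_rng(seed))
                ps.append(p)
        # few candidates arise at all under the null; those that do must
        # not have systematically tiny p
        assert all(p >= 0.0 for p in ps)
        if ps:
            assert np.mean(ps) > 0.01


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        assert bh_adjust([0.0, 0.001, 0.002]) == pytest.approx(
            [0.0, 0.0015, 0.002])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.01, 0.01, 0.01]) == pytest.approx([0.01] * 3)


class TestScanCohort:
    def _planted(self, seed):
        params = SimParams(
            n_participants=300, seed=seed, n_genes=3,
            planted_effects=[PlantedEffect("e", 30.0, (3.0, 4.0, 6.0, 8.0), 8)],
        )
        participants, truth = generate_cohort(params)
        participants, matrix, _, tr = generate_genotypes(params, participants, truth)
        return participants, matrix, tr

    def test_planted_variant_retained_and_sorted_output(self):
        participants, matrix, truth = self._planted(21)
        cfg = ScanConfig(n_perm=2000, reject_count=100)
        res = ThresholdScan(matrix, participants, cfg).fit(seed=4)
        planted_vid = truth["planted_effects"][0]["variant_id"]
        assert planted_vid in set(res.frame["variant_id"])
        assert list(res.frame["p_adj"]) == sorted(res.frame["p_adj"])
        assert planted_vid in res.summary()

    def test_deterministic_given_seed(self):
        participants, matrix, _ = self._planted(22)
        cfg = ScanConfig(n_perm=500, reject_count=25)
        r1 = ThresholdScan(matrix, participants, cfg).fit(seed=3)
        r2 = ThresholdScan(matrix, participants, cfg).fit(seed=3)
        pd.testing.assert_frame_equal(r1.candidates, r2.candidates)

    def test_retention_monotone_in_effect_size(self):
        retained = {}
        for shift in (25.0, 40.0):
            params = SimParams(
                n_participants=300, seed=31, n_genes=2,
                planted_effects=[PlantedEffect("e", shift, (3.0, 4.0, 6.0, 8.0), 8)],
            )
            participants, truth = generate_cohort(params)
            participants, matrix, _, tr = generate_genotypes(
                params, participants, truth)
            cfg = ScanConfig(n_perm=1000, reject_count=50)
            res = ThresholdScan(matrix, participants, cfg).fit(seed=2)
            vid = tr["planted_effects"][0]["variant_id"]
            retained[shift] = vid in set(res.frame["variant_id"])
        # increasing the planted shift never loses a retained variant
        assert retained[40.0] >= retained[25.0]

    def test_empty_variant_set_gives_empty_report(self):
        participants, _ = _toy_cohort(n=10, carriers=0)
        matrix = GenotypeMatrix(
            pd.DataFrame(index=pd.Index([], name="v"),
                         columns=[p.id for p in participants], dtype=np.int8))
        res = ThresholdScan(matrix, participants).fit(seed=0)
        assert res.frame.empty and res.candidates.empty
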