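"""Per-gene load counting, outlier regression and enrichment."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from audiogene.consensus import MISSING, GenotypeMatrix
from audiogene.variant_load import (
    ComparisonPlan,
    VariantLoadModel,
    adjust_pvalues,
    count_variants_per_gene,
    enrichment_test,
    regress_and_flag,
    run_comparisons,
)


def bh_stepup_oracle(p):
    """Direct implementation of the BH step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def hypergeom_enum_oracle(universe, gene_set, outlier_list):
    """Exhaustive enumeration over all possible draws of the outlier list."""
    universe = sorted(universe)
    k = len(outlier_list)
    observed = len(set(outlier_list) & set(gene_set) & set(universe))
    successes = set(gene_set) & set(universe)
    hits = sum(
        1 for draw in itertools.combinations(universe, k)
        if len(set(draw) & successes) >= observed
    )
    return hits / comb(len(universe), k)


def outlier_oracle(x, y, multiplier=6.0):
    """Independent OLS (numpy.polyfit) + quartile scan of residuals."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    q1, q3 = np.percentile(resid, [25, 75])
    d = q3 - q1
    return resid > q3 + multiplier * d, resid < q1 - multiplier * d


def _matrix(codes: dict, participants):
    return GenotypeMatrix(pd.DataFrame(codes, index=participants).T)


class TestCountVariants:
    def setup_method(self):
        self.participants = ["a", "b", "c"]
        self.matrix = _matrix({"1:100:A:G": [1, 2, 0]}, self.participants)
        self.ann = pd.DataFrame(
            {"variant_id": ["1:100:A:G"], "gene_id": ["G1"],
             "impact_class": ["high"], "ref_maf": [0.01]}
        ).set_index("variant_id")

    def test_allele_vs_carrier_dosage(self):
        groups = {"g": self.participants}
        allele = count_variants_per_gene(self.matrix, self.ann, groups, "allele")
        carrier = count_variants_per_gene(self.matrix, self.ann, groups, "carrier")
        assert allele.loc["G1", "g"] == 3
        assert carrier.loc["G1", "g"] == 2

    def test_empty_group_gives_zero_column(self):
        counts = count_variants_per_gene(self.matrix, self.ann, {"empty": []})
        assert (counts["empty"] == 0).all()

    def test_missing_genotypes_contribute_zero(self):
        matrix = _matrix({"1:100:A:G": [1, MISSING, MISSING]}, self.participants)
        counts = count_variants_per_gene(matrix, self.ann,
                                         {"g": self.participants})
        assert counts.loc["G1", "g"] == 1

    def test_unannotated_variant_excluded_with_warning(self):
        matrix = _matrix({"1:100:A:G": [1, 0, 0], "1:200:A:G": [2, 2, 2]},
                         self.participants)
        with pytest.warns(UserWarning, match="gene assignment"):
            counts = count_variants_per_gene(matrix, self.ann,
                                             {"g": self.participants})
        assert list(counts.index) == ["G1"]

    def test_planted_dosages_match_hand_computed_table(self):
        matrix = _matrix(
            {"1:100:A:G": [1, 2, 0], "1:110:A:G": [0, 1, 1],
             "2:200:A:G": [2, 0, MISSING]},
            self.participants,
        )
        ann = pd.DataFrame(
            {"variant_id": ["1:100:A:G", "1:110:A:G", "2:200:A:G"],
             "gene_id": ["G1", "G1", "G2"],
             "impact_class": ["high"] * 3, "ref_maf": [0.01] * 3}
        ).set_index("variant_id")
        counts = count_variants_per_gene(
            matrix, ann, {"ab": ["a", "b"], "c": ["c"]})
        assert counts.loc["G1", "ab"] == 4   # (1+2) + (0+1)
        assert counts.loc["G1", "c"] == 1
        assert counts.loc["G2", "ab"] == 2
        assert counts.loc["G2", "c"] == 0


class TestOutlierRegression:
    def test_perfect_fit_yields_no_outliers(self):
        x = pd.Series(np.arange(10, 60, 5), index=[f"g{i}" for i in range(10)])
        res = regress_and_flag(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.iqr == pytest.approx(0.0)
        assert res.outliers().empty

    def test_single_inflated_gene_flagged_and_matches_oracle(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(200)]
        x = pd.Series(rng.poisson(20, 200).astype(float), index=genes)
        y = pd.Series(
            (1.5 * x + rng.normal(0, 2, 200)).round().clip(lower=0), index=genes)
        y["g42"] += 50
        res = regress_and_flag(x, y)
        assert res.high_in_y == ["g42"]
        hi, lo = outlier_oracle(x.to_numpy(), y.to_numpy())
        assert set(np.array(genes)[hi]) == set(res.high_in_y)
        assert set(np.array(genes)[lo]) == set(res.high_in_x)

    def test_swapping_groups_swaps_direction(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(100)]
        x = pd.Series(rng.poisson(30, 100).astype(float), index=genes)
        y = x.copy()
        y["g5"] += 40
        fwd = regress_and_flag(x, y)
        rev = regress_and_flag(y, x)
        assert fwd.high_in_y == ["g5"]
        assert rev.high_in_x == ["g5"]

    def test_flags_invariant_to_order_and_common_scale(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(80)]
        x = pd.Series(rng.poisson(15, 80).astype(float), index=genes)
        y = pd.Series(x + rng.normal(0, 1, 80), index=genes)
        y["g9"] += 30
        base = regress_and_flag(x, y)
        perm = rng.permutation(genes)
        shuffled = regress_and_flag(x.loc[perm], y.loc[perm])
        assert set(base.high_in_y) == set(shuffled.high_in_y)
        scaled = regress_and_flag(3.0 * x, 3.0 * y)
        assert set(base.high_in_y) == set(scaled.high_in_y)

    def test_degenerate_inputs_raise(self):
        idx = ["a", "b", "c"]
        const = pd.Series([5.0, 5.0, 5.0], index=idx)
        var = pd.Series([1.0, 2.0, 3.0], index=idx)
        with pytest.raises(ValueError, match="constant"):
            VariantLoadModel(const, var)
        with pytest.raises(ValueError, match="3 genes"):
            VariantLoadModel(var[:2], var[:2])


class TestEnrichment:
    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = enrichment_test(universe[:3], universe[8:], universe)
        assert res["overlap"] == 0 or res["p"] == 1.0
        assert enrichment_test(universe[:3], ["absent"], universe)["p"] == 1.0

    def test_matches_enumeration_oracle(self):
        universe = [f"g{i}" for i in range(10)]
        gene_set = universe[:4]
        outliers = universe[:4] + [universe[7]]
        res = enrichment_test(outliers, gene_set, universe)
        assert res["overlap"] == 4
        assert res["p"] == pytest.approx(
            hypergeom_enum_oracle(universe, gene_set, outliers), rel=1e-9)

    def test_matches_enumeration_for_all_small_universes(self):
        for usize in range(2, 13):
            universe = [f"g{i}" for i in range(usize)]
            for set_size in (1, usize // 2, usize - 1):
                for list_size in (1, usize // 2):
                    gene_set = universe[:set_size]
                    outliers = universe[-list_size:]
                    res = enrichment_test(outliers, gene_set, universe)
                    assert res["p"] == pytest.approx(
                        hypergeom_enum_oracle(universe, gene_set, outliers),
                        rel=1e-9)

    def test_list_equal_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(6)]
        res = enrichment_test(universe, universe[:3], universe)
        assert res["overlap"] == 3
        assert res["p"] == pytest.approx(1.0)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            enrichment_test([], ["g"], [])


class TestAdjustPvalues:
    def test_bh_hand_computed_example(self):
        out = adjust_pvalues([0.01, 0.02, 0.03])
        assert out == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_one(self):
        assert adjust_pvalues([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 20))
            assert adjust_pvalues(p) == pytest.approx(bh_stepup_oracle(p),
                                                      rel=1e-12)

    def test_bonferroni_and_none(self):
        p = [0.01, 0.4]
        assert adjust_pvalues(p, "bonferroni") == pytest.approx([0.02, 0.8])
        assert adjust_pvalues(p, "none") == pytest.approx(p)


class TestRunComparisons:
    def _setup(self, rng, n=120, n_genes=40, planted_gene="G0005"):
        labels = pd.DataFrame(
            {
                "label": rng.choice(["OlderNormal", "Metabolic", "Sensory"],
                                    n, p=[0.3, 0.35, 0.35]),
                "sex": rng.choice(["M", "F"], n),
            },
            index=[f"p{i}" for i in range(n)],
        )
        genes = [f"G{i:04d}" for i in range(n_genes)]
        codes, ann_rows = {}, []
        sens = (labels["label"] == "Sensory").to_numpy()
        for gi, gene in enumerate(genes):
            for v in range(2):
                vid = f"1:{1000 + 10 * (2 * gi + v)}:A:G"
                p_carrier = 0.05
                probs = np.full(n, p_carrier)
                if gene == planted_gene:
                    probs[sens] = min(8 * p_carrier, 1.0)
                codes[vid] = (rng.random(n) < probs).astype(np.int8)
                ann_rows.append({"variant_id": vid, "gene_id": gene,
                                 "impact_class": "high", "ref_maf": 0.01})
        matrix = GenotypeMatrix(pd.DataFrame(codes, index=labels.index).T)
        ann = pd.DataFrame(ann_rows).set_index("variant_id")
        return labels, matrix, ann

    def test_planted_gene_appears_in_high_sensory_list(self):
        labels, matrix, ann = self._setup(np.random.default_rng(2))
        out = run_comparisons(labels, matrix, ann, min_group_size=10)
        res = out["results"]["OlderNormal_vs_Sensory_all"]
        assert "G0005" in res.high_in_y
        assert "G0005" in out["combined_candidates"].index

    def test_small_stratum_skipped_with_warning(self, caplog):
        labels, matrix, ann = self._setup(np.random.default_rng(2))
        plan = [ComparisonPlan("tiny", "OlderNormal", "Sensory", "M")]
        out = run_comparisons(labels, matrix, ann, plan=plan, min_group_size=1000)
        assert out["skipped"] == ["tiny"]
        assert out["results"] == {}

    def test_combined_list_deduplicates_with_provenance(self):
        labels, matrix, ann = self._setup(np.random.default_rng(2))
        out = run_comparisons(labels, matrix, ann, min_group_size=10)
        combined = out["combined_candidates"]
        assert combined.index.is_unique
        row = combined.loc["G0005"]
        assert row["n_comparisons"] == len(row["comparisons"].split(";"))

    def test_unknown_label_in_plan_raises(self):
        labels, matrix, ann = self._setup(np.random.default_rng(2))
        plan = [ComparisonPlan("bad", "Nonexistent", "Sensory")]
        with pytest.raises(ValueError, match="unknown"):
            run_comparisons(labels, matrix, ann, plan=plan)

    def test_enrichment_table_covers_gene_sets(self):
        labels, matrix, ann = self._setup(np.random.default_rng(2))
        out = run_comparisons(
            labels, matrix, ann, min_group_size=10,
            gene_sets={"planted": ["G0005"], "random": ["G0001", "G0002"]},
        )
        enr = out["enrichment"]
        assert set(enr["gene_set_id"]) == {"planted", "random"}
        assert (enr["p_adj"] >= enr["p"] - 1e-12).all()
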