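import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bescreen.fitness_scoring import (
    ControlBounds,
    category_comparisons,
    compute_lfc,
    control_bounds,
    depletion_enrichment_test,
    empirical_pvalues,
    roc_auc,
    tier_hits,
)
from bescreen.library_io import SampleMeta, ValidationError
from bescreen.screen_counts import NormalizedCounts
from oracles import fisher_greater, pairwise_auc

SAMPLES = [
    SampleMeta("T0_R1", "CL1", "T0", 1),
    SampleMeta("T0_R2", "CL1", "T0", 2),
    SampleMeta("T38_R1", "CL1", "TEND", 1),
    SampleMeta("T38_R2", "CL1", "TEND", 2),
]


def make_norm(t0_r1, t0_r2, tend_r1, tend_r2):
    n = len(t0_r1)
    values = pd.DataFrame(
        {"T0_R1": t0_r1, "T0_R2": t0_r2, "T38_R1": tend_r1, "T38_R2": tend_r2},
        index=[f"g{i}" for i in range(n)],
    )
    return NormalizedCounts(values=values, samples=SAMPLES,
                            genes=pd.Series("X", index=values.index))


class TestComputeLfc:
    def test_equal_abundance_gives_zero(self):
        norm = make_norm([1.0], [1.0], [1.0], [1.0])
        fit = compute_lfc(norm)
        assert fit["lfc"].iloc[0] == pytest.approx(0.0)

    def test_epsilon_regularized_values(self):
        norm = make_norm([1.0, 1.0], [1.0, 1.0], [0.0, 2.0], [0.0, 2.0])
        fit = compute_lfc(norm, epsilon=0.05)
        assert fit["lfc"].iloc[0] == pytest.approx(math.log2(0.05 / 1.05), abs=1e-9)
        assert fit["lfc"].iloc[1] == pytest.approx(math.log2(2.05 / 1.05), abs=1e-9)

    def test_swapping_timepoints_negates_lfc(self):
        rng = np.random.default_rng(0)
        vals = [rng.uniform(0.1, 3.0, 8) for _ in range(4)]
        fwd = compute_lfc(make_norm(*vals))
        rev = compute_lfc(make_norm(vals[2], vals[3], vals[0], vals[1]))
        assert np.allclose(fwd["lfc"], -rev["lfc"])

    def test_unpaired_replicate_is_error(self):
        values = pd.DataFrame({"T0_R1": [1.0], "T38_R2": [1.0]}, index=["g0"])
        norm = NormalizedCounts(values=values, samples=[SAMPLES[0], SAMPLES[3]],
                                genes=pd.Series("X", index=values.index))
        with pytest.raises(ValidationError, match="pair"):
            compute_lfc(norm)


class TestControlBounds:
    def test_linear_interpolation_quantiles(self):
        lfc = pd.Series([-2.0, -1.0, 0.0, 1.0, 2.0],
                        index=[f"n{i}" for i in range(5)])
        with pytest.warns(UserWarning):
            b = control_bounds(lfc, lfc.index, q=0.2)
        assert b.lo == pytest.approx(np.quantile(lfc.values, 0.2))
        assert b.lo == pytest.approx(-1.2)
        assert b.hi == pytest.approx(1.2)

    def test_degenerate_controls_give_zero_width(self):
        lfc = pd.Series(np.zeros(30), index=[f"n{i}" for i in range(30)])
        b = control_bounds(lfc, lfc.index)
        assert (b.lo, b.hi) == (0.0, 0.0)

    def test_q_half_collapses_to_median(self):
        vals = np.arange(25.0)
        lfc = pd.Series(vals, index=[f"n{i}" for i in range(25)])
        b = control_bounds(lfc, lfc.index, q=0.5)
        assert b.lo == b.hi == pytest.approx(np.median(vals))


class TestEmpiricalPvalues:
    def test_value_below_all_99_negatives(self):
        neg = pd.Series(np.linspace(-1, 1, 99), index=[f"n{i}" for i in range(99)])
        lfc = pd.concat([neg, pd.Series({"g": -5.0})])
        p = empirical_pvalues(lfc, neg.index)
        assert p["g"] == pytest.approx(2 * 1 / 100)

    def test_central_value_capped_at_one(self):
        neg = pd.Series(np.linspace(-1, 1, 101), index=[f"n{i}" for i in range(101)])
        lfc = pd.concat([neg, pd.Series({"g": 0.0})])
        assert empirical_pvalues(lfc, neg.index)["g"] == 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=-10, max_value=10, allow_nan=False))
    def test_symmetric_negatives_give_symmetric_p(self, x):
        base = np.linspace(0.1, 3.0, 40)
        neg = pd.Series(np.concatenate([base, -base]),
                        index=[f"n{i}" for i in range(80)])
        lfc = pd.concat([neg, pd.Series({"a": x, "b": -x})])
        p = empirical_pvalues(lfc, neg.index)
        assert p["a"] == pytest.approx(p["b"])


class TestTiers:
    BOUNDS = ControlBounds(lo=-0.66, hi=0.73)

    @pytest.mark.parametrize(
        "lfc, p, expected",
        [
            (-1.5, 0.005, "high_priority"),
            (-1.5, 0.03, "low_priority"),
            (0.1, 0.001, "none"),
            (1.5, 0.2, "none"),
        ],
    )
    def test_tier_rules(self, lfc, p, expected):
        tiers = tier_hits(pd.Series([lfc]), pd.Series([p]), self.BOUNDS)
        assert tiers.iloc[0] == expected


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([5, 6, 7], [1, 2, 3])
        assert r.auc == 1.0
        assert r.fpr[0] == 0.0 and r.tpr[-1] == 1.0

    def test_identical_distributions_give_half(self):
        r = roc_auc([1, 2, 3], [1, 2, 3])
        assert r.auc == pytest.approx(0.5)

    def test_interleaved_example(self):
        assert roc_auc([1, 3], [2]).auc == pytest.approx(0.5)

    def test_complement_identity(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 15)
        assert roc_auc(a, b).auc + roc_auc(b, a).auc == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        assert roc_auc(np.exp(a), np.exp(b)).auc == pytest.approx(roc_auc(a, b).auc)

    def test_depletion_direction_negates_scores(self):
        a, b = [-3.0, -2.5], [0.0, 0.2]  # depleted positives
        assert roc_auc(a, b, score_direction="lower_is_positive").auc == 1.0

    def test_empty_side_is_error(self):
        with pytest.raises(ValidationError):
            roc_auc([], [1.0])


class TestDepletionEnrichment:
    def test_complete_separation_matches_combinatorics(self):
        lfc = pd.Series(
            [-2.0] * 5 + [0.0] * 5,
            index=[f"c{i}" for i in range(5)] + [f"r{i}" for i in range(5)],
        )
        bounds = ControlBounds(lo=-1.0, hi=1.0)
        res = depletion_enrichment_test(lfc, [f"c{i}" for i in range(5)],
                                        [f"r{i}" for i in range(5)], bounds)
        assert res.p_value == pytest.approx(1 / math.comb(10, 5))

    def test_equal_rates_are_not_enriched(self):
        lfc = pd.Series(
            [-2.0, 0.0] * 10,
            index=[f"g{i}" for i in range(20)],
        )
        cat = [f"g{i}" for i in range(0, 10)]
        ref = [f"g{i}" for i in range(10, 20)]
        res = depletion_enrichment_test(lfc, cat, ref, ControlBounds(lo=-1.0, hi=1.0))
        assert res.p_value >= 0.5

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_cat, n_ref = rng.integers(2, 15, 2)
            lfc_vals = rng.normal(0, 1, n_cat + n_ref)
            ids = [f"g{i}" for i in range(n_cat + n_ref)]
            lfc = pd.Series(lfc_vals, index=ids)
            bounds = ControlBounds(lo=-0.5, hi=0.5)
            res = depletion_enrichment_test(lfc, ids[:n_cat], ids[n_cat:], bounds)
            table = [[res.k_category_depleted, res.n_category - res.k_category_depleted],
                     [res.k_reference_depleted, res.n_reference - res.k_reference_depleted]]
            if res.k_category_depleted + res.k_reference_depleted == 0:
                continue
            assert res.p_value == pytest.approx(fisher_greater(table), rel=1e-9)


class TestCategoryComparisons:
    def _meta(self):
        idx = [f"g{i}" for i in range(8)]
        return pd.DataFrame(
            {
                "control_class": ["istop_control", "istop_control", "aavs1_control",
                                  "aavs1_control", "nontargeting_control",
                                  "empty_window_control", "targeting", "targeting"],
                "category": ["nonsense", "nonsense", "NA", "NA", "NA",
                             "empty_window", "nonsense", "synonymous"],
                "clinical_class": ["NA"] * 8,
                "gene": [None, None, "AAVS1", "AAVS1", None, "E1", "E1", "E1"],
                "on_target_score": [0.9, 0.3, 0.5, 0.5, 0.5, 0.5, 0.8, 0.8],
            },
            index=idx,
        )

    def _fitness(self):
        return pd.DataFrame({"lfc": [-2, -1.8, 0, 0.1, -0.1, 0.05, -2.2, 0.0]},
                            index=[f"g{i}" for i in range(8)])

    def test_high_score_filter_drops_low_score_positives(self):
        report = category_comparisons(self._fitness(), self._meta(), ["E1"])
        assert report["istop_vs_aavs1"]["n_positive"] == 2
        assert report["istop_vs_aavs1_high_score"]["n_positive"] == 1

    def test_depleted_positives_score_high_auc(self):
        report = category_comparisons(self._fitness(), self._meta(), ["E1"])
        assert report["istop_vs_aavs1"]["auc"] == 1.0
        assert report["lof_vs_neutral_essential"]["auc"] == 1.0

    def test_missing_clinical_classes_skip_contrast(self):
        with pytest.warns(UserWarning, match="plp_vs_blb"):
            report = category_comparisons(self._fitness(), self._meta(), ["E1"])
        assert "plp_vs_blb_essential" not in report


class TestAucAgainstPairwiseOracle:
    def test_fifty_random_instances_match_midrank_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n, m = rng.integers(2, 25, 2)
            pos = np.round(rng.normal(0.5, 1, n), 1)  # rounding forces ties
            neg = np.round(rng.normal(0, 1, m), 1)
            assert roc_auc(pos, neg).auc == pytest.approx(
                pairwise_auc(pos, neg), abs=1e-12)
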