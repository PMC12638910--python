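import numpy as np
import pytest

from eegstages.stats import (
    ComparisonPlan, HEMISPHERES, cohens_d, posthoc_power, power_from_d,
    ranksum, run_comparisons,
)
from eegstages.synth import make_feature_dataset

from helpers import exact_ranksum_p, power_by_quadrature


class TestRanksum:
    def test_fully_separated_small_groups(self):
        r = ranksum([1, 2, 3], [4, 5, 6])
        assert r.U == 0
        assert r.p == pytest.approx(0.1)  # 2/20 by exhaustive labeling
        assert r.method == "exact"
        assert r.rank_biserial == pytest.approx(-1.0)

    def test_identical_multisets_give_p_one(self):
        r = ranksum([1.0, 1.0, 2.0], [2.0, 1.0, 1.0])
        assert r.p == 1.0

    def test_degenerate_constant_groups(self):
        r = ranksum([3.0, 3.0], [3.0, 3.0, 3.0])
        assert r.p == 1.0
        assert r.method == "degenerate"

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 5), (5, 5), (6, 6)])
    def test_exact_mode_matches_enumeration_oracle(self, n1, n2, rng):
        for _ in range(5):
            x = rng.normal(size=n1)
            y = rng.normal(0.5, size=n2)
            r = ranksum(x, y)
            assert r.method == "exact"
            assert r.p == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)

    def test_asymptotic_mode_for_large_or_tied_samples(self, rng):
        r = ranksum(rng.normal(size=30), rng.normal(size=30))
        assert r.method == "asymptotic"
        r2 = ranksum([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert r2.method == "asymptotic"  # ties forbid exact enumeration

    def test_invariance_under_monotone_transform(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(1.0, size=9)
        p_raw = ranksum(x, y).p
        p_exp = ranksum(np.exp(x), np.exp(y)).p
        assert p_raw == pytest.approx(p_exp, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ranksum([], [1.0])


class TestPosthocPower:
    def test_cohens_d_definition(self):
        x = np.array([-1.0, 0.0, 1.0]) + 0.0
        y = np.array([-1.0, 0.0, 1.0]) + 1.0
        assert cohens_d(x, y) == pytest.approx(-1.0)

    def test_power_matches_quadrature_oracle(self):
        for d, n in [(0.5, 20), (1.0, 30), (1.5, 10)]:
            assert power_from_d(d, n, n) == pytest.approx(
                power_by_quadrature(d, n, n), abs=1e-3)

    def test_null_effect_power_is_alpha(self):
        assert power_from_d(0.0, 30, 30, alpha=0.05) == pytest.approx(
            0.05, abs=1e-6)

    def test_zero_pooled_sd_flagged_as_nan(self):
        d, power = posthoc_power([1.0, 1.0], [1.0, 1.0])
        assert np.isnan(d) and np.isnan(power)

    def test_rejection_rate_tracks_predicted_power(self):
        # Gaussian shift d = 1: rank-sum rejections should land close to
        # the t-test power prediction (the tests are asymptotically close)
        rng = np.random.default_rng(7)
        n, d = 30, 1.0
        predicted = power_from_d(d, n, n)
        hits = sum(ranksum(rng.normal(size=n), rng.normal(d, size=n)).p < 0.05
                   for _ in range(400))
        assert hits / 400 == pytest.approx(predicted, abs=0.05)


class TestRunComparisons:
    def test_planted_stage_shift_detected_only_where_planted(self):
        # stage-dependent alpha trend in the lab task at a strong effect
        df = make_feature_dataset(n_per_stage=60, effect_size=1.5, seed=21,
                                  task="lab")
        table = run_comparisons(df, ComparisonPlan(measures=("alpha",)))
        assert len(table) == 3
        extreme = table[table["contrast"] == "stage1 vs stage3"]
        assert (extreme["p"] < 0.001).all()
        assert (table["d"].abs() > 0.5).any()

    def test_hemisphere_split_of_symmetric_generator(self):
        df = make_feature_dataset(n_per_stage=50, effect_size=1.0, seed=4)
        plan = ComparisonPlan(measures=("alpha",), regions=("left", "right"))
        table = run_comparisons(df, plan)
        left = table[table["region"] == "left"].set_index("contrast")
        right = table[table["region"] == "right"].set_index("contrast")
        # generator trends are hemisphere-symmetric: same significance calls
        extreme = "stage1 vs stage3"
        assert (left.loc[extreme, "p"] < 0.05) == \
               (right.loc[extreme, "p"] < 0.05)

    def test_missing_level_contrast_skipped(self, caplog):
        df = make_feature_dataset(n_per_stage=10, effect_size=0.0, seed=1,
                                  stages=(1, 2))
        table = run_comparisons(df, ComparisonPlan(measures=("alpha",)))
        assert len(table) == 1
        assert table.iloc[0]["contrast"] == "stage1 vs stage2"

    def test_stars_convention(self):
        df = make_feature_dataset(n_per_stage=60, effect_size=2.0, seed=2)
        table = run_comparisons(df, ComparisonPlan(measures=("alpha",)))
        for _, row in table.iterrows():
            expected = ("***" if row.p < 0.001 else
                        "**" if row.p < 0.01 else
                        "*" if row.p < 0.05 else "")
            assert row.stars == expected

    def test_fdr_column_optional_and_monotone(self):
        df = make_feature_dataset(n_per_stage=30, effect_size=1.0, seed=3)
        plain = run_comparisons(df, ComparisonPlan(measures=("alpha",)))
        assert "p_adj" not in plain.columns
        adj = run_comparisons(df, ComparisonPlan(measures=("alpha",)),
                              fdr=True)
        assert (adj["p_adj"] >= adj["p"] - 1e-12).all()

    def test_amplitude_measure_resolves_channels(self):
        df = make_feature_dataset(n_per_stage=10, effect_size=0.0, seed=5)
        table = run_comparisons(df, ComparisonPlan(measures=("amplitude",)))
        assert len(table) == 3


def test_hemisphere_sets_partition_montage():
    assert set(HEMISPHERES["left"]) | set(HEMISPHERES["right"]) == \
        set(HEMISPHERES["whole"])
    assert not set(HEMISPHERES["left"]) & set(HEMISPHERES["right"])
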