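"""Learner metrics, interaction tests, training curves, traits, group stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import make_test_trial, make_training_trial, mixed_anova_interaction_F
from pstlearn.behavior import (
    compute_learner_metrics,
    fit_training_curves,
    group_stats,
    interaction_test,
    score_traits,
)


def _test_log(a_hits, a_total, b_rejects, b_total, pid="p"):
    """Test trials with the requested select-A and reject-B counts."""
    trials = []
    i = 0
    a_pairs = ["AC", "AD", "AE", "AF"]
    b_pairs = ["BC", "BD", "BE", "BF"]
    for k in range(a_total):
        chosen = "A" if k < a_hits else a_pairs[k % 4][1]
        trials.append(make_test_trial(pid, i, a_pairs[k % 4], chosen)); i += 1
    for k in range(b_total):
        chosen = b_pairs[k % 4][1] if k < b_rejects else "B"
        trials.append(make_test_trial(pid, i, b_pairs[k % 4], chosen)); i += 1
    return trials


class TestLearnerMetrics:
    @pytest.mark.parametrize(
        "a_hits,b_rejects,expected_class",
        [
            (29, 22, "approach"),   # 0.906 vs 0.688: approach-learner profile
            (23, 26, "avoidance"),  # 0.719 vs 0.813: avoidance-learner profile
            (24, 24, "avoidance"),  # exact tie -> avoidance by the strict rule
        ],
    )
    def test_classification(self, a_hits, b_rejects, expected_class):
        m = compute_learner_metrics(_test_log(a_hits, 32, b_rejects, 32))
        assert m.select_a_rate == pytest.approx(a_hits / 32)
        assert m.reject_b_rate == pytest.approx(b_rejects / 32)
        assert m.learner_class == expected_class

    def test_missing_pair_type_raises(self):
        trials = _test_log(5, 8, 0, 0)
        with pytest.raises(ValueError, match="A- and B-pairs"):
            compute_learner_metrics(trials)

    def test_order_invariance(self):
        trials = _test_log(20, 32, 12, 32)
        m0 = compute_learner_metrics(trials)
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = [trials[j] for j in rng.permutation(len(trials))]
            m = compute_learner_metrics(shuffled)
            assert (m.select_a_rate, m.reject_b_rate) == (m0.select_a_rate, m0.reject_b_rate)


class TestInteractionTest:
    def test_identical_difference_distributions(self):
        base = np.column_stack([np.linspace(0, 1, 10), np.linspace(0.2, 1.2, 10)])
        t, df, p = interaction_test(base, base.copy())
        assert t == pytest.approx(0.0, abs=1e-12)
        assert df == 18

    def test_equals_mixed_anova_interaction(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            g1 = rng.normal(size=(int(rng.integers(3, 9)), 2))
            g2 = rng.normal(size=(int(rng.integers(3, 9)), 2))
            t, _, _ = interaction_test(g1, g2)
            assert t**2 == pytest.approx(mixed_anova_interaction_F(g1, g2), abs=1e-8)

    def test_power_for_crossover(self):
        # crossover of 0.2 with SD 0.1 at n=15 per group is detected at
        # p < 0.01 in nearly every replicate
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(100):
            g1 = np.column_stack(
                [rng.normal(0.8, 0.1, 15), rng.normal(0.6, 0.1, 15)]
            )
            g2 = np.column_stack(
                [rng.normal(0.6, 0.1, 15), rng.normal(0.8, 0.1, 15)]
            )
            _, _, p = interaction_test(g1, g2)
            hits += p < 0.01
        assert hits >= 90

    def test_small_group_raises(self):
        g = np.zeros((1, 2))
        with pytest.raises(ValueError, match="at least 2"):
            interaction_test(g, np.zeros((5, 2)))


def _curve_log(p_correct, pid="p"):
    """AB-pair training log with prescribed per-trial P(choose A)."""
    rng = np.random.default_rng(42)
    return [
        make_training_trial(pid, i, "AB", "A" if rng.random() < p else "B", 1)
        for i, p in enumerate(p_correct)
    ]


class TestTrainingCurves:
    def test_flat_performance_gives_near_zero_slope(self):
        curves = fit_training_curves(_curve_log([0.5] * 300))
        assert abs(curves[0].slope) < 0.01
        assert not curves[0].separated

    def test_improving_performance_gives_positive_slope(self):
        curves = fit_training_curves(_curve_log(np.linspace(0.5, 0.9, 200)))
        assert curves[0].slope > 0

    def test_worsening_performance_gives_negative_slope(self):
        curves = fit_training_curves(_curve_log(np.linspace(0.9, 0.5, 200)))
        assert curves[0].slope < 0

    def test_complete_separation_is_flagged_and_capped(self):
        trials = [
            make_training_trial("p", i, "AB", "B" if i < 10 else "A", 1)
            for i in range(20)
        ]
        curves = fit_training_curves(trials)
        assert curves[0].separated
        assert curves[0].slope == pytest.approx(5.0)

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError, match="responded trials"):
            fit_training_curves(_curve_log([0.5] * 3))


def _raw_traits(n, rng=None, pid_offset=0):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "participant_id": [f"p{i + pid_offset}" for i in range(n)],
            "drive": rng.integers(4, 17, n),
            "fun_seeking": rng.integers(4, 17, n),
            "reward_responsiveness": rng.integers(5, 21, n),
            "bis": rng.integers(7, 29, n),
            "sr": rng.integers(0, 25, n),
            "sp": rng.integers(0, 25, n),
        }
    )


class TestTraitScoring:
    def test_two_participant_z_scores(self):
        raw = _raw_traits(2)
        raw["sr"] = [10, 20]
        z = score_traits(raw)["sr_z"]
        # sample-SD convention: deviations +-5 over SD 7.071
        assert sorted(z) == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_location_invariance(self):
        raw = _raw_traits(20)
        shifted = raw.copy()
        shifted["sp"] = shifted["sp"] + 7
        assert np.allclose(score_traits(raw)["sp_z"], score_traits(shifted)["sp_z"])

    def test_normalization(self):
        scores = score_traits(_raw_traits(34))
        for col in ("bis_z", "bas_z", "sr_z", "sp_z"):
            assert scores[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert scores[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_bas_is_composite_of_three_subscales(self):
        raw = _raw_traits(25)
        total = raw["drive"] + raw["fun_seeking"] + raw["reward_responsiveness"]
        expected = (total - total.mean()) / total.std(ddof=1)
        assert np.allclose(score_traits(raw)["bas_z"], expected)

    def test_zero_variance_raises(self):
        raw = _raw_traits(5)
        raw["bis"] = 15
        with pytest.raises(ValueError, match="zero variance"):
            score_traits(raw)


def _metrics_frame(n_app, n_avd, rng):
    rows = []
    for i in range(n_app + n_avd):
        approach = i < n_app
        sel = rng.uniform(0.8, 1.0) if approach else rng.uniform(0.5, 0.75)
        rej = sel - 0.1 if approach else sel + 0.1
        rows.append(
            {
                "participant_id": f"p{i}",
                "select_a_rate": sel,
                "reject_b_rate": rej,
                "select_minus_reject": sel - rej,
                "learner_class": "approach" if approach else "avoidance",
            }
        )
    return pd.DataFrame(rows)


class TestGroupStats:
    def test_tables_and_self_correlation(self):
        rng = np.random.default_rng(3)
        metrics = _metrics_frame(12, 8, rng)
        traits = score_traits(_raw_traits(20, rng))
        res = group_stats(metrics, traits)
        assert np.allclose(np.diag(res.spearman_rho), 1.0)
        assert "select_a_rate" in res.group_ttests["measure"].values
        assert res.spearman_rho.loc["sr", "sr_minus_sp"] > 0

    def test_misaligned_ids_raise(self):
        rng = np.random.default_rng(4)
        metrics = _metrics_frame(6, 6, rng)
        traits = score_traits(_raw_traits(12, rng, pid_offset=50))
        with pytest.raises(ValueError, match="align"):
            group_stats(metrics, traits)

    def test_null_spearman_rarely_exceeds_threshold(self):
        # |rho| stays under 0.34 for ~95% of independent n=34 column pairs
        rng = np.random.default_rng(5)
        from scipy.stats import spearmanr

        hits = sum(
            abs(spearmanr(rng.normal(size=34), rng.normal(size=34)).statistic) < 0.34
            for _ in range(1000)
        )
        assert hits >= 930

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_spearman_invariant_under_monotone_transform(self, seed):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = spearmanr(x, y).statistic
        assert spearmanr(np.exp(x), y).statistic == pytest.approx(base)
        assert spearmanr(x, 3 * y - 7).statistic == pytest.approx(base)
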