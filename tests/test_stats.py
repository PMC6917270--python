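"""Statistical-pipeline tests: the balanced-panel coefficient oracle,
brute-force multiple-testing checks, random-effects recovery, and Welch
formula verification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cprlab.cohort import simulate_topic_panel
from cprlab.stats import (
    ALL_PAIRS,
    CollinearityError,
    bh_adjust,
    bonferroni_threshold,
    pairwise_treatment_model,
    run_pairwise_battery,
    topic_performance_model,
    welch_test,
)


def toy_balanced_panel(delta=3.0, n_groups=4, n_rounds=6, base=10.0,
                       trend=0.5, seed=0, demean=True):
    """Balanced two-arm panel whose arm means differ by exactly delta.

    With ``demean`` the group effects and noise are mean-zero within each
    arm, so the difference in arm means is delta by construction (the
    exact-identity oracle); without it the panel has ordinary sampling
    variation.  A shared round trend exercises the covariate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for arm, arm_base in (("A", base), ("C", base + delta)):
        offsets = rng.normal(0, 1.0, n_groups)
        if demean:
            offsets -= offsets.mean()
        for g, off in enumerate(offsets):
            noise = rng.normal(0, 0.5, n_rounds)
            if demean:
                noise -= noise.mean()
            for r in range(1, n_rounds + 1):
                rows.append({
                    "group_id": f"{arm}{g}",
                    "treatment": arm,
                    "round": r,
                    "mean_coin_harvest": arm_base + off + trend * r + noise[r - 1],
                    "optimal_difference": 0.0,
                })
    return pd.DataFrame(rows)


def brute_force_bh(pvalues, q):
    """Independent step-up oracle: largest k with p_(k) <= k q / m."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def welch_by_hand(x, y):
    """Direct evaluation of the Welch statistic and Satterthwaite df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


class TestPairwiseModel:
    def test_balanced_panel_coefficient_equals_mean_difference(self):
        """With both arms observed over the same rounds the treatment dummy
        is orthogonal to the round covariate, so the regression must give
        back the raw difference of arm means exactly."""
        delta = 3.0
        panel = toy_balanced_panel(delta=delta)
        res = pairwise_treatment_model(panel, ("A", "C"), "mean_coin_harvest")
        # indicator marks the first arm: A sits delta below C
        assert res.coefficient == pytest.approx(-delta, abs=1e-8)
        means = panel.groupby("treatment")["mean_coin_harvest"].mean()
        assert res.coefficient == pytest.approx(means["A"] - means["C"], abs=1e-8)

    def test_null_arms_give_coefficient_centered_on_zero(self):
        coefs = [
            pairwise_treatment_model(
                toy_balanced_panel(delta=0.0, seed=s, demean=False), ("A", "C")
            ).coefficient
            for s in range(40)
        ]
        assert abs(np.mean(coefs)) < 0.25
        assert np.mean(np.array(coefs) > 0) == pytest.approx(0.5, abs=0.25)

    def test_missing_treatment_rejected(self):
        panel = toy_balanced_panel()
        with pytest.raises(ValueError, match="absent"):
            pairwise_treatment_model(panel, ("A", "D"))

    def test_single_group_arm_rejected(self):
        panel = toy_balanced_panel(n_groups=1)
        with pytest.raises(ValueError, match="fewer than 2 groups"):
            pairwise_treatment_model(panel, ("A", "C"))

    def test_battery_shape_and_flag_consistency(self, small_panel):
        results = run_pairwise_battery(small_panel)
        assert len(results) == 12  # 6 pairs x 2 outcomes
        # Bonferroni (0.05/6) is stricter than BH at FDR 0.25
        bonf = results[results["significant_bonferroni"]]
        assert bonf["rejected_bh"].all()
        assert (results.loc[results["rejected_bh"], "p"] <= 0.25).all()


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 6, 0.05 / 6), (0.05, 1, 0.05), (0.10, 4, 0.025)]
    )
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_zero_models_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestBenjaminiHochberg:
    def test_all_ones_never_rejected(self):
        _, rej = bh_adjust([1.0, 1.0, 1.0], 0.25)
        assert not rej.any()

    def test_single_small_p_rejected(self):
        adj, rej = bh_adjust([0.01], 0.25)
        assert rej[0] and adj[0] == pytest.approx(0.01)

    def test_step_up_rejections_match_brute_force(self):
        p = [0.001, 0.013, 0.04, 0.2]
        _, rej = bh_adjust(p, 0.25)
        assert (rej == brute_force_bh(p, 0.25)).all()

    def test_output_order_matches_input_order(self):
        p = [0.2, 0.001, 0.04, 0.013]
        adj, _ = bh_adjust(p, 0.25)
        resorted, _ = bh_adjust(sorted(p), 0.25)
        assert sorted(adj) == pytest.approx(sorted(resorted))
        assert np.argmin(adj) == 1

    @given(
        p=st.lists(st.floats(0, 1), min_size=1, max_size=12),
        q=st.sampled_from([0.05, 0.1, 0.25]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_and_sandwich_property(self, p, q):
        """BH rejections equal the step-up definition; they contain every
        Bonferroni rejection and only raw p-values at most q."""
        adj, rej = bh_adjust(p, q)
        assert (rej == brute_force_bh(p, q)).all()
        arr = np.asarray(p)
        bonferroni = arr <= q / len(p)
        assert rej[bonferroni].all()
        assert (arr[rej] <= q + 1e-12).all()
        assert (rej == (adj <= q)).all()

    @given(
        p=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=10),
        idx=st.integers(0, 9),
    )
    @settings(max_examples=100, derandomize=True)
    def test_lowering_a_pvalue_never_removes_rejections(self, p, idx):
        idx = idx % len(p)
        _, rej_before = bh_adjust(p, 0.25)
        lowered = list(p)
        lowered[idx] = lowered[idx] / 2
        _, rej_after = bh_adjust(lowered, 0.25)
        assert rej_after[rej_before].all()

    def test_empty_input_gives_empty_output(self):
        adj, rej = bh_adjust([], 0.25)
        assert adj.size == 0 and rej.size == 0


class TestTopicModel:
    def test_recovers_injected_per_message_effect(self):
        """The random-intercept model's 95% CI should cover an injected
        beta in at least ~95% of replicates; require >=21/25."""
        beta = 0.5
        hits = 0
        for rep in range(25):
            panel = simulate_topic_panel(n_groups=8, beta=beta, seed=100 + rep)
            res = topic_performance_model(panel, "suggestion", "mean_coin_harvest")
            if res.extra["conf_int_low"] <= beta <= res.extra["conf_int_high"]:
                hits += 1
        assert hits >= 21

    def test_null_panel_estimates_center_on_zero(self):
        coefs = [
            topic_performance_model(
                simulate_topic_panel(beta=0.0, seed=200 + rep),
                "suggestion",
                "mean_coin_harvest",
            ).coefficient
            for rep in range(20)
        ]
        assert abs(np.mean(coefs)) < 0.15

    def test_constant_topic_column_raises_collinearity(self):
        panel = simulate_topic_panel(seed=1)
        panel["suggestion"] = 3
        with pytest.raises(CollinearityError):
            topic_performance_model(panel, "suggestion")

    def test_round_dummies_absorb_common_trend(self):
        # a pure time trend must not masquerade as a topic effect
        panel = simulate_topic_panel(beta=0.0, round_effect=1.5, seed=7)
        res = topic_performance_model(panel, "suggestion", "mean_coin_harvest")
        assert abs(res.coefficient) < 3 * res.std_error + 0.3


class TestWelch:
    def test_identical_samples_t_zero_p_one(self):
        res = welch_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_direct_formula_evaluation(self):
        x, y = [1, 2, 3, 4, 5], [2, 3, 4, 5, 6]
        res = welch_test(x, y)
        t, df = welch_by_hand(x, y)
        assert res.statistic == pytest.approx(t)
        assert res.df == pytest.approx(df)
        # two-sided p from the t distribution with Satterthwaite df
        import scipy.stats

        assert res.p_value == pytest.approx(2 * scipy.stats.t.sf(abs(t), df))

    def test_antisymmetric_in_sample_order(self):
        x, y = [1.0, 4.0, 2.5, 3.5], [5.0, 6.5, 4.5]
        a, b = welch_test(x, y), welch_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_welch_df_never_exceeds_pooled_df(self):
        x, y = [1.0, 4.0, 2.5, 3.5, 9.0], [5.0, 6.5, 4.5]
        res = welch_test(x, y)
        assert res.df <= len(x) + len(y) - 2

    def test_degenerate_zero_variance_cases(self):
        res = welch_test([2.0, 2.0], [2.0, 2.0])
        assert res.statistic == 0.0 and res.p_value == 1.0
        with pytest.raises(ValueError):
            welch_test([2.0, 2.0], [3.0, 3.0])
        with pytest.raises(ValueError):
            welch_test([2.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            welch_test([2.0], [3.0, 4.0])
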