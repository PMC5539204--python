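"""qPCR stack: efficiency estimation, geNorm, relative expression, REST, Mann-Whitney."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirmint.errors import InputError, NoExponentialPhaseError
from mirmint.qpcr import (
    AmplificationCurve,
    RelativeExpression,
    estimate_efficiency,
    genorm_stability,
    mann_whitney_exact,
    relative_expression,
    rest_randomization_test,
)
from mirmint.simulate import generate_amplification_curves


class TestEfficiencyEstimation:
    @pytest.mark.parametrize("e_true", [1.6, 1.8, 2.0, 1.3, 1.95])
    def test_noiseless_curves_recovered_exactly(self, e_true):
        curve = generate_amplification_curves(e_true, f0=1e-3, n_cycles=40, plateau_cycle=30)
        est = estimate_efficiency(curve)
        assert est.ok
        assert est.efficiency == pytest.approx(e_true, abs=1e-6)

    def test_plateau_only_curve_has_no_exponential_phase(self):
        curve = AmplificationCurve("w", np.arange(1, 21), np.full(20, 5.0))
        with pytest.raises(NoExponentialPhaseError):
            estimate_efficiency(curve)

    def test_decreasing_curve_has_no_positive_slope(self):
        fluo = 100.0 * 0.9 ** np.arange(20) + 50.0
        curve = AmplificationCurve("w", np.arange(1, 21), fluo)
        with pytest.raises(NoExponentialPhaseError):
            estimate_efficiency(curve)

    def test_noisy_curve_below_r2_reports_failure_with_best_fit(self):
        curve = generate_amplification_curves(1.8, noise_sd=0.4, seed=8, n_cycles=40, plateau_cycle=30)
        est = estimate_efficiency(curve, min_r2=0.9999)
        assert not est.ok
        assert 0.0 < est.r_squared < 0.9999

    def test_superdoubling_estimate_flagged_not_clamped(self):
        fluo = 1e-3 * 2.4 ** np.arange(1, 31, dtype=float)
        curve = AmplificationCurve("w", np.arange(1, 31), fluo)
        est = estimate_efficiency(curve)
        assert est.exceeds_doubling
        assert est.efficiency == pytest.approx(2.4, abs=1e-6)

    def test_curve_validation(self):
        with pytest.raises(InputError):
            AmplificationCurve("w", np.array([1, 1, 2]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(InputError):
            AmplificationCurve("w", np.array([1, 2]), np.array([1.0, -2.0]))


class TestGeNorm:
    def test_coregulated_pair_beats_noisy_candidate(self, tidy_ct):
        # two candidates at a constant Ct offset across samples, one erratic
        base = [20.0, 21.5, 19.0, 22.0, 20.5, 21.0]
        ct = tidy_ct({
            "stable_a": base,
            "stable_b": [x + 2.0 for x in base],
            "noisy_c": [20.0, 26.0, 17.0, 24.0, 16.0, 27.0],
        })
        res = genorm_stability(ct)
        assert res.exclusion_order == ["noisy_c"]
        assert set(res.ranking[:2]) == {"stable_a", "stable_b"}
        # perfectly co-regulated pair: pairwise sd and hence final Ms are 0
        assert res.m_values["noisy_c"] == max(res.m_values)

    def test_all_constant_candidates_tie_break_lexicographic(self, tidy_ct):
        ct = tidy_ct({name: [20.0] * 4 for name in ["d", "b", "a", "c"]})
        res = genorm_stability(ct)
        assert np.allclose(res.m_values, 0.0)
        # equal M: exclusion removes lexicographically-first id each round
        assert res.exclusion_order == ["a", "b"]
        assert res.ranking == ["c", "d", "b", "a"]

    def test_sample_wise_ct_shift_leaves_m_invariant(self, tidy_ct, rng):
        values = {f"t{i}": list(rng.normal(20, 1, size=8)) for i in range(5)}
        res1 = genorm_stability(tidy_ct(values))
        shifted = {t: [v + (3.0 if j == 2 else 0.0) for j, v in enumerate(vals)]
                   for t, vals in values.items()}
        res2 = genorm_stability(tidy_ct(shifted))
        pd.testing.assert_series_equal(res1.m_values, res2.m_values, atol=1e-9, rtol=0)

    def test_requires_three_candidates_and_complete_ct(self, tidy_ct):
        with pytest.raises(InputError, match=">= 3"):
            genorm_stability(tidy_ct({"a": [1, 2], "b": [2, 3]}))
        ct = tidy_ct({"a": [20, 21, 20], "b": [20, 21, 22], "c": [19, 20, 21]})
        missing = ct[~((ct["target"] == "b") & (ct["sample"] == "s2"))]
        with pytest.raises(InputError, match="b.*s2"):
            genorm_stability(missing)

    def test_planted_stable_panel_recovery_small(self):
        from mirmint.simulate import generate_reference_panel

        hits = 0
        for seed in range(20):
            ct, stable = generate_reference_panel(seed=seed)
            res = genorm_stability(ct)
            hits += set(res.ranking[:3]) == set(stable)
        assert hits >= 19


class TestRelativeExpression:
    def test_one_cycle_shift_doubles_expression(self, tidy_ct, two_group_labels):
        groups = two_group_labels(3, samples=[f"s{i}" for i in range(1, 7)])
        ct = tidy_ct({"tgt": [25, 25, 25, 24, 24, 24], "ref": [20, 20, 20, 20, 20, 20]})
        assert relative_expression(ct, "tgt", ["ref"], groups) == pytest.approx(2.0)

    def test_common_shift_cancels(self, tidy_ct, two_group_labels):
        groups = two_group_labels(3, samples=[f"s{i}" for i in range(1, 7)])
        ct = tidy_ct({"tgt": [25, 25, 25, 23, 23, 23], "ref": [20, 20, 20, 18, 18, 18]})
        assert relative_expression(ct, "tgt", ["ref"], groups) == pytest.approx(1.0)

    def test_efficiency_correction_closed_form(self, tidy_ct, two_group_labels):
        groups = two_group_labels(3, samples=[f"s{i}" for i in range(1, 7)])
        ct = tidy_ct({"tgt": [25, 25, 25, 23, 23, 23], "ref": [20, 20, 20, 20, 20, 20]})
        ratio = relative_expression(ct, "tgt", ["ref"], groups, efficiencies={"tgt": 1.8})
        assert ratio == pytest.approx(1.8**2, rel=1e-12)

    def test_empty_reference_set_rejected(self, tidy_ct, two_group_labels):
        groups = two_group_labels(3, samples=[f"s{i}" for i in range(1, 7)])
        ct = tidy_ct({"tgt": [25, 25, 25, 24, 24, 24]})
        with pytest.raises(InputError, match="reference"):
            relative_expression(ct, "tgt", [], groups)


class TestRandomizationTest:
    def test_identical_groups_give_large_p(self, tidy_ct, two_group_labels):
        groups = two_group_labels(3, samples=[f"s{i}" for i in range(1, 7)])
        ct = tidy_ct({"tgt": [25, 24, 26, 25, 24, 26], "ref": [20, 20, 20, 20, 20, 20]})
        _, p = rest_randomization_test(ct, "tgt", ["ref"], groups, n_permutations=2000, seed=0)
        assert p >= 0.5

    def test_planted_fourfold_ratio_detected(self, tidy_ct, two_group_labels, rng):
        samples = [f"s{i}" for i in range(1, 13)]
        groups = two_group_labels(6, samples=samples)
        tgt = np.concatenate([rng.normal(25, 0.05, 6), rng.normal(23, 0.05, 6)])  # dCt = 2 -> ratio 4
        ref = rng.normal(20, 0.05, 12)
        ct = tidy_ct({"tgt": list(tgt), "ref": list(ref)}, samples=samples)
        ratio, p = rest_randomization_test(ct, "tgt", ["ref"], groups, n_permutations=10_000, seed=1)
        assert ratio == pytest.approx(4.0, rel=0.1)
        # the two-sided reallocation p has a floor of 2/C(12,6) ~ 0.0022 at
        # n = 6 + 6 (identity and complement always tie the observed statistic)
        assert p <= 0.005

    def test_power_increases_with_effect_size(self, tidy_ct, two_group_labels, rng):
        samples = [f"s{i}" for i in range(1, 13)]
        groups = two_group_labels(6, samples=samples)
        rejections = []
        for effect in (0.0, 0.75, 1.5):
            hits = 0
            for _ in range(40):
                tgt = np.concatenate([rng.normal(25, 0.5, 6), rng.normal(25 - effect, 0.5, 6)])
                ref = rng.normal(20, 0.5, 12)
                ct = tidy_ct({"tgt": list(tgt), "ref": list(ref)}, samples=samples)
                _, p = rest_randomization_test(ct, "tgt", ["ref"], groups,
                                               n_permutations=500, seed=int(rng.integers(2**31)))
                hits += p <= 0.05
            rejections.append(hits)
        assert rejections[0] <= rejections[1] <= rejections[2]
        assert rejections[2] > rejections[0]

    def test_p_never_zero_and_permutation_count_validated(self, tidy_ct, two_group_labels):
        groups = two_group_labels(2, samples=[f"s{i}" for i in range(1, 5)])
        ct = tidy_ct({"tgt": [25, 25, 20, 20], "ref": [20, 20, 20, 20]}, samples=[f"s{i}" for i in range(1, 5)])
        _, p = rest_randomization_test(ct, "tgt", ["ref"], groups, n_permutations=100, seed=0)
        assert 0 < p <= 1
        with pytest.raises(InputError):
            rest_randomization_test(ct, "tgt", ["ref"], groups, n_permutations=0)

    def test_model_interface_matches_function(self, tidy_ct, two_group_labels):
        samples = [f"s{i}" for i in range(1, 9)]
        groups = two_group_labels(4, samples=samples)
        ct = tidy_ct({"tgt": [25, 24, 26, 25, 23, 24, 23, 23], "ref": [20.0] * 8}, samples=samples)
        res = RelativeExpression(ct, groups, references=["ref"]).fit(n_permutations=500, seed=4)
        assert list(res.table["target"]) == ["tgt"]
        row = res.table.iloc[0]
        assert row["ratio"] == pytest.approx(2.0 ** row["log2_ratio"])
        assert "randomization" in res.summary()


def brute_force_mw_p(a, b):
    """Independent oracle: enumerate label assignments, U from pairwise comparisons."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_of(idx_a):
        set_a = [pooled[i] for i in idx_a]
        set_b = [pooled[i] for i in range(len(pooled)) if i not in set(idx_a)]
        return sum((x > y) + 0.5 * (x == y) for x in set_a for y in set_b)

    center = n_a * (len(pooled) - n_a) / 2.0
    obs = u_of(tuple(range(n_a)))
    assignments = list(itertools.combinations(range(len(pooled)), n_a))
    extreme = sum(1 for idx in assignments if abs(u_of(idx) - center) >= abs(obs - center) - 1e-9)
    return extreme / len(assignments)


class TestMannWhitneyExact:
    def test_complete_separation_six_vs_six(self, rng):
        a = rng.normal(344.6, 17.5, 6)
        b = rng.normal(255.0, 13.7, 6)
        assert a.min() > b.max()
        p = mann_whitney_exact(a, b)
        assert p == pytest.approx(2 / 924, abs=1e-12)
        assert round(p, 4) == 0.0022

    def test_complete_separation_two_vs_two(self):
        assert mann_whitney_exact([5, 6], [1, 2]) == pytest.approx(2 / 6)

    def test_identical_multisets_give_one(self):
        assert mann_whitney_exact([1, 2, 3], [3, 1, 2]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            mann_whitney_exact([], [1.0])

    @given(
        n_a=st.integers(1, 6),
        n_b=st.integers(1, 6),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_agrees_with_brute_force_enumeration(self, n_a, n_b, data):
        values = data.draw(
            st.lists(st.integers(0, 8), min_size=n_a + n_b, max_size=n_a + n_b)
        )
        a, b = values[:n_a], values[n_a:]
        assert mann_whitney_exact(a, b) == pytest.approx(brute_force_mw_p(a, b), abs=1e-12)

    def test_large_samples_use_tie_corrected_normal_approximation(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.8, 1, 30)
        from scipy import stats

        expected = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                      use_continuity=False).pvalue
        assert mann_whitney_exact(a, b) == pytest.approx(expected, rel=1e-12)
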