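"""Within-review pooling against independent brute-force formula oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaror import (
    EffectEstimate,
    MetaResult,
    SubgroupComparison,
    ValidationError,
    ZeroCellError,
    dersimonian_laird,
    heterogeneity,
    invert_direction,
    pool_inverse_variance,
    pool_mantel_haenszel,
    subgroup_difference,
    trial_effect,
)

from conftest import rob, trial

# ---------------------------------------------------------------------------
# brute-force oracles: plain-Python re-evaluations of the textbook formulas,
# written without reference to the implementation


def oracle_iv(thetas, ses, model):
    w = [1.0 / s**2 for s in ses]
    mu = sum(wi * t for wi, t in zip(w, thetas)) / sum(w)
    q = sum(wi * (t - mu) ** 2 for wi, t in zip(w, thetas))
    if model == "fixed":
        return mu, math.sqrt(1.0 / sum(w)), q, 0.0
    c = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (q - (len(thetas) - 1)) / c) if len(thetas) > 1 else 0.0
    wr = [1.0 / (s**2 + tau2) for s in ses]
    mu_r = sum(wi * t for wi, t in zip(wr, thetas)) / sum(wr)
    return mu_r, math.sqrt(1.0 / sum(wr)), q, tau2


def oracle_mh(tables):
    """Mantel-Haenszel estimate and Robins-Breslow-Greenland variance."""
    sr = sum(a * d / (a + b + c + d) for a, b, c, d in tables)
    ss = sum(b * c / (a + b + c + d) for a, b, c, d in tables)
    log_or = math.log(sr / ss)
    t1 = t2 = t3 = 0.0
    for a, b, c, d in tables:
        n = a + b + c + d
        p, q, r, s = (a + d) / n, (b + c) / n, a * d / n, b * c / n
        t1 += p * r
        t2 += p * s + q * r
        t3 += q * s
    var = t1 / (2 * sr**2) + t2 / (2 * sr * ss) + t3 / (2 * ss**2)
    return log_or, math.sqrt(var)


def oracle_subgroup_q(thetas, ses):
    w = [1.0 / s**2 for s in ses]
    mu = sum(wi * t for wi, t in zip(w, thetas)) / sum(w)
    return sum(wi * (t - mu) ** 2 for wi, t in zip(w, thetas))


def random_effects_list(rng, k):
    return [
        EffectEstimate(trial_id=f"T{i}",
                       log_or=float(rng.normal(0, 0.8)),
                       se=float(rng.uniform(0.05, 0.9)))
        for i in range(k)
    ]


def random_tables(rng, k):
    tables = []
    while len(tables) < k:
        n1, n2 = rng.integers(20, 200, size=2)
        a = int(rng.integers(1, n1))
        c = int(rng.integers(1, n2))
        tables.append((a, int(n1) - a, c, int(n2) - c))
    return tables


# ---------------------------------------------------------------------------


class TestTrialEffect:
    def test_symmetric_table_has_zero_log_or(self):
        t = trial("R1", "T1", events_treat=10, n_treat=100,
                  events_ctrl=10, n_ctrl=100)
        eff = trial_effect(t)
        assert eff.log_or == pytest.approx(0.0)
        assert eff.se == pytest.approx(0.4714, abs=1e-4)
        assert not eff.corrected

    def test_zero_cell_corrected_by_half(self):
        t = trial("R1", "T1", events_treat=0, n_treat=20,
                  events_ctrl=5, n_ctrl=20)
        eff = trial_effect(t, "constant_half")
        assert eff.corrected
        assert eff.log_or == pytest.approx(math.log(0.5 * 15.5 / (20.5 * 5.5)))
        assert eff.se == pytest.approx(
            math.sqrt(1 / 0.5 + 1 / 20.5 + 1 / 5.5 + 1 / 15.5)
        )

    def test_zero_cell_without_correction_raises(self):
        t = trial("R1", "T1", events_treat=0, n_treat=20,
                  events_ctrl=5, n_ctrl=20)
        with pytest.raises(ZeroCellError):
            trial_effect(t, "none")

    @pytest.mark.parametrize("et,ec", [(0, 0), (20, 20)])
    def test_no_information_tables_are_excluded(self, et, ec):
        t = trial("R1", "T1", events_treat=et, n_treat=20,
                  events_ctrl=ec, n_ctrl=20)
        assert trial_effect(t) is None


class TestInverseVariance:
    def test_two_equal_effects(self):
        effects = [EffectEstimate("T1", 0.0, 0.5), EffectEstimate("T2", 0.0, 0.5)]
        result = pool_inverse_variance(effects, "fixed")
        assert result.pooled_log_or == pytest.approx(0.0)
        assert result.se == pytest.approx(0.35355, abs=1e-5)

    def test_identical_effects_degenerate(self):
        effects = [EffectEstimate(f"T{i}", 0.3, 0.2) for i in range(4)]
        fixed = pool_inverse_variance(effects, "fixed")
        random = pool_inverse_variance(effects, "random")
        assert fixed.q == pytest.approx(0.0)
        assert random.tau2 == 0.0
        assert random.pooled_log_or == pytest.approx(fixed.pooled_log_or)
        assert random.se == pytest.approx(fixed.se)

    def test_empty_input_raises(self):
        from metaror import EmptyAnalysisError
        with pytest.raises(EmptyAnalysisError):
            pool_inverse_variance([], "fixed")

    @pytest.mark.parametrize("model", ["fixed", "random"])
    def test_matches_brute_force_on_random_instances(self, model):
        rng = np.random.default_rng(12345)
        for _ in range(25):
            effects = random_effects_list(rng, int(rng.integers(2, 12)))
            result = pool_inverse_variance(effects, model)
            mu, se, q, tau2 = oracle_iv(
                [e.log_or for e in effects], [e.se for e in effects], model
            )
            assert result.pooled_log_or == pytest.approx(mu, rel=1e-12, abs=1e-12)
            assert result.se == pytest.approx(se, rel=1e-12)
            assert result.q == pytest.approx(q, rel=1e-12, abs=1e-12)
            assert result.tau2 == pytest.approx(tau2, rel=1e-12, abs=1e-12)

    def test_matches_statsmodels_dersimonian_laird(self):
        # independent cross-check against an established implementation
        from statsmodels.stats.meta_analysis import combine_effects

        # clearly heterogeneous effects so the DL moment estimate is positive
        # (statsmodels reports the untruncated estimate, which may be negative)
        effects = [
            EffectEstimate("T1", 0.9, 0.2),
            EffectEstimate("T2", -0.5, 0.25),
            EffectEstimate("T3", 0.1, 0.15),
            EffectEstimate("T4", 1.4, 0.3),
            EffectEstimate("T5", -0.2, 0.2),
        ]
        theta = np.array([e.log_or for e in effects])
        var = np.array([e.se**2 for e in effects])
        reference = combine_effects(theta, var, method_re="dl")
        assert float(reference.tau2) > 0
        result = pool_inverse_variance(effects, "random")
        assert result.tau2 == pytest.approx(float(reference.tau2), rel=1e-10)
        assert result.pooled_log_or == pytest.approx(
            float(reference.mean_effect_re), rel=1e-10
        )
        assert result.se == pytest.approx(float(reference.sd_eff_w_re), rel=1e-10)

    def test_random_ci_never_narrower_than_fixed(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            effects = random_effects_list(rng, int(rng.integers(2, 10)))
            fixed = pool_inverse_variance(effects, "fixed")
            random = pool_inverse_variance(effects, "random")
            assert random.se >= fixed.se - 1e-12
            assert fixed.se <= min(e.se for e in effects) + 1e-12


class TestMantelHaenszel:
    def test_single_trial_equals_trial_or(self):
        t = trial("R1", "T1", events_treat=8, n_treat=50,
                  events_ctrl=14, n_ctrl=60)
        result = pool_mantel_haenszel([t])
        expected = (8 * 46) / (42 * 14)
        assert result.or_point == pytest.approx(expected, rel=1e-12)

    def test_arm_swap_reciprocates(self):
        trials = [
            trial("R1", "T1", events_treat=8, n_treat=50, events_ctrl=14, n_ctrl=60),
            trial("R1", "T2", events_treat=20, n_treat=80, events_ctrl=9, n_ctrl=40),
        ]
        swapped = [
            trial("R1", t.trial_id, events_treat=t.events_ctrl, n_treat=t.n_ctrl,
                  events_ctrl=t.events_treat, n_ctrl=t.n_treat)
            for t in trials
        ]
        forward = pool_mantel_haenszel(trials)
        backward = pool_mantel_haenszel(swapped)
        assert backward.or_point == pytest.approx(1.0 / forward.or_point, rel=1e-12)
        assert backward.se == pytest.approx(forward.se, rel=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            tables = random_tables(rng, int(rng.integers(1, 10)))
            trials = [
                trial("R1", f"T{i}", events_treat=a, n_treat=a + b,
                      events_ctrl=c, n_ctrl=c + d)
                for i, (a, b, c, d) in enumerate(tables)
            ]
            result = pool_mantel_haenszel(trials)
            log_or, se = oracle_mh(tables)
            assert result.pooled_log_or == pytest.approx(log_or, rel=1e-12, abs=1e-12)
            assert result.se == pytest.approx(se, rel=1e-12)

    def test_all_trials_excluded_raises(self):
        from metaror import EmptyAnalysisError
        t = trial("R1", "T1", events_treat=0, n_treat=20, events_ctrl=0, n_ctrl=20)
        with pytest.raises(EmptyAnalysisError):
            pool_mantel_haenszel([t])


class TestDerSimonianLaird:
    def test_identical_effects_give_zero(self):
        effects = [EffectEstimate(f"T{i}", 0.1, 0.3) for i in range(3)]
        assert dersimonian_laird(effects) == 0.0

    def test_truncated_at_zero_when_q_small(self):
        # nearly identical effects with large ses: Q << k - 1
        effects = [
            EffectEstimate("T1", 0.10, 1.0),
            EffectEstimate("T2", 0.11, 1.0),
            EffectEstimate("T3", 0.09, 1.0),
        ]
        assert dersimonian_laird(effects) == 0.0

    def test_single_effect_returns_zero(self):
        assert dersimonian_laird([EffectEstimate("T1", 0.5, 0.2)]) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(55)
        for _ in range(25):
            effects = random_effects_list(rng, int(rng.integers(2, 15)))
            _, _, _, tau2 = oracle_iv(
                [e.log_or for e in effects], [e.se for e in effects], "random"
            )
            assert dersimonian_laird(effects) == pytest.approx(tau2, rel=1e-12, abs=1e-12)


class TestHeterogeneity:
    def test_moderate_and_substantial_bands_overlap(self):
        i2, bands, p = heterogeneity(20.0, 9)
        assert i2 == pytest.approx(55.0)
        assert set(bands) == {"moderate", "substantial"}
        assert 0 < p < 1

    def test_truncation_when_q_below_df(self):
        i2, bands, _ = heterogeneity(5.0, 9)
        assert i2 == 0.0
        assert "not_important" in bands

    def test_negative_q_rejected(self):
        with pytest.raises(ValidationError):
            heterogeneity(-1.0, 3)

    @pytest.mark.parametrize("i2,expected", [
        (0.0, {"not_important"}),
        (35.0, {"not_important", "moderate"}),
        (80.0, {"substantial", "considerable"}),
        (100.0, {"considerable"}),
    ])
    def test_band_membership(self, i2, expected):
        # construct q/df giving the wanted i2: i2 = (q - df)/q*100 with df=1
        q = 1.0 / (1.0 - i2 / 100.0) if i2 < 100 else 1e12
        got_i2, bands, _ = heterogeneity(q, 1)
        assert got_i2 == pytest.approx(i2, abs=1e-6)
        assert set(bands) == expected


class TestSubgroupDifference:
    def _result(self, log_or, se):
        return pool_inverse_variance([EffectEstimate("T", log_or, se)], "fixed")

    def test_identical_groups_no_difference(self):
        groups = [self._result(0.2, 0.3), self._result(0.2, 0.3)]
        comparison = subgroup_difference(groups)
        assert comparison.q_between == pytest.approx(0.0)
        assert comparison.p_value == pytest.approx(1.0)

    def test_three_groups_match_brute_force(self):
        thetas, ses = [0.1, -0.4, 0.6], [0.2, 0.35, 0.15]
        groups = [self._result(t, s) for t, s in zip(thetas, ses)]
        comparison = subgroup_difference(groups)
        assert comparison.q_between == pytest.approx(
            oracle_subgroup_q(thetas, ses), rel=1e-12
        )
        assert comparison.df == 2

    @pytest.mark.parametrize("p,flag", [(0.049, True), (0.051, False)])
    def test_significance_threshold(self, p, flag):
        assert SubgroupComparison(q_between=1.0, df=1, p_value=p).significant is flag

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValidationError):
            subgroup_difference([self._result(0.1, 0.2)])


class TestInvertDirection:
    def _result(self):
        return MetaResult(
            k=3, pooled_log_or=math.log(2.0), se=0.13,
            or_point=2.0, ci_low=1.5, ci_high=2.5,
            q=1.0, df=2, p_q=0.6, tau2=0.0, i2_percent=0.0,
            i2_bands=("not_important",), model="fixed", method="inverse_variance",
        )

    def test_reciprocates_or_and_swaps_ci(self):
        inverted = invert_direction(self._result())
        assert inverted.or_point == pytest.approx(0.5)
        assert inverted.ci_low == pytest.approx(0.4)
        assert inverted.ci_high == pytest.approx(2.0 / 3.0)
        assert inverted.se == pytest.approx(0.13)
        assert inverted.q == pytest.approx(1.0)

    def test_double_inversion_is_identity(self):
        result = self._result()
        twice = invert_direction(invert_direction(result))
        assert twice.pooled_log_or == pytest.approx(result.pooled_log_or)
        assert twice.ci_low == pytest.approx(result.ci_low)
        assert twice.ci_high == pytest.approx(result.ci_high)


@settings(max_examples=60, deadline=None)
@given(data=st.data())
def test_pooling_invariants_hold_on_arbitrary_effects(data):
    """I2 in [0,100], tau2 >= 0, p-values in [0,1], CI brackets estimate."""
    k = data.draw(st.integers(1, 10))
    effects = [
        EffectEstimate(
            trial_id=f"T{i}",
            log_or=data.draw(st.floats(-3, 3, allow_nan=False)),
            se=data.draw(st.floats(0.01, 2.0, allow_nan=False)),
        )
        for i in range(k)
    ]
    model = data.draw(st.sampled_from(["fixed", "random"]))
    result = pool_inverse_variance(effects, model)
    assert 0.0 <= result.i2_percent <= 100.0
    assert result.tau2 >= 0.0
    assert 0.0 <= result.p_q <= 1.0
    assert result.ci_low <= result.or_point <= result.ci_high


@settings(max_examples=40, deadline=None)
@given(data=st.data())
def test_arm_swap_negates_pooled_log_or(data):
    """Swapping treatment and control arms in every trial flips the sign."""
    k = data.draw(st.integers(1, 6))
    trials_fwd, trials_rev = [], []
    for i in range(k):
        nt = data.draw(st.integers(2, 150))
        nc = data.draw(st.integers(2, 150))
        et = data.draw(st.integers(1, nt - 1))
        ec = data.draw(st.integers(1, nc - 1))
        trials_fwd.append(trial("R1", f"T{i}", events_treat=et, n_treat=nt,
                                events_ctrl=ec, n_ctrl=nc))
        trials_rev.append(trial("R1", f"T{i}", events_treat=ec, n_treat=nc,
                                events_ctrl=et, n_ctrl=nt))
    fwd = pool_mantel_haenszel(trials_fwd)
    rev = pool_mantel_haenszel(trials_rev)
    assert rev.pooled_log_or == pytest.approx(-fwd.pooled_log_or, rel=1e-9, abs=1e-12)
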