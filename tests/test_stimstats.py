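import itertools

import numpy as np
import pytest

from retinaosc.io import Condition
from retinaosc.spikes import SpikeTrain
from retinaosc.stimstats import (
    EfficiencyResult,
    MWUMode,
    compare_phases,
    mann_whitney_u,
    stars,
    stimulation_efficiency,
)


def _train(times):
    return SpikeTrain(np.asarray(sorted(set(times)), float), "c", 0.0, 0.0)


class TestEfficiency:
    def test_equal_rates_give_unit_ratio(self):
        pre = 2.0 + np.arange(80) * 0.0999  # 80 spikes in the 8-s pre window
        post = 10.0 + np.array([0.05, 0.15, 0.25, 0.35])  # 10 Hz in 0.4 s
        res = stimulation_efficiency(_train(np.r_[pre, post]), [10.0])
        assert res.per_stimulus_ratio == [pytest.approx(1.0)]

    def test_ratio_arithmetic(self):
        pre = 2.0 + np.arange(40) * 0.19  # 5 Hz
        post = 10.0 + np.linspace(0.01, 0.39, 13)  # 32.5 Hz
        res = stimulation_efficiency(_train(np.r_[pre, post]), [10.0])
        assert res.per_stimulus_ratio == [pytest.approx(6.5)]
        assert res.n == 1

    def test_zero_pre_rate_excluded(self):
        post = 10.0 + np.linspace(0.01, 0.39, 5)
        res = stimulation_efficiency(_train(post), [10.0])
        assert res.n == 0
        assert res.n_excluded == 1

    @pytest.mark.parametrize("factor", [2, 3])
    def test_ratio_invariant_under_common_rate_scaling(self, factor):
        pre = 2.0 + np.arange(40) * 0.19
        post = 10.0 + np.linspace(0.01, 0.39, 8)
        base = stimulation_efficiency(_train(np.r_[pre, post]), [10.0])
        pre_k = 2.0 + np.arange(40 * factor) * (0.19 / factor)
        post_k = 10.0 + np.linspace(0.005, 0.395, 8 * factor)
        scaled = stimulation_efficiency(_train(np.r_[pre_k, post_k]), [10.0])
        assert scaled.per_stimulus_ratio[0] == pytest.approx(
            base.per_stimulus_ratio[0]
        )

    def test_mean_and_sem_aggregation(self):
        res = EfficiencyResult.from_ratios([1.0, 2.0, 3.0])
        assert res.mean == pytest.approx(2.0)
        assert res.sem == pytest.approx(1.0 / np.sqrt(3))
        assert res.n == 3


def _exact_mwu_p(a, b):
    """Independent oracle: full enumeration of rank assignments."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    ranks = {}
    for v in set(pooled):
        idx = [i + 1 for i, x in enumerate(pooled) if x == v]
        ranks[v] = sum(idx) / len(idx)
    n1 = len(a)

    def u_of(sample):
        r = sum(ranks[v] for v in sample)
        return r - n1 * (n1 + 1) / 2

    u_obs = u_of(a)
    n = len(pooled)
    us = [u_of([pooled[i] for i in comb]) for comb in itertools.combinations(range(n), n1)]
    mean_u = n1 * (n - n1) / 2
    extreme = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return extreme / len(us)


class TestMannWhitney:
    def test_textbook_separation(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], mode=MWUMode.EXACT)
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)
        assert res.stars == "ns"

    def test_strong_separation_normal_approx(self):
        res = mann_whitney_u(
            list(range(1, 11)), list(range(11, 21)), mode=MWUMode.NORMAL_APPROX
        )
        assert res.p_value < 0.001

    @pytest.mark.parametrize(
        "n1,n2,seed",
        [(2, 3, 0), (3, 3, 1), (4, 4, 2), (5, 3, 3), (5, 5, 4), (8, 8, 5), (6, 2, 6)],
    )
    def test_exact_p_matches_enumeration_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, n1).round(3)
        b = rng.normal(0.5, 1, n2).round(3)
        while np.unique(np.r_[a, b]).size < n1 + n2:  # oracle assumes no ties
            b = b + 1e-4
        res = mann_whitney_u(a, b, mode=MWUMode.EXACT)
        assert res.p_value == pytest.approx(_exact_mwu_p(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.00005, "****"),
            (0.0001, "****"),
            (0.0005, "***"),
            (0.001, "***"),
            (0.04, "*"),
            (0.05, "*"),
            (0.2, "ns"),
            (0.0011, "*"),  # the ladder has no ** rung
        ],
    )
    def test_ladder(self, p, expected):
        assert stars(p) == expected

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            stars(1.5)


def _poisson_session(rng, pre_rate, post_rate, n_stim=40, pre_s=8.0, post_s=0.4):
    """Per-stimulus ratios from Poisson window counts (null or effect)."""
    ratios = []
    for _ in range(n_stim):
        pre = rng.poisson(pre_rate * pre_s)
        post = rng.poisson(post_rate * post_s)
        if pre > 0:
            ratios.append((post / post_s) / (pre / pre_s))
    return ratios


class TestComparePhases:
    def test_null_mostly_nonsignificant(self, rng):
        """No GABA effect on efficiency: PRE vs GABA should be ns >= 90%."""
        ns = 0
        for _ in range(50):
            results = {
                Condition.PRE_GABA: EfficiencyResult.from_ratios(
                    _poisson_session(rng, 5.0, 16.35), condition=Condition.PRE_GABA
                ),
                Condition.GABA: EfficiencyResult.from_ratios(
                    _poisson_session(rng, 5.0, 16.35), condition=Condition.GABA
                ),
            }
            table = compare_phases(results)
            assert len(table) == 1
            ns += table[0].stars == "ns"
        assert ns >= 45

    def test_type_one_error_near_nominal(self, rng):
        """Under the null, rejection rate at 0.05 stays below 0.07 (500 sessions)."""
        rejections = 0
        for _ in range(500):
            a = _poisson_session(rng, 5.0, 5.0)
            b = _poisson_session(rng, 5.0, 5.0)
            if mann_whitney_u(a, b).p_value <= 0.05:
                rejections += 1
        assert rejections / 500 <= 0.07

    def test_doubled_evoked_detected(self, rng):
        """GABA doubling the evoked response is flagged in >= 90% of sessions."""
        hits = 0
        for _ in range(50):
            pre = _poisson_session(rng, 5.0, 10.0)
            gaba = _poisson_session(rng, 5.0, 20.0)
            hits += mann_whitney_u(pre, gaba).p_value <= 0.05
        assert hits >= 45

    def test_all_three_pairs_when_present(self, rng):
        results = {
            c: EfficiencyResult.from_ratios(_poisson_session(rng, 5.0, 8.0), condition=c)
            for c in (Condition.PRE_GABA, Condition.GABA, Condition.WASHOUT)
        }
        table = compare_phases(results)
        assert [t.groups for t in table] == [
            ("PRE_GABA", "GABA"),
            ("GABA", "WASHOUT"),
            ("PRE_GABA", "WASHOUT"),
        ]

    def test_single_condition_empty_table(self, rng):
        results = {
            Condition.PRE_GABA: EfficiencyResult.from_ratios(
                _poisson_session(rng, 5.0, 8.0)
            )
        }
        assert compare_phases(results) == []
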