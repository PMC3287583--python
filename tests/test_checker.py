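"""Checker numerics against analytic oracles and structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pumpmc import (
    bounded_reachability,
    bottom_sccs,
    expected_hitting_time,
    instantaneous_expected_reward,
    recurrent_pair_probability,
    transient_distribution,
    unbounded_reachability,
)
from pumpmc.checker import _absorb, prob01_states
from pumpmc.synthetic import (
    birth_death_chain,
    death_chain,
    forked_absorbing_chain,
    three_cycle_chain,
    two_state_chain,
)

ORACLES = {
    "two_state_irreversible": lambda: two_state_chain(1.0, 0.0),
    "two_state_symmetric": lambda: two_state_chain(1.0, 1.0),
    "two_state_asymmetric": lambda: two_state_chain(2.0, 3.0),
    "death_3": lambda: death_chain(3, 1.0),
    "death_5": lambda: death_chain(5, 2.0),
    "fork": lambda: forked_absorbing_chain(1.5, 0.5),
    "cycle": lambda: three_cycle_chain(1.3),
}


class TestClosedForms:
    @pytest.mark.parametrize("name", list(ORACLES))
    @pytest.mark.parametrize("t", [0.0, 0.1, 0.7, 2.5])
    def test_transient_matches_analytic(self, name, t):
        oc = ORACLES[name]()
        got = transient_distribution(oc.ctmc, t, method="uniformisation")
        np.testing.assert_allclose(got, oc.transient(t), atol=1e-8)
        assert got.sum() == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("name", list(ORACLES))
    def test_reachability_and_hitting_time(self, name):
        oc = ORACLES[name]()
        assert unbounded_reachability(oc.ctmc, oc.goal) == pytest.approx(
            oc.reach_prob, abs=1e-8
        )
        got = expected_hitting_time(oc.ctmc, oc.goal)
        if math.isinf(oc.hitting_time):
            assert math.isinf(got)
        else:
            assert got == pytest.approx(oc.hitting_time, abs=1e-8)

    @given(
        lam=st.floats(min_value=0.05, max_value=20),
        mu=st.floats(min_value=0.0, max_value=20),
        t=st.floats(min_value=0.0, max_value=5.0),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_two_state_family(self, lam, mu, t):
        oc = two_state_chain(lam, mu)
        got = transient_distribution(oc.ctmc, t, method="uniformisation")
        np.testing.assert_allclose(got, oc.transient(t), atol=1e-8)

    def test_gamblers_ruin(self):
        oc = birth_death_chain(10, 1.0, 2.0)
        assert unbounded_reachability(oc.ctmc, oc.goal) == pytest.approx(
            oc.reach_prob, abs=1e-10
        )


class TestBoundedReachability:
    def test_toy_exponential(self):
        oc = two_state_chain(1.0, 0.0)
        assert bounded_reachability(oc.ctmc, "goal", 1.0) == pytest.approx(
            1 - math.exp(-1), abs=1e-9
        )

    def test_zero_horizon_outside_goal(self):
        oc = two_state_chain(1.0, 0.0)
        assert bounded_reachability(oc.ctmc, "goal", 0.0) == 0.0

    def test_monotone_in_horizon(self, pump_nearest):
        ts = [0.0, 1e-4, 1e-2, 1.0, 10.0]
        vals = [bounded_reachability(pump_nearest, "kout_zero", t) for t in ts]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_converges_to_unbounded(self):
        oc = two_state_chain(0.8, 0.0)
        assert bounded_reachability(oc.ctmc, "goal", 60.0) == pytest.approx(
            unbounded_reachability(oc.ctmc, "goal"), abs=1e-9
        )

    def test_goal_absorption_idempotent(self, pump_nearest):
        """Pre-absorbing the goal must not change the bounded value."""
        mask = pump_nearest.states_with("kout_zero")
        absorbed = _absorb(pump_nearest, mask)
        for t in (0.01, 1.0):
            assert bounded_reachability(absorbed, "kout_zero", t) == pytest.approx(
                bounded_reachability(pump_nearest, "kout_zero", t), rel=1e-9, abs=1e-12
            )

    def test_negative_horizon_rejected(self, pump_nearest):
        with pytest.raises(ValueError):
            bounded_reachability(pump_nearest, "kout_zero", -1.0)

    def test_unknown_label_rejected(self, pump_nearest):
        with pytest.raises(KeyError):
            bounded_reachability(pump_nearest, "nope", 1.0)


class TestTransientOnPump:
    def test_point_mass_at_zero(self, pump_ceiling):
        pi = transient_distribution(pump_ceiling, 0.0)
        assert pi[pump_ceiling.initial] == 1.0 and pi.sum() == 1.0

    def test_uniformisation_matches_matrix_exponential(self, pump_ceiling):
        """Dual-route check on the stiff pump chain at a horizon where the
        Poisson series is affordable."""
        t = 2e-3
        pu = transient_distribution(pump_ceiling, t, method="uniformisation")
        pe = transient_distribution(pump_ceiling, t, method="expm")
        assert np.max(np.abs(pu - pe)) < 1e-8
        assert pu.sum() == pytest.approx(1.0, abs=1e-8)


class TestHittingTimes:
    def test_death_chain_sum_of_means(self):
        oc = death_chain(3, 1.0)
        assert expected_hitting_time(oc.ctmc, oc.goal) == pytest.approx(3.0, abs=1e-10)

    def test_unreachable_goal_is_infinite(self):
        oc = forked_absorbing_chain(1.0, 1.0)
        # from the B-absorbed state, A is unreachable
        per = unbounded_reachability(oc.ctmc, "goal", per_state=True)
        assert per[2] == 0.0
        t = expected_hitting_time(oc.ctmc, "goal")
        assert math.isinf(t)  # absorption at B with prob 1/2

    def test_filter_aggregation_on_pump(self, pump_nearest):
        lo = expected_hitting_time(
            pump_nearest, "kout_positive", from_filter="kout_zero", aggregation="min"
        )
        hi = expected_hitting_time(
            pump_nearest, "kout_positive", from_filter="kout_zero", aggregation="max"
        )
        per = expected_hitting_time(
            pump_nearest, "kout_positive", from_filter="kout_zero", aggregation="per-state"
        )
        assert 0 < lo <= hi
        assert min(per.values()) == pytest.approx(lo) and max(per.values()) == pytest.approx(hi)
        assert len(per) == int(pump_nearest.labels["kout_zero"].sum())

    def test_empty_filter_rejected(self, pump_ceiling):
        # under ceiling rounding no state has kOut = 0
        with pytest.raises(ValueError):
            expected_hitting_time(
                pump_ceiling, "kout_positive", from_filter="kout_zero"
            )


class TestInstantaneousReward:
    def test_kout_at_zero_is_initial_count(self, pump_ceiling):
        assert instantaneous_expected_reward(
            pump_ceiling, "kOut", 0.0
        ) == pump_ceiling.network.KO

    def test_unit_time_reward_everywhere(self, pump_ceiling):
        for t in (0.0, 0.5):
            assert instantaneous_expected_reward(pump_ceiling, "time", t) == pytest.approx(
                1.0, abs=1e-8
            )

    def test_unknown_reward_rejected(self, pump_ceiling):
        with pytest.raises(KeyError):
            instantaneous_expected_reward(pump_ceiling, "entropy", 1.0)


class TestQualitative:
    def test_prob01_classification_on_fork(self):
        oc = forked_absorbing_chain(1.0, 3.0)
        p0, p1 = prob01_states(oc.ctmc, "goal")
        assert p0.tolist() == [False, False, True]
        assert p1.tolist() == [False, True, False]

    def test_bsccs_of_fork_are_the_two_sinks(self):
        oc = forked_absorbing_chain(1.0, 1.0)
        comps = sorted(tuple(c.tolist()) for c in bottom_sccs(oc.ctmc))
        assert comps == [(1,), (2,)]

    def test_recurrent_pair_on_irreducible_cycle(self):
        oc = three_cycle_chain(2.0)
        assert recurrent_pair_probability(oc.ctmc, "start", "goal") == 1.0

    def test_recurrent_pair_zero_when_absorbed_apart(self):
        oc = forked_absorbing_chain(1.0, 1.0)
        assert recurrent_pair_probability(oc.ctmc, "goal", "other") == 0.0
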