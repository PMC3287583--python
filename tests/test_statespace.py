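"""Reachability exploration, labelling, rewards, conservation, exports."""

import numpy as np
import pytest

from pumpmc import (
    CONFORMATIONS,
    CountPredicate,
    KineticParameters,
    RewardStructure,
    SPECIES,
    VolumeContext,
    attach_rewards,
    build_network,
    conserved_quantities,
    explore,
    label_states,
)
from pumpmc.pump_model import Reaction, ReactionNetwork
from pumpmc.statespace import StateSpaceLimitError, to_dot, to_state_table


def toy_conversion_network() -> ReactionNetwork:
    """Single irreversible unimolecular conversion of one pump molecule."""
    rx = Reaction(
        label="conv",
        source_conformation="E1.ATP",
        target_conformation="Na3.E1.ATP",
        species_deltas={},
        reagent_exponents={},
        kinetic_constant=1.0,
        molecularity=1,
        stochastic_constant=1.0,
    )
    return ReactionNetwork(
        reactions=(rx,),
        species=SPECIES,
        n_pumps=1,
        initial_counts={s: 0 for s in SPECIES},
        initial_conformation="E1.ATP",
        volume=1e-20,
        rounding="nearest",
    )


class TestExplore:
    @pytest.mark.parametrize(
        "volume, n_states, n_transitions",
        [(1e-20, 194, 386), (1e-21, 32, 62), (1e-22, 9, 16)],
    )
    def test_ceiling_state_counts(self, params, volume, n_states, n_transitions):
        ctmc = explore(
            build_network(params, VolumeContext(volume=volume, rounding="ceiling"))
        )
        assert (ctmc.n_states, ctmc.n_transitions) == (n_states, n_transitions)

    def test_nearest_state_counts(self, pump_nearest):
        assert (pump_nearest.n_states, pump_nearest.n_transitions) == (188, 374)

    def test_toy_network(self):
        ctmc = explore(toy_conversion_network())
        assert (ctmc.n_states, ctmc.n_transitions) == (2, 1)
        assert ctmc.exit_rates()[1] == 0.0  # absorbing end state is retained

    def test_state_count_monotone_in_volume(self, params):
        sizes = [
            explore(
                build_network(params, VolumeContext(volume=v, rounding="ceiling"))
            ).n_states
            for v in (1e-22, 1e-21, 1e-20)
        ]
        assert sizes == sorted(sizes)

    def test_state_cap(self, params, ctx_ceiling):
        with pytest.raises(StateSpaceLimitError):
            explore(build_network(params, ctx_ceiling), max_states=10)

    def test_transitions_replay_to_their_targets(self, pump_ceiling):
        """Applying the annotated reaction to each source state yields the
        annotated target state exactly."""
        net = pump_ceiling.network
        conf_idx = {c: i for i, c in enumerate(CONFORMATIONS)}
        for k in range(pump_ceiling.n_transitions):
            src = pump_ceiling.states[pump_ceiling.t_src[k]]
            dst = pump_ceiling.states[pump_ceiling.t_dst[k]]
            r = net.reaction(pump_ceiling.t_label[k])
            expected_sp = list(src.species)
            for sp, d in r.species_deltas.items():
                expected_sp[net.species.index(sp)] += d
            expected_cf = list(src.conformations)
            expected_cf[conf_idx[r.source_conformation]] -= 1
            expected_cf[conf_idx[r.target_conformation]] += 1
            assert tuple(expected_sp) == dst.species
            assert tuple(expected_cf) == dst.conformations


class TestConservation:
    @pytest.mark.parametrize("fixture", ["pump_ceiling", "pump_nearest"])
    def test_all_four_laws_on_every_reachable_state(self, fixture, request):
        ctmc = request.getfixturevalue(fixture)
        totals = conserved_quantities(
            ctmc.species_matrix(), ctmc.conformation_matrix()
        )
        assert np.all(totals == totals[0])

    def test_pump_count_conserved(self, pump_ceiling):
        assert np.all(pump_ceiling.conformation_matrix().sum(axis=1) == 1)


class TestLabels:
    def test_initial_state_is_full(self, pump_ceiling):
        assert pump_ceiling.labels["kout_initial"][pump_ceiling.initial]

    def test_zero_and_full_labels_disjoint_nonempty(self, pump_nearest):
        zero = pump_nearest.labels["kout_zero"]
        full = pump_nearest.labels["kout_initial"]
        assert zero.any() and full.any()
        assert not (zero & full).any()

    def test_unknown_species_predicate_rejected(self, pump_ceiling):
        with pytest.raises(KeyError):
            label_states(pump_ceiling, {"bogus": CountPredicate("Ca", "==", 0)})

    def test_duplicate_label_rejected(self, pump_ceiling):
        with pytest.raises(ValueError):
            label_states(pump_ceiling, {"kout_zero": CountPredicate("K_o", "==", 0)})


class TestRewards:
    def test_time_reward_is_one_everywhere(self, pump_ceiling):
        assert np.all(pump_ceiling.state_rewards["time"] == 1.0)

    def test_kout_reward_at_initial_equals_ko(self, pump_ceiling):
        assert (
            pump_ceiling.state_rewards["kOut"][pump_ceiling.initial]
            == pump_ceiling.network.KO
        )

    def test_transport_rewards_mark_step4_firings(self, pump_ceiling):
        minus = pump_ceiling.transition_rewards["minusKout"]
        plus = pump_ceiling.transition_rewards["plusKout"]
        for k in range(pump_ceiling.n_transitions):
            assert minus[k] == (1.0 if pump_ceiling.t_label[k] == "r4" else 0.0)
            assert plus[k] == (1.0 if pump_ceiling.t_label[k] == "rr4" else 0.0)

    def test_duplicate_reward_rejected(self, pump_ceiling):
        with pytest.raises(ValueError):
            attach_rewards(
                pump_ceiling, RewardStructure("time", state_rewards=lambda s: 1.0)
            )


class TestExports:
    def test_dot_deterministic_and_sized(self):
        ctmc = explore(toy_conversion_network())
        text = to_dot(ctmc)
        assert text == to_dot(ctmc)
        assert text.count("shape=") == 2 and text.count("->") == 1

    def test_state_table_row_count(self, pump_ceiling):
        assert len(to_state_table(pump_ceiling)) == pump_ceiling.n_states
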