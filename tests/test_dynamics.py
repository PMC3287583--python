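"""Gillespie simulation and the deterministic mass-action limit."""

import numpy as np
import pytest

from pumpmc import (
    KineticParameters,
    bounded_reachability,
    conserved_quantities,
    ensemble_mean,
    explore,
    ode_solve,
    ssa_trajectory,
)


class TestSsaTrajectory:
    def test_identical_seed_identical_trajectory(self, net_small):
        a = ssa_trajectory(net_small, 0.5, seed=42)
        b = ssa_trajectory(net_small, 0.5, seed=42)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.species, b.species)
        assert np.array_equal(a.reactions, b.reactions)

    def test_different_seed_different_trajectory(self, net_small):
        a = ssa_trajectory(net_small, 0.5, seed=1)
        b = ssa_trajectory(net_small, 0.5, seed=2)
        assert not np.array_equal(a.times, b.times)

    def test_times_strictly_increasing(self, net_small):
        tr = ssa_trajectory(net_small, 0.5, seed=3)
        assert np.all(np.diff(tr.times) > 0)

    def test_conservation_at_every_event(self, net_small):
        tr = ssa_trajectory(net_small, 1.0, seed=5)
        totals = conserved_quantities(tr.species, tr.conformations)
        assert np.all(totals == totals[0])

    def test_consecutive_snapshots_differ_by_one_reaction(self, net_small):
        tr = ssa_trajectory(net_small, 0.2, seed=7)
        deltas = np.array(
            [
                [r.species_deltas.get(s, 0) for s in net_small.species]
                for r in net_small.reactions
            ]
        )
        for i, k in enumerate(tr.reactions[:200]):
            assert np.array_equal(
                tr.species[i + 1] - tr.species[i], deltas[k]
            )

    def test_empty_network_yields_single_snapshot(self):
        from pumpmc import VolumeContext, build_network

        dead = KineticParameters(
            conc_NaIn=0, conc_NaOut=0, conc_KIn=0, conc_KOut=0,
            conc_ATP=0, conc_Pi=0, conc_ADP=0,
        )
        net = build_network(dead, VolumeContext(volume=1e-20))
        tr = ssa_trajectory(net, 1.0, seed=0)
        assert tr.n_events == 0 and len(tr.times) == 1

    def test_rare_event_frequency_consistent_with_checker(self, net_nearest, pump_nearest):
        """The depletion probability within 10 s is so small that no short
        ensemble should ever observe it; the binomial 3-SE band around the
        checker's value contains the observed frequency."""
        p = bounded_reachability(pump_nearest, "kout_zero", 10.0)
        n = 60
        hits = 0
        for run in range(n):
            tr = ssa_trajectory(net_nearest, 10.0, seed=1000 + run)
            ko = tr.species[:, list(net_nearest.species).index("K_o")]
            hits += int((ko == 0).any())
        se = np.sqrt(max(p * (1 - p), p) / n)
        assert abs(hits / n - p) <= 3 * se + 1e-12


class TestEnsembleMean:
    def test_degenerate_network_zero_se(self):
        from pumpmc import VolumeContext, build_network

        dead = KineticParameters(
            conc_NaIn=0, conc_NaOut=0, conc_KIn=0, conc_KOut=0.01,
            conc_ATP=0, conc_Pi=0, conc_ADP=0,
        )
        net = build_network(dead, VolumeContext(volume=1e-20))
        em = ensemble_mean(net, "K_o", np.array([0.0, 1.0]), n_runs=2, seed=0)
        assert np.all(em["mean"] == net.initial_counts["K_o"])
        assert np.all(em["se"] == 0.0)

    def test_validation_errors(self, net_small):
        with pytest.raises(ValueError):
            ensemble_mean(net_small, "K_o", np.array([0.0, 1.0]), n_runs=1, seed=0)
        with pytest.raises(ValueError):
            ensemble_mean(net_small, "K_o", np.array([]), n_runs=4, seed=0)
        with pytest.raises(KeyError):
            ensemble_mean(net_small, "Ca", np.array([0.0]), n_runs=4, seed=0)

    def test_se_shrinks_with_ensemble_size(self, net_small):
        grid = np.linspace(0.0, 0.5, 6)
        small = ensemble_mean(net_small, "K_o", grid, n_runs=60, seed=9)
        large = ensemble_mean(net_small, "K_o", grid, n_runs=240, seed=9)
        ratio = np.median(large["se"][1:] / small["se"][1:])
        assert 0.3 < ratio < 0.8  # ~ 1/2 expected for 4x the runs


class TestOde:
    def test_total_potassium_conserved(self, params):
        sol = ode_solve(params, np.linspace(0, 10, 41), volume=1e-20)
        ept = 1.0
        frac = sol.conformation_fractions
        bound = 2 * (frac["K2.E2"] + frac["K2.E1.ATP"]) / (6.022e23 * 1e-20)
        total = sol["K_i"] + sol["K_o"] + bound.to_numpy()
        assert np.max(np.abs(total - total[0])) < 1e-9

    def test_conformation_fractions_sum_to_one(self, params):
        sol = ode_solve(params, np.linspace(0, 10, 11), volume=1e-20)
        sums = sol.conformation_fractions.sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_self_convergence_under_tighter_tolerances(self, params):
        grid = np.array([0.0, 10.0])
        a = ode_solve(params, grid, volume=1e-20, rtol=1e-9, atol=1e-14)
        b = ode_solve(params, grid, volume=1e-20, rtol=1e-11, atol=1e-16)
        assert abs(a["K_o"][-1] - b["K_o"][-1]) < 1e-6

    def test_plateau_value_from_this_kinetics_set(self, params):
        """[K_o] relaxes to the mass-action equilibrium ~0.00246 M, the value
        fixed by detailed balance of the twelve published coefficients."""
        sol = ode_solve(params, np.linspace(0, 10, 41), volume=1e-20)
        assert sol["K_o"][-1] == pytest.approx(0.002461, rel=1e-3)

    def test_grid_validation(self, params):
        with pytest.raises(ValueError):
            ode_solve(params, np.array([1.0, 0.5]))
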