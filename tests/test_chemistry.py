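"""Discrete-chemistry conversions: counts, stochastic constants, propensities."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from pumpmc import (
    AVOGADRO,
    VolumeContext,
    kinetic_to_stochastic,
    molarity_to_count,
)
from pumpmc.chemistry import mass_action_propensity

NAV20 = AVOGADRO * 1e-20  # 6022 count-units per molar at the analysis volume


class TestMolarityToCount:
    @pytest.mark.parametrize(
        "conc, rounding, expected",
        [
            (0.01, "ceiling", 61),   # the study's initial extracellular K
            (0.01, "nearest", 60),
            (0.005, "nearest", 30),  # 0.005 * 6022 = 30.11
            (0.0, "ceiling", 0),
            (0.0, "floor", 0),
        ],
    )
    def test_examples(self, conc, rounding, expected):
        ctx = VolumeContext(volume=1e-20, rounding=rounding)
        assert molarity_to_count(conc, ctx) == expected

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            molarity_to_count(-1e-3, VolumeContext(volume=1e-20))

    @given(
        conc=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        rounding=st.sampled_from(["nearest", "floor", "ceiling"]),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_error_below_one_count(self, conc, rounding):
        """count/(V N_A) recovers the concentration to within one count."""
        ctx = VolumeContext(volume=1e-20, rounding=rounding)
        count = molarity_to_count(conc, ctx)
        assert count >= 0
        # one-count bound, with <= for the float-degenerate tiny-c cases
        assert abs(count / ctx.nav - conc) <= 1.0 / ctx.nav


class TestKineticToStochastic:
    def test_unimolecular_identity(self):
        ctx = VolumeContext(volume=1e-20)
        assert kinetic_to_stochastic(1e4, 1, ctx) == 1e4

    @pytest.mark.parametrize(
        "k, kappa, expected",
        [
            (1.5e7, 3, 1.5e7 / NAV20**2),   # ~0.41363 /s, the step-4 constant
            (2.5e11, 4, 2.5e11 / NAV20**3),  # ~1.1448 /s, the step-1 constant
        ],
    )
    def test_dimensional_analysis(self, k, kappa, expected):
        ctx = VolumeContext(volume=1e-20)
        assert kinetic_to_stochastic(k, kappa, ctx) == pytest.approx(expected, rel=1e-12)
        # spot values quoted to 5 significant digits
        assert kinetic_to_stochastic(1.5e7, 3, ctx) == pytest.approx(0.41363, rel=1e-4)
        assert kinetic_to_stochastic(2.5e11, 4, ctx) == pytest.approx(1.1448, rel=1e-4)

    def test_invalid_molecularity(self):
        ctx = VolumeContext(volume=1e-20)
        with pytest.raises(ValueError):
            kinetic_to_stochastic(1.0, 0, ctx)

    @given(
        k=st.floats(min_value=1e-6, max_value=1e12),  # physical coefficient range
        kappa=st.integers(min_value=2, max_value=4),
        scale=st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_linear_in_k_and_decreasing_in_volume(self, k, kappa, scale):
        small = VolumeContext(volume=1e-20)
        large = VolumeContext(volume=2e-20)
        assert kinetic_to_stochastic(scale * k, kappa, small) == pytest.approx(
            scale * kinetic_to_stochastic(k, kappa, small)
        )
        assert kinetic_to_stochastic(k, kappa, large) < kinetic_to_stochastic(
            k, kappa, small
        )


class TestPropensity:
    def test_step4_example(self):
        """c * 1 pump * kOut^2 with the converted step-4 constant at kOut=60."""
        c = 1.5e7 / NAV20**2
        p = mass_action_propensity(c, 1, {"K_o": 2}, {"K_o": 60})
        assert p == pytest.approx(c * 3600, rel=1e-12)
        assert p == pytest.approx(1489.1, rel=1e-3)

    def test_vanishes_without_reagents(self):
        assert mass_action_propensity(1.0, 1, {"K_o": 2}, {"K_o": 1}) == 0.0
        assert mass_action_propensity(1.0, 0, {}, {}) == 0.0

    def test_unimolecular_is_constant_times_occupancy(self):
        assert mass_action_propensity(172.0, 3, {}, {}) == pytest.approx(3 * 172.0)

    def test_homogeneous_in_constant(self):
        counts = {"A": 5, "B": 2}
        base = mass_action_propensity(0.7, 2, {"A": 3, "B": 1}, counts)
        assert mass_action_propensity(1.4, 2, {"A": 3, "B": 1}, counts) == pytest.approx(
            2 * base
        )

    def test_combinatorial_option_uses_falling_factorials(self):
        raw = mass_action_propensity(1.0, 1, {"A": 2}, {"A": 5})
        comb = mass_action_propensity(1.0, 1, {"A": 2}, {"A": 5}, combinatorial=True)
        assert raw == 25.0 and comb == 20.0


def test_volume_context_validation():
    with pytest.raises(ValueError):
        VolumeContext(volume=0.0)
    with pytest.raises(ValueError):
        VolumeContext(volume=1e-20, rounding="stochastic")
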