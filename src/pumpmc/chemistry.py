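"""Discrete-chemistry conversions and mass-action propensities.

A stochastic, molecule-counting description of a reaction system needs three
conversions from the continuous (molar) description:

* initial molarities become integer counts, ``#X = round([X] * V * N_A)``;
* kinetic rate coefficients (units ``M^-(kappa-1) s^-1``) become stochastic
  rate constants (units ``s^-1`` per combination of reactant counts),
  ``c = k / (N_A * V)^(kappa-1)`` where ``kappa`` is the molecularity of the
  elementary reaction, counting every reacting entity including the enzyme;
* reaction propensities follow the law of mass action on counts.

Propensities use raw powers of the reactant counts (``c * E * n_K^2`` for a
step consuming two potassium ions), matching guarded-command model-checking
practice for this system; the combinatorial (falling-factorial) form of the
chemical master equation is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

AVOGADRO = 6.022e23
"""Avogadro constant in 1/mol, at the precision used throughout."""

ROUNDING_MODES = ("nearest", "floor", "ceiling")


@dataclass(frozen=True)
class VolumeContext:
    """Reaction volume plus the count-rounding convention.

    The rounding convention is not cosmetic: it decides the parity of the
    two-ion potassium counts and with it the reachability of ``kOut = 0``
    (see :mod:`pumpmc.statespace`).  ``ceiling`` is the package default
    because it is the convention calibrated against the reference state-space
    sizes of this model.
    """

    volume: float
    avogadro: float = AVOGADRO
    rounding: str = "ceiling"

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"volume must be positive, got {self.volume}")
        if self.avogadro <= 0:
            raise ValueError(f"avogadro must be positive, got {self.avogadro}")
        if self.rounding not in ROUNDING_MODES:
            raise ValueError(
                f"rounding must be one of {ROUNDING_MODES}, got {self.rounding!r}"
            )

    @property
    def nav(self) -> float:
        """``N_A * V``: counts per molar unit in this volume."""
        return self.avogadro * self.volume


def molarity_to_count(concentration: float, ctx: VolumeContext) -> int:
    """Convert a molar concentration to an integer molecule/ion count.

    Parameters
    ----------
    concentration
        Concentration in M; must be nonnegative.
    ctx
        Volume context supplying ``V``, ``N_A`` and the rounding mode.
    """
    if concentration < 0:
        raise ValueError(f"concentration must be nonnegative, got {concentration}")
    x = concentration * ctx.nav
    if ctx.rounding == "nearest":
        return int(round(x))
    if ctx.rounding == "floor":
        return math.floor(x)
    return math.ceil(x)


def kinetic_to_stochastic(k: float, molecularity: int, ctx: VolumeContext) -> float:
    """Convert a kinetic rate coefficient to a stochastic rate constant.

    ``c = k / (N_A V)^(molecularity - 1)``.  Unimolecular coefficients pass
    through unchanged.  ``molecularity`` counts all reacting entities,
    enzyme included (for ``A + 2B -> AB2`` it is 3).
    """
    if k < 0:
        raise ValueError(f"rate coefficient must be nonnegative, got {k}")
    if not isinstance(molecularity, int) or molecularity < 1:
        raise ValueError(f"molecularity must be a positive integer, got {molecularity}")
    return k / ctx.nav ** (molecularity - 1)


def mass_action_propensity(
    stochastic_constant: float,
    source_conformation_count: int,
    reagent_exponents: dict[str, int],
    counts: dict[str, int],
    combinatorial: bool = False,
) -> float:
    """Raw mass-action propensity from explicit count data.

    Returns ``c * n_conf * prod_x counts[x]^m_x`` and 0 whenever any reagent
    count falls below its stoichiometry.  With ``combinatorial=True`` the
    raw powers are replaced by falling factorials ``n(n-1)...(n-m+1)``,
    the chemical-master-equation convention.  Raw powers are the default
    convention for every analysis in this package.
    """
    if source_conformation_count <= 0:
        return 0.0
    p = stochastic_constant * source_conformation_count
    for species, m in reagent_exponents.items():
        n = counts[species]
        if n < m:
            return 0.0
        if combinatorial:
            for i in range(m):
                p *= n - i
        else:
            p *= n**m
    return p


def propensity(reaction, state, combinatorial: bool = False) -> float:
    """Mass-action propensity of ``reaction`` in ``state``.

    ``reaction`` needs ``stochastic_constant``, ``source_conformation`` and
    ``reagent_exponents`` attributes; ``state`` needs ``species_counts`` and
    ``conformation_counts`` mappings (duck-typed so the chemistry layer does
    not depend on the model layer).
    """
    return mass_action_propensity(
        reaction.stochastic_constant,
        state.conformation_counts[reaction.source_conformation],
        reaction.reagent_exponents,
        state.species_counts,
        combinatorial=combinatorial,
    )
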