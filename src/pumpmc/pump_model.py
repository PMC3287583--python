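"""The six-step reversible Albers-Post reaction network of the Na,K-pump.

The pump enzyme cycles through six conformations, exporting three sodium
ions and importing two potassium ions per ATP hydrolysed:

====  =============================================  ====================
step  forward reaction                               conformation change
====  =============================================  ====================
1     E1.ATP + 3 Na_i   -> Na3.E1.ATP                E1.ATP     -> Na3.E1.ATP
2     Na3.E1.ATP        -> Na3.E1~P + ADP            Na3.E1.ATP -> Na3.E1~P
3     Na3.E1~P          -> E2~P + 3 Na_o             Na3.E1~P   -> E2~P
4     E2~P + 2 K_o      -> K2.E2 + P_i               E2~P       -> K2.E2
5     K2.E2 + ATP       -> K2.E1.ATP                 K2.E2      -> K2.E1.ATP
6     K2.E1.ATP         -> E1.ATP + 2 K_i            K2.E1.ATP  -> E1.ATP
====  =============================================  ====================

Every step is reversible (labels ``r1..r6`` forward, ``rr1..rr6`` backward);
the backward stoichiometries follow from the units of the published rate
coefficients (e.g. ``b3`` in M^-3 s^-1 binds three extracellular sodium
ions).  Bound nucleotide and phosphoryl bookkeeping lives in the
conformation label, so the free-ATP count changes only at steps 5 (forward)
and backward 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import NamedTuple

from .chemistry import VolumeContext, kinetic_to_stochastic, molarity_to_count

SPECIES = ("Na_i", "Na_o", "K_i", "K_o", "ATP", "ADP", "P_i")
CONFORMATIONS = ("E1.ATP", "Na3.E1.ATP", "Na3.E1~P", "E2~P", "K2.E2", "K2.E1.ATP")

#: per-step (reagent stoichiometries, species deltas) for the forward direction
_FORWARD = (
    ({"Na_i": 3}, {"Na_i": -3}),
    ({}, {"ADP": +1}),
    ({}, {"Na_o": +3}),
    ({"K_o": 2}, {"K_o": -2, "P_i": +1}),
    ({"ATP": 1}, {"ATP": -1}),
    ({}, {"K_i": +2}),
)


@dataclass(frozen=True)
class KineticParameters:
    """Initial concentrations (M) and rate coefficients of the pump cycle.

    Defaults are the published experimental data set for this mechanism.
    ``temperature`` is stored for provenance only; no computation uses it.
    Units of the coefficients: ``f1`` M^-3 s^-1, ``f2`` s^-1, ``f3`` s^-1,
    ``f4`` M^-2 s^-1, ``f5`` M^-1 s^-1, ``f6`` s^-1, ``b1`` s^-1, ``b2``
    M^-1 s^-1, ``b3`` M^-3 s^-1, ``b4`` M^-1 s^-1, ``b5`` s^-1, ``b6``
    M^-2 s^-1.
    """

    conc_NaIn: float = 0.022
    conc_NaOut: float = 0.14
    conc_KIn: float = 0.127
    conc_KOut: float = 0.01
    conc_ATP: float = 0.005
    conc_Pi: float = 0.00495
    conc_ADP: float = 0.00006
    f1: float = 2.5e11
    f2: float = 1e4
    f3: float = 172.0
    f4: float = 1.5e7
    f5: float = 2e6
    f6: float = 1.15e4
    b1: float = 1e5
    b2: float = 1e5
    b3: float = 1.72e4
    b4: float = 2e5
    b5: float = 30.0
    b6: float = 6e8
    volume: float = 1e-12
    temperature: float = 310.0

    def concentrations(self) -> dict[str, float]:
        return {
            "Na_i": self.conc_NaIn,
            "Na_o": self.conc_NaOut,
            "K_i": self.conc_KIn,
            "K_o": self.conc_KOut,
            "ATP": self.conc_ATP,
            "ADP": self.conc_ADP,
            "P_i": self.conc_Pi,
        }

    def forward_rates(self) -> tuple[float, ...]:
        return (self.f1, self.f2, self.f3, self.f4, self.f5, self.f6)

    def backward_rates(self) -> tuple[float, ...]:
        return (self.b1, self.b2, self.b3, self.b4, self.b5, self.b6)

    @classmethod
    def from_mapping(cls, data: dict) -> "KineticParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "KineticParameters":
        """Load parameters from a YAML or JSON mapping."""
        import json

        import yaml

        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_mapping(data)


#: molecularity of each step, forward and backward, from the coefficient units
FORWARD_MOLECULARITY = (4, 1, 1, 3, 2, 1)
BACKWARD_MOLECULARITY = (1, 2, 4, 2, 1, 3)


@dataclass(frozen=True)
class Reaction:
    """One elementary, directed reaction of the pump cycle."""

    label: str
    source_conformation: str
    target_conformation: str
    species_deltas: dict[str, int]
    reagent_exponents: dict[str, int]
    kinetic_constant: float
    molecularity: int
    stochastic_constant: float

    def apply(self, counts: dict[str, int]) -> dict[str, int]:
        """Species counts after one firing (conformation change not included)."""
        out = dict(counts)
        for sp, d in self.species_deltas.items():
            out[sp] += d
        return out


@dataclass(frozen=True)
class ReactionNetwork:
    """The 12 directed reactions plus the discrete initial condition."""

    reactions: tuple[Reaction, ...]
    species: tuple[str, ...]
    n_pumps: int
    initial_counts: dict[str, int]
    initial_conformation: str
    volume: float
    rounding: str

    @property
    def KO(self) -> int:
        """Initial extracellular potassium count."""
        return self.initial_counts["K_o"]

    def reaction(self, label: str) -> Reaction:
        for r in self.reactions:
            if r.label == label:
                return r
        raise KeyError(label)

    def initial_state(self):
        from .statespace import State

        confs = [0] * len(CONFORMATIONS)
        confs[CONFORMATIONS.index(self.initial_conformation)] = self.n_pumps
        return State(
            species=tuple(self.initial_counts[s] for s in self.species),
            conformations=tuple(confs),
        )


def build_network(
    params: KineticParameters,
    ctx: VolumeContext,
    n_pumps: int = 1,
) -> ReactionNetwork:
    """Assemble the discrete reaction network from kinetic parameters.

    The pump starts in E1.ATP; species counts come from the molarity
    conversion under ``ctx.rounding``; stochastic constants from the
    molecularity-dependent rate conversion.
    """
    if n_pumps < 1:
        raise ValueError(f"n_pumps must be >= 1, got {n_pumps}")
    fwd = params.forward_rates()
    bwd = params.backward_rates()
    reactions: list[Reaction] = []
    for i in range(6):
        reagents, deltas = _FORWARD[i]
        src = CONFORMATIONS[i]
        dst = CONFORMATIONS[(i + 1) % 6]
        kf = FORWARD_MOLECULARITY[i]
        reactions.append(
            Reaction(
                label=f"r{i + 1}",
                source_conformation=src,
                target_conformation=dst,
                species_deltas=dict(deltas),
                reagent_exponents=dict(reagents),
                kinetic_constant=fwd[i],
                molecularity=kf,
                stochastic_constant=kinetic_to_stochastic(fwd[i], kf, ctx),
            )
        )
    for i in range(6):
        reagents_f, deltas_f = _FORWARD[i]
        # backward reaction: mirror of the forward one
        deltas = {sp: -d for sp, d in deltas_f.items()}
        # reagents of the backward direction are the species the forward
        # direction released (positive forward deltas)
        reagents = {sp: d for sp, d in deltas_f.items() if d > 0}
        kb = BACKWARD_MOLECULARITY[i]
        reactions.append(
            Reaction(
                label=f"rr{i + 1}",
                source_conformation=CONFORMATIONS[(i + 1) % 6],
                target_conformation=CONFORMATIONS[i],
                species_deltas=deltas,
                reagent_exponents=reagents,
                kinetic_constant=bwd[i],
                molecularity=kb,
                stochastic_constant=kinetic_to_stochastic(bwd[i], kb, ctx),
            )
        )
    initial = {
        sp: molarity_to_count(c, ctx) for sp, c in params.concentrations().items()
    }
    return ReactionNetwork(
        reactions=tuple(reactions),
        species=SPECIES,
        n_pumps=n_pumps,
        initial_counts=initial,
        initial_conformation="E1.ATP",
        volume=ctx.volume,
        rounding=ctx.rounding,
    )


class Finding(NamedTuple):
    severity: str  # "error" | "warning"
    message: str


def validate_parameters(
    params: KineticParameters, ctx: VolumeContext | None = None
) -> list[Finding]:
    """Sanity-check a parameter set; reporting only, never raises.

    Flags negative concentrations/coefficients, non-positive volume, and the
    parity hazard: an odd initial K_o count makes ``kOut = 0`` unreachable
    because every reaction changes K_o by 0 or +-2.
    """
    findings: list[Finding] = []
    for name, value in params.concentrations().items():
        if value < 0:
            findings.append(Finding("error", f"negative concentration for {name}"))
    for i, (f, b) in enumerate(zip(params.forward_rates(), params.backward_rates())):
        if f < 0:
            findings.append(Finding("error", f"negative rate coefficient f{i + 1}"))
        if b < 0:
            findings.append(Finding("error", f"negative rate coefficient b{i + 1}"))
    if params.volume <= 0:
        findings.append(Finding("error", "volume must be positive"))
    if ctx is not None and not any(f.severity == "error" for f in findings):
        ko = molarity_to_count(params.conc_KOut, ctx)
        if ko % 2 == 1:
            findings.append(
                Finding(
                    "warning",
                    f"initial K_o count {ko} is odd: kOut=0 is unreachable "
                    "under the two-ion potassium steps",
                )
            )
    return findings
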