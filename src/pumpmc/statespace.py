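"""Explicit-state CTMC: reachability exploration, labels, rewards, exports.

The continuous-time Markov chain is the tuple (S, R, L): a finite state set,
a sparse transition-rate matrix whose entries are mass-action propensities,
and a labelling of states with atomic propositions.  States are discovered
by breadth-first closure from the initial state; BFS discovery order (with
reactions tried in the fixed order r1..r6, rr1..rr6) defines the canonical
state indexing, so all exports are byte-reproducible.

Reward structures attach real values to states (accumulated per unit time)
or to transitions (accumulated per firing); the standard set for the pump is

* ``kOut``  - state reward, the current extracellular potassium count;
* ``time``  - state reward 1 everywhere (expected-time queries);
* ``minusKout`` - transition reward 1 on every r4 firing (consumes 2 K_o);
* ``plusKout``  - transition reward 1 on every rr4 firing (releases 2 K_o).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import scipy.sparse as sp

from .chemistry import mass_action_propensity
from .pump_model import CONFORMATIONS, Reaction, ReactionNetwork


class StateSpaceLimitError(RuntimeError):
    """Raised when exploration exceeds the configured state-count cap."""


@dataclass(frozen=True)
class State:
    """Counts of the free species plus the pump-conformation occupancies."""

    species: tuple[int, ...]
    conformations: tuple[int, ...]

    @property
    def species_counts(self):  # mapping view used by the chemistry layer
        return _SpeciesView(self)

    @property
    def conformation_counts(self):
        return _ConfView(self)


class _SpeciesView:
    """Read-only mapping from species name to count for one State."""

    __slots__ = ("_s",)

    def __init__(self, s: State):
        self._s = s

    def __getitem__(self, name: str) -> int:
        from .pump_model import SPECIES

        return self._s.species[SPECIES.index(name)]


class _ConfView:
    __slots__ = ("_s",)

    def __init__(self, s: State):
        self._s = s

    def __getitem__(self, name: str) -> int:
        return self._s.conformations[CONFORMATIONS.index(name)]


@dataclass
class RewardStructure:
    """Named reward assignment.

    ``state_rewards`` maps a state to a real (default 0 via ``None``);
    ``transition_rewards`` maps a reaction label to the reward earned each
    time that reaction fires, optionally restricted by a guard on the source
    state.
    """

    name: str
    state_rewards: Callable[[State], float] | None = None
    transition_rewards: dict[str, float] = field(default_factory=dict)
    transition_guard: Callable[[State], bool] | None = None


@dataclass
class CountPredicate:
    """Atomic proposition ``<species> <op> <value>`` on the free-species counts.

    ``value`` may be an int or the string ``"KO"`` (the initial count of the
    species, resolved against the network at labelling time).
    """

    species: str
    op: str  # "==", ">", "<", ">=", "<="
    value: int | str

    _OPS = {
        "==": np.equal,
        ">": np.greater,
        "<": np.less,
        ">=": np.greater_equal,
        "<=": np.less_equal,
    }

    def evaluate(self, counts: np.ndarray, species: tuple[str, ...], initial: dict) -> np.ndarray:
        if self.species not in species:
            raise KeyError(f"unknown species {self.species!r}")
        v = initial[self.species] if self.value == "KO" else self.value
        return self._OPS[self.op](counts[:, species.index(self.species)], v)


class CTMC:
    """Explicit-state CTMC with labels and rewards.

    Attributes
    ----------
    states : list
        Canonically ordered states (index 0 is the initial state for chains
        produced by :func:`explore`; synthetic chains set ``initial``).
    t_src, t_dst, t_rate, t_label : arrays
        Parallel transition arrays (source index, target index, positive
        rate, annotating reaction label).
    labels : dict[str, np.ndarray]
        Boolean state masks per atomic proposition.
    """

    def __init__(
        self,
        states: list,
        t_src: np.ndarray,
        t_dst: np.ndarray,
        t_rate: np.ndarray,
        t_label: list[str],
        initial: int = 0,
        network: ReactionNetwork | None = None,
    ):
        self.states = states
        self.t_src = np.asarray(t_src, dtype=np.int64)
        self.t_dst = np.asarray(t_dst, dtype=np.int64)
        self.t_rate = np.asarray(t_rate, dtype=float)
        self.t_label = list(t_label)
        self.initial = initial
        self.network = network
        self.labels: dict[str, np.ndarray] = {}
        self.state_rewards: dict[str, np.ndarray] = {}
        self.transition_rewards: dict[str, np.ndarray] = {}
        if np.any(self.t_rate <= 0):
            raise ValueError("all transition rates must be positive")
        if np.any(self.t_src == self.t_dst):
            raise ValueError("self-loops are not permitted")

    # -- structure ---------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.t_rate)

    def rate_matrix(self) -> sp.csr_matrix:
        """Sparse R with R[s, s'] = total rate of transitions s -> s'."""
        return sp.csr_matrix(
            (self.t_rate, (self.t_src, self.t_dst)),
            shape=(self.n_states, self.n_states),
        )

    def exit_rates(self) -> np.ndarray:
        e = np.zeros(self.n_states)
        np.add.at(e, self.t_src, self.t_rate)
        return e

    def generator(self) -> sp.csr_matrix:
        """Infinitesimal generator Q = R - diag(E)."""
        R = self.rate_matrix()
        return (R - sp.diags(self.exit_rates())).tocsr()

    def states_with(self, label: str) -> np.ndarray:
        if label not in self.labels:
            raise KeyError(f"unknown label {label!r}")
        return self.labels[label]

    def species_matrix(self) -> np.ndarray:
        """(n_states, n_species) integer matrix of free-species counts."""
        return np.array([s.species for s in self.states], dtype=np.int64)

    def conformation_matrix(self) -> np.ndarray:
        return np.array([s.conformations for s in self.states], dtype=np.int64)


def explore(
    network: ReactionNetwork,
    max_states: int = 10**7,
    combinatorial: bool = False,
) -> CTMC:
    """Breadth-first closure of the initial state under the 12 reactions.

    Reachability is limited only by the nonnegativity of counts; states with
    zero exit rate (absorbing) are retained.  Raises
    :class:`StateSpaceLimitError` beyond ``max_states``.
    """
    from .pump_model import SPECIES

    conf_index = {c: i for i, c in enumerate(CONFORMATIONS)}
    sp_index = {s: i for i, s in enumerate(network.species)}
    # pre-resolve reactions into index form for speed
    rx = []
    for r in network.reactions:
        rx.append(
            (
                r.label,
                conf_index[r.source_conformation],
                conf_index[r.target_conformation],
                [(sp_index[s], m) for s, m in r.reagent_exponents.items()],
                [(sp_index[s], d) for s, d in r.species_deltas.items()],
                r.stochastic_constant,
            )
        )
    init = network.initial_state()
    key0 = (init.species, init.conformations)
    index = {key0: 0}
    states = [init]
    t_src: list[int] = []
    t_dst: list[int] = []
    t_rate: list[float] = []
    t_label: list[str] = []
    frontier = [key0]
    while frontier:
        next_frontier = []
        for key in frontier:
            i = index[key]
            spc, confs = key
            for label, src_c, dst_c, reagents, deltas, c in rx:
                n_src = confs[src_c]
                if n_src == 0:
                    continue
                p = c * n_src
                ok = True
                for si, m in reagents:
                    n = spc[si]
                    if n < m:
                        ok = False
                        break
                    if combinatorial:
                        for k in range(m):
                            p *= n - k
                    else:
                        p *= n**m
                if not ok or p <= 0:
                    continue
                new_sp = list(spc)
                for si, d in deltas:
                    new_sp[si] += d
                new_cf = list(confs)
                new_cf[src_c] -= 1
                new_cf[dst_c] += 1
                nkey = (tuple(new_sp), tuple(new_cf))
                if nkey not in index:
                    if len(states) >= max_states:
                        raise StateSpaceLimitError(
                            f"state space exceeds cap of {max_states} states"
                        )
                    index[nkey] = len(states)
                    states.append(State(species=nkey[0], conformations=nkey[1]))
                    next_frontier.append(nkey)
                t_src.append(i)
                t_dst.append(index[nkey])
                t_rate.append(p)
                t_label.append(label)
        frontier = next_frontier
    ctmc = CTMC(
        states,
        np.array(t_src, dtype=np.int64),
        np.array(t_dst, dtype=np.int64),
        np.array(t_rate, dtype=float),
        t_label,
        initial=0,
        network=network,
    )
    apply_standard_labels(ctmc)
    for rs in standard_rewards(network):
        attach_rewards(ctmc, rs)
    return ctmc


def label_states(ctmc: CTMC, predicates: dict[str, CountPredicate]) -> CTMC:
    """Attach boolean atomic-proposition masks to the CTMC (in place).

    Predicate names must be unique among the chain's labels.
    """
    if ctmc.network is None:
        raise ValueError("label_states requires a network-backed CTMC")
    dup = set(predicates) & set(ctmc.labels)
    if dup:
        raise ValueError(f"duplicate label names: {sorted(dup)}")
    counts = ctmc.species_matrix()
    for name, pred in predicates.items():
        ctmc.labels[name] = pred.evaluate(
            counts, ctmc.network.species, ctmc.network.initial_counts
        )
    return ctmc


def apply_standard_labels(ctmc: CTMC) -> CTMC:
    """The built-in potassium labels: kOut=0, kOut=KO, kOut>0."""
    return label_states(
        ctmc,
        {
            "kout_zero": CountPredicate("K_o", "==", 0),
            "kout_initial": CountPredicate("K_o", "==", "KO"),
            "kout_positive": CountPredicate("K_o", ">", 0),
        },
    )


def standard_rewards(network: ReactionNetwork) -> list[RewardStructure]:
    from .pump_model import SPECIES

    ko_idx = SPECIES.index("K_o")
    return [
        RewardStructure("kOut", state_rewards=lambda s: float(s.species[ko_idx])),
        RewardStructure("time", state_rewards=lambda s: 1.0),
        RewardStructure("plusKout", transition_rewards={"rr4": 1.0}),
        RewardStructure("minusKout", transition_rewards={"r4": 1.0}),
    ]


def attach_rewards(ctmc: CTMC, spec: RewardStructure) -> CTMC:
    """Realize a reward structure as per-state / per-transition arrays."""
    if spec.name in ctmc.state_rewards or spec.name in ctmc.transition_rewards:
        raise ValueError(f"duplicate reward name {spec.name!r}")
    if spec.state_rewards is not None:
        vals = np.array([float(spec.state_rewards(s)) for s in ctmc.states])
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite state reward in {spec.name!r}")
        ctmc.state_rewards[spec.name] = vals
    if spec.transition_rewards:
        tv = np.zeros(ctmc.n_transitions)
        for k, lab in enumerate(ctmc.t_label):
            r = spec.transition_rewards.get(lab, 0.0)
            if r and (
                spec.transition_guard is None
                or spec.transition_guard(ctmc.states[ctmc.t_src[k]])
            ):
                tv[k] = r
        ctmc.transition_rewards[spec.name] = tv
    return ctmc


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def to_state_table(ctmc: CTMC):
    """CSV-ready table: index, species counts, conformations, labels, exit rate."""
    import pandas as pd

    net = ctmc.network
    cols = {}
    if net is not None:
        counts = ctmc.species_matrix()
        for j, s in enumerate(net.species):
            cols[s] = counts[:, j]
        confs = ctmc.conformation_matrix()
        for j, c in enumerate(CONFORMATIONS):
            cols[c] = confs[:, j]
    for name, mask in ctmc.labels.items():
        cols[name] = mask.astype(int)
    cols["exit_rate"] = ctmc.exit_rates()
    df = pd.DataFrame(cols)
    df.index.name = "state"
    return df


def to_dot(ctmc: CTMC, decorations: dict[str, str] | None = None) -> str:
    """GraphViz DOT text of the labelled transition graph.

    ``decorations`` optionally maps reaction labels to a +/-/+- marker that
    is appended to the edge label (used for trend-annotated renderings).
    """
    lines = ["digraph ctmc {", "  rankdir=LR;"]
    for i, s in enumerate(ctmc.states):
        labs = [name for name, m in ctmc.labels.items() if m[i]]
        shape = "doublecircle" if i == ctmc.initial else "circle"
        text = str(i) if not labs else f"{i}\\n{','.join(labs)}"
        lines.append(f'  s{i} [shape={shape}, label="{text}"];')
    for k in range(ctmc.n_transitions):
        lab = ctmc.t_label[k]
        if decorations and lab in decorations:
            lab = f"{lab} ({decorations[lab]})"
        lines.append(
            f'  s{ctmc.t_src[k]} -> s{ctmc.t_dst[k]} '
            f'[label="{lab}: {ctmc.t_rate[k]:.6g}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_graphml(ctmc: CTMC, path: str | Path) -> None:
    import networkx as nx

    g = nx.MultiDiGraph()
    for i in range(ctmc.n_states):
        g.add_node(i, **{name: bool(m[i]) for name, m in ctmc.labels.items()})
    for k in range(ctmc.n_transitions):
        g.add_edge(
            int(ctmc.t_src[k]),
            int(ctmc.t_dst[k]),
            rate=float(ctmc.t_rate[k]),
            reaction=ctmc.t_label[k],
        )
    nx.write_graphml(g, str(path))


def to_prism(network: ReactionNetwork, ctmc: CTMC | None = None) -> str:
    """Guarded-command model text in the PRISM language.

    One module per species group plus the pump module, synchronized on the
    reaction labels; variable ranges are taken from the explored chain when
    given (else generous bounds).  The product-rate convention of
    synchronized commands carries the count dependence: each species module
    contributes its reagent-count power, the pump module the stochastic
    constant times the source-conformation count.
    """
    from .pump_model import SPECIES

    net = network
    if ctmc is not None:
        counts = ctmc.species_matrix()
        lo = counts.min(axis=0)
        hi = counts.max(axis=0)
    else:
        lo = np.zeros(len(net.species), dtype=int)
        hi = np.array(
            [net.initial_counts[s] + 12 * max(net.initial_counts.values()) for s in net.species]
        )
    ident = {s: s.replace(".", "").replace("_", "") for s in net.species}
    cident = {c: c.replace(".", "_").replace("~", "") for c in CONFORMATIONS}
    out = ["ctmc", "", f"const int NP = {net.n_pumps};", ""]
    # one rate constant per reaction
    for r in net.reactions:
        out.append(f"const double c_{r.label} = {r.stochastic_constant!r};")
    out.append("")
    # group species into modules as in the guarded-command original:
    groups = {
        "na": ["Na_i", "Na_o"],
        "k": ["K_i", "K_o"],
        "atp": ["ATP"],
        "adp": ["ADP"],
        "p": ["P_i"],
    }
    for mod, members in groups.items():
        out.append(f"module {mod}")
        for s in members:
            j = net.species.index(s)
            out.append(
                f"  {ident[s]} : [{lo[j]}..{hi[j]}] init {net.initial_counts[s]};"
            )
        for r in net.reactions:
            touched = [s for s in members if s in r.species_deltas]
            if not touched:
                continue
            guards = []
            rate_terms = []
            updates = []
            for s in touched:
                d = r.species_deltas[s]
                m = r.reagent_exponents.get(s, 0)
                v = ident[s]
                if d < 0:
                    guards.append(f"{v} >= {-d}")
                j = net.species.index(s)
                if d > 0:
                    guards.append(f"{v} <= {hi[j] - d}")
                if m == 1:
                    rate_terms.append(v)
                elif m > 1:
                    rate_terms.append(f"pow({v}, {m})")
                updates.append(f"({v}' = {v} {'+' if d > 0 else '-'} {abs(d)})")
            rate = " * ".join(rate_terms) if rate_terms else "1"
            out.append(
                f"  [{r.label}] {' & '.join(guards) if guards else 'true'} -> {rate} : "
                f"{' & '.join(updates)};"
            )
        out.append("endmodule")
        out.append("")
    out.append("module pump")
    for c in CONFORMATIONS:
        init = net.n_pumps if c == net.initial_conformation else 0
        out.append(f"  {cident[c]} : [0..NP] init {init};")
    for r in net.reactions:
        s, d = cident[r.source_conformation], cident[r.target_conformation]
        out.append(
            f"  [{r.label}] {s} >= 1 & {d} <= NP - 1 -> c_{r.label} * {s} : "
            f"({s}' = {s} - 1) & ({d}' = {d} + 1);"
        )
    out.append("endmodule")
    out.append("")
    ko = net.initial_counts["K_o"]
    out.append(f'label "kOutOver" = {ident["K_o"]} = 0;')
    out.append(f'label "kOutFull" = {ident["K_o"]} = {ko};')
    out.append("")
    out.append('rewards "kOut"')
    out.append(f"  true : {ident['K_o']};")
    out.append("endrewards")
    out.append('rewards "time"')
    out.append("  true : 1;")
    out.append("endrewards")
    out.append('rewards "minusKout"')
    out.append("  [r4] true : 1;")
    out.append("endrewards")
    out.append('rewards "plusKout"')
    out.append("  [rr4] true : 1;")
    out.append("endrewards")
    return "\n".join(out) + "\n"
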