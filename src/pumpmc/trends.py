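"""Rate-trend analysis of the pump cycle.

A reaction has a *positive (ascending) trend* in state s when its rate is
the dominant share of the exit rate:

    indicator(s, r) = 1  iff  rate_r(s) / E(s) >= xi,

with threshold ``xi`` in (0, 1]; any ``xi > 0.5`` guarantees at most one
positive-trend reaction per state.  Over the reachable space a reaction is
*always-positive* (indicator 1 wherever its source conformation is
occupied), *always-negative* (never 1), or *mixed*.  For mixed reactions
the analysis localizes the trend flip: the expected extracellular potassium
count at the first moment the trend changes sign, computed from the
first-passage distribution into the flipped set (and, as an independent
route, from the net accumulated potassium-transport transition rewards up
to that moment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .checker import unbounded_reachability, expected_accumulated_reward
from .pump_model import CONFORMATIONS, SPECIES
from .statespace import CTMC


@dataclass(frozen=True)
class TrendConfig:
    xi: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 < self.xi <= 1.0:
            raise ValueError(f"xi must be in (0, 1], got {self.xi}")


@dataclass
class FlipResult:
    """Localization of a trend change for one mixed reaction."""

    reaction: str
    direction: str  # "loses_positive" | "gains_positive"
    flipped: bool
    expected_kout: float | None
    first_entry_distribution: dict[int, float] = field(default_factory=dict)
    expected_kout_reward_route: float | None = None


@dataclass
class TrendReport:
    classification: dict[str, str]
    positive_states: dict[str, np.ndarray]
    flips: dict[str, FlipResult] = field(default_factory=dict)
    xi: float = 0.6

    def to_frame(self):
        import pandas as pd

        rows = []
        for lab, cls in self.classification.items():
            flip = self.flips.get(lab)
            rows.append(
                {
                    "reaction": lab,
                    "classification": cls,
                    "n_positive_states": int(self.positive_states[lab].sum()),
                    "flip_expected_kout": flip.expected_kout if flip and flip.flipped else None,
                }
            )
        return pd.DataFrame(rows)

    def decorations(self) -> dict[str, str]:
        """+ / - / +- markers per reaction for annotated graph renderings."""
        m = {"always_positive": "+", "always_negative": "-", "mixed": "+/-"}
        return {lab: m[cls] for lab, cls in self.classification.items()}


def _reaction_rates(ctmc: CTMC) -> dict[str, np.ndarray]:
    """Per-state rate of each reaction label (0 where disabled)."""
    out: dict[str, np.ndarray] = {}
    for k in range(ctmc.n_transitions):
        lab = ctmc.t_label[k]
        if lab not in out:
            out[lab] = np.zeros(ctmc.n_states)
        out[lab][ctmc.t_src[k]] += ctmc.t_rate[k]
    return out


def _source_occupied(ctmc: CTMC, reaction: str) -> np.ndarray:
    src = ctmc.network.reaction(reaction).source_conformation
    j = CONFORMATIONS.index(src)
    return ctmc.conformation_matrix()[:, j] > 0


def trend_indicator(
    ctmc: CTMC, state_index: int, reaction: str, cfg: TrendConfig = TrendConfig()
) -> int:
    """Indicator of a positive trend for ``reaction`` in one state.

    Undefined (raises) on absorbing states; 0 when the reaction is disabled.
    """
    E = ctmc.exit_rates()[state_index]
    if E <= 0:
        raise ValueError(f"trend undefined in absorbing state {state_index}")
    rate = 0.0
    for k in range(ctmc.n_transitions):
        if ctmc.t_src[k] == state_index and ctmc.t_label[k] == reaction:
            rate += ctmc.t_rate[k]
    return int(rate / E >= cfg.xi)


def _indicator_masks(
    ctmc: CTMC, cfg: TrendConfig
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """(positive-indicator mask, evaluated mask) per reaction label.

    A reaction is evaluated only in non-absorbing states where its source
    conformation is occupied; elsewhere it is vacuously non-positive.
    """
    E = ctmc.exit_rates()
    rates = _reaction_rates(ctmc)
    pos: dict[str, np.ndarray] = {}
    dom: dict[str, np.ndarray] = {}
    labels = [r.label for r in ctmc.network.reactions]
    for lab in labels:
        occupied = _source_occupied(ctmc, lab) & (E > 0)
        rate = rates.get(lab, np.zeros(ctmc.n_states))
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(E > 0, rate / np.where(E > 0, E, 1.0), 0.0)
        pos[lab] = occupied & (share >= cfg.xi)
        dom[lab] = occupied
    return pos, dom


def classify_rate_trends(ctmc: CTMC, cfg: TrendConfig = TrendConfig()) -> TrendReport:
    """Classify all 12 reactions and localize the flips of the mixed ones."""
    pos, dom = _indicator_masks(ctmc, cfg)
    classification: dict[str, str] = {}
    for lab in pos:
        n_pos = int(pos[lab].sum())
        n_dom = int(dom[lab].sum())
        if n_pos == 0:
            classification[lab] = "always_negative"
        elif n_pos == n_dom:
            classification[lab] = "always_positive"
        else:
            classification[lab] = "mixed"
    report = TrendReport(classification=classification, positive_states=pos, xi=cfg.xi)
    for lab, cls in classification.items():
        if cls == "mixed":
            report.flips[lab] = trend_flip_expectation(ctmc, lab, cfg)
    return report


def trend_flip_expectation(
    ctmc: CTMC,
    reaction: str,
    cfg: TrendConfig = TrendConfig(),
    direction: str = "loses_positive",
) -> FlipResult:
    """Expected K_o count at the first trend change of ``reaction``.

    The flip moment is the first entry into an opposite-indicator state of
    the reaction's source conformation after having visited a
    same-indicator state of that conformation.  Realized on a two-phase
    product chain (phase 0: not yet armed; phase 1: armed after visiting the
    pre-flip set), where the flip set is absorbing; the result is the
    expectation of K_o over the first-entry distribution.

    A second, independent route recovers the same number from the expected
    net potassium-transport reward accumulated up to absorption:
    ``KO - 2 (E[minusKout] - E[plusKout])``.
    """
    if direction not in ("loses_positive", "gains_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    pos, dom = _indicator_masks(ctmc, cfg)
    if direction == "loses_positive":
        arm_set = pos[reaction]
        flip_set = dom[reaction] & ~pos[reaction]
    else:
        arm_set = dom[reaction] & ~pos[reaction]
        flip_set = pos[reaction]
    if not arm_set.any() or not flip_set.any():
        return FlipResult(reaction, direction, flipped=False, expected_kout=None)
    product = _armed_product(ctmc, arm_set, flip_set)
    # absorption probability at each flip state = first-entry probability
    reach = unbounded_reachability(product, product.states_with("flip"), per_state=True)
    entry: dict[int, float] = {}
    total = 0.0
    expected = 0.0
    ko_idx = SPECIES.index("K_o")
    for j in np.where(product.labels["flip"])[0]:
        # probability that the first armed entry happens exactly at this state
        pj = _first_entry_probability(product, j)
        if pj <= 0:
            continue
        base = product.states[j].base_index
        entry[base] = entry.get(base, 0.0) + pj
        total += pj
        expected += pj * ctmc.states[base].species[ko_idx]
    if total <= 0:
        return FlipResult(reaction, direction, flipped=False, expected_kout=None)
    expected /= total
    # independent route via the potassium-transport transition rewards
    reward_route = None
    if "minusKout" in ctmc.transition_rewards and "plusKout" in ctmc.transition_rewards:
        # assumes probability-1 absorption (true on the irreducible pump
        # chain); agreement with the first-entry route is limited by the
        # conditioning of the metastable linear systems
        minus = _product_accumulated(ctmc, product, "minusKout")
        plus = _product_accumulated(ctmc, product, "plusKout")
        reward_route = ctmc.network.KO - 2.0 * (minus - plus)
    return FlipResult(
        reaction,
        direction,
        flipped=True,
        expected_kout=expected,
        first_entry_distribution=entry,
        expected_kout_reward_route=reward_route,
    )


@dataclass(frozen=True)
class _ProductState:
    base_index: int
    armed: int


def _armed_product(ctmc: CTMC, arm_set: np.ndarray, flip_set: np.ndarray) -> CTMC:
    """Two-phase product chain; armed flip states are absorbing."""
    n = ctmc.n_states
    states = [_ProductState(i, 0) for i in range(n)] + [
        _ProductState(i, 1) for i in range(n)
    ]

    def phase_of(i: int, armed: int) -> int:
        # entering an arm state arms the flag permanently
        return 1 if (armed or arm_set[i]) else 0

    src, dst, rate, labels = [], [], [], []
    for k in range(ctmc.n_transitions):
        s, d, r, lab = int(ctmc.t_src[k]), int(ctmc.t_dst[k]), ctmc.t_rate[k], ctmc.t_label[k]
        for armed in (0, 1):
            s_armed = phase_of(s, armed)
            if s_armed != armed:
                continue  # canonical phase only
            if armed == 1 and flip_set[s]:
                continue  # absorbed
            d_armed = phase_of(d, s_armed)
            src.append(s + armed * n)
            dst.append(d + d_armed * n)
            rate.append(r)
            labels.append(lab)
    product = CTMC(
        states,
        np.array(src, dtype=np.int64),
        np.array(dst, dtype=np.int64),
        np.array(rate, dtype=float),
        labels,
        initial=ctmc.initial + (n if phase_of(ctmc.initial, 0) else 0),
        network=None,
    )
    flip_mask = np.zeros(2 * n, dtype=bool)
    flip_mask[n:] = flip_set
    product.labels["flip"] = flip_mask
    return product


def _first_entry_probability(product: CTMC, j: int) -> float:
    """Probability that absorption happens exactly at product state j."""
    only_j = np.zeros(product.n_states, dtype=bool)
    only_j[j] = True
    return unbounded_reachability(product, only_j)


def _product_accumulated(ctmc: CTMC, product: CTMC, reward: str) -> float:
    """Expected accumulated base-chain transition reward until absorption."""
    base_trew = ctmc.transition_rewards[reward]
    # per-label reward (the pump rewards are label-keyed and guard-free)
    label_reward: dict[str, float] = {}
    for k in range(ctmc.n_transitions):
        if base_trew[k]:
            label_reward[ctmc.t_label[k]] = float(base_trew[k])
    tv = np.array([label_reward.get(lab, 0.0) for lab in product.t_label])
    product.transition_rewards[reward] = tv
    return expected_accumulated_reward(
        product, product.states_with("flip"), reward
    )
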