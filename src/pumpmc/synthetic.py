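"""Small CTMCs with closed-form answers, and perturbed pump parameters.

Every numerical routine in :mod:`pumpmc.checker` is validated against these
oracle chains: the closed forms are independent of the checker's numerics,
so agreement is a genuine dual-route check.  The set deliberately covers an
absorbing chain, an irreducible chain, a birth-death chain with the
gambler's-ruin closed form, and a multi-BSCC chain, so that the
probability-0/1 graph passes and the bottom-SCC logic are all exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy import stats

from .pump_model import KineticParameters
from .statespace import CTMC


@dataclass
class OracleChain:
    """A CTMC bundled with its analytic answers.

    ``transient(t)`` returns the exact occupancy vector; ``reach_prob`` and
    ``hitting_time`` give P[F goal] and the expected hitting time from the
    initial state for the chain's canonical goal label; ``analytic`` records
    the formulas as text for provenance.
    """

    ctmc: CTMC
    goal: str
    transient: Callable[[float], np.ndarray]
    reach_prob: float
    hitting_time: float
    analytic: str


def _chain(states, transitions, labels, initial=0) -> CTMC:
    src = np.array([t[0] for t in transitions], dtype=np.int64)
    dst = np.array([t[1] for t in transitions], dtype=np.int64)
    rate = np.array([t[2] for t in transitions], dtype=float)
    lab = [t[3] for t in transitions]
    c = CTMC(states, src, dst, rate, lab, initial=initial)
    for name, mask in labels.items():
        c.labels[name] = np.asarray(mask, dtype=bool)
    return c


def two_state_chain(lam: float, mu: float) -> OracleChain:
    """A <-> B with forward rate ``lam`` and backward rate ``mu``.

    P_B(t) = lam/(lam+mu) (1 - exp(-(lam+mu) t)); for mu = 0 the expected
    hitting time of B is 1/lam.
    """
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    if mu < 0:
        raise ValueError(f"mu must be nonnegative, got {mu}")
    transitions = [(0, 1, lam, "fwd")]
    if mu > 0:
        transitions.append((1, 0, mu, "bwd"))
    c = _chain(["A", "B"], transitions, {"goal": [False, True]})
    s = lam + mu

    def transient(t: float) -> np.ndarray:
        pb = lam / s * (1.0 - math.exp(-s * t))
        return np.array([1.0 - pb, pb])

    return OracleChain(
        ctmc=c,
        goal="goal",
        transient=transient,
        reach_prob=1.0,
        hitting_time=1.0 / lam if mu == 0 else 1.0 / lam,
        analytic="P_B(t) = lam/(lam+mu) (1 - e^{-(lam+mu) t}); E[T_B] = 1/lam",
    )


def death_chain(n: int, lam: float) -> OracleChain:
    """Linear pure-death chain n -> n-1 -> ... -> 0, rate ``lam`` per step.

    Expected hitting time of 0 is n/lam; the occupancy of state 0 at time t
    is the Erlang(n, lam) CDF, and of intermediate state k the Poisson-like
    Erlang density difference (equivalently, state n-j holds the probability
    of exactly j events of a rate-lam Poisson process, j < n).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    states = list(range(n, -1, -1))
    transitions = [(i, i + 1, lam, "death") for i in range(n)]
    labels = {"goal": [s == 0 for s in states]}
    c = _chain(states, transitions, labels)

    def transient(t: float) -> np.ndarray:
        out = np.empty(n + 1)
        out[:n] = stats.poisson.pmf(np.arange(n), lam * t)
        out[n] = stats.erlang.cdf(t, n, scale=1.0 / lam)
        return out

    return OracleChain(
        ctmc=c,
        goal="goal",
        transient=transient,
        reach_prob=1.0,
        hitting_time=n / lam,
        analytic="E[T_0] = n/lam; occupancy(0, t) = Erlang(n, lam).cdf(t)",
    )


def birth_death_chain(n: int, lam: float, mu: float) -> OracleChain:
    """Birth-death chain on 0..n started at the midpoint; goal = ruin (0).

    With 0 and n absorbing and up-rate ``lam`` / down-rate ``mu``, the ruin
    probability from i follows the gambler's-ruin closed form
    ``(q^i - q^N)/(1 - q^N)`` with ``q = mu/lam`` (and ``1 - i/N`` when
    ``lam = mu``).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if lam <= 0 or mu <= 0:
        raise ValueError("rates must be positive")
    states = list(range(n + 1))
    transitions = []
    for i in range(1, n):
        transitions.append((i, i + 1, lam, "up"))
        transitions.append((i, i - 1, mu, "down"))
    start = n // 2
    c = _chain(states, transitions, {"goal": [s == 0 for s in states]}, initial=start)
    if lam == mu:
        ruin = 1.0 - start / n
    else:
        q = mu / lam  # ratio of down-rate to up-rate
        ruin = (q**start - q**n) / (1.0 - q**n)

    def transient(t: float) -> np.ndarray:  # no simple closed form; not provided
        raise NotImplementedError("use the reachability closed form")

    # expected absorption time (either end) from the midpoint has a closed
    # form too, but reach_prob is the canonical oracle for this chain
    return OracleChain(
        ctmc=c,
        goal="goal",
        transient=transient,
        reach_prob=ruin,
        hitting_time=math.inf,  # goal not reached with probability 1
        analytic="gambler's ruin: P_i[F 0] = (q^i - q^N)/(1 - q^N), q = mu/lam",
    )


def forked_absorbing_chain(alpha: float, beta: float) -> OracleChain:
    """Start state forking into two absorbing states A (rate alpha) and
    B (rate beta): two singleton BSCCs, reach probabilities alpha/(alpha+beta)
    and beta/(alpha+beta)."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("rates must be positive")
    transitions = [(0, 1, alpha, "toA"), (0, 2, beta, "toB")]
    c = _chain(
        ["S", "A", "B"],
        transitions,
        {"goal": [False, True, False], "other": [False, False, True]},
    )
    s = alpha + beta

    def transient(t: float) -> np.ndarray:
        live = math.exp(-s * t)
        return np.array(
            [live, alpha / s * (1 - live), beta / s * (1 - live)]
        )

    return OracleChain(
        ctmc=c,
        goal="goal",
        transient=transient,
        reach_prob=alpha / s,
        hitting_time=math.inf,
        analytic="P[F A] = alpha/(alpha+beta); two singleton BSCCs",
    )


def three_cycle_chain(rate: float = 1.0) -> OracleChain:
    """Irreducible 3-cycle (uniform rates): single BSCC equal to the whole
    chain; every label pair recurs with probability 1."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    transitions = [(0, 1, rate, "a"), (1, 2, rate, "b"), (2, 0, rate, "c")]
    c = _chain(
        [0, 1, 2],
        transitions,
        {"goal": [False, False, True], "start": [True, False, False]},
    )

    def transient(t: float) -> np.ndarray:
        # eigen-decomposition of the circulant generator
        w = np.exp(2j * np.pi / 3)
        out = np.zeros(3)
        for j in range(3):
            acc = 0.0 + 0.0j
            for k in range(3):
                lam_k = rate * (w**k - 1.0)
                acc += (w ** (-k * j)) * np.exp(lam_k * t)
            out[j] = (acc / 3).real
        return out

    return OracleChain(
        ctmc=c,
        goal="goal",
        transient=transient,
        reach_prob=1.0,
        hitting_time=2.0 / rate,
        analytic="circulant eigenbasis; E[T_2 from 0] = 2/rate",
    )


def perturb_parameters(
    params: KineticParameters, log_sd: float, seed: int
) -> KineticParameters:
    """Multiply each rate coefficient by an independent lognormal factor.

    Rates are positive scale parameters, hence the lognormal family.
    Concentrations (and volume/temperature) are untouched; deterministic
    under a fixed seed.
    """
    if log_sd < 0:
        raise ValueError("log_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    names = [f"f{i}" for i in range(1, 7)] + [f"b{i}" for i in range(1, 7)]
    factors = np.exp(rng.normal(0.0, log_sd, size=len(names)))
    return replace(
        params, **{n: getattr(params, n) * f for n, f in zip(names, factors)}
    )
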