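"""CSL-style property evaluation on explicit-state CTMCs.

Implements the transient fragment of continuous stochastic logic used for
this analysis: time-bounded and unbounded reachability (F), expected
first-passage times (the accumulated "time" reward up to a goal), expected
instantaneous rewards (R[I=t]), and the qualitative infinitely-often pair
property via bottom-strongly-connected-component analysis.

Numerics
--------
Transient distributions are computed by uniformisation: with uniformisation
rate ``q >= max exit rate``, the jump matrix ``P = I + Q/q`` and

    pi(t) = sum_k  Poisson(k; q t) * pi(0) P^k,

truncated so the discarded Poisson mass is below ``epsilon``.  The pump
chain is stiff (exit rates span eight orders of magnitude), so for horizons
where the Poisson term count ``~ q t`` exceeds a budget the dense matrix
exponential (scipy's scaling-and-squaring expm) is used instead; ``auto``
picks between them.  Unbounded properties use exact graph precomputation
(probability-0/1 state classification) before any linear solve, so
qualitative answers are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from scipy.stats import poisson

from .statespace import CTMC

#: default truncation error for uniformisation
DEFAULT_EPSILON = 1e-9
#: safety factor on the uniformisation rate (avoids degenerate self-loops)
Q_FACTOR = 1.02
#: beyond this many Poisson terms, 'auto' switches to the matrix exponential
MAX_UNIFORMISATION_TERMS = 200_000
#: sparse direct solves below this size, iterative refinement above
DIRECT_SOLVE_LIMIT = 10**5


@dataclass
class PropertyQuery:
    """A property template instance (bookkeeping for reports)."""

    kind: str  # bounded_reach | unbounded_reach | hitting_time | instant_reward | recurrent_pair
    goal: str | None = None
    goal_b: str | None = None
    t: float | None = None
    reward: str | None = None
    from_filter: str | None = None
    aggregation: str = "per-state"


@dataclass
class PropertyResult:
    query: PropertyQuery
    value: float | dict
    tolerance: float
    convention: dict = field(default_factory=dict)


def _goal_mask(ctmc: CTMC, goal) -> np.ndarray:
    if isinstance(goal, str):
        return ctmc.states_with(goal)
    mask = np.asarray(goal, dtype=bool)
    if mask.shape != (ctmc.n_states,):
        raise ValueError("goal mask has wrong length")
    return mask


# ---------------------------------------------------------------------------
# transient analysis
# ---------------------------------------------------------------------------

def _uniformised_jump_matrix(ctmc: CTMC, q: float) -> sp.csr_matrix:
    P = ctmc.rate_matrix() / q
    diag = 1.0 - ctmc.exit_rates() / q
    return (P + sp.diags(diag)).tocsr()


def transient_distribution(
    ctmc: CTMC,
    t: float,
    epsilon: float = DEFAULT_EPSILON,
    method: str = "auto",
    p0: np.ndarray | None = None,
) -> np.ndarray:
    """State distribution pi(t) from the initial state (or ``p0``).

    ``method``: ``"uniformisation"``, ``"expm"`` (dense matrix exponential)
    or ``"auto"`` (uniformisation while the Poisson term count stays within
    budget).  Absorbing states are handled naturally: they hold a self-loop
    of weight 1 in the uniformised chain.
    """
    if t < 0:
        raise ValueError(f"t must be nonnegative, got {t}")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n = ctmc.n_states
    if p0 is None:
        p0 = np.zeros(n)
        p0[ctmc.initial] = 1.0
    else:
        p0 = np.asarray(p0, dtype=float)
    if t == 0:
        return p0.copy()
    q = Q_FACTOR * float(ctmc.exit_rates().max(initial=0.0))
    if q == 0.0:  # no transitions anywhere
        return p0.copy()
    qt = q * t
    if qt > 10 * MAX_UNIFORMISATION_TERMS:
        # far beyond the uniformisation budget; normal-tail bound suffices
        n_terms = int(qt + 10 * math.sqrt(qt)) + 1
    else:
        n_terms = int(poisson.isf(epsilon, qt)) + 1 if qt > 0 else 1
    if method == "auto":
        method = "uniformisation" if n_terms <= MAX_UNIFORMISATION_TERMS else "expm"
    if method == "uniformisation":
        P = _uniformised_jump_matrix(ctmc, q).T.tocsr()
        weights = poisson.pmf(np.arange(n_terms + 1), qt)
        out = weights[0] * p0
        v = p0
        for k in range(1, n_terms + 1):
            v = P @ v
            if weights[k] > 0:
                out = out + weights[k] * v
        return out
    if method == "expm":
        Q = ctmc.generator().toarray()
        return p0 @ la.expm(Q * t)
    raise ValueError(f"unknown method {method!r}")


def bounded_reachability(
    ctmc: CTMC,
    goal,
    t: float,
    epsilon: float = DEFAULT_EPSILON,
    method: str = "auto",
) -> float:
    """P[F<=t goal] from the initial state.

    Standard time-bounded-eventually semantics: goal states are made
    absorbing, then the transient mass on the goal at time t is returned.
    Monotone nondecreasing in t.
    """
    mask = _goal_mask(ctmc, goal)
    if t < 0:
        raise ValueError(f"t must be nonnegative, got {t}")
    if mask[ctmc.initial]:
        return 1.0
    sub = _absorb(ctmc, mask)
    pi = transient_distribution(sub, t, epsilon=epsilon, method=method)
    return float(np.clip(pi[mask].sum(), 0.0, 1.0))


def _absorb(ctmc: CTMC, mask: np.ndarray) -> CTMC:
    """Copy of the chain with all transitions out of ``mask`` removed."""
    keep = ~mask[ctmc.t_src]
    sub = CTMC(
        ctmc.states,
        ctmc.t_src[keep],
        ctmc.t_dst[keep],
        ctmc.t_rate[keep],
        [l for l, k in zip(ctmc.t_label, keep) if k],
        initial=ctmc.initial,
        network=ctmc.network,
    )
    sub.labels = ctmc.labels
    sub.state_rewards = ctmc.state_rewards
    return sub


# ---------------------------------------------------------------------------
# graph precomputation + unbounded reachability
# ---------------------------------------------------------------------------

def _adjacency(ctmc: CTMC) -> sp.csr_matrix:
    return sp.csr_matrix(
        (np.ones(ctmc.n_transitions), (ctmc.t_src, ctmc.t_dst)),
        shape=(ctmc.n_states, ctmc.n_states),
        dtype=bool,
    )


def _backward_reachable(adj: sp.csr_matrix, targets: np.ndarray) -> np.ndarray:
    """States from which some target state is reachable (including targets)."""
    adj_T = adj.T.tocsr()
    reach = targets.copy()
    frontier = np.where(targets)[0]
    while frontier.size:
        nxt = np.unique(adj_T[frontier].indices)
        nxt = nxt[~reach[nxt]]
        reach[nxt] = True
        frontier = nxt
    return reach


def prob01_states(ctmc: CTMC, goal) -> tuple[np.ndarray, np.ndarray]:
    """Exact graph classification for P[F goal]: (prob-0 mask, prob-1 mask)."""
    mask = _goal_mask(ctmc, goal)
    adj = _adjacency(ctmc)
    can_reach = _backward_reachable(adj, mask)
    prob0 = ~can_reach
    # with goal absorbed, probability 1 iff no prob-0 state is reachable
    keep = ~mask[ctmc.t_src]
    adj_abs = sp.csr_matrix(
        (np.ones(int(keep.sum())), (ctmc.t_src[keep], ctmc.t_dst[keep])),
        shape=(ctmc.n_states, ctmc.n_states),
        dtype=bool,
    )
    fwd_to_prob0 = _backward_reachable(adj_abs, prob0)
    prob1 = ~fwd_to_prob0
    return prob0, prob1


def _solve(A: sp.spmatrix, b: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Sparse direct solve below the size limit, else Gauss-Seidel sweeps."""
    n = A.shape[0]
    if n == 0:
        return np.zeros(0)
    if n < DIRECT_SOLVE_LIMIT:
        return spla.spsolve(A.tocsr(), b)
    # Gauss-Seidel on the (diagonally dominant) system
    A = A.tocsr()
    x = np.zeros(n)
    d = A.diagonal()
    for _ in range(100_000):
        x_new = x.copy()
        for i in range(n):
            row = A.getrow(i)
            s = row.data @ x_new[row.indices] - d[i] * x_new[i]
            x_new[i] = (b[i] - s) / d[i]
        if np.max(np.abs(x_new - x)) <= rtol * max(1.0, np.max(np.abs(x_new))):
            return x_new
        x = x_new
    raise RuntimeError("Gauss-Seidel failed to converge")


def unbounded_reachability(
    ctmc: CTMC, goal, per_state: bool = False
) -> float | np.ndarray:
    """P[F goal]; exact 0/1 answers from the graph passes, the rest solved
    from the embedded-jump-chain linear system."""
    mask = _goal_mask(ctmc, goal)
    prob0, prob1 = prob01_states(ctmc, goal)
    x = np.zeros(ctmc.n_states)
    x[prob1 | mask] = 1.0
    unknown = ~(prob0 | prob1 | mask)
    if unknown.any():
        idx = np.where(unknown)[0]
        pos = -np.ones(ctmc.n_states, dtype=np.int64)
        pos[idx] = np.arange(idx.size)
        E = ctmc.exit_rates()
        rows, cols, vals = [], [], []
        b = np.zeros(idx.size)
        # x_s = sum_{s'} P(s,s') x_{s'} over jump probabilities
        for k in range(ctmc.n_transitions):
            s, d = ctmc.t_src[k], ctmc.t_dst[k]
            if not unknown[s]:
                continue
            pjump = ctmc.t_rate[k] / E[s]
            if unknown[d]:
                rows.append(pos[s])
                cols.append(pos[d])
                vals.append(-pjump)
            else:
                b[pos[s]] += pjump * x[d]
        A = sp.csr_matrix(
            (vals + [1.0] * idx.size, (rows + list(range(idx.size)), cols + list(range(idx.size)))),
            shape=(idx.size, idx.size),
        )
        x[idx] = np.clip(_solve(A, b), 0.0, 1.0)
    if per_state:
        return x
    return float(x[ctmc.initial])


# ---------------------------------------------------------------------------
# expected first-passage times and accumulated rewards
# ---------------------------------------------------------------------------

def expected_hitting_time(
    ctmc: CTMC,
    goal,
    from_filter=None,
    aggregation: str = "per-state",
):
    """Expected time to reach ``goal`` (the accumulated unit-time reward).

    Solves ``x_s = 1/E(s) + sum_s' (R(s,s')/E(s)) x_s'`` with ``x = 0`` on
    the goal.  A start state from which the goal is not reached with
    probability 1 gets ``+inf`` (the standard model-checking convention for
    undefined expected rewards).

    ``from_filter`` restricts the reported start states (a label or mask);
    ``aggregation`` is ``"min"``, ``"max"`` or ``"per-state"``.
    """
    return _expected_accumulated(
        ctmc, goal, state_reward=None, from_filter=from_filter, aggregation=aggregation
    )


def expected_accumulated_reward(
    ctmc: CTMC,
    goal,
    reward: str,
    from_filter=None,
    aggregation: str = "per-state",
):
    """Expected reward accumulated until first reaching ``goal`` (R[F goal]).

    Handles both state rewards (rate ``r(s)`` per unit time) and transition
    rewards (earned per firing).
    """
    return _expected_accumulated(
        ctmc, goal, state_reward=reward, from_filter=from_filter, aggregation=aggregation
    )


def _expected_accumulated(ctmc, goal, state_reward, from_filter, aggregation):
    mask = _goal_mask(ctmc, goal)
    prob0, prob1 = prob01_states(ctmc, goal)
    certain = prob1 | mask
    E = ctmc.exit_rates()
    n = ctmc.n_states
    if state_reward is None:
        srew = np.ones(n)
        trew = None
    else:
        srew = ctmc.state_rewards.get(state_reward)
        trew = ctmc.transition_rewards.get(state_reward)
        if srew is None and trew is None:
            raise KeyError(f"unknown reward {state_reward!r}")
        if srew is None:
            srew = np.zeros(n)
    x = np.full(n, np.inf)
    x[mask] = 0.0
    solve_states = certain & ~mask
    if solve_states.any():
        idx = np.where(solve_states)[0]
        pos = -np.ones(n, dtype=np.int64)
        pos[idx] = np.arange(idx.size)
        rows, cols, vals = [], [], []
        b = srew[idx] / E[idx]
        for k in range(ctmc.n_transitions):
            s, d = ctmc.t_src[k], ctmc.t_dst[k]
            if not solve_states[s]:
                continue
            pjump = ctmc.t_rate[k] / E[s]
            if trew is not None and trew[k]:
                b[pos[s]] += pjump * trew[k]
            if solve_states[d]:
                rows.append(pos[s])
                cols.append(pos[d])
                vals.append(-pjump)
        A = sp.csr_matrix(
            (vals + [1.0] * idx.size, (rows + list(range(idx.size)), cols + list(range(idx.size)))),
            shape=(idx.size, idx.size),
        )
        x[idx] = _solve(A, b)
    if from_filter is None:
        start = np.zeros(n, dtype=bool)
        start[ctmc.initial] = True
    else:
        start = _goal_mask(ctmc, from_filter)
        if not start.any():
            raise ValueError("no start states satisfy the filter")
    vals_out = x[start]
    if aggregation == "min":
        return float(vals_out.min())
    if aggregation == "max":
        return float(vals_out.max())
    if aggregation == "per-state":
        if from_filter is None:
            return float(vals_out[0])
        return dict(zip(np.where(start)[0].tolist(), vals_out.tolist()))
    raise ValueError(f"unknown aggregation {aggregation!r}")


# ---------------------------------------------------------------------------
# rewards at an instant, and qualitative recurrence
# ---------------------------------------------------------------------------

def instantaneous_expected_reward(
    ctmc: CTMC,
    reward: str,
    t: float,
    epsilon: float = DEFAULT_EPSILON,
    method: str = "auto",
) -> float:
    """R[I=t]: the expected state reward at time instant t."""
    if reward not in ctmc.state_rewards:
        raise KeyError(f"unknown state reward {reward!r}")
    pi = transient_distribution(ctmc, t, epsilon=epsilon, method=method)
    return float(pi @ ctmc.state_rewards[reward])


def bottom_sccs(ctmc: CTMC) -> list[np.ndarray]:
    """Bottom strongly connected components (no outgoing edges)."""
    adj = _adjacency(ctmc)
    n_comp, comp = connected_components(adj, directed=True, connection="strong")
    leaves = np.ones(n_comp, dtype=bool)
    for k in range(ctmc.n_transitions):
        cs, cd = comp[ctmc.t_src[k]], comp[ctmc.t_dst[k]]
        if cs != cd:
            leaves[cs] = False
    # states with no outgoing transitions at all form singleton BSCCs and are
    # already leaves by construction
    return [np.where(comp == c)[0] for c in np.where(leaves)[0]]


def recurrent_pair_probability(ctmc: CTMC, label_a: str, label_b: str) -> float:
    """P[GF a and GF b]: both labels visited infinitely often.

    In a finite CTMC every state of an entered BSCC is visited infinitely
    often, so this equals the probability of reaching a BSCC containing at
    least one ``label_a`` state and at least one ``label_b`` state.
    """
    a = ctmc.states_with(label_a)
    b = ctmc.states_with(label_b)
    target = np.zeros(ctmc.n_states, dtype=bool)
    for comp in bottom_sccs(ctmc):
        if a[comp].any() and b[comp].any():
            target[comp] = True
    if not target.any():
        return 0.0
    return unbounded_reachability(ctmc, target)
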