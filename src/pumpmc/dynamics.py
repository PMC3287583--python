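"""Stochastic simulation (Gillespie direct method) and mass-action ODEs.

These two routes bracket the CTMC analysis: the SSA samples exact
trajectories of the same jump process the model checker analyses
exhaustively, and the ODE system is its large-volume (thermodynamic) limit
in concentration units.  Both therefore serve as independent
cross-validation of every transient quantity the checker computes.

The SSA inner loop is compiled with numba when available (the pump chain
fires ~2e4 events per simulated second, so ensembles need the compiled
path); a pure-Python fallback keeps the module importable everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .chemistry import VolumeContext
from .pump_model import CONFORMATIONS, SPECIES, KineticParameters, ReactionNetwork

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@dataclass
class Trajectory:
    """Event-resolved SSA trajectory.

    ``times[0] = 0`` is the initial snapshot; each later row differs from
    its predecessor by exactly one reaction's update.
    """

    times: np.ndarray
    species: np.ndarray  # (n_events + 1, n_species)
    conformations: np.ndarray  # (n_events + 1, 6)
    reactions: np.ndarray  # (n_events,) reaction index fired
    seed: int

    @property
    def n_events(self) -> int:
        return len(self.reactions)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.species, columns=list(SPECIES))
        for j, c in enumerate(CONFORMATIONS):
            df[c] = self.conformations[:, j]
        df.insert(0, "time", self.times)
        return df


def network_arrays(network: ReactionNetwork):
    """Index-form arrays of the network for the compiled kernels."""
    nsp = len(network.species)
    nrx = len(network.reactions)
    conf_index = {c: i for i, c in enumerate(CONFORMATIONS)}
    sp_index = {s: i for i, s in enumerate(network.species)}
    src = np.zeros(nrx, dtype=np.int64)
    dst = np.zeros(nrx, dtype=np.int64)
    expo = np.zeros((nrx, nsp), dtype=np.int64)
    delt = np.zeros((nrx, nsp), dtype=np.int64)
    cs = np.zeros(nrx)
    for k, r in enumerate(network.reactions):
        src[k] = conf_index[r.source_conformation]
        dst[k] = conf_index[r.target_conformation]
        cs[k] = r.stochastic_constant
        for s, m in r.reagent_exponents.items():
            expo[k, sp_index[s]] = m
        for s, d in r.species_deltas.items():
            delt[k, sp_index[s]] = d
    sp0 = np.array([network.initial_counts[s] for s in network.species], dtype=np.int64)
    conf0 = np.zeros(len(CONFORMATIONS), dtype=np.int64)
    conf0[conf_index[network.initial_conformation]] = network.n_pumps
    return sp0, conf0, cs, src, dst, expo, delt


@njit(cache=False)
def _propensities(sp, conf, cs, src, expo, props):
    tot = 0.0
    for k in range(cs.shape[0]):
        props[k] = 0.0
        nsrc = conf[src[k]]
        if nsrc == 0:
            continue
        p = cs[k] * nsrc
        ok = True
        for i in range(sp.shape[0]):
            e = expo[k, i]
            if e > 0:
                if sp[i] < e:
                    ok = False
                    break
                for _ in range(e):
                    p *= sp[i]
        if ok:
            props[k] = p
            tot += p
    return tot


@njit(cache=False)
def _ssa_events(sp0, conf0, t_max, seed, cs, src, dst, expo, delt, max_events):
    np.random.seed(seed)
    nsp = sp0.shape[0]
    sp = sp0.copy()
    conf = conf0.copy()
    times = np.zeros(max_events)
    fired = np.zeros(max_events, dtype=np.int64)
    props = np.zeros(cs.shape[0])
    t = 0.0
    n = 0
    while n < max_events:
        tot = _propensities(sp, conf, cs, src, expo, props)
        if tot == 0.0:
            break
        t = t - math.log(np.random.random()) / tot
        if t > t_max:
            break
        u = np.random.random() * tot
        acc = 0.0
        k = 0
        for k in range(cs.shape[0]):
            acc += props[k]
            if acc >= u:
                break
        conf[src[k]] -= 1
        conf[dst[k]] += 1
        for i in range(nsp):
            sp[i] += delt[k, i]
        times[n] = t
        fired[n] = k
        n += 1
    return times[:n], fired[:n]


@njit(cache=False)
def _ssa_observe(sp0, conf0, seed, cs, src, dst, expo, delt, grid, obs_index):
    """Observable count at each grid time for one run (fast path)."""
    np.random.seed(seed)
    sp = sp0.copy()
    conf = conf0.copy()
    props = np.zeros(cs.shape[0])
    out = np.zeros(grid.shape[0])
    t = 0.0
    gi = 0
    t_max = grid[-1]
    while True:
        tot = _propensities(sp, conf, cs, src, expo, props)
        if tot == 0.0:
            t_next = t_max + 1.0
        else:
            t_next = t - math.log(np.random.random()) / tot
        while gi < grid.shape[0] and grid[gi] < t_next:
            out[gi] = sp[obs_index]
            gi += 1
        if gi >= grid.shape[0] or tot == 0.0:
            break
        t = t_next
        u = np.random.random() * tot
        acc = 0.0
        k = 0
        for k in range(cs.shape[0]):
            acc += props[k]
            if acc >= u:
                break
        conf[src[k]] -= 1
        conf[dst[k]] += 1
        for i in range(sp.shape[0]):
            sp[i] += delt[k, i]
    return out


def ssa_trajectory(
    network: ReactionNetwork,
    t_max: float,
    seed: int,
    max_events: int = 20_000_000,
) -> Trajectory:
    """One exact direct-method trajectory; identical seeds give identical
    trajectories.  Stops at ``t_max`` or on absorption."""
    if t_max <= 0:
        raise ValueError(f"t_max must be positive, got {t_max}")
    sp0, conf0, cs, src, dst, expo, delt = network_arrays(network)
    times, fired = _ssa_events(
        sp0, conf0, t_max, seed, cs, src, dst, expo, delt, max_events
    )
    n = len(times)
    species = np.empty((n + 1, len(sp0)), dtype=np.int64)
    confs = np.empty((n + 1, len(conf0)), dtype=np.int64)
    species[0] = sp0
    confs[0] = conf0
    spc = sp0.copy()
    cfc = conf0.copy()
    for i, k in enumerate(fired):
        spc = spc + delt[k]
        cfc = cfc.copy()
        cfc[src[k]] -= 1
        cfc[dst[k]] += 1
        species[i + 1] = spc
        confs[i + 1] = cfc
    return Trajectory(
        times=np.concatenate(([0.0], times)),
        species=species,
        conformations=confs,
        reactions=fired,
        seed=seed,
    )


def ensemble_mean(
    network: ReactionNetwork,
    observable: str,
    t_grid: np.ndarray,
    n_runs: int,
    seed: int,
) -> pd.DataFrame:
    """Sample mean and standard error of a species count on a time grid.

    Per-run seeds are ``seed + run index`` (deterministic, logged in the
    output).  Returns a DataFrame with columns time, mean, se, n_runs.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty time grid")
    if observable not in network.species:
        raise KeyError(f"unknown species {observable!r}")
    sp0, conf0, cs, src, dst, expo, delt = network_arrays(network)
    obs_index = network.species.index(observable)
    acc = np.zeros_like(t_grid)
    acc2 = np.zeros_like(t_grid)
    for run in range(n_runs):
        out = _ssa_observe(
            sp0, conf0, seed + run, cs, src, dst, expo, delt, t_grid, obs_index
        )
        acc += out
        acc2 += out**2
    mean = acc / n_runs
    var = np.maximum(acc2 / n_runs - mean**2, 0.0) * n_runs / (n_runs - 1)
    se = np.sqrt(var / n_runs)
    return pd.DataFrame(
        {"time": t_grid, "mean": mean, "se": se, "n_runs": n_runs, "seed": seed}
    )


# ---------------------------------------------------------------------------
# deterministic mass-action ODE limit
# ---------------------------------------------------------------------------

@dataclass
class OdeSolution:
    times: np.ndarray
    concentrations: pd.DataFrame  # per species, M
    conformation_fractions: pd.DataFrame

    def __getitem__(self, species: str) -> np.ndarray:
        return self.concentrations[species].to_numpy()


def ode_solve(
    params: KineticParameters,
    t_grid: np.ndarray,
    n_pumps: int = 1,
    volume: float | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-14,
) -> OdeSolution:
    """Integrate the deterministic mass-action equations of the 12 reactions.

    Concentration units throughout; the total pump concentration is
    ``n_pumps / (N_A V)`` so the ODE and the CTMC describe the same system
    at any volume.  Uses stiff-capable adaptive integration (LSODA).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0 or np.any(np.diff(t_grid) <= 0) or t_grid[0] < 0:
        raise ValueError("t_grid must be increasing and nonnegative")
    V = params.volume if volume is None else volume
    ctx = VolumeContext(volume=V)
    e_total = n_pumps / ctx.nav
    f = params.forward_rates()
    b = params.backward_rates()

    def rhs(t, y):
        NaIn, NaOut, KIn, KOut, ATP, ADP, Pi, e0, e1, e2, e3, e4, e5 = y
        v = (
            f[0] * e0 * NaIn**3 - b[0] * e1,
            f[1] * e1 - b[1] * e2 * ADP,
            f[2] * e2 - b[2] * e3 * NaOut**3,
            f[3] * e3 * KOut**2 - b[3] * e4 * Pi,
            f[4] * e4 * ATP - b[4] * e5,
            f[5] * e5 - b[5] * e0 * KIn**2,
        )
        return (
            -3 * v[0],
            3 * v[2],
            2 * v[5],
            -2 * v[3],
            -v[4],
            v[1],
            v[3],
            v[5] - v[0],
            v[0] - v[1],
            v[1] - v[2],
            v[2] - v[3],
            v[3] - v[4],
            v[4] - v[5],
        )

    conc = params.concentrations()
    y0 = [conc[s] for s in SPECIES] + [e_total, 0, 0, 0, 0, 0]
    t0, t1 = t_grid[0], t_grid[-1]
    sol = solve_ivp(
        rhs,
        (t0, t1),
        y0,
        method="LSODA",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    concs = pd.DataFrame(sol.y[: len(SPECIES)].T, columns=list(SPECIES))
    fracs = pd.DataFrame(
        sol.y[len(SPECIES) :].T / e_total, columns=list(CONFORMATIONS)
    )
    return OdeSolution(times=sol.t, concentrations=concs, conformation_fractions=fracs)


# ---------------------------------------------------------------------------
# conservation checks shared by the CTMC and SSA routes
# ---------------------------------------------------------------------------

def conserved_quantities(species: np.ndarray, conformations: np.ndarray) -> np.ndarray:
    """The four conserved totals, rows aligned with the input snapshots.

    potassium:  K_i + K_o + 2 (#K2.E2 + #K2.E1.ATP)
    sodium:     Na_i + Na_o + 3 (#Na3.E1.ATP + #Na3.E1~P)
    nucleotide: ATP + ADP + (#E1.ATP + #Na3.E1.ATP + #K2.E1.ATP)
    phosphate:  P_i + ATP + (#Na3.E1~P + #E2~P) + (#E1.ATP + #Na3.E1.ATP + #K2.E1.ATP)
    """
    sp = np.atleast_2d(species)
    cf = np.atleast_2d(conformations)
    i = {s: j for j, s in enumerate(SPECIES)}
    c = {s: j for j, s in enumerate(CONFORMATIONS)}
    k_total = sp[:, i["K_i"]] + sp[:, i["K_o"]] + 2 * (
        cf[:, c["K2.E2"]] + cf[:, c["K2.E1.ATP"]]
    )
    na_total = sp[:, i["Na_i"]] + sp[:, i["Na_o"]] + 3 * (
        cf[:, c["Na3.E1.ATP"]] + cf[:, c["Na3.E1~P"]]
    )
    bound_atp = cf[:, c["E1.ATP"]] + cf[:, c["Na3.E1.ATP"]] + cf[:, c["K2.E1.ATP"]]
    nucleotide = sp[:, i["ATP"]] + sp[:, i["ADP"]] + bound_atp
    phosphate = (
        sp[:, i["P_i"]]
        + sp[:, i["ATP"]]
        + cf[:, c["Na3.E1~P"]]
        + cf[:, c["E2~P"]]
        + bound_atp
    )
    return np.stack([k_total, na_total, nucleotide, phosphate], axis=1)
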