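# pumpmc — model checking the sodium-potassium pump cycle

`pumpmc` is an analysis package for the Na,K-ATPase: it builds the
discrete-state continuous-time Markov chain (CTMC) of the six-step
Albers-Post cycle from published kinetic constants and interrogates it the
way a probabilistic model checker would — exhaustively, over *all* states —
rather than by sampling trajectories.  It answers questions simulation
handles poorly: does extracellular potassium *certainly* deplete? how long
is that expected to take? do depletion and full recovery recur forever
(reversibility)? which reaction dominates the dynamics in each state, and
when do those trends flip?  The same model is cross-validated with exact
Gillespie simulation and the deterministic mass-action ODE limit.

It is written for systems biologists and quantitative modellers who want
exhaustive transient/first-passage analysis of small reaction networks
without running a separate model-checking tool (a PRISM-language export is
provided for cross-checks).

## The model in brief

Six reversible mass-action reactions move one pump enzyme through the
conformations E1.ATP → Na3.E1.ATP → Na3.E1~P → E2~P → K2.E2 → K2.E1.ATP →
E1.ATP, exporting 3 Na⁺ and importing 2 K⁺ per ATP.  In volume V, counts
are `#X = round([X]·V·N_A)` and a coefficient of molecularity κ becomes the
stochastic constant `c = k/(N_A·V)^(κ−1)`; propensities are mass-action on
counts (e.g. `c₄·#E2~P·kOut²`).  The CTMC (S, R, L) is explored by BFS
from the initial state; properties evaluated include P[F≤t Φ] (bounded
reachability via uniformisation / matrix exponential), P[F Φ] (exact graph
passes + linear solve), expected hitting times R{"time"}[F Φ], expected
instantaneous rewards R{"kOut"}[I=t], and P[GF a ∧ GF b] via bottom-SCC
analysis.  See `docs/methods.md` for the full account, including the
count-rounding subtlety (ceiling rounding calibrates the state space;
nearest rounding makes depletion reachable).

## Worked example

```python
import numpy as np
from pumpmc import (
    KineticParameters, VolumeContext, build_network, explore,
    bounded_reachability, expected_hitting_time, recurrent_pair_probability,
)

params = KineticParameters()                      # published kinetics
ctx = VolumeContext(volume=1e-20, rounding="nearest")   # K_o = 60 (even)
ctmc = explore(build_network(params, ctx))
print(ctmc.n_states, ctmc.n_transitions)
# 188 374

t = expected_hitting_time(ctmc, "kout_zero")      # E[time to kOut = 0]
print(f"{t:.4g} s")
# 9.446e+07 s

print(bounded_reachability(ctmc, "kout_zero", t)) # P[F<=E[T] kOut=0]
# 0.6332292393990977

print(recurrent_pair_probability(ctmc, "kout_zero", "kout_initial"))
# 1.0
```

Reading: depletion of extracellular potassium is *certain* and, once the
pump has run down, it recurs forever in alternation with full recovery
(probability exactly 1, from the bottom-SCC structure) — but the expected
time to the first depletion is ~9.4e7 s, because the chain must cross from
its quasi-equilibrium of ~15 ions down to 0 against a strong thermodynamic
gradient.  The 0.633 ≈ 1 − 1/e shows the depletion time is close to
exponentially distributed.  Under the ceiling convention (`rounding=
"ceiling"`, K_o = 61) the same call builds the 194-state chain used for
calibration and trend analysis.

The numbered drivers under `analysis/` run the full study and write tables
to `results/`:

```
python analysis/01_build_statespace.py    # sizes + exports, calibration
python analysis/02_rare_events.py         # depletion & recovery times
python analysis/03_reversibility.py       # BSCC analysis
python analysis/04_trends.py              # trend classification & flips
python analysis/05_validate_dynamics.py   # checker vs SSA vs ODE curves
```

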