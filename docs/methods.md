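# Methods

## The model

The Na,K-ATPase exports 3 Na⁺ and imports 2 K⁺ per ATP hydrolysed, against
both gradients.  The package models the Albers-Post cycle as six
elementary, reversible mass-action reactions over seven free species
(Na_i, Na_o, K_i, K_o, ATP, ADP, P_i) and six enzyme conformations
(E1.ATP, Na3.E1.ATP, Na3.E1~P, E2~P, K2.E2, K2.E1.ATP):

1. `E1.ATP + 3 Na_i  ⇌  Na3.E1.ATP`            (f1 = 2.5e11 M⁻³s⁻¹, b1 = 1e5 s⁻¹)
2. `Na3.E1.ATP       ⇌  Na3.E1~P + ADP`        (f2 = 1e4 s⁻¹,      b2 = 1e5 M⁻¹s⁻¹)
3. `Na3.E1~P         ⇌  E2~P + 3 Na_o`         (f3 = 172 s⁻¹,      b3 = 1.72e4 M⁻³s⁻¹)
4. `E2~P + 2 K_o     ⇌  K2.E2 + P_i`           (f4 = 1.5e7 M⁻²s⁻¹, b4 = 2e5 M⁻¹s⁻¹)
5. `K2.E2 + ATP      ⇌  K2.E1.ATP`             (f5 = 2e6 M⁻¹s⁻¹,   b5 = 30 s⁻¹)
6. `K2.E1.ATP        ⇌  E1.ATP + 2 K_i`        (f6 = 1.15e4 s⁻¹,   b6 = 6e8 M⁻²s⁻¹)

Backward stoichiometries are inferred from the units of the backward
coefficients (b3 in M⁻³s⁻¹ must bind three extracellular sodium ions, and
so on); bound-nucleotide/phosphoryl bookkeeping lives in the conformation
label, so the free ATP count changes only at step 5.  One full forward turn
nets ΔNa_i = −3, ΔNa_o = +3, ΔK_o = −2, ΔK_i = +2, ΔATP = −1, ΔADP = +1,
ΔP_i = +1, which is the electrogenic 3Na/2K exchange.

**Discretization.**  In a reaction volume V, molarities become counts
`#X = round([X]·V·N_A)` and a coefficient of molecularity κ (all reacting
entities, enzyme included) becomes a stochastic constant
`c = k/(N_A·V)^(κ−1)`.  Eq-level propensities use *raw powers* of the
reactant counts (`c·E·kOut²`), the guarded-command model-checking
convention for this system; a combinatorial (falling-factorial) option
exists behind a flag but is off everywhere.  The analyses run at
V = 1e-20 l with one pump molecule (NP = 1); the explicit-state engine is
comfortable up to V = 1e-19 l (1838 states).

**Rounding conventions.**  The count-rounding mode is a real modelling
choice here because all potassium updates are ±2 ions:

* `ceiling` reproduces the reference state-space sizes exactly at every
  volume (9/16, 32/62, 194/386, 1838/3674 states/transitions at
  1e-22..1e-19 l) and gives initial K_o = 61 — but an odd K_o makes
  `kOut = 0` unreachable, so every depletion property is vacuously false on
  this chain.
* `nearest` gives K_o = 60 (188 states at 1e-20 l), under which depletion
  and reversibility are well-defined.

Both facts cannot hold in one model; the package therefore defaults to the
calibrated `ceiling` convention but runs depletion/reversibility analyses
under `nearest` and trend analyses under `ceiling`, reporting the
convention in every result row.  This split is inherited from the source
analysis itself (see "Reproduction status").

## Property evaluation

The chain is the tuple (S, R, L) with exit rates E(s) = Σ R(s,·) and jump
probabilities R(s,s′)/E(s).

* **Transient distributions** use uniformisation: with q = 1.02·max E(s)
  and P = I + Q/q, π(t) = Σ_k Poisson(k; qt)·π(0)Pᵏ, truncated so the
  discarded Poisson mass is < ε (default 1e-9).  The pump chain is stiff —
  exit rates span ~8 orders of magnitude (fast Na/K binding vs slow
  conformational steps), so qt ≈ 1.2e8 already at t = 10 s.  Beyond a
  2e5-term budget the implementation switches to the dense matrix
  exponential (scaling-and-squaring `expm`; the chains here have ≤ ~2e3
  states).  The two routes agree to < 1e-8 on the pump chain at horizons
  where both are exact, and uniformisation is validated against analytic
  occupancies on the oracle chains.  Steady-state detection is not used;
  exactness is preferred at these sizes.
* **Bounded reachability** P[F≤t goal]: absorb the goal, take the transient
  mass on it; monotone in t by construction.
* **Unbounded reachability**: exact probability-0/1 classification by graph
  passes (backward reachability; then backward reachability to the prob-0
  set with the goal absorbed), the remaining states solved from the
  embedded-chain linear system (sparse direct solve below 1e5 states,
  Gauss-Seidel above; all study chains use the direct path).
* **Expected hitting times / accumulated rewards** solve
  x_s = ρ(s)/E(s) + Σ (R(s,s′)/E(s))·x_{s′} with x = 0 on the goal, where
  ρ is the state reward (1 for time) plus per-firing transition rewards.
  Start states that do not reach the goal with probability 1 (decided by
  the exact graph passes, not numerically) report +∞, the standard
  model-checking convention for undefined expected rewards.
* **Recurrence** P[GF a ∧ GF b]: bottom SCCs via strong-component
  decomposition; every state of an entered BSCC is visited infinitely
  often, so the probability equals reachability of the union of BSCCs
  containing both labels.  This route is exact (graph + the 0/1 cases).

## Trend analysis

A reaction has a positive (ascending) trend in state s when
`rate(s)/E(s) ≥ ξ`, with ξ = 0.6 by default; ξ > 0.5 forces at most one
dominant reaction per state.  A reaction is evaluated only in states where
its source conformation is occupied (elsewhere it is vacuously
non-positive and excluded from always-positive judgments).  Classification
is invariant under uniform rate scaling.

The *flip localization* answers "what is the expected K_o count when a
mixed reaction first changes trend?".  The flip moment is the first entry
into an opposite-indicator state of the source conformation after having
visited a same-indicator one; this is realized exactly on a two-phase
(armed/unarmed) product chain with the armed flip set absorbing.  The
expectation of K_o over the first-entry distribution is cross-checked by an
independent route: the expected net potassium-transport transition rewards
(`minusKout` per r4 firing, `plusKout` per rr4 firing) accumulated up to
absorption give `KO − 2·(E[minus] − E[plus])`.  Both formulations agree to
~1e-10 for the forward steps; for rr2, whose arming requires a deep
metastable excursion, agreement is limited to ~3e-3 by the conditioning of
the linear systems.  Alternatives (expectation at every flip, or
time-averaged) are not computed; first-flip is the implemented semantics,
with the `gains_positive` direction also exposed.

## Simulation and the deterministic limit

The Gillespie direct method samples the same jump process the checker
analyses: exponential waiting times at the total propensity, reactions
chosen proportionally.  Output is event-resolved (no time discretization),
so no event shorter than a sampling step can be missed.  One named seed
controls everything; ensemble run r uses seed `master + r`.  The inner
loop is numba-compiled when numba is importable (the pump fires ~2e4
events per simulated second at 1e-20 l); a pure-Python fallback keeps the
package importable without it.

The mass-action ODE system over concentrations (pump concentration
NP/(N_A·V), conformations as mole fractions) is integrated with LSODA at
rtol 1e-9/atol 1e-14; halving tolerances moves [K_o](10 s) by < 1e-6 M.
The ODE is the large-volume limit of the CTMC and shares its four
conservation laws (total K, total Na, nucleotide, phosphate — each
counting the enzyme-bound contributions).

## Synthetic oracles

Every numeric routine is tested against chains with closed forms written
independently of the checker: the reversible two-state chain
(P_B(t) = λ/(λ+μ)(1−e^{−(λ+μ)t})), pure-death chains (Erlang occupancies,
hitting time n/λ), the gambler's-ruin birth-death chain, a forked
two-absorber chain (multi-BSCC), and an irreducible 3-cycle (circulant
eigenbasis).  Perturbed parameter sets (independent lognormal factors on
the 12 coefficients — rates are positive scale parameters) check that the
structural invariants are kinetics-independent.  These oracles emulate the
*numerical* content of the study only; they do not emulate biological
variability, so passing them validates the solvers, not the kinetics.

## Problem sizes used

All headline computations run on the 188/194-state chains (seconds).  The
test suite uses a 2000-run SSA ensemble (seed 0) for the 3-standard-error
curve comparison on the 0..10 s grid, 500 runs in the analysis driver, and
60-240-run ensembles for the statistical sanity checks; these sizes give
standard errors of ~0.05-0.3 ions, ample for every comparison made.  Note
that a "within 3 SE at every one of 41 grid points" criterion has a ~10%
family-wise false-alarm rate under the null; the shipped seeds are fixed
once for reproducibility.

## Reproduction status and known limitations

Reproduced exactly by this reconstruction:

* state/transition counts at all four published volumes (ceiling);
* the full qualitative trend classification (r1, r2 always-negative, r6
  always-positive, r3/r4/r5 mixed, and the backward pattern);
* reversibility: P[GF kOut=0 ∧ GF kOut=KO] = 1 (nearest);
* depletion is certain (P[F kOut=0] = 1, nearest), and the probability of
  depletion *within its own expected time* is 0.633 (the reference prints
  0.63).

Not reproduced from the published kinetics (the reference implementation
of the original analysis is not available; its printed numbers evidently
come from a source differing from its own parameter table in some rate
detail):

* expected depletion time: computed 9.45e7 s vs 1287 s printed;
* depletion probability within 10 s: 8.5e-8 vs 6.33e-3;
* recovery times: 6.4/65.2 ms vs 14/111 ms;
* return time: ~1.1e12 s vs ~132,515 s;
* trend-flip counts for r3/r4: 51/13 (ceiling) vs 21/7;
* ODE plateau: 0.00246 M vs "about 0.0018 M".

The plateau disagreement is decisive: the plateau is the mass-action
equilibrium, and solving the detailed-balance condition
Keq = Πf_i/Πb_i = 2.396e5 M with the stated conservation totals gives
[K_o]_eq = 0.00246 M analytically — no choice made in this package can
move it.  The first-passage quantities are exponentially sensitive to that
quasi-equilibrium level (depletion means crossing from ~15 ions to 0
against the gradient), which is why they disagree by orders of magnitude
while all structural results match.  The corresponding acceptance
comparisons are left failing rather than loosened.

Numerical caveat: expected return times at the 1e12 s scale sit at the
edge of double precision for this chain (rate ratios span ~19 orders of
magnitude); they are order-of-magnitude estimates.  The depletion-scale
quantities (≤ 1e8 s) are stable to ~1e-4 relative.

Out of scope: symbolic (decision-diagram) state representation, full CSL
(no X, nested path formulas, or steady-state operator), membrane-potential
dependence, tau-leaping, and volumes above 1e-19 l for the explicit
engine.
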