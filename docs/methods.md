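# Methods

## Model and assumptions

The package models the post-stroke inflammatory response as a
well-mixed, deterministic three-species network: TNF-α (`C_T`) and IL-6
(`C_6`) cross-activate each other (rate constants `k_T6`, `k_6T`,
abstracting NF-κB-mediated co-expression), decay with first-order kinetics
(`β_T`, `β_6`, `β_10`), and are suppressed bilinearly by IL-10
(`γ_T10 C_10 C_T`, `γ_610 C_10 C_6`). IL-10 is produced at a basal rate
`α_10` and induced by the combined pro-inflammatory drive
`k_10T C_T + k_106 C_6`, gated twice: a cooperative Hill function of the
pro-inflammatory excess `d = C_T − C_6` (cooperativity `n = 5`, half-max
`K = 0.3 nM`) and a hard transcriptional delay `H(t − t_d)` with
`t_d = 18 h`. Units are nM and hours throughout; no receptor-level
(TNFR1/2, STAT3) states are resolved — their effects are folded into the
rate constants.

Two deliberate regularizations of the raw equations:

* **Clamped Hill input.** The gate is evaluated on `max(C_T − C_6, 0)`.
  The induction mechanism is meaningful only under pro-inflammatory
  dominance (`C_T > C_6`); without the clamp, an even cooperativity would
  spuriously activate induction when IL-6 dominates and an odd one would
  produce negative production rates. Clamping makes the right-hand side
  well defined for every state and every `n ≥ 1`, at the cost of a
  derivative kink at `d = 0` (the Jacobian uses the flat, zero branch
  there).
* **Right-continuous delay gate**, `H(0) = 1`: induction switches on
  exactly at `t = t_d`.

The IL-10 induction drive is `k_10T C_T + k_106 C_6`; `k_106` is an
IL-6-driven rate and multiplies `C_6`, consistent with the steady-state
form of the equations and the parameter table.

## Parameters

Defaults (per hour, per nM): `α_T = 0.02`, `α_6 = 0.01`, `α_10 = 0.005`,
`k_T6 = 0.45`, `k_6T = 0.40`, `k_10T = 0.15`, `k_106 = 0.12`,
`γ_T10 = 0.10`, `γ_610 = 0.06`, `β_T = 1.8`, `β_6 = 1.2`, `β_10 = 0.35`,
`n = 5`, `K = 0.3 nM`, `t_d = 18 h`; initial concentrations
`(0.1, 0.05, 0.01) nM`. The dimensionless rescaling `C̃ = C/K`
(`C̃_10 = γ_T10 C_10/K`), `τ = β_T t` exposes the control ratios
`k_T6/β_T = 0.25`, `k_6T/β_6 = 1/3`, `γ_610/γ_T10 = 0.6`,
`β_10/β_T ≈ 0.194`; the first two being well below 1 is why the
pro-inflammatory loop is subcritical at the default parameterization.

## Integration

Classical fixed-step RK4 with default `dt = 0.01 h`. The delay gate,
bolus times and modulation-window boundaries are forced onto the grid
(per-segment uniform step `≤ dt`), so each step integrates a smooth field;
within a step the gate and the effective (modulated) parameters are those
of the step's left endpoint. With breakpoint alignment this convention is
exact except for the measure-zero case of an internal RK4 stage landing
exactly on `t_d`. The empirical convergence order on the pre-delay segment
is 4.0 (sup-norm against a `dt = 1e-4` reference), and the pre-delay
trajectory agrees with the matrix-exponential solution of the linear
subsystem to below `1e-8` at `dt = 1e-3` (the comparison zeroes the small
`γ·C_10` coupling, which the 2-D linear reduction omits). Step output is
snapped to zero if a coordinate falls in `(−1e-9, 0)` — distinguishing
integration roundoff from genuine instability, which raises an error
instead. A bolus is applied after the state at its node is recorded, so
output trajectories show the pre-bolus value at the bolus node and the
jump immediately after.

## Equilibria and stability

For fixed `C_10` the TNF-α/IL-6 balance equations are linear, with
determinant `D(C_10) = (β_T + γ_T10 C_10)(β_6 + γ_610 C_10) − k_T6 k_6T`.
Substituting their solution into the IL-10 balance gives one scalar
residual `f(C_10)`; equilibria are exactly its roots. Enumeration scans
`[0, C10_max]` on a uniform grid (default 10001 points), refines each
sign change by bisection to `1e-12`, and discards roots with a negative
concentration. `C10_max` defaults to twice the IL-10 level that the
maximal (C_10 = 0) pro-inflammatory state could sustain, which bounds all
physical roots. Near-singular `D` subintervals are excluded and reported
via a warning; with the default couplings `D > 0` everywhere, so this path
only triggers for user-supplied parameterizations. This scan-based
approach is exhaustive on the interval and cheap, which is why no Newton
multistart or continuation machinery is used.

Stability is classified from the eigenvalues of the analytic Jacobian with
a `±1e-9` threshold on real parts (`stable` / `unstable` / `marginal`).
Two conventions are implemented for the IL-10 row: `exact` (product rule:
`∂f_10/∂C_T = k_10T·Hill + (k_10T C_T + k_106 C_6)·Hill′`, and the
analogous `C_6` entry) and `paper` (only the Hill-derivative term with the
combined prefactor `(k_10T + k_106)` and antisymmetric entries — the form
used in the published stability arithmetic, defined only for `C_T > C_6`).
`exact` is the default; at the reference evaluation state the two differ
in the third-row entries by ~0.04 but shift the eigenvalues by less than
5e-3.

## Bifurcation and hysteresis

A parameter sweep re-enumerates equilibria at each grid value; a fold
(saddle-node) is flagged wherever the equilibrium count changes between
adjacent values, and the bracketing interval is refined by bisection on
the parameter to width `≤ 1e-4`. The refinement logic is shared with the
analytic saddle-node fixture (`q + x − x³`, folds at `±2/(3√3)`), which is
how the detector is validated. Hysteresis is probed dynamically: ascending
and descending passes over the grid integrate to `t_settle = 500 h`
(default `dt = 0.05`), inheriting the attained state between grid values;
`t_settle` is two orders of magnitude above the slowest default time
constant (`1/β_10 ≈ 2.9 h`). Settling is verified by `‖f‖_∞ ≤ 1e-9` at
the horizon, with one 4× extension before a point is flagged unsettled.

An important negative result is locked in as expected behavior: with the
default parameters the post-delay equilibrium is unique for every
`γ_T10 ∈ [0.02, 0.15]` (steady-state `C_T ≈ 0.014 nM ≪ K` keeps the Hill
drive at ~1e-14, making `f` strictly decreasing), steady-state TNF-α
varies by under `1e-3 nM` across the sweep, and the up/down hysteresis gap
is below `1e-6 nM`. Bistability, fold points and hysteresis loops are
therefore not attainable in this region of parameter space, and the
fold/hysteresis machinery is validated on the analytic fixtures instead.
Users can search other regimes with the generic sweep (any `ParameterSet`
field can be swept).

## Sensitivity analysis

LHS alone cannot produce Sobol indices, so the design is Saltelli-style
with LHS-stratified base matrices: one Latin hypercube draw in `2k`
dimensions is split into `A` and `B`, and the `k` pick-one-column hybrids
`AB_i` complete the `n_base(k+2)` evaluations. First-order indices use the
Saltelli (2010) estimator `S1_i = E[f_B (f_{AB_i} − f_A)]/V`, total-order
the Jansen (1999) estimator `ST_i = E[(f_A − f_{AB_i})²]/(2V)`;
95% confidence half-widths come from a 200-replicate row bootstrap. The
default ranges are the tested ranges of the global sensitivity study
(e.g. `γ_T10 ∈ [0.02, 0.15]`, `n ∈ [2, 8]` sampled continuously);
`n_base` defaults to 1024 and everything is deterministic given a seed.
Estimator accuracy is validated on the Ishigami function (analytic total
indices 0.5576/0.4424/0.2437, recovered within 0.05 at `n_base = 2^13`),
on additive functions (`S1 = ST`) and on null inputs (`ST ≈ 0`). Because
the default steady state is insensitive to most parameters (closed Hill
gate), model-based indices mostly rank the IL-10 balance parameters; the
estimator test surface is the analytic fixtures.

Output quantities (QOIs) available for model-based analysis:
`steady_state_CT` (default; stable equilibrium with largest TNF-α),
`final_CT_72h`, `peak_C10`, `auc_CT_0_72` (trapezoid over the reference
simulation at `dt = 0.02`) and `resolution_time` (earliest time after
which TNF-α stays within 5% of its final value; never-resolved runs are
coded as 72).

## Synthetic fixtures — what they do and do not show

The test fixtures (`pure_decay`, `linear_2d`, `cubic_fold`, `ishigami`)
pair inputs with closed-form answers, so they validate the numerical
machinery — integrator order, matrix exponentials, fold refinement, Sobol
estimators — independently of the cytokine model. They emulate none of the
biology: passing them says the solvers are correct, not that the model
reproduces clinical cytokine kinetics. Conversely, the baseline trajectory
under the default parameters decays monotonically from the initial
conditions (both pro-inflammatory derivatives are negative at `t = 0`),
so the package makes no claim of reproducing an early TNF-α/IL-6 surge;
that behavior would require a different parameterization, which users can
explore through the configuration interface.

## Known limitations

Single well-mixed compartment (no core/penumbra gradients); no IL-1β,
MCP-1 or cellular actors; deterministic kinetics only; sharp (Heaviside)
delay rather than a distributed lag; fixed-step integration without error
control (step-size adequacy is established by the convergence test rather
than adaptively). Fold detection reports count-change intervals, not
normal-form coefficients; classification stops at "marginal" without
center-manifold analysis.
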