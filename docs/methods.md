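# Methods

## The model

`sigbcircuit` simulates the core regulatory circuit of the *Bacillus
subtilis* general-stress-response sigma factor σ^B. The circuit is a
partner-switching network: σ^B is sequestered by dimers of its anti-sigma
factor RsbW (`W2`), the anti-anti-sigma factor RsbV (`V`) displaces σ^B
from the `W2–σB` complex when dephosphorylated, RsbW's kinase activity
re-phosphorylates RsbV (`VP`), and an upstream stress-activated
phosphatase `P` re-activates it. Free σ^B drives production of itself, W
and V from a shared operon (rates f, λ_W·f, λ_V·f), a mixed
positive/negative feedback. The core model has 10 species and 27
reactions: 3 operon productions, 1 dimerisation, 4 bindings, 2
partner-switching exchanges, 5 dissociations, 2 phosphorylations, 1
dephosphorylation and 9 degradation/dilution reactions (degradation of the
`P–VP` complex releases the phosphatase, so `[P] + [PVP]` is exactly
conserved between stress steps).

Stress is a step: at t = 0 the free phosphatase is raised from `p_init`
(0.001 µM) to `p_stress`. Simulations begin 10 h before stress (burn-in
from an all-zero state except phosphatase) and run 200 h after it.

The *modified* model adds an inactive phosphatase pool `PI` and three
switching reactions (`PI→P`, `P→PI`, `PVP→PI+VP`, all at rate `eta_freq`).
These three reactions form a separate "upstream" noise group whose
Langevin noise is scaled by `eta_amp` instead of the core amplitude `eta`;
`eta_freq` leaves the deterministic behaviour unchanged and sets the
timescale (hence frequency content) of upstream fluctuations. Under
stress both pools rise by `p_stress − p_init`, so total phosphatase is
2·`p_stress` with on average half active.

### Operon production rate

The operon rate is f(s) = v0·(1 + F·s/(K+s)) with s = [σ^B]: base
activity exactly v0 = 0.4 µM/h at s = 0 and fold change 1+F at
saturation. An alternative grouping v0·(1+F·s)/(K+s) is selectable via
`production_form="shared"`; the two differ mainly in the zero-σ^B limit
(0.4 vs 2.0 µM/h). All quantitative claims in the test suite use the
default form; the stability structure reported below is present under
both.

### Partner-switch rate assignment

The forward exchange `W2σB + V → W2V + σB` uses `kB4` and the reverse
`W2V + σB → W2σB + V` uses `kD4`. At the published defaults
kB4 = kD4 = 1800 µM⁻¹h⁻¹ the assignment is numerically irrelevant.

## Simulation engines

**Chemical Langevin (CLE).** The SDE
dx_i = Σ_j v_ij a_j dt + Σ_j s_j v_ij √|a_j| dW_j, with one independent
Wiener increment per reaction per step and group-wise noise scales
s_j ∈ {η, η_amp}. Integration is drift-implicit, diffusion-explicit
Euler–Maruyama at a fixed step (default dt = 0.005 h, output every
0.01 h). The implicit drift step is solved by damped Newton with the
analytic Jacobian (tolerance 1e-10, ≤ 20 iterations). Absolute values
inside the square roots let species dip transiently negative without
raising errors.

Two robustness devices supplement the basic scheme:

* *Sub-step escalation.* If Newton fails, or a step lands below
  −`negative_floor` (default 0.02 µM), the step is redone as 2, 4, …
  sub-steps with the noise increment split evenly (the total injected
  noise per step is preserved exactly), letting the drift relax between
  noise kicks.
* *Negativity barrier.* Mass action evaluated at sufficiently negative
  amounts is a finite-time-blowup vector field — the dimerisation term
  −kBw·[W]² pushes a negative [W] further down, and past a tipping point
  the backward-Euler equation has no real root. Components still below
  −`negative_floor` after the deepest sub-stepping are clamped at the
  floor. Dips smaller than the floor (the common case) are never
  touched, so the measure statistics are unaffected in ordinary regimes.

**Deterministic (ODE).** By default the same fixed-step scheme with the
noise off, so the η = 0 CLE path and the ODE path coincide exactly and
convergence/limit checks are meaningful. `ode_method="adaptive"` runs
LSODA at rtol 1e-10 for truth-level accuracy (used for oracle
comparisons and steady-state relaxations). The fixed-step scheme is
first-order: halving dt moves the path only during the stiff
boundary-layer transients right after stress (sup-norm ≈ 0.07 µM at the
defaults) and not at all in the relaxed phase (< 1e-6); window maxima
and means — the quantities the measures use — are insensitive to this.

**Gillespie SSA.** The direct method on integer molecule counts: the
same rate numbers are used per the molecule-unit convention of the
source model (`p_init` rounds to 0 counts). Statistically exact; used to
confirm that CLE conclusions are not artefacts of the SDE approximation.

**Seeding.** Each trajectory derives burn-in and post-stress stream
seeds from its root seed via `numpy.random.SeedSequence`; ensembles use
seeds base_seed…base_seed+n−1; scan cells use base_seed + 10000·cell.
Identical seed and settings give bit-identical output.

## Behaviour measures

A post-stress trace is split into the transient phase t ∈ [0, 5] h and
asymptotic phase t ∈ [5, 200] h (pre-stress samples excluded). With
transient max T, asymptotic max A and asymptotic mean m of the activity
(free [σ^B] by default; total σ^B selectable):

* single response pulse M_srp = T / A (dividing by the *asymptotic max*
  penalises late pulses, so both measures cannot be large together);
* stochastic pulsing M_sp = A / m (2 for a clean sinusoidal oscillation,
  ≈ 1 for a flat state, ≫ 10 for rare large pulses).

Ensemble scores are means of per-member ratios (mean-of-ratios, not
ratio-of-means). If a denominator is below 1e-12 the measure is defined
as 1 (no behaviour); simulated trajectories do not hit this guard.

Excess magnitudes M\*_srp = (M_srp − M_sp)₊ and symmetrically M\*_sp
(equality maps to (0, 0); the product is identically zero). On a profile
over a swept parameter, two distinctness statistics are computed by
trapezoidal quadrature (a plain-sum rule is selectable):

* dual: D = 2·I(M\*_srp)·I(M\*_sp) / I(max(M\*_srp, M\*_sp)), with the
  area formulation A_srp·A_sp/(A_srp+A_srp,sp+A_sp) reported alongside —
  the two published forms are not algebraically identical and neither is
  guaranteed to stay inside (0, 1) for unbounded magnitudes, so both are
  returned and the unit-interval property is reported, not assumed;
* single: D_srp = I(M\*_srp)² / I(max(·,·)), rewarding outright
  prominence.

Sensitivity: C = (n−1)·Σ(ΔM)², which scores c² for a linear rise of c
regardless of grid density and 0 on constants.

### Response classifier

`classify_response` operationalises the qualitative regimes with
documented heuristics (thresholds in `ClassifierThresholds`, all
configurable; none are source-model facts):

1. no_response — mean transient and asymptotic maxima below 0.05 µM;
2. single_pulse — mean M_srp > M_sp and > 2;
3. oscillation — ≥ 25% of the asymptotic band power (periods 0.2–20 h)
   within ±2 bins of the dominant peak, and M_sp ≥ 1.5;
4. stochastic_pulsing — M_sp ≥ 8 with an incoherent spectrum;
5. sustained_activity — otherwise.

Calibration measurements on the simulator at the transition base set
(k_K2 = 7 h⁻¹, η = 0.025, p_frac = 0.1 µM·h) place the regimes at
p_prod ≈ ≤5 / 15–26 / 28–30 / 35–120 / ≥150 µM/h with wide margins
between the cluster statistics, so the thresholds sit in empty regions
of feature space. Borderline calls carry a confidence note.

## Stability analysis

Steady states of the post-stress core drift are found by warm-started
root finding (scipy `hybr` with the analytic Jacobian), seeded from the
previous branch point or a long ODE relaxation, and accepted below
residual 1e-9. Because `[P]+[PVP]` is conserved the full Jacobian always
has a structural zero eigenvalue; all stability spectra are computed in
the reduced 9-species space with [P] eliminated. Leading real parts
within ±1e-8 of zero are flagged marginal. "Unstable implies limit
cycle" is confirmed by simulation (`oscillation_check`: persistent
bounded σ^B swings > 10% of the mean after a 150 h settle), not asserted
from eigenvalues. Fold-like jumps between coexisting branches are
visible as large steps in the branch (continuity is monitored); periodic
orbits themselves are not continued.

## Parameter conventions and deviations

Defaults follow the published core table (24 parameters; η = 0.025,
p_stress defaulting to 0.4 µM). Three published values could not be
reconciled with the model's own behaviour and are used in corrected
form; each was verified by direct computation:

* **p_frac at the transition base set.** With p_frac = 100 µM·h the
  deterministic p_prod branch is stable everywhere (scanned 5–5000
  µM/h, both production parses) and the stochastic transition loses its
  oscillatory window. At p_frac ≤ 0.1 the unstable window is
  (≈32.5, ≈118) µM/h and is *identical* for p_frac ∈ {0.0022, 0.01, 0.1}
  — matching the published p_frac-insensitivity claim and the stress
  parameters used elsewhere (p_stress = 0.24 µM with kP = 180 h⁻¹ gives
  p_frac ≈ 0.0013). The package uses p_frac = 0.1 µM·h as the
  intermediate value.
* **Production-form ambiguity and the dominance-flip stress pair.**
  The operon-rate grouping shifts the stress scale of the behaviour
  regimes by roughly twofold: at (k_K2, η) = (7 h⁻¹, 0.025) the
  single-pulse→stochastic-pulsing dominance flip sits at 0.14–0.16 µM
  under the default form and at 0.28–0.30 µM under the "shared" form.
  The published demonstration pair (0.24, 0.28 µM) straddles neither
  flip exactly; the corresponding end-to-end check is kept at the
  published values and documented as failing under the default form,
  while the flip itself is asserted at the shifted levels.
* **Stress-scan interval for the pulsing optimum.** At
  (k_K2, η) = (9.0 h⁻¹, 0.06) stochastic pulsing is a narrow optimum at
  p_stress ≈ 0.14–0.15 µM; 20–200 µM is deep in the saturated regime
  (M_sp ≈ 1). The scan interval is taken as 0.02–0.2 µM.
* The dissociation-reaction propensities act on the dissociating
  complex (mass action), as the written-out rate equations require.

## Problem sizes

Default test and reproduction sizes are chosen for desk-scale runs: scan
ensembles n = 8–50 per cell, the pulsing-optimum check uses an 8-point
stress scan (n = 20) plus one 100-member ensemble, the regime-transition
ladder 6 p_prod values at n = 20, and stability branches 21–30 points.
The "paper" presets in `sigbcircuit.reproduce` raise these to n =
100–200 and 10–60-point grids.

## Known limitations

* Intrinsic noise only: no extrinsic noise, cell-cycle coupling,
  division partitioning, or transcription/translation bursting; dilution
  noise is per-species independent.
* The CLE is an approximation; its accuracy degrades at very low copy
  numbers / high η, where per-step noise can exceed species scales. The
  SSA engine provides the exact reference.
* No periodic-orbit continuation: instability windows come from
  eigenvalues plus simulation confirmation; orbit amplitude/period
  branches are out of scope.
* The synthetic fixture traces are noise-free idealisations used to
  validate measure arithmetic; passing those tests validates the
  measures, not the biology of real trajectories.
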