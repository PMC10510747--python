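# Methods

## The pathway model

The ground truth is a seven-reaction synthetic pathway (shikimate-like) that
consumes phosphoenolpyruvate (pep) and erythrose-4-phosphate (e4p) and
produces a product G through six intermediates A–F. Host coupling is reduced
to fixed boundary concentrations: pep, e4p, inorganic phosphate, the
NADPH/NADP and ATP/ADP pairs, and the product sink G are constants of the
configuration (`src/dbtlsim/data/pathway.yaml`, concentrations in mM). Only
the six intermediates carry ODEs, so the pathway is a standalone dynamical
system rather than a module inside a genome-scale host model. This reduction
keeps the design→flux landscape fully reproducible from the shipped
configuration; the cost is that host-level feedbacks (substrate depletion,
cofactor balancing) are not represented, so absolute fluxes are arbitrary and
only *relative* fluxes are meaningful.

Rate laws per mechanism tag (all concentrations c, parameters per reaction):

- **IrrevMM** — v = ℓ·Vmax·∏ₛ cₛ/(Kₘₛ + cₛ) over the substrates.
- **RevMM** (uni-uni) — v = ℓ·Vmax·(S − P/Keq) / (Kₘₛ·(1 + S/Kₘₛ + P/Kₘₚ)).
- **GenRevHill** — v = ℓ·Vmax·∏ₛ cₛʰ/(Kₘₛʰ + cₛʰ) · (1 − Γ/Keq), with Γ the
  mass-action ratio and Hill coefficient h (default 1).

ℓ is the relative enzyme level; Vmax = kcat·[E] makes ℓ a proportional Vmax
multiplier, which is the model's only engineering handle. Reversible rates
vanish at Γ = Keq and their sign always equals sign(1 − Γ/Keq), with
Keq = exp(−ΔG°/RT) at T = 298.15 K, R = 8.314 J/(mol·K).

Every intermediate additionally carries a first-order **growth-dilution term**
(−μ·c, default μ = 0.1 h⁻¹). Without it the system can lack a steady state
altogether: the first reaction's substrates are boundary constants, so its
flux is level-proportional and independent of the intermediates, and any
design whose downstream Vmax capacity falls below that influx would
accumulate intermediates indefinitely. Dilution by growth is the standard
physical resolution and guarantees a bounded steady state for every design.

## Thermodynamically consistent parameter generation

Reference kinetic parameter sets are sampled, not tabulated:

1. Reference intermediate concentrations log-uniform in [0.01, 1] mM; Km
   values log-uniform in [0.001, 1] mM (both configurable).
2. Reject states where any reversible reaction sits at ≥ 80% of equilibrium
   (Γ/Keq ≥ 0.8): the back-calculated Vmax would diverge as the driving
   force vanishes.
3. The terminal product flux is drawn lognormally around 1 mM/h (σ = 0.2 in
   log space); per-reaction reference fluxes then solve the steady-state
   balance S·J = μ·c_ref anchored at that terminal flux.
4. Each Vmax is back-calculated so its reaction carries exactly its reference
   flux at the reference state — making the reference an *exact* steady state.
5. The candidate is accepted only if all eigenvalues of the Jacobian at the
   reference state have negative real parts.

The generator is a deliberately simplified stand-in for full structural
thermokinetic sampling: it preserves the two properties the downstream
analyses rely on — Keq consistency with ΔG° and a verified stable reference
steady state — but does not impose host-level flux or concentration
constraints. Consequently each seed defines its own landscape, and all
learning/recommendation results are properties of the generated landscape,
not of one canonical parameter table.

## Steady states and the bioprocess

`simulate_steady_state` integrates the ODEs (LSODA, rtol 1e-8, atol 1e-12)
from the reference state over geometrically growing windows until
max|dC/dt|/J_ref < 1e-9 (horizon 1e5 h; non-convergence is flagged, not
raised). `solve_steady_state_root` is an independent oracle: trust-region
nonlinear least squares on dC/dt = 0 in log-concentration space. The two
routes agree to ~1e-11 relative flux on random designs; the test suite
requires 1e-6.

`simulate_batch` wraps a design's relative steady-state flux in a minimal
1 L batch bioprocess: Monod growth on glucose (μmax 0.4 h⁻¹, Ks 0.05 g/L,
yield 0.5 g/g, 10 g/L glucose, 1 g inoculum) with a specific production rate
proportional to the design's relative flux and to glucose saturation, so
growth and production cease at depletion. An optional `burden` hook scales
the growth rate by a function of the levels vector (off by default).

## Design space

The default grid is P = 6 log2-spaced levels {0.125, 0.25, 0.5, 1, 2, 4}
over all N = 7 enzymes: 6⁷ = 279,936 designs. The grid is fully
configurable; the enumerator refuses spaces above a 300,000-design cap
unless the cap is raised. Enumeration is lexicographic (first enzyme varies
slowest), which fixes the deterministic tie-break used by the top-k metric.
Landscapes are cached to a keyed CSV (parameter + design hash); a stale key
recomputes silently, a corrupt file recomputes with a warning.

## Sampling scenarios and noise

Designs are assembled one-pot: each enzyme's level is an independent draw
from a per-enzyme probability vector, duplicates allowed. Defaults over the
6-level grid: equal (1/6 each); strong-effect bias
(0.20, 0.15, 0.075, 0.075, 0.20, 0.30) favouring levels far from the initial
strain with extra mass on upregulation; mild-effect bias
(0.05, 0.10, 0.25, 0.30, 0.20, 0.10) concentrated near level 1. For
non-default grids the same shapes are generated from |log2 level|. The exact
vectors are conventions (only the qualitative shapes are specified anywhere);
they are overridable per enzyme.

Measurement noise is applied to the relative flux (the learning target):
homoscedastic ε ~ N(0, σ) or heteroscedastic ε ~ N(0, σ·|y|), with σ = 0.04
and 0.15 the two study settings. The heteroscedastic scale σ·|y| (noise
proportional to signal) is the standard reading of "heteroscedastic" here.

## Learning and metrics

Features are the raw level multipliers; no one-hot encoding by default.
Scale-sensitive estimators (elastic net, linear SVM, SVR, k-NN uses raw
distances, neural network) are wrapped in a standardizing pipeline; tree
ensembles are not. Random forest, gradient boosting and the neural network
can be tuned by Bayesian optimization — 20 iterations of GP expected
improvement (Matern-5/2 on the unit cube, in-package implementation in
`bayesopt.py`) over 5-fold CV R² on the training set only. Search ranges:
RF {trees 50–500, depth 2–20, min leaf 1–10}; GBR {trees 50–500, learning
rate 1e-3–0.3 log, depth 2–8}; NN {1–2 layers, 8–128 units log, L2 1e-6–1e-2
log}. Untuned fits use library defaults, which is also how the low-data
model screen is run.

Metrics: R² is the squared Pearson correlation between predicted and
simulated fluxes over the evaluation space (constant predictions score 0 and
are flagged; a constant truth vector is an error). The top-k score is
|top-k by prediction ∩ top-k by truth| with ties broken by enumeration
order; k = 100 on large spaces, scaled to the space in the tests. Benchmark
run seeds depend only on (scenario, n), so all models see identical training
sets and runs are paired across models.

## Recommendation algorithm

The threshold sweep uses a uniform λ* grid of n_eval = 100 points on
[0, y_max] (100 keeps the trapezoidal AUC stable to well under 1% for smooth
curves). Negative predictions are clipped to 0 first. Survivor counts are
exact (descending sort + cumulative level counts); thresholds past the last
survivor are truncated, never extrapolated, and contribute no area. The AUC
is trapezoidal on the normalized frequencies, then normalized per enzyme.
At λ* = 0 the full space survives and every frequency is exactly 1/P; the
resulting distribution is scale-equivariant in the predictions and entirely
model-free (it reads only the prediction table).

## DBTL loop

Cycle 1 samples its budget from the equal scenario; each later cycle samples
from the previous cycle's recommendation distribution; the model is retrained
each cycle on all measurements so far (duplicates kept — their noisy
measurements differ). When the model spec requests tuning, hyperparameters
are re-optimized every cycle because the training set grows by up to an
order of magnitude. Per-cycle metrics are computed against the noiseless
landscape. Seeds derive from a master seed via spawned `SeedSequence`s
(master → repeat → cycle), so the whole multi-repeat experiment is a pure
function of (config, seed). Shipped strategies: (50,50,50,50,50),
(150,50,25,25), (25,25,50,150) — all 250 strains. Strategy comparisons report
per-cycle mean ± sd and assess final-cycle differences with a two-sided
permutation test on repeat-level metrics.

## Problem sizes in the shipped checks

Simulating all 279,936 designs takes hours on one core (~15 ms per steady
state), so the shipped analyses use documented reductions chosen once:

- benchmark: a 2,000-design uniformly sampled evaluation subset of the full
  6⁷ space; training sets of 50 are scenario-weighted draws from that subset;
  20 runs; default (untuned) hyperparameters, matching the model-screen
  setting.
- DBTL comparison: the full landscape of a P = 4, N = 5 grid (1,024 designs,
  levels {0.25, 0.5, 1, 2}), k = 50, 30 repeats, 15% homoscedastic noise,
  untuned gradient boosting.
- unit tests use P = 3 grids over 3–4 enzymes (27/81 designs).

## Known limitations

- The reduced host model removes feedbacks through shared precursors and
  cofactors; enzyme responses are monotone-or-unimodal, whereas a full host
  model can invert responses (e.g. downregulating the terminal step raising
  net production). Conclusions about model rankings and cycle strategies are
  therefore statements about this class of saturating, thermodynamically
  consistent landscapes.
- Generated parameter sets differ per seed; quantities tied to one specific
  parameter table (absolute fold-changes of individual enzymes) are not
  reproduced, only structural/statistical behaviours.
- Only enzyme-level (Vmax) engineering is encoded; catalytic-property (kcat)
  variants and design-of-experiments samplers are out of scope.
- The simple batch bioprocess has no substrate inhibition, maintenance, or
  fed-batch operation.
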