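# Methods

## Scope and model

`instmfa` implements isotopically nonstationary ¹³C metabolic flux analysis
(INST-MFA): inferring intracellular fluxes and metabolite pool sizes from the
transient approach of mass isotopomer distributions (MIDs) to isotopic steady
state after a tracer step. The intended application profile is a
photosynthetic microbe (a Chlamydomonas-like cell) in a turbidostat whose
medium CO₂ is switched to high ¹³C enrichment at t = 0, optionally with an
unlabeled acetate co-substrate, and whose biomass is sampled on a fixed grid
(0 s, 30 s, 90 s, 3, 5, 10, 15, 30 min, 1 h).

The metabolic model is an atom-mapped, compartmented reaction network at
metabolic steady state: net fluxes satisfy `S·v = 0` over balanced
metabolites (µmol·gDW⁻¹·h⁻¹), while labeling is transient. Reversible
reactions are split into net and exchange components; the exchange flux is
parameterized as `x = β/(1−β)` with β ∈ [0, 0.9999], keeping reversibility
finite and bounded during optimization (unbounded exchange fluxes are
unidentifiable at the high end and destabilize fitting). Molecular symmetry
(succinate, fumarate) is encoded as two alternative atom maps of weight 0.5
rather than a special flag, which keeps the EMU machinery generic.

## EMU decomposition and forward simulation

Measured fragments are traced backward through every atom map (both
directions for reversible reactions) to the minimal closed set of elementary
metabolite units (EMUs). Within one EMU size the balance is linear,

    c_i dX_i/dt = Σ_in w_j v_j Y_j − (Σ_out v) X_i ,

where `Y_j` is a same-size EMU MID or a convolution of strictly smaller
(or tracer-boundary) EMU MIDs. Source EMUs take a binomial MID from the
tracer's per-atom enrichment (atoms of one source molecule are labeled
independently). Growth dilution cancels in MID space because newly made
material carries the instantaneous MID; turnover of pre-existing unlabeled
macromolecules is therefore represented by explicit slow protein/starch
pools in the network, not by a dilution term.

Two integrators:

* **Reference path** (`method="bdf"`, default): SciPy's BDF per size
  stratum with the exact (constant) Jacobian, rtol 1e-8 / atol 1e-10 by
  default, dense output feeding the higher strata. Used for ground-truth
  generation and all oracle comparisons (at rtol 1e-10 there).
* **Fitting path** (`method="fast"`): a fixed-grid, variable-step BDF2
  scheme (L-stable; backward-Euler startup) on a piecewise-uniform grid
  anchored at the sampling times with logarithmic step allocation (~96
  points by default). Matrix factorizations are cached per distinct step
  size and the whole structural indexing is precompiled once per fit
  (`FastSimulator`), giving ~millisecond simulations with ~1e-3 worst-case
  and ~4e-4 rms MID error at the sampling times — well below the 5e-3
  measurement noise it is paired with.

An exhaustive full-isotopomer integrator (`isotopomer_oracle`, 2ⁿ states per
metabolite, guarded to ≤ 20 total balanced carbons) serves as an independent
oracle; the EMU cascade matches it to better than 1e-8 on all small fixtures.

Every simulated MID is renormalized to sum exactly 1 (relative adjustment
~solver tolerance); clipping at 0 guards against tolerance-level negatives.

## Estimation

The objective is the variance-weighted SSR over all scalar MID measurements.
Because each observed MID sums to 1, its M+0 channel is redundant and is
dropped from both the objective and the degrees of freedom. When the
dataset records its raw channel-noise scale, predictions are first mapped
through the *measurement operator*: recorded fractions are clipped at 0 and
renormalized, so the expected recorded value of a channel with true
fraction m is the censored-Gaussian mean `m·Φ(m/sd) + sd·φ(m/sd)`
(renormalized). Without this, structurally-zero channels — which the
post-processing biases upward by ~0.4·sd — drag the estimates by a
substantial fraction of their standard error and degrade CI coverage. Free parameters
are the orthonormal null-space coordinates of the constrained flux polytope
(steady state + fixed fluxes such as gas supply and biomass demands), one β
per reversible reaction, and optionally log₁₀ pool sizes in [1e-4, 1e2]
µmol·gDW⁻¹. Per-coordinate sampling boxes are the tightest axis-aligned box
around the bounded polytope (found by linear programming); flux-bound
violations inside the box are penalized with hinge residuals.

Multi-start strategy: `n_starts` random initial points are drawn uniformly
in the box; all are scored, the `n_local` most promising are locally
optimized (trust-region reflective least squares, numerical Jacobian), and
the best solution is polished to convergence with trust-region *restarts* —
re-launching the optimizer from its own endpoint until the SSR improvement
falls below a relative tolerance. The restarts matter: a collapsed trust
region otherwise reports premature "optima" orders of magnitude above the
true minimum. Fits are bit-reproducible for a given seed; rank deficiency
of the measurement Jacobian at the optimum raises an identifiability
warning. Goodness of fit uses the two-sided χ² test at α = 0.05.

Confidence intervals use profile likelihood (parameter continuation): one
net flux is stepped away from its optimum (initial step max(5 % |v̂|, 0.01),
×1.6 acceleration, adaptive halving on failed re-optimization), all other
parameters re-optimized at each step from a warm start, until the SSR
crosses `SSR_min + χ²₁,₀.₉₅ = 3.84`; the crossing is bisected to
max(1e-3·|v̂|, 1e-6). Walks truncate at the admissible flux range and are
flagged unbounded beyond 10× the largest substrate uptake. The reported
point estimate on flux maps is the interval midpoint (config-exposed choice;
"CI median" is not otherwise defined by a profile).

## Synthetic data and what it does (not) show

The generator simulates the fixture's true trajectories with the reference
integrator, adds independent Gaussian noise (default SD 0.005 per mass
fraction, typical MS precision), clips at 0 and renormalizes each MID to
sum 1. The *recorded* SD of channel i is the delta-method standard deviation
of the renormalized fraction, `sd·√(1 − 2mᵢ + mᵢ²(n+1))` (floored at sd/2):
renormalization shrinks the dispersion of small fractions and inflates the
dominant channel, and weighting with the nominal SD instead demonstrably
miscalibrates the fit (spurious "detections" of the structurally zero
gluconeogenic flux, CI under-coverage). Residual channel-to-channel
correlations from renormalization are ignored, as in standard weighted
least squares.

Fixture design (free choices a practitioner must make; values frozen before
the validation studies were run):

* `mini_chlamy_auto` / `mini_chlamy_mixo`: 30 reactions, 15 balanced pools;
  CBC (with a lumped, carbon-conserving 5 PGA → 3 RuBP regeneration),
  photorespiratory glycine branch, chloroplast hexose-P/starch turnover,
  lower glycolysis, PEPC anaplerosis, TCA + glyoxylate cycles, acetate
  activation, malic enzyme, a gluconeogenic PEPCK reaction whose true flux
  is 0 in both presets, and slow protein (300 µmol·gDW⁻¹) and starch pools.
  True fluxes reproduce the qualitative architecture of the two trophic
  conditions — shunt partition 0.5 and PDH 40-fold lower in mixotrophy,
  protein turnover 53 % (auto) vs 32 % (mixo), carboxylation ~11 % lower in
  mixotrophy, acetate supplying ~99 % of acetyl-CoA — not any particular
  measured flux map. Gas exchange is large relative to fixation (bubbled
  culture), so reassimilated respiratory ¹²CO₂ dilutes the CO₂ pool by only
  ~1–2 % in mixotrophy.
* `toy_tca_glyox`: a 19-balanced-carbon TCA + glyoxylate cycle with lumped
  skeletons (no separate AKG/fumarate/malate pools) so the isotopomer
  oracle applies.
* Pool sizes are order-of-magnitude plausible (time constants seconds to
  minutes for central metabolites; ~10 h for protein) and are recorded as
  part of ground truth.

The replicate validation studies (`instmfa.studies`) fix pool sizes at their
true values, i.e., they treat pools as measured; joint flux+pool estimation
is demonstrated separately on the toy cycle. Study sizes follow the
validation design: 50 replicates × 20 starts for recovery, 20 replicates for
zero-flux detection, 50 replicates (two profiled fluxes) for CI coverage.

What passing these studies shows: the estimator recovers fluxes, detects
structural zeros, and produces approximately calibrated intervals *under the
generator's assumptions* — Gaussian, independent, homoscedastic channel
noise; a correctly specified network; known pool sizes in the replicate
studies; instantaneous gas equilibration (a first-order lag is available as
an option). Real MS data violate several of these (correlated fragment
noise, natural-abundance correction error, unmodeled compartmentation), so
performance there is expected to be worse in ways these tests do not probe.

## Numerical choices and limitations

* Steady-state flux consistency: particular solutions via least squares
  (residual guard 1e-6), null spaces orthonormal, so parameter ↔ flux-map
  round trips are identities; `S·v` residuals are ≤ 1e-10.
* Stratum steady states solve the linear balance directly; a condition
  number above 1e12 (zero-throughput pool) is reported as an error naming
  the EMU.
* Ties in EMU ordering are broken lexicographically for reproducibility.
* The isotopic-steady-state solver and the autotrophic preset interact:
  the auto preset's succinate pool has zero throughput by design (noncyclic
  TCA), so only transient simulation is meaningful there.
* Profile CIs inherit any residual optimizer noise as slight conservatism
  (the threshold sits on the fitted, not the true, minimum).
* SSR/dof typically runs at ~0.8 rather than 1 on generated data: the
  renormalization of each MID leaves weak negative correlations between
  channels that the diagonal weighting cannot represent, so the χ²
  goodness-of-fit verdict is mildly conservative toward "reject-low".
* The CLI's condition report derives metrics from fitted flux maps; the
  growth-rate rescaling between conditions is multiplicative
  (`µ_ref/µ_own`), with per-doubling normalization as the obvious
  alternative if flux per biomass doubling is preferred.
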