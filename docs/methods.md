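# Methods

## The model

`gutmuscle` simulates an eight-species dynamical system describing how the
intensity of a bout of resistance exercise propagates along the gut–muscle
axis into skeletal muscle mass.  The state vector tracks dimensionless
expression levels of

| symbol | species | role |
|---|---|---|
| S | SCFAs | gut-microbiome metabolites; entry node transducing exercise intensity |
| A | AKT | anabolic kinase; activated by SCFAs, represses FoxO |
| T | mTOR | downstream effector of AKT driving protein synthesis |
| G | atrogins | E3 ubiquitin ligases of the degradation machinery |
| Mu | muscle | skeletal muscle mass |
| F | FoxO | transcription factor of the atrophy program |
| N | TNF-α | pro-inflammatory cytokine antagonizing AKT |
| Y | myostatin | growth factor negatively regulating muscle |

Every equation has the same balance structure: a constant basal production
`a_i`, mass-action (bilinear) activation/deactivation terms `c_j · u · v`
for the positive feedbacks, Hill repression factors

    H_j(u) = K_j / (u + K_j)  ∈ (0, 1]

multiplying the fluxes inhibited by `u` for the negative feedbacks, and
first-order degradation `d_i · u_i`.  Exercise intensity `s` (a
dimensionless scale; the mapping to %1RM is display-only) enters through
exactly two channels:

* a saturating production stimulus on SCFAs, `a(s) = c1·s/(s+K)`,
  reflecting the intensity-dependent rise of SCFA-producing microbiota; and
* an intensity-proportional acceleration of AKT dephosphorylation,
  `d2·(1 + s/M)`.  `M` is the **delay coefficient**: the larger it is, the
  weaker the intensity-driven decay of AKT, delaying its deactivation.

The full right-hand side is transcribed in `gutmuscle.model._make_rhs`; a
term ledger of the paired fluxes (each interaction appearing with opposite
signs in its two species) is asserted numerically in the test suite.  Two
deliberate asymmetries of the printed system are implemented exactly as
they stand and are covered by dedicated tests: the `c3` coupling removes
`c3·A·T` from AKT but injects only `c3·A` into mTOR, and the `l1` flux
drains *both* atrogins and muscle.

### Hill orientation

All Hill factors use the repressive form `K/(u+K)` (flux inhibited by the
`u` species), consistent with the rule that negative feedbacks are
Hill-shaped.  Under this form the `l1·H1(atrogins)·muscle` loss *decreases*
as atrogins rise, which runs against the biological picture of
atrogin-mediated degradation.  Because the intent cannot be resolved from
the equations alone, the alternative saturating reading `u/(u+K)` is
exposed as `hill_orientation="saturating"` on every entry point; the
default follows the printed formula.

### Units and initial conditions

One model time unit is one hour; the default horizon is 24 h.  All
simulations start from the homogeneous zero state — modeling begins at the
removal of the exercise stimulus, and the zero start makes the transient
overshoot relative to the control steady state part of the modeled signal.
Fold changes are defined as `u_i(t)` divided by the control (no-exercise)
steady state of species `i`.

## Numerical integration

Trajectories are integrated with SciPy's adaptive Bogacki–Shampine 2(3)
pair (`RK23`), the same Runge–Kutta family as MATLAB's `ode23`, with
`rtol=1e-6`, `atol=1e-9`, reported on a uniform 0.01 h grid.  Halving the
tolerances moves the headline fold changes by far less than 0.1%, and the
suite cross-checks the solver against a fixed-step classical RK4 oracle at
step 1e-3 (relative agreement better than 1e-4 at t=24 h) and against the
closed form of the decoupled linear system.

The model does not guarantee positivity.  Small negative excursions are
reported (a warning plus a `flagged` trajectory), never clamped, so
modeling artifacts stay visible.  Excursions cannot be allowed to grow
arbitrarily, though: each Hill factor has a pole at `u = -K_j`, and a state
that falls toward a pole collapses in finite time, which an adaptive solver
can only grind against.  Integration therefore carries two terminal guard
events — a species falling below half-way to its Hill pole (or below -1
where no pole exists), and any species exceeding 1e6 — that convert these
pathologies into a `SolverError` carrying the failing time.

Steady states are found by relaxing from zero in geometrically growing
chunks (cap 10,000 h) with the stiffness-switching LSODA solver — only the
endpoint matters here, so the trajectory solver's pedigree does not apply —
followed by a Newton polish (`scipy.optimize.root`) once the residual is
small, because the relaxation alone bottoms out at the integrator's error
floor.  The returned state satisfies `max|du/dt| < 1e-8` by default.

## Experiment protocols

* **Control baseline** — the steady state at `s=0`; cached per parameter
  set and used as the fold-change denominator everywhere.
* **Condition triplet** — low/moderate/high intensities `(1, 1.25, 1.5)`:
  a 1.5-fold span, the ratio between the ~45% and ~70% 1RM loads the
  triplet represents.  Discrete sampling at 0/3/6/24 h (linear
  interpolation on the dense grid) sits next to the continuous curves.
* **Graded sweep** — 10 equally spaced intensities spanning a 4-fold range
  `[1, 4]` (≈25% to 100% 1RM), plus the `s=0` control entry.  The summary
  per intensity is the *maximized muscle mass*: the maximum over the 24 h
  horizon of the muscle fold change.
* **Noise ensembles** — each replicate redraws all 37 parameters as
  `p + 0.001·z`, `z ~ N(0,1)` i.i.d. (additive noise; the alternative
  relative mode `p·(1+0.001·z)` is available as `noise_mode`).  A perturbed
  parameter that lands at or below zero is redrawn and the event logged.
  Default 20 replicates per condition.  The fold-change denominator is the
  *unperturbed* control baseline — the control is a separate stimulus-free
  experiment, and perturbing it per replicate would confound the noise
  analysis (a `per_replicate_baseline` flag restores the alternative).
* **Delay grid** — the full factorial of delay coefficients `M·{1,2,3,4}`
  (a linear 4-fold span) against the 10-intensity sweep.  Replicate streams
  are counter-based: seeded by `(master seed, M index, intensity index,
  replicate index)`, so cells are independent of evaluation order and full
  grids are bit-reproducible.  A failing replicate is flagged and recorded
  as NaN, never fatal.
* **720-sample preset** — `preset_720` factorizes a 720-run budget as 10
  intensities × 18 replicates × 4 delay coefficients, one consistent
  reading of that round number over the default grids.

Quadratic fits of maximized muscle mass against intensity (one fit per
delay coefficient) use ordinary least squares on `[x², x, 1]`;
`R² = 1 − SS_res/SS_tot` about the mean, `RMSE = sqrt(SS_res/n)` with the
raw count `n` in the denominator (no degrees-of-freedom correction; a
`ddof` switch is provided).  By default the fits use the per-intensity
replicate *medians*; fitting all replicate points is a flag away.  Boxplot
statistics follow the Tukey convention with linear-interpolation quantiles
— the most common plotting rule; the convention is fixed here because no
single standard exists.

## Calibration to printed anchors

The 37 parameters are dimensionless and mostly unmeasurable; what is
available are headline observables: the peak AKT (≈3.9-fold) and mTOR
(≈5.5-fold) fold changes at the high intensity of the triplet, the span of
maximized muscle mass across the graded sweep (≈1.2–1.7), SCFA (≈2 h) and
myostatin (≈4 h) peak times, and the replicate-median maximized muscle mass
at the base and 4× delay coefficients (≈1.8 and ≈4.6).  `calibrate` turns
these into a weighted sum of squared relative errors and searches the
admissible box — (1e-4, 10) for rates, (1e-2, 10) for half-saturations and
`M`, the O(1) regime implied by the fold-change magnitudes — with a
deterministic Latin-hypercube scan in log space followed by Nelder–Mead
refinement from the best point.  The best evaluation ever made is returned,
so a larger budget can never end worse, and fixed seeds make runs
bit-reproducible.

Failure handling matters for the search: an observable whose simulation
leaves the admissible region contributes a large bounded per-anchor penalty
instead of poisoning the whole loss, and sweep-type observables skip
failing intensities (mirroring the sweep protocol), so the optimizer still
sees partial credit near the boundary of the stable region.

Identifiability is explicitly *not* claimed: eight anchors cannot pin down
37 parameters.  The acceptance property is anchor reproduction — a
synthetic-recovery test generates anchors from a known set, perturbs it,
and requires the search to reproduce the anchors (not the parameters) to
within 5%.  Noise-median anchors are evaluated at a reduced replicate count
(5) inside the loss for speed and at the full count for final verification.

The bundled `data/params_reference.yaml` is the product of this
calibration and stands in for the original supplementary parameter table,
which is not redistributed here.  Its per-anchor residuals are reported by
`gutmuscle calibrate` and recomputed by `scripts/acceptance.py`.  Three
anchors are in structural tension under the printed equations: the muscle
fold ceiling at the 4× delay coefficient bounds the product
`c4·muscle/c3` (mTOR's input must stay positive), which in turn caps the
achievable mTOR fold relative to the AKT fold.  The shipped set makes that
compromise openly rather than silently breaking an anchor; rerun
`gutmuscle calibrate` or `scripts/acceptance.py` to reproduce the
per-anchor residuals.

## What the simulations do and do not show

The synthetic-data generator *is* the model: every quantity the package
reports is a property of the printed equation system under the reference
parameters, not of any biological measurement.  Passing tests demonstrate
that the implementation reproduces the system's documented behavior
(oracle-checked integration, cancellation identities, reproducible
ensembles) — they say nothing about whether the minimal network is an
adequate description of muscle physiology.  Known limitations, beyond those
flagged above: training periodization, repeated bouts and time-under-
tension are outside the model's assumptions (intensity is a single scale);
the noise model perturbs parameters, not states, so intrinsic expression
noise is not represented; and protein species aggregate phosphorylated and
unphosphorylated forms.
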