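# gutmuscle

Dynamic model of how resistance-exercise intensity regulates skeletal
muscle mass through the gut–muscle axis.

Sarcopenia research measures key signaling proteins (AKT, mTOR, myostatin,
...) at a handful of discrete times after an exercise bout, which leaves
the dynamics between samples — and the dose–response in intensity — a
black box.  This package implements a minimal regulatory-network model
that fills that gap: an eight-species system of ordinary differential
equations over SCFAs (short-chain fatty acids, the gut-microbiome signal),
AKT, mTOR, atrogins, muscle mass, FoxO, TNF-α and myostatin, together with
the complete in-silico experimental battery built on it.  It is aimed at
exercise physiologists and systems biologists who want to simulate,
perturb and refit the model rather than re-derive it.

## The model

Each species `u_i` follows the same balance,

    du_i/dt = basal value + activation − deactivation − degradation,

with mass-action terms `c_j·u·v` for positive feedbacks and Hill
repression factors `K_j/(u+K_j)` for negative feedbacks.  Exercise
intensity `s` (dimensionless scale) enters twice:

* SCFA production gains a saturating stimulus `a(s) = c1·s/(s+K)`;
* AKT degradation accelerates as `d2·(1 + s/M)`, where `M` is the *delay
  coefficient* — larger `M` delays AKT dephosphorylation.

All 37 parameters are dimensionless and strictly positive; simulations
start from the all-zero state (modeling begins at stimulus removal) and
results are reported as fold changes relative to the no-exercise control
steady state.  The system is integrated with an adaptive Bogacki–Shampine
2(3) Runge–Kutta pair on a dense 0.01 h grid over 24 h.  See
`docs/methods.md` for the full equations, assumptions and numerical
choices.

## Worked example

```python
import numpy as np
from gutmuscle import (
    GutMuscleModel, ConditionSpec, reference_parameters,
    run_condition, intensity_sweep, fold_change_series, peak,
)

params = reference_parameters()          # bundled calibrated parameter set
model = GutMuscleModel(params)

# continuous dynamics at the "high" intensity of the low/moderate/high
# triplet (s = 1.5, i.e. 1.5x the low intensity)
res = run_condition(params, ConditionSpec(s=1.5, label="high"))
for sp in ("SCFAs", "AKT", "mTOR", "myo"):
    v, t = peak(res.fold.times, res.fold.species(sp))
    print(f"{sp:6s} peak fold {v:5.2f} at {t:5.2f} h")

# graded-intensity sweep: maximized muscle mass across a 4-fold range
sweep = intensity_sweep(params).exercised()
print("muscle fold range:",
      round(float(np.nanmin(sweep.max_fold)), 3), "to",
      round(float(np.nanmax(sweep.max_fold)), 3))
```

prints

```
SCFAs  peak fold 22.32 at  2.10 h
AKT    peak fold  4.02 at  4.49 h
mTOR   peak fold  4.14 at  5.05 h
myo    peak fold  0.83 at  3.78 h
muscle fold range: 1.281 to 1.519
```

SCFAs surge first (the upstream gut signal, peaking ~2 h after the bout),
AKT spikes about 4-fold at 4–5 h and mTOR follows; myostatin crests just
before 4 h while staying *below* its resting level (exercise suppresses
it).  Maximized muscle mass responds non-monotonically across the
intensity sweep — an intermediate intensity builds the most muscle,
because overload accelerates AKT dephosphorylation faster than the
saturating SCFA stimulus can compensate.

The same pipeline is scriptable from the shell:

```bash
gutmuscle simulate --params params.yaml --intensity 1.5 --out run/
gutmuscle sweep    --params params.yaml --out sweep/
gutmuscle grid     --params params.yaml --reps 20 --seed 7 --out grid/
gutmuscle report   --params params.yaml --plots --out report/
```

Every run writes tidy CSVs, the fully resolved configuration, a content-
hash manifest and a structured log next to its outputs; fixed seeds make
ensemble grids bit-reproducible.

## The bundled reference parameter set

The model's parameter values live in `gutmuscle/data/params_reference.yaml`.
They were produced by the package's own calibration module
(`gutmuscle.calibrate`), which searches the admissible parameter box for a
set reproducing the headline observables of the study the model describes
(peak AKT/mTOR fold changes, SCFA/myostatin peak times, the span of the
muscle-mass sweep, and the ensemble medians at the base and 4× delay
coefficients).  Residuals per anchor are printed by
`gutmuscle calibrate` and recomputed by the acceptance script; one anchor
(the mTOR peak fold) is in structural tension with the others under the
printed equations and lands below its target — `docs/methods.md` explains
the mechanism.

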