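# gtpase-circuit

Modeling toolkit for the Golgi-localized coupled GTPase circuit that links
growth-factor sensing to protein secretion and cell survival.

## The biology and the model

Two molecular switches sit at the heart of Golgi secretion: the monomeric
GTPase **Arf1** (mG) and the trimeric GTPase **Gi** (tG).  EGF recruits a
GEF for Arf1 (mGEF), active Arf1 (mG\*) recruits the linker protein
**GIV/Girdin**, which acts as the GEF for Gi (tGEF).  Active Gi (tG\*)
releases Gβγ which, together with GIV itself, activates the Arf1 GAP
(ArfGAP2/3, mGAP) — two negative feedback arms that close the loop and
terminate Arf1 signaling.  mGAP activity also drives vesicle formation, so
secreted growth factors S accumulate, and cells sense their own secretion:
an autocrine secrete-and-sense loop that sustains the cell number X.

Each interaction is a normalized Hill function

    fact(x) = B·xⁿ / (Kⁿ + xⁿ)   for 0 ≤ x < 1,   fact(x) = 1 for x ≥ 1,

with B = (EC50ⁿ − 1)/(2·EC50ⁿ − 1) and K = (B − 1)^(1/n), so that
fact(0) = 0, fact(EC50) = ½, fact(1) = 1.  The circuit is seven ODEs — the
fractional activations of mGEF, mGAP, mG\*, tGEF, tG\* plus S and X:

    τ_mGEF d(mGEF)/dt = (fact₁(stimulus) + k_mGEF)·Y_mGEF − mGEF
    τ_mGAP d(mGAP)/dt = (fact₂(tGEF)·fact₃(tG*) + k_mGAP)·Y_mGAP − mGAP
    τ_mG*  d(mG*)/dt  = (fact₄(mGEF) + k_mG*)·(1 − mG*) − fact₅(mGAP)·mG*
    τ_tGEF d(tGEF)/dt = (fact₆(mG*) + k_tGEF)·Y_tGEF − tGEF
    τ_tG*  d(tG*)/dt  = (fact₇(tGEF) + k_tG*)·(1 − tG*) − fact₈(tGAP)·tG*
    dS/dt = (β_S·fact₉(mGAP) + k_S − α_S·S/(S+K₂))·X − γ·S
    dX/dt = λ·S/(S+K₁)·(1 − X/K) − μ·X

Model variants: the **coupled** circuit (AND or OR feedback logic on
mGAP), the **uncoupled single switch** (mGAP relaxes to its basal level),
and **GIV-depleted** cells (Y_tGEF forced to 0.1, i.e. ~10% of control
GIV).  EGF doses are non-dimensionalized by 217.4 nM, so 50 nM ↦ 0.23.

On top of the deterministic core the package provides:

* `stochastic` — Ornstein–Uhlenbeck noise injected into the stimulus, the
  species equations, or the interaction arrows, integrated with a
  fixed-step Euler scheme and summarised over ensembles of repeats;
* `dose_response` — steady-state dose sweeps, Hill/linear curve fits, and
  dose–response alignment (DoRA) quantification for upstream–downstream
  pairs such as mGEF→mG\* and tGEF→tG\*;
* `fitting` — normalized-RMSE parameter constraining against fold-change
  time courses (control and GIV-depleted jointly);
* `sensitivity` — local logarithmic gains d ln X / d ln α from ±10%
  parameter perturbations;
* `network` — differential shortest-path analysis of STRING-style PPI
  networks upon in-silico node deletion (shortest-path alteration
  fractions, end-protein rankings);
* `synthetic` — generators for surrogate experimental datasets and PPI
  fixtures with planted ground truth.

## Worked example

```python
import numpy as np
import gtpase_circuit as gc
from gtpase_circuit.dose_response import (dose_sweep, default_dose_grid,
                                          fit_hill, stimulus_to_egf)

p = gc.default_parameters()
v = gc.ModelVariant.coupled()

# EGF stimulation protocol: relax to the starved steady state, then 50 nM
basal = gc.pre_equilibrate(p, v)
tc = gc.simulate_deterministic(p, v, gc.egf_to_stimulus(50.0), (0, 30),
                               init=basal,
                               t_eval=np.array([0.0, 5.0, 15.0, 30.0]))
print(np.round(tc.variable("mGstar") / basal.mGstar, 2))
# [1.   3.   2.71 2.54]

# steady-state dose responses and Hill fits
curve = dose_sweep(p, v, default_dose_grid())
fS = fit_hill(curve.doses, curve.mean("S"))
fE = fit_hill(stimulus_to_egf(curve.doses), curve.mean("tGstar"))
print(f"secretion: n={fS.n:.2f} r2={fS.r2:.3f}")   # n=1.86 r2=0.999
print(f"EGF->tG*:  n={fE.n:.2f} r2={fE.r2:.3f}")   # n=1.73 r2=0.999
```

Active Arf1 rises ~3-fold within 5 min of EGF and declines toward
baseline — the transient produced by the closed-loop feedback.  At steady
state, secretion is an ultrasensitive function of the EGF dose
(n_Hill ≈ 1.9) and Gi activation follows with n_Hill ≈ 1.7, while the
mGEF→mG\* relationship stays nearly linear (dose–response alignment);
uncoupling the switches removes the secretion response entirely.

A `gtpase-circuit` command-line interface wraps the same functionality
(`simulate`, `ensemble`, `sweep`, `fit`, `sensitivity`, `network`,
`make-synthetic`); run `gtpase-circuit --help`.

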