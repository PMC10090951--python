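# Methods

## Model structure and assumptions

The circuit couples two GTPase switches through normalized-Hill
("logic-based") kinetics: every regulatory arrow is an increasing sigmoid
rescaled to pass through (0, 0), (EC50, ½) and (1, 1), saturating at 1 for
inputs ≥ 1 and clamped to 0 for negative inputs (noise can push arguments
slightly below zero; clamping preserves continuity and the [0, 1] range).
The abstraction deliberately skips mass-action detail — copy numbers are
assumed large enough for ODEs, total GTPase pools constant, tGAP constant —
and carries no spatial resolution.  Variables are fractional activations;
with basal rates k > 0 a variable may exceed its Y_max·(1) plateau
slightly, in which case it reads as a relative activation.

Time scales: the Arf1 block is fast (τ ≈ 1–1.5 min), the Gi block slower
(τ = 4 min), the mGAP feedback slower still (τ = 12 min) — this ordering
produces the Arf1 overshoot: activation completes before the two feedback
arms (tGEF→mGAP and tG*→mGAP, combined with AND logic) raise mGAP and
throttle mG* back down.  The secretion/cell-number module operates on
hour-long time scales (γ = 0.008 min⁻¹, μ = 0.004 min⁻¹), slow enough to
integrate the upstream signal and fast enough to reach steady state within
the 1,440-min simulation horizon.

## The default parameter set

The package ships a calibrated default parameter table
(`gtpase_circuit/data/default_params.yaml`, flat key–value YAML with one
row per kinetic constant).  It was constrained the same way the model
itself prescribes — tune until the simulated behaviour reproduces the
experimental anchors — using a seeded Nelder–Mead search over eight shape
parameters against these targets:

* active Arf1 (mG\*) fold change ≈ 3 at 5 min after the 0.23 stimulus,
  declining by 30 min;
* sustained mG\* under GIV depletion, with the GIV-depleted trajectories
  of the Arf1 block (mGEF, mGAP, mG\*) indistinguishable from the
  uncoupled single switch;
* saturating Gi activation over 0–30 min;
* steady-state dose–response Hill coefficients ≈ 1.86 (stimulus→S),
  ≈ 1.73 (EGF→tG\*) and ≈ 3.8 (tGEF→tG\*), all with r² > 0.99;
* near-linear mGEF→mG\* alignment (linear r² > 0.97) in the coupled
  circuit, lost in the single switch;
* basal steady-state agreement between the AND- and OR-gate feedback
  logics with the OR rescaling constants 0.24 and 0.0017.

Two structural choices deserve comment.

**fact₂ is switch-like.**  The tGEF→mGAP feedback arm uses a very steep
Hill function (EC50 = 0.135, n = 45): it is OFF below tGEF ≈ 0.1 and fully
ON above tGEF ≈ 0.17.  This makes arrow 2 a near-digital "GIV present?"
input to the AND gate — consistent with the digital-logic reading of the
feedback — and it is what makes GIV depletion (tGEF ≤ 0.1) *exactly*
equivalent to deleting the feedback: with fact₂ ≈ 10⁻⁶ the GIV-depleted
and uncoupled trajectories agree pointwise to ~10⁻⁸.  The dose-dependence
of the feedback then flows entirely through the graded tG\*→mGAP arm
(fact₃), which keeps the secretion dose–response from becoming too steep.
Steep fact₂ comes at a price: the B and K normalisation constants suffer
catastrophic cancellation if evaluated naively, so K^n is computed as
EC50ⁿ/(1 − 2·EC50ⁿ) (algebraically identical to B − 1).

**The OR-gate constants pin the basal operating point.**  With fact₂ ≈ 1
at the basal coupled state, AND ≈ fact₃(tG\*_basal) and
OR ≈ 0.24 + 0.0017·fact₃(tG\*_basal); the two coincide exactly when
fact₃(tG\*_basal) ≈ 0.2404.  The basal Gi activation (via k_tG\* = 0.075)
is calibrated to sit at that point, which reproduces the stated property
that both logics share their steady states (basal agreement ≈ 0.1%).  The
placement of the constants — multiplying the two fact terms — is a
documented choice (the OR-gate equation is described but its constant
placement is not printed); it is configurable through
`or_gate_c_tGEF`/`or_gate_c_tGstar`.  Away from the basal state the two
logics do diverge dynamically in this parameterisation; only the
steady-state agreement is contracted and tested.

## Numerical choices

* Deterministic reference: LSODA (stiff-capable, adaptive) at
  rtol 1e-8 / atol 1e-10, dense output on caller grids.
* Pre-equilibration: from an arbitrary start (all variables 0.5) the
  system is integrated in growing chunks (up to 144,000 min, covering
  either reading of the ambiguous "[0, 2,400 h]" horizon) and polished
  with a Newton solve; a polished root is accepted only if it is
  physical and locally stable (Jacobian eigenvalues ≤ 0), which guards
  against landing on spurious fixed points.  Residual tolerance 1e-8,
  verified < 1e-6 in tests; the result is start-independent at basal.
* Fixed-step RK4 at small dt serves as a brute-force cross-check of the
  adaptive solver (1e-4 relative on a 60-min window).
* Stochastic engine: fixed-step Euler at dt = 0.01 min on [0, 1,440] min.
  OU noise channels are advanced first each step with the scheme
  η' = η − η·dt + σ·δW + ½σ²(δW² − dt); the last term is the printed
  Milstein-style correction, which for additive noise has zero mean —
  a plain Euler–Maruyama scheme is available and both share the
  stationary statistics (mean 0, variance σ²/(2τ), verified).  Channel
  order (stimulus; species incl. the tGAP perturbation; connections) is
  fixed, all draws come from one seeded PCG64 stream, and trajectories
  are bit-reproducible for a given seed and batch layout.  S and X are
  floored at zero with a logged warning if a noisy step undershoots.
  Species noise enters the τ-scaled bracket for the five GTPase
  variables but is added directly to dS/dt and dX/dt, mirroring the
  different printed forms; the tGAP perturbation enters fact₈'s
  argument.  Ensembles (default 1,000 runs; mean and SD with the N−1
  denominator at 1,440 min) are advanced as one vectorised batch.
* Hill fits a·xⁿ/(xⁿ + K) + d: multi-start nonlinear least squares
  (n ∈ {0.5, 1, 2, 4} × K at the quartiles of x), ties broken toward the
  smaller n; the offset d is kept only when it lowers the residual sum
  of squares by > 1%.  r² = 1 − SS_res/SS_tot throughout (squared
  deviations; the printed formula's exponents are taken as 2, consistent
  with the negative r² the procedure can report).
* Sensitivity: the ±10% central difference
  [ln X(1.1α) − ln X(0.9α)]/0.2 is the default (dimensionless
  d ln X/d ln α); a literal variant dividing by 0.2·α is provided since
  the printed denominator reads that way.  Outputs must be strictly
  positive.
* Parameter fitting: joint, equally weighted normalized RMSE over the
  control and GIV-depleted datasets; simulated fold changes are
  normalized to their own pre-stimulus baseline (the same convention the
  synthetic generator uses for its "experimental" traces — for the
  GIV-depleted condition this is that condition's own t = 0, a
  documented choice).  The optimizer is a seeded Latin-hypercube +
  Nelder–Mead surrogate for hand tuning with a bounded evaluation
  budget; the acceptance rule is the printed one (nRMSE < 0.2 for mG\*,
  < 0.45 for tG\*, strict) and no identifiability claim is attached to
  the fitted values.
* Network stage: edges are unweighted after the confidence-score filter
  (hop-count geodesics, default STRING cutoff 667).  The shortest-path
  alteration fraction is |before Δ after| / |before ∪ after| over the
  geodesic sets; the published definition lives in an external reference,
  so this symmetric-difference form is a documented choice — downstream
  rankings only use fraction-1 pairs (fully turned-over geodesic sets),
  which are insensitive to the denominator convention.

## The synthetic-data generator

`synthetic.generate_timecourses` emulates the *statistical shape* of
densitometry and FRET fold-change measurements: the ground-truth model is
simulated (control = coupled, GIV-depleted = Y_tGEF 0.1), sampled on the
experimental grids (0/5/15/30 min for pulldowns, 5-min steps to 30 for
FRET), converted to fold change, and given Gaussian replicate noise with
SD = 10% of the trace mean (SEM bars in the source figures are graphical
only; 10% over n = 3 replicates is the documented choice), truncated at
zero because ratio measurements are positive.  It does **not** emulate
blot saturation, FRET bleed-through, batch effects or non-Gaussian
outliers — so passing fits on synthetic data demonstrate that the
workflow recovers trajectories under honest noise of realistic magnitude,
not that the model is identifiable from real experiments.
`generate_ppi_fixture` plants a linker node whose deletion fully rewires
the anchor→partner geodesics (unique 2-hop paths through the linker, with
a 3-hop detour guaranteeing new, strictly longer geodesics afterwards),
giving the network stage a known answer.

## Problem sizes

Default analysis sizes: 27-point dose grids (the seven canonical doses
plus 20 log-spaced fillers), stochastic ensembles of 1,000 runs for
production figures and 100 runs per dose for the routine checks, fitting
budget 400 objective evaluations from 4 starts.  These sizes give fitted
Hill coefficients stable to well under the comparison tolerances.

## Known limitations

* No spatial/compartmental resolution and no mass-action mechanism behind
  the Hill abstraction — by design.
* The OR-gate logic matches the AND gate at steady state only; its
  transient dynamics differ in this parameterisation.
* The kinetic parameters are a calibrated surrogate, not estimates of
  rate constants; only the behaviours listed above are constrained, and
  many parameter combinations reproduce them equally well (the fitting
  module makes the same disclaimer for its outputs).
* Gillespie-style discrete-molecule noise is out of scope; the OU/Euler
  scheme assumes abundant species.
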