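# Methods

## Physical model

The pipeline treats one epicardial coronary segment as an axisymmetric tube
whose lumen diameter d(s) is known along the centerline arc length s (mm).
Blood is Newtonian with dynamic viscosity μ = 0.0035 Pa·s and density
ρ = 1050 kg/m³ — standard whole-blood values at body temperature; both are
configurable. All internal physics is evaluated in SI; mmHg and mL/s appear
only at the interface (1 mmHg = 133.322 Pa).

Mean (time-averaged) trans-stenotic pressure drop is modelled as the sum of
a viscous and a turbulent-expansion term, quadratic in flow:

* **Viscous**: Δp_v = k1·Q with k1 = ∫ 128 μ / (π d⁴) ds, the Poiseuille
  integral over the full sampled profile. For a uniform tube this is
  exactly 128 μ L / (π D⁴); for tapered or diseased vessels the integral
  handles the geometry automatically, which is why the implementation
  integrates rather than lumping a per-lesion viscous constant. A lumped
  form (kv supplied per lesion) is available for cross-checks.
* **Expansion**: each discrete lesion contributes
  Δp_e = k2·Q² with k2 = kt·ρ·(A0/A1 − 1)²/(2 A0²), the classical
  separation-loss law with A0 = π d_ref²/4 the reference area at the lesion
  and A1 = π MLD²/4 the minimal lumen area. U in the underlying velocity
  form is the unobstructed-section velocity Q/A0, which makes the
  coefficient dimensionally consistent. kt defaults to 1.52, the classic
  empirical separation constant; it is exposed in the run config and is one
  of the two calibratable constants.
* **Inertial**: dropped. FFR is a ratio of mean pressures, and the mean of
  ρ L dU/dt over the cardiac cycle is taken as zero (steady-flow
  assumption); the inertance constant ku = 1.2 is carried in the
  coefficient type for completeness only.

Tandem lesions: expansion losses add lesion by lesion; the viscous integral
is additive over any partition of the profile by construction. Both
additivity properties are asserted to 1e-9 relative in the test suite.

When the modelled loss exceeds the driving pressure (Pd ≤ 0) the result is
reported as undefined with a "supra-physiologic loss" diagnostic rather
than a negative ratio — a real vessel would have collapsed its flow long
before this regime, which the steady one-way coupling cannot represent.

## Flow and simulated hyperemia

Resting flow uses the TIMI frame count: transit time t = frames/fps,
contrast velocity U = L/t, and Q_rest = V/t with V the axisymmetric vessel
volume ∫ π d²/4 ds. Contrast velocity is taken as blood velocity with no
bolus-dispersion correction, per the frame-count convention. A 15 fps
acquisition is assumed in the synthetic cohort.

Hyperemia is simulated, not induced: Pa_hyp = α·MAP_rest + β with defaults
α = 0.90, β = 0 (≈10% mean-pressure decline under intravenous adenosine),
and Q_hyp = f·Q_rest with f = 2.0 (a normal-range coronary flow reserve).
These constants are deliberate stand-ins for proprietary literature
regressions that are not public; they are exposed in the config, and the
calibration module exists precisely to fit f (and/or kt) against wire FFR.
An optional severity-dependent attenuation of f (linear to 1.0 at 90% DS,
motivated by flow-reserve blunting in severe disease) ships behind a flag,
default off. The reported FFR is evaluated at hyperemic flow only.

## Geometry conventions

* Arc length in mm, zero at the proximal end; diameters are lumen diameters
  in mm. Profiles are resampled at 0.1 mm (sub-pixel relative to typical
  angiographic resolution) before any integral.
* Reference diameter: iteratively reweighted straight-line fit of d on s —
  fit, exclude samples more than 10% below the line, refit until stable
  (max 10 iterations). This is the standard QCA healthy-taper convention;
  no claim is made that it matches any vendor's proprietary rule.
* Stenosis detection: lesion cores are maximal runs with
  d < 0.90·d_ref (entry fraction 0.10); cores closer than 2 mm merge into
  one tandem-component lesion; bounds extend outward to the first sample
  with d ≥ 0.95·d_ref (exit fraction 0.05). All three thresholds are
  configurable. The lesion reference diameter is the line fit evaluated at
  the MLD location (robust to catheter-adjacent artifacts); a
  proximal-segment-mean mode is available.

## Calibration

`calibrate_kfold` shuffles cases with a fixed seed, splits into k folds,
and grid-searches the tunable constants (flow factor over [1.5, 3.0] step
0.05; kt over [0.8, 2.4] step 0.05) minimizing mean squared FFR-vs-wire
error on the training folds; held-out bias, SD and RMSE are reported per
fold and the returned optimum is refit on all data. Grid search was chosen
over gradient methods because the space is 1–2 dimensional, the objective
is cheap after per-case constants are precomputed, and a fixed grid plus a
fixed shuffle seed makes every result exactly reproducible.

## Segmentation front-end

The image module is a functional desk-scale stand-in for semi-automatic
contour delineation, validated only against the package's own synthetic
renders. Ordered user seeds are densified to ~1 px spacing and pulled onto
the lumen center of their perpendicular scanline over three refinement
passes; each lumen edge is the half-height crossing between the local
vessel-core and background intensity, located to sub-pixel precision by
linear interpolation at quarter-pixel sampling. The half-max rule was
chosen because it is the simplest defensible densitometric edge model and
is exactly correct for a uniform-opacity silhouette under symmetric blur —
which is how the renderer draws vessels, deliberately, so that round-trip
tests isolate the measurement chain from the (unknowable) true x-ray
densitometry. Scanlines with insufficient contrast are dropped; an image
with more than 20% dropped samples fails quality review, mirroring the
image-quality exclusions of clinical practice. Pixel coordinates are
0-based (row, col) with pixel centers at integers.

## Synthetic cohort

The generator draws per-case parameters from truncated normals matching a
typical intermediate-stenosis study population: %DS 45.7 ± 11.0 truncated
to [10, 90], reference diameter 3.25 ± 0.56 mm truncated at ≥ 2 mm (the
usual inclusion criterion), resting MAP 93.9 ± 7.0 mmHg on [60, 130], and
contrast velocity 14.2 ± 5.9 cm/s truncated at ≥ 2 cm/s (the frame-count
method is unusable below; this shifts the realized mean up by ~0.3 cm/s).
About 10% of arteries carry 2–3 tandem lesions; lesion dips are Gaussian in
diameter (σ = length/6) so the dip center hits the target %DS exactly.
Draws whose modelled losses rival the perfusion pressure itself (model
FFR < 0.02 or undefined) are rejected and redrawn — a hard cap of 1000
rejections guards against infeasible configurations.

Wire FFR is generated as the forward pipeline's own FFR plus Gaussian noise
(default SD 0.03, the order of pressure-wire repeat-measurement
variability) clipped to (0, 1]. **This is a deliberate limitation**: the
reference shares the forward model, so parameter-recovery and agreement
tests demonstrate that inversion, calibration and the statistics machinery
work — they say nothing about whether the physics matches real vessels.
Real cohort-level agreement numbers cannot be reproduced without patient
data. Likewise the synthetic joint distribution of severity, flow and wire
FFR is a modelling choice; only the marginals are matched.

With the default constants the synthetic prevalence of positive (≤ 0.80)
cases is well below typical clinical cohorts: a 45% DS lesion costs only a
few mmHg at 2× resting flow, so positives are dominated by the >60% DS
tail. This is consistent with the textbook non-linearity of stenosis
hemodynamics (negligible drops below ~50% DS) rather than a bug; studies
enrich for physiologically ambiguous lesions in ways the marginal
distributions alone cannot encode.

## Statistics

Proportion CIs are Clopper–Pearson exact (they can never leave [0, 1]);
likelihood-ratio CIs use the standard log method. Threshold comparisons are
inclusive (≤ 0.80 positive) for both index and reference. The ROC AUC is
the Mann–Whitney pair-counting estimator with ties counting one half,
computed via midranks; its variance and the paired-AUC test use DeLong's
structural components, with the ROC direction set by an explicit flag
(lower FFR = diseased) rather than silent negation. All p-values are
two-sided. Degenerate cases degrade softly: zero-denominator metrics are
NaN, identical paired scores give p = 1, and zero DeLong variance with a
non-zero AUC difference warns and reports the difference with an undefined
p.

Note on the 24/4/56/4 worked confusion table: the positive likelihood
ratio computed from those counts is 12.86; rounded variants (12.7, 13.0)
circulate from intermediate rounding of sensitivity/specificity. The
package always reports the value computed from the counts.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen for fast iteration:
100-case cohorts for calibration recovery, 200 cases for the in-silico
study, 5000 for distribution-marginal checks, 60–100 mm vessels at 0.1 mm
sampling, and 0.2 mm/px renders. Every stochastic path (cohort draws,
calibration shuffles, render noise, ROC instances) flows from one integer
seed; identical seeds are bit-identical end to end.

## Known limitations

* Single-view geometry cannot capture eccentric or irregular cross-sections;
  the axisymmetric assumption under- or over-estimates A1 for such lesions.
* No bifurcation flow splitting: the measured volumetric flow is assumed to
  traverse the whole interrogated segment.
* Steady mean-pressure physics only — no waveform, no pulsatile inertance,
  no microvascular or collateral modelling.
* The hyperemia constants are population-level stand-ins; per-patient
  hyperemic response variability is not modelled.
* The segmentation module handles single-frame stills with user seeds; it
  is not a vesselness-filter or learned segmenter and has only been
  validated on synthetic renders.
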