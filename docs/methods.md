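# Methods

## Scope and workflow

`radbioqa` implements the radiobiological layer of patient-specific plan
verification: given one dose-volume-histogram (DVH) set computed by the
treatment planning system and one reconstructed from phantom measurements,
it evaluates per-structure TCP/NTCP, pools them into plan-level
probabilities (P_I, P_B, P+), takes measured-minus-planned differences,
optionally attaches 3D gamma-index pass rates, and aggregates cohorts. The
vendor-specific step that reconstructs a delivered 3D dose and DVHs from
detector measurements is out of scope: the package consumes any exported
DVH text and any dose grid (DICOM RT Dose, NPZ, or CSV+JSON).

## Dose-response model

The voxel/bin response is the Poisson model

    P(D) = exp(−exp(eγ − (D/D50)(eγ − ln ln 2)))

parametrised by D50 (50%-response dose, Gy) and γ, the maximum normalized
dose-response gradient. The ln ln 2 term calibrates the curve so that
P(D50) = 0.5 exactly — the package asserts this to 1e-12 for every bundled
parameter row. γ is the value of the normalized gradient D·dP/dD at the
steepest point of the curve (D* = argmax dP/dD); `max_normalized_gradient`
verifies the implementation recovers it numerically via central
differences. Note that the *unrestricted* maximum over D of D·dP/dD is
attained slightly above D* and exceeds γ by up to ~7% at γ = 1 (an
intrinsic property of this model family, not an implementation artifact),
which is why the check evaluates the gradient at the steepest point.

Fractionation is handled per DVH bin with the linear-quadratic EQD2
correction, EQD2 = D(x + α/β)/(2 + α/β), taking each bin's dose per
fraction as x = D/n with n the plan's fraction count — the standard
convention when only total bin doses and the fraction number are known.

TCP aggregates bins as ∏ P_i^Δv_i; NTCP uses the relative-seriality model
{1 − ∏ (1 − P_i^s)^Δv_i}^{1/s}. Plan level: P_I = 1 − ∏(1 − NTCP_j) over
organs at risk, P_B = ∏ TCP_j over targets, and P+ = P_B − P_I. The joint
term P_{B∩I} is not modelled; P+ uses the standard disjointness
approximation. Empty-collection conventions: P_I of no organs is 0, P_B of
no targets is 1, but a plan-level evaluation requires at least one matched
target (P+ is meaningless without one) and raises otherwise.

## Parameter tables

Four treatment-group tables (brain, head-neck, lung, pelvis/prostate; 24
organ rows) ship as YAML. D50, γ, α/β and the endpoint per organ come from
the published clinical dose-response compilations used for plan scoring.
The relative-seriality parameter s is taken equal to the compilations'
α column, which matches the organ-by-organ s values reported in the
relative-seriality literature (e.g. lung 0.01 and parotid 0.01 — highly
parallel; rectum/sigmoid/penile bulb 0.7; heart, mandible, spinal cord 1.0;
brachial plexus 8.4 — highly serial) and is blank exactly for the tumour
rows, where seriality is undefined. The α value itself feeds no computation
and is retained for provenance only. Any organ can be overridden from a
user YAML file; normal-tissue entries without a seriality value are
rejected at load time so the gap can never pass silently.

Structure names from clinical exports are resolved by ordered
case-insensitive regex rules (first match wins). Laterality prefixes
("Rt./Lt.") map left and right structures onto the same parameter row, and
each structure then contributes independently to P_I; head-neck high- and
low-risk targets (PTV7000/PTV5400) enter P_B as separate targets. Unmatched
labels are reported and excluded, never dropped silently.

## DVH conventions

Doses are Gy everywhere; cGy inputs are converted only when a file header
declares them. Differential bins carry their left-edge dose; cumulative
V(D) is the fraction receiving ≥ D. Cumulative → differential differencing
assigns Δv_i = V(D_i) − V(D_{i+1}) to D_i, and the conversions are exact
inverses (tested to 1e-12). The DVH form is always declared in file
headers, never guessed from the data shape. Grid-derived DVHs use a 0.1 Gy
default bin width.

## Gamma index

γ(r) = min over r′ of sqrt(|r′ − r|²/dta² + (D_eval(r′) − D_ref(r))²/ΔD²).
"N%/M mm normalized to 90% of max dose" is read literally: ΔD = N% of
(0.9 × maximum reference dose); fixed-value and local normalization are
available as options. The default low-dose threshold is 0 (all points
evaluated), with a configurable percentage-of-normalization threshold. The
minimisation samples the evaluated grid by trilinear interpolation on an
offset lattice of step dta/10 within a search radius of 3×dta, visited in
order of increasing distance with an early exit once the distance term
alone exceeds a point's current best γ — this is exact for the lattice, and
the implementation is tested to 1e-9 against an unoptimised double-loop
oracle. γ values whose true minimum lies beyond the radius cap report the
best value inside the cap (necessarily > 3, already a clear failure).
Mismatched geometries are handled by interpolating the evaluated grid at
reference points; the reference grid is never resampled. Tightening the
criteria or coarsening the search step can only raise γ; both properties
are tested.

Naming: the gamma *index* and the dose-response *slope* are unrelated
quantities that share a symbol in the field; the code calls the latter
`gamma_slope` throughout.

## Synthetic data

No patient-level verification data are publicly deposited, so cohorts are
generated. Target DVHs are narrow truncated normals around the
prescription (mean within ±1%, sd 1.5–3% of prescription); organ-at-risk
DVHs are monotone sigmoid-decay cumulative curves spanning 0 to
near-prescription dose; dose grids are Gaussian blobs on a 15% bath,
normalized to a 10 Gy peak. Prescriptions are drawn from the dose and
fraction ranges these five cohorts span in conventionally fractionated
practice (e.g. brain 50.4–60 Gy in 28–30 fractions, prostate 45–70.2 Gy in
25–30), with the fraction count chosen nearest 2 Gy/fraction within range.

Measurement discrepancy is a three-knob phenomenological model — systematic
dose scale (optionally split target/OAR), spatial Gaussian blur (grids
only), multiplicative noise (per structure for DVHs, to preserve
monotonicity; per voxel for grids) — because verification practice
attributes planned/delivered differences to these effect classes. It does
not model detector geometry, reconstruction algorithms, or anatomy, so
passing tests demonstrate correct propagation of dose discrepancies through
the models, not agreement with any clinical cohort's absolute numbers.
Cohorts use one root seed with per-patient child seeds spawned via
`numpy.random.SeedSequence`, so individual patients regenerate in
isolation.

## Numerical choices

- The inner exponent of the Poisson response is clamped to ±700 before
  exponentiation; extreme doses saturate at 0/1 instead of overflowing.
- TCP/NTCP accumulate in log space; 1 − P^s is computed as
  −expm1(s·log P) → log1p(−·) to keep precision when P^s approaches 0 or 1
  (the whole-organ identity NTCP = P holds to ~1e-15 for s from 0.01 to 10).
- Differential DVH volumes are renormalized on construction only when their
  sum differs from 1 by more than 1e-12, making re-wrapping idempotent
  (identity perturbations stay bit-identical end-to-end).
- Cohort standard deviations use the sample (n−1) convention and are
  reported as undefined, not 0, for n < 2. The gamma-vs-|ΔP+| fit reports
  R² as the squared Pearson correlation and refuses constant regressors.
- P+ is a probability difference in [−1, 1] internally; reports use the
  percent scale.

## Problem sizes

The test suite and examples use grid shapes around 16×20×20 at 2.5 mm
spacing and cohorts of 8–10 patients — sizes chosen so every invariant runs
on commodity hardware while still exercising heterogeneous dose
distributions; nothing in the implementation is specific to these sizes.

## Known limitations

- No EUD/gEUD (Niemierko) models, LQ extensions (repopulation, repair
  kinetics), or confidence intervals on model parameters.
- The P+ approximation ignores the benefit–injury correlation.
- Model parameters carry substantial clinical uncertainty; for tissues with
  poorly determined parameters, TCP/NTCP values index delivered-dose
  uncertainty rather than predicting outcomes.
- Absolute-volume (cc) DVHs are supported only via normalization at read
  time; proprietary binary exports are not parsed.
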