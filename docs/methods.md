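# Methods

## Quantification models

### Conjugate-view planar LSF

Anterior and posterior whole-body counts over lung and liver ROIs are
combined per organ as the geometric mean √(A·P), which cancels the
depth-dependent factor of attenuation for a source at any depth in a
*uniform* attenuator (A·P ∝ exp(−μT) with T the total body thickness,
independent of source depth). The shunt fraction is

    LSF = √(La·Lp) / (√(La·Lp) + √(Lva·Lvp)).

Because lung tissue attenuates less than soft tissue and body thickness
varies, the cancellation is not exact across organs: liver counts are
suppressed more than lung counts and the planar LSF overestimates. This
residual bias is a feature under study, not a defect to remove.

### Dual-energy-window scatter correction

Scatter in the photopeak window is estimated from a lower energy window:

    C_true = C_main − (C_low / W_low) · W_main / 2,

with fractional window widths W (defaults 0.15/0.15, reducing the rule to
C_main − C_low/2). The correction is applied to ROI sums, not pixels: the
rule is linear, so both orders agree in expectation, and it is defined on
counts. Negative corrected counts are floored at zero (counts are
physical; Poisson noise can drive the estimator negative). An all-zero
denominator in the LSF is an error rather than zero, to distinguish
missing data from a true zero shunt.

### SPECT LSF and segmentation

From a count volume, LSF = Lc/(Lc+LVc) with LVc the *whole-liver* counts
(tumor included — "liver counts" taken literally; IHL is defined as liver
minus tumor). Tumor/target compartments are segmented by iso-contour
region growing: threshold at a fraction (default 0.40, configurable) of
the maximum intensity in a user box, keep the 26-connected component
containing the seed. The threshold convention and connectivity are
explicit because vendor tools vary; the operation is deterministic and
idempotent on its own output.

### Shine-through correction

Liver activity spills into the right-lung base through scatter, limited
resolution and SPECT/CT misregistration. The corrected lung count
expands the liver mask by a margin (default 20 mm, Euclidean distance
transform), excludes the expansion from the left lung, measures the clean
left-lung concentration (counts/cm³), and multiplies by the total
unexpanded lung volume. For homogeneous lungs with no spill this is
exactly the raw count. When the lungs are unlabeled the left lung is taken
as the low-x half of the lung bounding box (mid-sagittal split).

### Partition model and prescription

Three compartments (tumor, injected healthy liver, lung) share the
activity according to masses, the tumor-to-liver concentration ratio TLR
and the shunt fraction SF:

    liver uptake = (1−SF) · m_liver / (m_tumor·TLR + m_liver)
    tumor uptake = (1−SF) · TLR·m_tumor / (m_tumor·TLR + m_liver)

so liver + tumor uptake = 1 − SF identically. Activity for a prescribed
liver dose and the tumor dose use the ⁹⁰Y equilibrium constant
184,000 rad·g/mCi; the lung dose uses 49.33 Gy·kg/GBq with the shunted
activity A_admin·SF assumed uniform in the lung mass. **The two constants
disagree**: 184,000 rad·g/mCi is 49.73 Gy·kg/GBq. They are not reconciled
here — each is used inside its own equation as published, both are module
constants, and every dose function accepts an override to force a single
value. Units: Gy↔rad ×100 and mCi↔GBq ×0.037 exactly. TLR can be derived
from images as (tumor counts/mass)/(IHL counts/mass) when not supplied.

The prescription bands (resin spheres): factor 1.0 for SF < 10 %, 0.8 for
10–15 %, 0.6 for 15–20 %, contraindicated above 20 %. Band edges at 10 %
and 15 % belong to the higher-reduction band (the sources say "between"
without fixing ties); 20 % itself is still treatable at factor 0.6.
Flags are raised when the session lung dose exceeds 30 Gy or prior +
session exceeds 50 Gy. Default lung mass is 1.0 kg (patient lung masses
are rarely measured pre-treatment); configurable everywhere it enters.

### Deviation closed forms

With the target volume, masses and TLR fixed and only the shunt estimate
switched from SF_ref to SF_alt, the suggested activity scales as
1/(1−SF) and the lung dose as SF/(1−SF), giving

    Δ_activity = (1−SF_ref)/(1−SF_alt) − 1
    Δ_lungdose = SF_alt(1−SF_ref) / (SF_ref(1−SF_alt)) − 1.

These equal the full pipeline (activity equation then lung-dose equation)
to 1e-12, which the tests assert.

## Cohort statistics

The packaged 18-patient table carries the four LSF estimates per patient
at three decimals. Per-patient percent deviations are 100·(alt−ref)/ref
against the standard planar column. Reporting conventions, chosen once:
column SDs are population SDs (ddof=0); integer deviation summaries use
standard rounding; activity-deviation means are rounded to one decimal.
Both the Welch unequal-variance t-test and the Mann-Whitney U test are
computed for every method pair. The comparisons are statistically unpaired
even though the data are paired — this mirrors the two-sample design the
summaries derive from; a paired test is available via scipy directly. The
St-vs-NoAC-SC comparison is borderline: Welch p = 0.055, Mann-Whitney
p = 0.0497, so the significance *classification* of that pair rests on the
rank test. Deviations are computed on the three-decimal table values, so
integer summaries can differ by one unit from analyses run on
higher-precision source data.

## The phantom

A 64³ grid of 4 mm voxels holds a soft-tissue torso ellipsoid, two lung
ellipsoids (anterior), one liver ellipsoid (posterior and caudal — deeper
than the lungs, which is what makes the uncorrected planar and
non-attenuation-corrected SPECT estimators overestimate), and a 20 mm
tumor sphere inside the liver. Activity is normalized to total fraction 1:
the lungs hold exactly `true_lsf`, and the liver splits between tumor and
normal tissue at concentration ratio `tlr_true`. Defaults: true_lsf 0.05
(near the cohort's fully corrected mean), TLR 5, 10⁶ expected photopeak
counts per view, μ_soft 0.153 cm⁻¹ and μ_lung 0.045 cm⁻¹ (standard
narrow-beam values at 140 keV), scatter fraction 0.3, scatter kernel
σ = 30 mm, window widths 0.15/0.15, down-window ratio 2.0. Densities:
1.03 g/mL liver/tumor, 0.3 g/mL lung.

Planar projection is parallel-beam along the anterior–posterior axis with
per-voxel attenuation exp(−∫μ dl) accumulated to the detector side (half
the emitting voxel's own μ is included, i.e. path from the voxel center).
Scatter is modelled as `scatter_fraction` × Gaussian blur of the attenuated
primary image; the down-scatter image is `downwindow_ratio` × that term.
With downwindow_ratio = 2·W_low/W_main the DEW estimator equals the true
scatter in expectation, so the scatter-corrected planar LSF is unbiased —
the **generator contract** that closed-loop tests rely on. SPECT is not
reconstructed: the AC-SC volume is the calibrated activity map; NoAC-SC
weights each voxel by the mean over the four lateral cardinal directions
of exp(−∫μ dl) to the body surface; NoAC-NoSC adds a 3-D Gaussian-blurred
scatter term. Poisson noise derives from the single spec seed.

What the phantom does *not* emulate — collimator blur, depth-dependent
resolution, OSEM convergence and noise correlations, septal penetration,
respiratory motion, CT misregistration — bounds what passing tests show:
they validate the estimators' algebra and the direction and rough
magnitude of attenuation/scatter biases, not absolute clinical accuracy.
On the default geometry the four estimators order exactly as on patient
data (standard planar > NoAC-SC SPECT > scatter-corrected planar > AC-SC
= truth).

Validation tests that isolate the scatter/DEW model run the planar chain
with the attenuation map zeroed, because the geometric mean cancels
attenuation exactly only in a uniform attenuator; exactness (|error|
< 1e-6 noise-free, < 2 % relative in the mean over 100 Poisson
realizations) is asserted there, while the attenuated configuration is
asserted for ordering and bias sign. Problem sizes throughout (64³ voxels,
100–200 noise realizations, 10-phantom cohorts, 10⁴ random partition
inputs) were chosen as the smallest that make the statistical assertions
stable.

## Numerical and interface choices

* Degenerate inputs: all-zero LSF denominators raise; zero-variance
  columns raise in the correlation and (both-degenerate) t-test; an
  iso-contour seed below threshold raises; a liver margin that swallows
  the left lung raises.
* Masks are voxel-center inclusion tests with strict inequality; organ
  overlap or a tumor escaping the liver is a geometry error at build time.
* Volumes and masks travel as NIfTI (nibabel), planar images as 2-D NIfTI
  or TSV, configs as flat YAML, tables as CSV; the report generator is
  deterministic byte-for-byte given its input.
* Known limitations: no attenuation correction of planar data, no
  background-ROI subtraction, no CT-derived μ maps, no voxel-wise β
  transport; the phantom's SPECT emulation cannot probe
  reconstruction-dependent effects.
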