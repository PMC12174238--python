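# Methods

## Problem and model

`voxdose90` implements voxel-based internal dosimetry for transarterial
radioembolization (TARE) with Y-90 microspheres. The physical model is
the **local deposition method** (LDM): each voxel's activity is assumed
to deposit its complete decay energy in that voxel. Integrated over the
full decay of Y-90, the released energy is **49.67 J per GBq**, so a
voxel of mass `m` kg holding activity `A` GBq absorbs

```
D [Gy] = 49.67 [J/GBq] × A [GBq] / m [kg]
```

Activity maps are obtained from emission count images (Tc-99m-MAA SPECT
before treatment, Y-90 PET after) by the **patient-relative
conversion**: voxel counts are rescaled so the field-of-view total
equals the net administered activity (administered minus measured
residual). LDM ignores cross-voxel energy transport; for Y-90 beta
particles (mean range a few mm) on SPECT/PET voxel scales this is the
standard clinical approximation. Half-life and spectrum enter only
through the 49.67 J/GBq constant; no biological weighting (BED/EUD) is
computed.

### Compartments and metrics

Segmentations are binary masks on the common analysis grid: whole
liver, tumor, normal liver (= liver minus tumor), perfused volume (the
injected territory), perfused tumor, perfused normal tissue, and
lungs. Per compartment the engine reports the arithmetic mean voxel
dose (voxels are equal-mass, so this is the mass-weighted mean), the
cumulative dose-volume histogram (exact empirical survival function of
voxel doses on a uniform grid, 1000 bins by default for export), and
D-metrics. **D_x** is the dose received by at least x% of the
compartment: with voxel doses sorted descending, `D_x =
d(ceil(x·n/100))`, an exact order statistic with no interpolation —
oracle-checkable and well defined for small masks; D metrics are never
read off the binned DVH. The **T/N ratio** divides the mean tumor dose
by the mean perfused-normal dose; the tumor numerator uses the
perfused-tumor mask by default (the treated tumor), switchable to the
whole tumor.

### Lung shunt and lung dose

The lung shunt fraction (LSF) comes from conjugate planar views:
per-organ geometric means of anterior and posterior ROI totals,
`gm = sqrt(ant × post)`, and `LSF = gm_lung / (gm_lung + gm_liver)`.
Lung dose applies single-compartment LDM to the shunted activity:
`49.67 × net × LSF / lung_mass`. Lung mass defaults to 1.0 kg
(configurable); tissue density defaults to 1.03 g/mL for liver and
tumor (configurable). Both are conventional reference values; the
workflow they feed does not prescribe them more precisely.

## Geometry and resampling

Grids are axis-aligned in world millimetres with a voxel-center origin
convention; oblique or sheared NIfTI affines are rejected rather than
reinterpreted, and axis flips are likewise refused so that a volume
read back is exactly the volume written. Registration is applied from
user-supplied rigid parameters (intrinsic Z-Y-X Euler angles in
degrees plus a translation); no automatic registration is attempted,
matching a workflow in which registration is manual. Resampling is
tri-linear for scalar fields and nearest-neighbour for masks, with
out-of-field samples treated as zero signal (air background). Counts
and activity are extensive quantities, so their resampling rescales
the output to conserve the input total exactly; dose is intensive and
conservation mode is refused for it. Compartment doses are computed on
the common (reference-frame) grid with shared segmentations.

## Treatment planning

Doses are linear in administered activity under LDM, so planning
reduces to activity bounds. From a predictive count image the planner
computes per-compartment dose-per-GBq factors `s_role` (calibrate to
1 GBq, convert, take means). The prescription is

```
A = min( target / s_tumor ,  limit / s_normal_role ,  lung_headroom / (49.67·LSF/m_lung) )
```

with `lung_headroom = min(30 Gy, 50 Gy − prior lung dose)`. Defaults:
glass microspheres target 250 Gy (HCC) / 200 Gy (metastasis) and
constrain whole-liver normal tissue; resin microspheres target 100 Gy
and constrain perfused normal tissue at 40 Gy. The glass normal-liver
window of 50–90 Gy is implemented as a single configurable ceiling
(default 90 Gy) plus a warning once the plan exceeds 50 Gy, since
per-case adjudication inside the window is a clinical judgement the
calculator cannot make. When the tumor target is unreachable the
planner prescribes the limit activity and flags `tumor_target_met =
False` instead of failing; an exhausted cumulative lung budget yields
an explicitly infeasible plan. Constraint ties are reported in the
fixed order tumor target, normal tissue, lung. Shunted activity is not
subtracted from the hepatic compartments before dose prediction (the
LSF enters only the lung bound); the hepatic calibration in the
pipeline uses `net × (1 − LSF)` so the liver-frame total is the
activity that actually reaches the liver.

## Synthetic phantoms

Because no patient images ship with the package, every downstream
stage is exercised on digital phantoms with known truth. The phantom
is an ellipsoidal liver (default semiaxes 90 × 60 × 75 mm, ≈1.7 L,
matching a typical cohort median) holding spherical tumors (default
one 30 mm-radius sphere, ≈113 mL), split into perfused and
non-perfused parts by a single sagittal plane at the liver-volume
quantile given by `perfused_fraction` (default 0.625, ≈1.06 L
perfused), with a lung slab superior to the liver. Activity is
piecewise uniform: one concentration in perfused normal tissue,
`true_TN` times that in perfused tumor (default 3.75, a typical
measured median), zero elsewhere; the hepatic total is
`net × (1 − LSF_true)` with defaults net 2.35 GBq and LSF 0.05. An
optional log-normal voxel texture (unit mean, `heterogeneity_sigma`,
off by default) makes tumor dose heterogeneity non-trivial for
DVH-compression studies. The truth grid is 2.5 mm isotropic.

Acquisitions are emulated in three steps: count-conserving resampling
onto the modality grid (SPECT 4.42 × 4.42 × 2.50 mm, PET 2.34 × 2.34 ×
2.78 mm), isotropic Gaussian blur with kernel renormalized to conserve
the total (defaults: SPECT-like FWHM 12 mm, PET-like 5 mm — stated
configuration of this generator, chosen as representative system
resolutions, not measured values), scaling by a count budget
(default 10⁶ counts per GBq, configurable since real count statistics
depend on acquisition time), and optional Poisson sampling. Planar
views are straight projections along the anterior–posterior axis; the
posterior view is the anterior mirrored, without attenuation.
Attenuation is the physical motivation for the geometric-mean
estimator, but simulating it is out of scope: with identical
projections the geometric mean is exact, which is what testing the
estimator's algebra requires. ROI masks are left–right symmetrized so
one mask is valid on both views.

What the phantoms deliberately do **not** emulate: attenuation and
scatter, reconstruction artifacts (OSEM noise correlations, PET hot
spots at low counts), respiratory motion, anatomical realism, and
catheter-position variability. Passing tests therefore demonstrate the
correctness of the dosimetry/planning/statistics machinery and the
direction of resolution-driven biases — not clinical accuracy on real
images.

### What the simulations show

On the clean path (no blur, no noise, matched grids) every truth
metric — compartment means, T/N, tumor D10/D50/D90, LSF — is recovered
to 1e-6 relative; this is the end-to-end conservation test of the
whole chain. With blur on, the measured T/N falls between 1 and the
true ratio, and on a textured tumor the measured D10 falls below truth
while D90 rises above it: partial-volume smoothing compresses the
apparent dose distribution. This is the mechanism by which a
lower-resolution modality (SPECT) reports higher D90 and lower D10
than a higher-resolution one (PET) on the same case.

## Agreement statistics

The comparison layer treats each dose metric as paired measurements by
two fixed methods across a cohort.

* **Wilcoxon signed-rank**: zero differences dropped, ties mid-ranked;
  exact null distribution by dynamic programming over (mid-)ranks for
  up to 25 non-zero pairs, normal approximation with tie and
  continuity corrections beyond. The exact path handles tied ranks,
  which textbook tables do not.
* **ICC**, two-way model with two raters, single measures, from the
  ANOVA mean squares: consistency `(MS_R − MS_E)/(MS_R + MS_E)` and
  absolute agreement `(MS_R − MS_E)/(MS_R + MS_E + 2(MS_C − MS_E)/n)`;
  p-value from the F test `MS_R/MS_E`. Default definition is absolute
  agreement, single measures — the common SPSS "two-way mixed, absolute
  agreement" reading — with consistency available by flag, since
  published reports often leave the choice unstated. Bands: poor < 0.5
  ≤ moderate < 0.75 ≤ good < 0.9 ≤ excellent.
* **Bland–Altman** on differences `y − x`: parametric (mean ± 1.96 sd,
  t-based CIs, the classical construction) and distribution-free
  (median with order-statistic CI; limits as empirical 2.5th/97.5th
  percentiles with linear interpolation and order-statistic CIs, NaN
  when the sample is too small to support them). The nonparametric
  variant is the default because skewed dose differences with
  asymmetric CIs are the norm in this application.
* **OLS** of y on x with `R² = 1 − SSE/SST`; a constant response is
  reported as R² = 0, a constant predictor is an error.

No multiplicity correction is applied by default (single-comparison
reading at α = 0.05); Holm adjustment over the Wilcoxon p-values is
available by flag for reuse.

## Numerical choices and edge cases

* Calibration with zero in-FOV counts, empty masks, zero
  perfused-normal dose (T/N), zero liver planar counts (LSF), constant
  predictors (OLS), and zero between-subject variance (ICC) are all
  explicit errors, not NaNs.
* Conservation contracts (calibration total, resampling total, energy
  bookkeeping `Σ D·m = 49.67 × ΣA`) hold to 1e-9 relative.
* DVH export uses 1000 bins by default; D metrics always come from the
  unbinned order statistics.
* All random number use flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical
  volumes, and the pipeline derives per-stage seeds by fixed offsets
  from the run seed.

## Problem sizes

The default truth grid is ≈4.5 × 10⁵ voxels, which makes a full
simulate → shunt → dose → plan run take about two seconds on one CPU;
structural tests use a coarser 5 mm phantom. Statistical validity
checks use 2000 replicates of 30 pairs (Wilcoxon type-I error) and
10⁴ differences (Bland–Altman coverage), sizes at which Monte-Carlo
bands are tight enough to detect real defects without being flaky.
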