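# Methods

## Signal model and index definition

DSC perfusion imaging tracks a gadolinium bolus through the brain with a
T2\*-weighted gradient-echo EPI series S(v, t). Susceptibility effects
make the signal drop during bolus passage; the drop is deep and sharp in
voxels dominated by large vessels and shallow in parenchyma. The per-voxel
temporal coefficient of variation CV = σ/μ therefore separates the pial
vessel compartment from tissue much more cleanly than σ alone, and is
invariant to global signal scaling (coil gain, scanner calibration).

The collateral vessel index is the ratio of high-CV vessel volume between
the affected and unaffected hemispheres, computed inside a leptomeningeal
compartment defined by a vessel-density atlas with the venous sinuses
removed. The full extraction chain is:

1. motion-correct the series (6-DOF, temporal mean volume as reference);
2. σ, μ per voxel over time (population normalization, 1/N), CV = σ/μ
   inside the brain mask;
3. highCV = CV ≥ rmin + 0.5·(rmax − rmin), where (rmin, rmax) is the
   2nd–98th percentile range of strictly positive in-brain CV values
   ("keep the upper 50% of the robust range");
4. remove ventricular CSF (ventricle mask);
5. find the bolus peak t\* = argmin of the in-brain mean time course, and
   remove the 5% of highCV voxels with the lowest signal at t\* (outer
   CSF and partial-volume cortex mimic vessels at very low intensity);
6. intersect with the leptomeningeal compartment (atlas support minus
   sinuses), split at the median plane, and form
   CVI = affected / unaffected highCV volume in mm³.

Lesion metrics follow the standard threshold conventions: ischaemic core
0 < ADC < 600×10⁻⁶ mm²/s; TTP = tr·argmin_t S(v, t) at frame resolution;
TTP-delay = max(0, TTP − median TTP of the unaffected-hemisphere brain,
ventricles excluded); tissue at risk delay ≥ 4.5 s; severe hypoperfusion
delay ≥ 9.5 s; HIR = severe/at-risk volume; mismatch ratios divide by the
acute diffusion-lesion volume (the ADC core stands in when no separately
traced DWI lesion is provided).

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `robust_lower_pct` / `robust_upper_pct` | 2 / 98 | percentiles of the robust CV range |
| `highcv_range_fraction` | 0.5 | keep the upper half of the robust range |
| `strip_fraction` | 0.05 | low-intensity fraction removed at the bolus peak |
| `strip_scope` | `highcv` | quantile computed over highCV voxels |
| `adc_core_threshold` | 600×10⁻⁶ mm²/s | upper ADC bound of the core |
| `delay_at_risk_s` / `delay_severe_s` | 4.5 / 9.5 s | TTP-delay compartments |
| `min_component_mm3` | 300 mm³ | lesion-cleaning component floor |
| `cvi_cutoff` | 0.963 | good/moderate vs poor dichotomization |

## Design choices where the procedure was open

* **Median plane.** Defined as the image-grid midplane along the declared
  left-right axis (all volumes are reoriented to RAS on load, so low
  indices are the left hemisphere). For an odd axis length the exact
  midplane slice belongs to neither hemisphere. No world-space midsagittal
  estimation is attempted; axial, roughly AC-PC-aligned acquisitions are
  assumed.
* **Robust range.** The 2nd–98th percentile of strictly positive in-mask
  values with linear interpolation, the convention of common FMRI display
  tools. Zero-valued voxels never influence it.
* **σ normalization.** Population (1/N). At ~67 time points the
  difference from 1/(N−1) is immaterial, but the choice must be fixed for
  exact oracle tests.
* **Division guard.** CV is set to 0 where μ ≤ 1e-6 × median positive μ,
  so background can neither produce infinities nor enter the robust range.
* **Low-intensity strip.** The intensity quantile at t\* is computed over
  the highCV voxels themselves (config-switchable to the whole brain);
  voxels *strictly below* the quantile are removed, so a constant
  intensity distribution is left untouched, and the fraction→0 limit is
  the identity.
* **Tie-breaking.** All thresholds are inclusive (≥); argmin ties resolve
  to the earliest frame. This makes every stage deterministic.
* **Lesion cleaning.** Thresholded ADC/TTP masks are restricted to the
  brain, 26-connected components smaller than 300 mm³ are removed, and
  fully enclosed holes are filled. Component floor and connectivity are
  config keys. Cleaning is monotone, so severe ⊆ at-risk ⊆ perfusion
  lesion survives it.
* **Perfusion-lesion domain.** Restricted to the affected hemisphere
  (config-switchable) and to brain tissue excluding the ventricles: CSF
  has no bolus passage, so its TTP is noise and would otherwise
  contaminate the delay compartments.
* **ADC units.** Auto-detected from the in-brain median (values in
  [100, 3000] ⇒ 10⁻⁶ mm²/s; in [1e-4, 3e-3] ⇒ mm²/s); anything ambiguous
  requires an explicit declaration.
* **Registration backend.** SimpleITK's Euler3D registration fulfils the
  rigid-registration contract. Similarity defaults to Pearson correlation
  (invariant to linear intensity relationships, appropriate both within a
  DSC series and between T2-weighted contrasts), switchable to Mattes
  mutual information. Metric sampling is dense, so registration is
  deterministic. Motion correction registers at full resolution with mild
  smoothing (σ = 1 voxel); volumes in a DSC series are already within a
  voxel or two of alignment, and a coarse pyramid level can lock onto a
  false optimum on the bolus-peak volume, whose contrast differs most
  from the temporal mean. Inter-modality coregistration keeps a
  multi-resolution schedule for capture range.
* **Sub-precision motion.** A volume whose estimated transform displaces
  no field-of-view point by more than a quarter of the smallest voxel
  edge — the registration accuracy this module guarantees — is copied
  unresampled with an identity transform. Estimates below that scale are
  dominated by optimizer noise and by contamination of the mean-volume
  reference, and resampling on them only blurs the series and biases CV
  at tissue/background edges.
* **Resampling.** Trilinear for scalar data (out-of-field = NaN, or 0
  inside a corrected series), nearest-neighbour for masks (out-of-field =
  0), implemented with scipy's affine resampler.

## The synthetic phantom

`cvipwi.phantom` builds a 64×64×19-voxel (1.8×1.8×5.2 mm) ellipsoidal
brain — anteroposteriorly elongated so that in-plane rotation is
observable to the registration — with 67 volumes at TR = 1.5 s, emulating
a clinical gradient-echo EPI bolus acquisition at half matrix. It
contains CSF ventricles, a one-voxel pial vessel ring per slice along the
lateral/cranial convexity, a midline venous-sinus strip, a cortical
ribbon, and an optional 1000-voxel ischaemic-core block (ADC 450×10⁻⁶
against 800×10⁻⁶ mm²/s parenchyma, CSF 3000×10⁻⁶).

Signal curves are peak-normalized gamma variates (arrival 24 s, shape
α = 3, β = 1.5 s ⇒ peak at 28.5 s, volume 19): the bolus drops vessel
signal by 50% of its 150 a.u. baseline, parenchyma by 15% of 240 a.u.,
CSF not at all. Gaussian noise with σ = 5 a.u. (baseline SNR ≈ 48,
typical of 3 T EPI) is the default study condition; the generator seed
fixes the noise exactly and truth masks never depend on it.

Collateral asymmetry is produced by deterministically thinning the pial
ring on one side so that affected = ratio × unaffected vessel volume
(±1 voxel); hypoperfusion by delaying the affected-side bolus arrival;
motion by per-volume rigid shifts of the sampled volumes. The bundled
suite covers symmetric (noise-free and noisy), asymmetry 0.25/0.5/1.5,
6 s and 10.5 s delays, a 2-voxel single-volume shift, and doubled noise.

What the phantom does **not** emulate: recirculation and leakage, EPI
distortion, partial-volume mixtures at compartment boundaries, vascular
tree geometry, spatially correlated noise, and patient-specific anatomy.
Passing the phantom suite therefore demonstrates that the implementation
computes the intended quantities correctly and robustly under known
asymmetry, delay, noise and motion — not that the index is clinically
valid on patient data.

## Problem sizes and verification

Unit tests run on 32×32×10×20 phantoms and small constructed arrays;
end-to-end checks use the full 64×64×19×67 default phantom (the generator
also accepts a 128×128 matrix). The oracle-equivalence test compares the
vectorized pipeline against a per-voxel, loop-based reference with manual
percentile interpolation on a random 16×16×4×20 series and requires
agreement to 1e-10 together with bit-identical masks. Recovery checks:
CVI within ±0.15 of asymmetry ratios 0.25–1.5 over 10 noise seeds
(observed spread is ±0.02), noise-free symmetric CVI exactly 1, TTP-delay
recovery within half a TR, 2-voxel motion recovered within a quarter
voxel. `scripts/acceptance.py` re-runs all of these from scratch.

## Known limitations

* Arterial and venous high-CV voxels are not distinguished; the sinus
  mask removes only the large named veins.
* TTP is frame-resolution; sub-sample bolus timing is not interpolated.
* The median plane is the grid midplane, so heavily rotated acquisitions
  must be reoriented upstream.
* Nonlinear registration, slice-timing and susceptibility-distortion
  correction are out of scope; inputs are assumed to be standard axial
  clinical acquisitions.
* Cohort-level statistics (correlations, ROC, regression) are left to
  downstream analysis of the CSV output.
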