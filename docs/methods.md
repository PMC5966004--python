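# Methods

## Model and assumptions

The pipeline treats every voxel of a co-registered sequential activity-map
series as an independent time–activity curve (TAC) and carries four
assumptions throughout:

1. **First-order kinetics.** Lesion clearance of each radiopharmaceutical
   combines radioactive decay and biological washout, both first order, so
   decay constants add: λ_eff = λ_phys + λ_bio. Extrapolation from the
   delivered agent D to an alternative E multiplies the measured activity
   by (A0_E/A0_D)·(U_E/U_D)·exp[(λ_D − λ_E)t]. The uptake ratio U_E/U_D is
   applied to activities; because every later stage is linear, applying it
   to cumulated activities instead would give identical doses.
2. **Uniform uptake within a lesion.** Clinical SPECT resolution cannot
   resolve intralesional heterogeneity; lesion dosimetry at this scale
   conventionally assumes uniform uptake, and the synthetic generator
   follows suit.
3. **Local energy deposition described by a voxel S-value kernel** in a
   uniform soft-tissue medium, with activity outside the imaged volume set
   to zero. Long-range photon dose beyond the kernel extent is neglected
   (orders of magnitude below the beta contribution for these nuclides).
4. **Co-registration.** Scans are assumed aligned; no re-registration,
   partial-volume correction or resolution matching between nuclides is
   attempted.

## Units

Half-lives are entered in days and scan times in hours, the units they are
quoted in; all internal rates are per second so cumulated activity is in
MBq·s, matching the kernel unit Gy/(MBq·s). The bundled published
self/neighbour S-value pairs are stored as printed, in Gy/(MBq·h): an
energy-balance check (self S-value × 4.67 mm voxel mass versus each
nuclide's mean beta energy per decay) confirms the per-hour reading — e.g.
¹⁷⁷Lu's 0.7782 Gy MBq⁻¹h⁻¹ corresponds to 0.137 MeV absorbed per decay
against a 0.133 MeV mean beta energy, whereas a per-second reading would
imply several hundred MeV per decay. `build_reference_kernels` converts by
1/3600 when constructing kernels.

## Kernels

Monte Carlo dose-voxel kernels are *inputs* (JSON container: radionuclide,
voxel size, odd axis extents, raveled C-order values). Where none are
supplied, the package fabricates analytic stand-ins: isotropic exponential
falloff exp(−k·r) with k = ln(self/neighbour)/pitch, calibrated so the
centre and face-neighbour voxels reproduce the published pair exactly.
These stand-ins preserve the dominant feature of real beta kernels — an
89–99% drop from the source voxel to its first neighbour — but not the
nuclide-specific tail shape or any photon component, so *absolute*
synthetic doses and kernel-sum ratios between nuclides are indicative
only; all structural and relative properties are unaffected. "First
nearest neighbour" means the face-adjacent voxel throughout. Kernel
validation checks odd extents, non-negativity, a centre maximum and
reflection symmetry within a 1% relative tolerance — permissive for Monte
Carlo noise (published statistical uncertainties are ≤0.1%) while catching
format errors.

## Time integration

Between scans: trapezoid where activity does not decrease (uptake follows
no assumed law), exact monoexponential where it decreases. Ties and decays
to exactly zero use the trapezoid — both are continuous limits of their
neighbouring cases and avoid an undefined exponential fit.

The scans bracket neither t = 0 nor infinity, so two conventions close the
integral, both configurable and recorded in every run manifest:

- **Head** (0 → first scan): default `zero_start`, a trapezoid from an
  implicit (0, 0) point — appropriate for bone-seekers still accumulating
  at the first scan, and exact when uptake rises linearly to a peak at the
  first scan time (the synthetic generator's default). The `flat`
  alternative (A_first × t_first) suits activity already at or past its
  plateau, and is the appropriate setting when integrating a pure
  monoexponential sampled from t = 0 — with it, the five-point clinical
  schedule recovers A0/λ to better than 0.1% across effective half-lives
  of 0.66–29 d, versus a worst case of ≈2.2% under `zero_start`.
- **Tail** (last scan → ∞): analytic A_last/λ_tail. Default `fit` takes
  λ_tail per voxel from the final decreasing phase, falling back to the
  effective (then physical) decay constant where the final phase does not
  decrease; `effective`/`physical` force the fixed constant. One caveat
  follows from the fit rule: cumulated activity is then not globally
  monotone in the input activities, because raising the penultimate sample
  can create a fitted (faster) tail rate that shrinks the tail more than
  the added phase area — monotonicity holds under the fixed rules.

Voxels whose activity never reaches `min_activity_MBq` (default 0) are
skipped.

## Dose and lesion statistics

Convolution supports a direct spatial path and an FFT path padded to the
linear-convolution size (no wrap-around); they agree to ~1e-12 relative
and the FFT path clips its sub-epsilon negative round-off. Lesion peak
dose averages the maximum-dose voxel with its 6 face neighbours —
neighbours outside the lesion are included (the definition does not
restrict to the lesion), neighbours outside the volume are dropped; a
26-neighbour variant is selectable. Cohort profiles are maximum-likelihood
log-normal fits on log peak doses (mean doses also exported). The cDVH
pools *voxel-level* doses from all lesion voxels across patients, weighted
by voxel volume; D50 is the largest dose covering ≥50% of that pooled
volume (a step-convention quantile — curves are gridded only for display).
Percent differences between treatments are computed from unrounded medians
and rounded to integers for reporting.

## Registry defaults

The seven radiopharmaceuticals ship with their tabulated physical and
lesion effective half-lives, skeletal uptake (stored as fractions of
injected activity) and typical administered activities (absolute MBq, or
MBq/kg for ¹⁵³Sm- and ¹⁷⁷Lu-EDTMP; per-kg plans take the patient mass at
run time, default 70 kg). For each entry exactly one of the
effective/biological half-life pair is supplied and the other derived, so
the pair is always consistent. Tabulated effective half-lives are kept
verbatim even where they imply slightly different biological half-lives
for agents described as sharing one (¹⁵³Sm ≈9.2 d vs ¹⁷⁷Lu ≈9.4 d —
rounding in the source values; no harmonisation is attempted). The
delivered ¹⁸⁶Re-HEDP plan needs three constants not in that table: its
physical half-life (3.7183 d, standard nuclear data), lesion effective
half-life (default 2.7 d) and skeletal uptake (default 0.30). The latter
two are package defaults, always overridable through a registry file, and
every run manifest records the values used.

## Synthetic cohorts

The generator emulates the *structure* of a therapy-trial dataset: 22
patients by default, ellipsoidal non-overlapping lesions (truncated
Poisson count, mean 17.2/patient), 4.67 mm isotropic voxels on a 64³ grid
(desk-scale stand-in for 128²-slice clinical volumes; the clinical pitch
is kept so bundled kernels apply unchanged), scans at 1/4/24/48/72 h, and
a delivered plan of 5020 MBq. Voxel TACs rise linearly to a peak at 1 h
(the first scan — so the default head rule integrates the rise exactly)
then wash out monoexponentially at the delivered plan's 2.7 d effective
half-life; `time_to_peak_h = 0` gives pure monoexponentials for oracle
tests. Per-lesion amplitudes are log-normal (σ_log 0.7, matching the
spread of reported cohort dose profiles) and normalised so whole-volume
activity at the end of uptake equals uptake × administered activity. Of
that, 92% sits in a uniform background compartment modelling the normal
skeleton in the field of view — bone-seekers deposit most skeletal uptake
outside the lesions, and this split puts delivered-plan median lesion peak
doses in the clinically reported tens-of-Gy range. Optional multiplicative
Gaussian noise (default off) is the only corruption; no SPECT physics
(collimator blur, attenuation, Poisson projection noise) or anatomical
realism is modelled. Generation is deterministic per seed (independent
per-patient child seeds), and each dataset retains its generating
parameters so an analytic dose oracle (exact TAC integral convolved with
the kernel) can be evaluated against the pipeline.

Passing tests on these cohorts therefore demonstrate the numerical
fidelity of the chain (extrapolation, integration, convolution, metrics)
under the model's own assumptions — not robustness to scatter, partial
volume, misregistration or heterogeneous intralesional uptake, which real
data exhibit and this generator deliberately does not.

## Problem sizes

The test suite runs cohorts of 1–6 patients on 24³–48³ grids with 7³–11³
kernels (seconds in total); the analysis scripts and acceptance script use
6 patients at 48³ with 11³ kernels, chosen as the smallest sizes at which
lesions are large relative to the kernel core and cohort statistics are
stable.

## Known limitations

- Stand-in kernels make absolute doses and inter-nuclide dose ratios
  indicative; supply Monte Carlo kernel files for production use.
- Single-exponential washout only; no multi-exponential or regularised TAC
  fitting.
- No decay-chain daughters (no ²²³Ra), no organ-level or red-marrow
  dosimetry, no PSMA-type agents (different uptake mechanism than the
  bone-seekers modelled here).
- Masks are inputs; no lesion segmentation is provided.
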