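# Methods

## The study design

The package re-enacts a two-arm acquisition comparison: segmented
(multishot, MS) EPI with per-excitation TR 500 ms × 4 shots, 900 volumes,
versus single-shot (SS) EPI with TR 1000 ms, 1800 volumes; both TE 17 ms,
96×96×16 matrix over a 35×35×16 mm field of view, parallel factor 2,
flip angle 60°, 30 minutes of scanning.  The default ("desk") configuration
preserves every structural parameter but shrinks the matrix to 48×48×12 and
the series to 120 MS / 240 SS volumes with 8 subjects per arm, so the whole
experiment runs in about a minute on one CPU.  A full-size configuration
(`full_config()`) restores the printed protocol.

## The digital subject

`make_phantom` builds an ellipsoidal brain: a cortical sheet on the
strictly dorsal shell (anterior–posterior strips, left/right copies) and
compact subcortical parcels (farthest-point seeding plus Lloyd iterations
on the left hemisphere, mirrored to the right).  The ventro-lateral shell
band — where amygdala/insula-type structures sit — is deliberately classed
subcortical, because that is where the susceptibility sources live.  Four
air cavities (aural pair, ventro-lateral posterior; nasal pair,
ventro-medial anterior) are carved out; baseline signal is ~100 a.u. with a
gentle seeded linear trend.

## Field and signal model

The off-resonance map is a sum of narrow (2 mm SD) Gaussian bumps of
alternating sign at the cavity centroids (peak 200 Hz) plus a ventral
"shim-failure" term: the field dips toward the skull base with a PE-axis
gradient growing as depth⁴, zero at the dorsal surface — the signature of a
shim optimized over dorsal cortex.  Three consequences follow, each scaled
by sequence timing:

* **displacement** along PE of Δf/bw_pe voxels (bw_pe = 1/(ETL×esp)):
  ~0.9 voxels maximal for MS, ~3.8 for SS at desk scale;
* **TE-driven dropout** exp(−TE·κ|∇Δf|) with κ = 1.5 — identical in both
  arms (same TE), the mesoscopic stand-in for intravoxel dephasing;
* **echo-train dephasing** exp(−κ_ro·T_etl·|∂Δf/∂pe|), κ_ro = 15,
  T_etl = ETL×esp — phase errors accumulate over the echo train and are
  reset on each excitation, so the attenuation near susceptibility
  gradients is four times milder per shot in the 4-shot arm.  This is the
  physical mechanism by which segmentation rescues deep-brain signal.

Voxel signal is baseline × Ernst steady state (sin α (1−E1)/(1−E1 cos α),
E1 = exp(−TR_shot/T1), T1 = 1400 ms) × dropout × echo-train dephasing ×
exp(−TE/T2\*) modulated by the planted networks, then warped along PE
(pull-based linear interpolation; exact pass-through when the shift is
zero), scaled by (1+η_t) inter-shot instability (MS only, SD 0.002),
translated and brightened at motion-spike volumes (3% of MS volumes, 1% of
SS), with white thermal noise (SD 0.3 a.u.) added last.  The Ernst factors
(0.40 MS vs 0.59 SS) reproduce the real saturation penalty of short-TR
segmented imaging.

## Planted functional architecture

Networks are parcel sets: three cortical networks on the dorsal strips and
four "deep" networks on the subcortical parcels ordered by distance to the
cavities, each spanning two or three bilateral pairs.  Fluctuations are
band-limited (0.01–0.1 Hz) unit-variance series, sample-orthogonalized so
that every pairwise network correlation equals the requested 0.1 *exactly*,
through one independent shared channel per network pair (a single global
common mode would leave arm-level sampling wobble that does not average
over edges).  Deep networks fluctuate at 3% of baseline, cortical at 2% —
deep gray-matter nuclei are given a stronger planted signal so that the
clean arm detects them comfortably at desk scale.

Parcel-coherent "vasomotor" noise (band-limited, uniform over each parcel,
fixed amplitude in image units) provides the structured noise floor that
parcel averaging cannot remove: SD 0.22 a.u. (MS) / 0.352 a.u. (SS),
calibrated so the two arms have equal *measured* cortical contrast-to-noise
after the full preprocessing chain (the naive Ernst-ratio calibration is
~10% off because filtering, censoring and resampling act slightly
differently on the two series).  Half of this noise is a subject trait,
half is session specific.

**Yoked subjects.**  Subject identity — network time-course realizations
(generated at the finest volume rate and integrated per arm), the trait
half of the vasomotor noise, and the per-subject field-map amplitude
(±10%) — is shared between arms: the same digital animal is scanned by
both sequences.  This common-random-numbers pairing matches the paired
edge-wise statistics and isolates the sequence contrast from
between-subject sampling noise.  Per-subject network-amplitude jitter is
deliberately *not* modeled: proportional amplitude variability scales the
edge mean and its between-subject SD alike, making the one-sample-t
robustness statistic scale-invariant and blind to any real CNR difference.

## Pipeline

Per subject: DVARS censoring (outlier iff DVARS > Q75 + 1.5 IQR; censored
volumes get one-hot regressors and are excluded from correlation
statistics — keeping them as regressed-to-zero frames induces a spurious
+0.04 correlation on shared zero frames), 12-confound OLS regression
(synthetic motion is an Ornstein–Uhlenbeck process with a 20 s correlation
time sampled at each arm's volume rate, so its in-band content is
rate-independent), linear detrend, FFT band-pass 0.01–0.1 Hz (hard
high-pass; low-pass 2^(−(f/hi)⁴), half-amplitude exactly at hi).  tSNR
(mean/population-SD) is computed on the raw series over uncensored volumes,
since band-passed data are zero-mean.  SS parcel series are boxcar-averaged
to the MS volume rate before correlation.

Group level: voxelwise two-sample tSNR comparison with TFCE (E = 0.5,
H = 2, dh = max/100, 26-connectivity) and max-statistic permutation FWE
(100 permutations, identity always included); brain-mask Dice versus the
true anatomy (threshold at 50% of the robust maximum); Jacobian
determinants of the known inverse-distortion field (registration is never
estimated — out of scope — so group analyses run in acquisition space and
residual distortion plays the role that imperfect normalization plays with
real data); pooled group ICA (subject-wise temporal PCA reduction, then
fixed-point negentropy ICA with tanh contrast) with dual regression and
per-component permutation tests; and the connectome consistency analysis:
per edge, the z-equivalent (clamped at |z| = 8) of the one-sample t across
subjects on Fisher-z correlations, stratified into cortico-cortical edges
and edges with at least one subcortical endpoint, compared across arms by
paired Wilcoxon, with a noncentral-t power analysis (z₀ = 2.3, α = 0.05,
1−β = 0.8; both plain and offset effect-size modes are reported because
the field does not fix the definition).

## Numerical choices

TFCE integrates thresholds dh, 2dh, … ≤ max with connected components from
`scipy.ndimage.label`; negative values are enhanced on the negated map.
Permutation p-values include the identity permutation
(p = (1+k)/(n_perm+1)) and switch to exhaustive enumeration when the
permutation group is small.  Fisher z clips |r| at 1−1e−7.  ICA
non-convergence (inevitable when the requested order exceeds the number of
identifiable non-Gaussian sources) raises after three retries by default;
the pipeline accepts the final attempt with a logged warning, the standard
practice for denoising decompositions.  All randomness derives from a
single master seed through `numpy.random.SeedSequence` counters; a
re-run with the same configuration produces a byte-identical report.

## What the synthetic study shows — and what it does not

At the default configuration the desk-scale study reproduces the
directional pattern of the real comparison: multishot tSNR advantage
confined to subcortical parcels (with a general cortical tSNR advantage
for single-shot), higher brain-mask Dice, a ~5× lighter Jacobian tail, a
right-shifted subcortical edge z-stat distribution (paired p ≪ 0.01) with
no cortical difference, and a smaller required group size for subcortical
detection.  The absolute numbers of the real experiment (tSNR in the
40–130 range, Dice ~0.86/0.84, required n of 11/31) derive from scanner
data and are not reproduction targets; the simulation lands in comparable
ranges by calibration, not by physics alone.

Limitations worth keeping in mind: no k-space simulation (image-domain
warping with linear interpolation), Gaussian rather than Rician noise,
no RF-coil or parallel-reconstruction modeling, no physiological cardiac/
respiratory waveforms, no estimated registration, and a rule-based rather
than trained component classifier.  With 8 subjects per arm the
stratified paired comparison sits near the resolution limit of the design:
the subcortical right-shift is robust, but the cortical null condition can
cross p = 0.01 in either direction for some master seeds, a small-sample
property of the shared-realization design rather than a physical effect.
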