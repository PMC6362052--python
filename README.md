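# episeg

Segmented (multishot) versus single-shot echo-planar imaging for
resting-state fMRI of the rat brain, re-enacted end to end on synthetic
data.

Gradient-echo EPI at high field suffers from B0 off-resonance near
air–tissue interfaces (aural and nasal cavities, the poorly shimmed skull
base).  Off-resonance Δf displaces signal along the phase-encode (PE) axis
by Δf / bw_pe voxels, where the per-pixel PE bandwidth is set by the echo
train: bw_pe = 1 / (ETL × echo spacing), ETL = n_pe / (NSHOTS × PPI).
Splitting k-space over NSHOTS excitations shortens the echo train, so a
4-shot acquisition suffers one quarter of the geometric distortion and a
quarter of the echo-train phase-error accumulation — at the price of a 4×
slower volume rate, lower steady-state signal (shorter TR → stronger
saturation) and sensitivity to inter-shot instability.  The scientific
question: where, if anywhere, does segmentation pay off for functional
connectivity mapping?

`episeg` answers it at desk scale with a fully synthetic but physically
structured study:

* **synth** — digital rat-brain phantom (cortical shell, compact
  subcortical parcels, aural/nasal air cavities), B0 field maps, Ernst
  steady-state signal, TE-driven dropout, echo-train dephasing, planted
  resting-state networks (band-limited 0.01–0.1 Hz, exact pairwise
  correlation structure), parcel-coherent physiological noise, motion
  spikes and thermal noise;
* **preprocess** — 12-confound regression, FFT band-pass (hard high-pass,
  half-amplitude low-pass at the band edge), DVARS censoring;
* **qc** — ROI SNR and voxelwise temporal SNR (mean/SD) with permutation
  TFCE/FWE group comparison;
* **spatial** — Dice overlap, Jacobian determinants of warp fields,
  field-map dewarping;
* **stats** — TFCE, max-statistic permutation FWE (exhaustive when
  feasible), Fisher z, noncentral-t power analysis;
* **networks** — subject/group spatial ICA (fixed-point negentropy,
  tanh contrast), rule-based component classification, non-aggressive
  denoising, dual regression;
* **connectome** — parcellated time series, Fisher-z adjacency matrices,
  edge-wise one-sample-t "robustness" z-stats, stratified paired arm
  comparison and sample-size analysis.

Both arms image the *same* digital animals (yoked network fluctuations and
field maps), so the paired comparison isolates the sequence difference.

## Worked example

```python
from episeg.config import default_config
from episeg.pipeline import run_experiment

cfg = default_config()          # 48x48x12, 120 multishot volumes, 8/arm
report = run_experiment(cfg, "out")

c = report["comparisons"]
print(c["tsnr"]["ms_gt_ss_subcortical_voxels"],
      c["tsnr"]["ms_gt_ss_cortical_voxels"])      # 2645 0
print(report["arms"]["ms"]["dice_mean"],
      report["arms"]["ss"]["dice_mean"])          # 0.938 0.835
print(c["consistency"]["subcortical"]["p"],
      c["consistency"]["cortical"]["p"])          # 1.6e-09 0.51
```

Reading: voxels where multishot EPI has significantly higher temporal SNR
(TFCE, FWE-corrected 1−p > 0.95) lie exclusively in subcortical parcels
(2645 voxels, none cortical); the multishot brain mask matches the true
anatomy better (Dice 0.938 vs 0.835); and the distribution of edge-wise
connectivity z-statistics is right-shifted for multishot in the subcortical
stratum (paired Wilcoxon p ≈ 2e-9) while cortico-cortical edges do not
differ (p ≈ 0.5).  The same run reports the group size needed to detect
subcortical correlations at the z = 2.3 threshold: 8 subjects for the
multishot arm versus 12 for single-shot.

The same experiment runs from the shell:

```
episeg run --out out --seed 0
```

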