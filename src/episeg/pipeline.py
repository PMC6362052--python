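"""End-to-end orchestration of the two-arm (multishot vs single-shot EPI)
synthetic experiment.

For every subject of each arm: simulate the acquisition, build confounds,
censor motion spikes via DVARS, regress confounds (including one-hot spike
regressors), band-pass filter, and derive tSNR, brain-mask Dice, the
ground-truth Jacobian map and the parcellated Fisher-z adjacency matrix.
Group stages then compare the arms: voxelwise tSNR permutation test with
TFCE/FWE, Dice t-test, Jacobian tail masses, pooled group ICA + dual
regression with per-component permutation tests, edge-wise consistency
z-stats with paired Wilcoxon arm comparison, and the sample-size analysis.

Everything is reproducible from (config, master seed); per-subject seeds are
derived from the master seed by a fixed counter scheme
(SeedSequence([master, arm_index, subject_index])).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from . import connectome as conn
from . import io as _io
from . import networks as net
from . import preprocess as pre
from . import qc, spatial
from .config import ExperimentConfig, build_network_spec
from .synth import (NetworkSpec, _fft_band_limit, acquire_series,
                    acquisition_time_min, derive_seed, make_confounds,
                    make_fieldmap, make_phantom, pe_displacement,
                    simulate_network_timecourses)

logger = logging.getLogger(__name__)

__all__ = ["run_experiment", "run_subject"]

ARMS = ("ms", "ss")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_subject(phantom, netspec, arm_cfg, cfg: ExperimentConfig,
                arm_index: int, subject_index: int) -> dict:
    """Simulate and preprocess one subject; return per-subject artifacts."""
    seq = arm_cfg.seq
    seed = derive_seed(cfg.seed, arm_index, subject_index)
    rng = np.random.default_rng(derive_seed(seed, 7))

    # subject identity (anatomy-linked field map and network fluctuations) is
    # arm-independent: the same digital animal is scanned by both sequences,
    # so the paired edge-wise comparison contrasts sequences, not subjects
    subj_seed = derive_seed(cfg.seed, 500, subject_index)
    subj_rng = np.random.default_rng(derive_seed(subj_seed, 1))
    peak = cfg.peak_hz * (1.0 + cfg.fieldmap_jitter * subj_rng.uniform(-1, 1))
    fmap = make_fieldmap(phantom, peak, cfg.width_mm,
                         seed=derive_seed(subj_seed, 2),
                         ventral_gradient_hz=cfg.ventral_gradient_hz
                         * (1.0 + cfg.fieldmap_jitter
                            * subj_rng.uniform(-1, 1)))

    # per-subject network strength: animals differ in how strongly each
    # network fluctuates; the factor is a subject trait (yoked across arms)
    amp_u = np.random.default_rng(derive_seed(subj_seed, 5)).uniform(
        -1.0, 1.0, size=len(netspec.networks))
    netspec = NetworkSpec(
        networks=[(name, mem, amp * max(0.2, 1.0 + cfg.amplitude_jitter * u))
                  for (name, mem, amp), u in zip(netspec.networks, amp_u)],
        band_hz=netspec.band_hz,
        cross_network_correlation=netspec.cross_network_correlation)

    # one biological fluctuation realization per subject, generated at the
    # finest volume rate across arms and integrated to this arm's rate
    dt_fine = min(cfg.ms.seq.tr_vol_s, cfg.ss.seq.tr_vol_s)
    n_fine = int(round(seq.n_rep * seq.tr_vol_s / dt_fine))
    tcs = simulate_network_timecourses(netspec, n_fine, dt_fine,
                                       derive_seed(subj_seed, 3))
    # parcel-coherent physiological noise: a subject-trait component shared
    # by both scanning sessions plus a session-specific component
    n_tissue = int((phantom.parcels.klass != "air").sum())
    rho = cfg.session_noise_fraction
    reg_subj = _fft_band_limit(
        np.random.default_rng(derive_seed(subj_seed, 4)).standard_normal(
            (n_tissue, n_fine)), dt_fine, netspec.band_hz)
    reg_sess = _fft_band_limit(
        np.random.default_rng(derive_seed(seed, 14)).standard_normal(
            (n_tissue, n_fine)), dt_fine, netspec.band_hz)
    reg = np.sqrt(1.0 - rho) * reg_subj + np.sqrt(rho) * reg_sess
    k = int(round(seq.tr_vol_s / dt_fine))
    if k > 1:
        tcs = tcs[:, :(tcs.shape[1] // k) * k]
        tcs = tcs.reshape(tcs.shape[0], -1, k).mean(axis=2)
        reg = reg[:, :(reg.shape[1] // k) * k]
        reg = reg.reshape(reg.shape[0], -1, k).mean(axis=2)

    n_spikes = int(round(arm_cfg.spike_rate * seq.n_rep))
    spikes = tuple(sorted(rng.choice(np.arange(1, seq.n_rep), size=n_spikes,
                                     replace=False))) if n_spikes else ()

    raw = acquire_series(phantom, fmap, seq, netspec,
                         motion_spike_times=spikes, seed=seed, kappa=cfg.kappa,
                         kappa_readout=cfg.kappa_readout, tcs=tcs,
                         regional_tcs=reg)
    conf = make_confounds(seq.n_rep, spikes, seed=derive_seed(seed, 9),
                          dt_s=seq.tr_vol_s)

    tissue = phantom.brain_mask
    d = pre.dvars(raw, tissue)
    cens = pre.censor(d)
    censored_idx = np.where(~cens.keep)[0]
    extra = None
    if censored_idx.size:
        extra = np.zeros((seq.n_rep, censored_idx.size))
        extra[censored_idx, np.arange(censored_idx.size)] = 1.0

    clean = pre.regress_confounds(raw, conf, extra_regressors=extra)
    clean = pre.bandpass(clean, *cfg.band_hz)

    mean_img = raw.data.mean(axis=-1)
    mask_i = spatial.threshold_mask(mean_img, frac=0.5)
    tsnr = qc.tsnr_map(raw, mask=tissue, keep=cens.keep)
    warp = spatial.correction_warp(fmap, seq, phantom.pe_axis)
    jmap = spatial.jacobian_map(warp)
    shift = pe_displacement(fmap, seq, phantom.pe_axis).shift_vox

    brain_table = phantom.parcels[phantom.parcels.klass != "air"]
    ts = conn.parcellate(clean, phantom.labels, brain_table)

    return dict(seed=seed, fmap=fmap, raw=raw, clean=clean, censor=cens,
                tsnr=tsnr, mask=mask_i, jmap=jmap, ts=ts,
                max_shift=float(np.abs(shift).max()),
                spikes=list(int(s) for s in spikes))


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path,
                   save_images: bool = False, make_plots: bool = False) -> dict:
    """Run the full two-arm experiment and write a machine-readable report.

    Returns the report dict (also written to ``out_dir/report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    phantom = make_phantom(cfg.shape, cfg.n_cortical, cfg.n_subcortical,
                           seed=cfg.seed, fov_mm=cfg.fov_mm, pe_axis=cfg.pe_axis)
    netspec = build_network_spec(phantom, cfg)
    tissue = phantom.brain_mask
    cort_mask = np.isin(phantom.labels, phantom.parcel_ids("cortical"))
    sub_mask = np.isin(phantom.labels, phantom.parcel_ids("subcortical"))
    loose_mask = ndimage.binary_dilation(tissue, iterations=2)

    report: dict = {
        "config_hash": cfg.config_hash,
        "seed": int(cfg.seed),
        "protocol": {
            arm: dict(tr_shot_ms=getattr(cfg, arm).seq.tr_shot_ms,
                      n_shots=getattr(cfg, arm).seq.n_shots,
                      n_rep=getattr(cfg, arm).seq.n_rep,
                      acq_time_min=acquisition_time_min(getattr(cfg, arm).seq))
            for arm in ARMS
        },
        "arms": {},
        "comparisons": {},
    }

    subjects: dict[str, list[dict]] = {}
    ms_dt = cfg.ms.seq.tr_vol_s
    for ai, arm in enumerate(ARMS):
        arm_cfg = getattr(cfg, arm)
        subs = []
        for si in range(cfg.n_subjects):
            logger.info("simulating %s subject %d/%d", arm, si + 1,
                        cfg.n_subjects)
            rec = run_subject(phantom, netspec, arm_cfg, cfg, ai, si)
            keep = rec["censor"].keep
            if arm == "ss":
                rec["ts"] = conn.resample_to_rate(rec["ts"], ms_dt)
                k = int(round(ms_dt / arm_cfg.seq.tr_vol_s))
                n = (keep.shape[0] // k) * k
                keep = keep[:n].reshape(-1, k).all(axis=1)
            # censored volumes are excluded from the correlation statistics
            ts_kept = conn.ParcelTimeseries(rec["ts"].data[:, keep],
                                            rec["ts"].roi_table,
                                            rec["ts"].dt_s,
                                            list(rec["ts"].flagged))
            rec["adj"] = conn.adjacency(ts_kept)
            subs.append(rec)
        subjects[arm] = subs
        dices = [spatial.dice(s["mask"], tissue) for s in subs]
        jsum = spatial.jacobian_summary([s["jmap"] for s in subs],
                                        brain_mask=tissue)
        report["arms"][arm] = dict(
            censor_fraction_mean=float(np.mean([s["censor"].fraction
                                                for s in subs])),
            dice=[float(x) for x in dices],
            dice_mean=float(np.mean(dices)),
            dice_sd=float(np.std(dices, ddof=1)),
            max_shift_vox_mean=float(np.mean([s["max_shift"] for s in subs])),
            jacobian_tail_above=jsum["tail_above"],
            jacobian_tail_below=jsum["tail_below"],
            tsnr_cortical_mean=float(np.mean(
                [s["tsnr"].data[cort_mask].mean() for s in subs])),
            tsnr_subcortical_mean=float(np.mean(
                [s["tsnr"].data[sub_mask].mean() for s in subs])),
        )

    # ---------------- group statistics ----------------
    if cfg.n_subjects < 3:
        raise RuntimeError("group-statistics stage: need >= 3 subjects per arm")

    # voxelwise tSNR comparison (MS vs SS), TFCE + permutation FWE
    cmp_tsnr = qc.compare_tsnr([s["tsnr"] for s in subjects["ms"]],
                               [s["tsnr"] for s in subjects["ss"]],
                               n_perm=cfg.n_perm, seed=derive_seed(cfg.seed, 11),
                               mask=tissue, E=cfg.tfce_E, H=cfg.tfce_H)
    supra = cmp_tsnr["a_gt_b"].one_minus_p > 0.95
    supra_rev = cmp_tsnr["b_gt_a"].one_minus_p > 0.95
    report["comparisons"]["tsnr"] = dict(
        ms_gt_ss_subcortical_voxels=int((supra & sub_mask).sum()),
        ms_gt_ss_cortical_voxels=int((supra & cort_mask).sum()),
        ss_gt_ms_subcortical_voxels=int((supra_rev & sub_mask).sum()),
        ss_gt_ms_cortical_voxels=int((supra_rev & cort_mask).sum()),
        max_one_minus_p_ms_gt_ss=float(cmp_tsnr["a_gt_b"].one_minus_p.max()),
    )

    t_dice = sps.ttest_ind(report["arms"]["ms"]["dice"],
                           report["arms"]["ss"]["dice"])
    report["comparisons"]["dice"] = dict(t=float(t_dice.statistic),
                                         p=float(t_dice.pvalue))

    # connectome consistency and arm comparison
    res = {arm: conn.group_consistency([s["adj"] for s in subjects[arm]])
           for arm in ARMS}
    report["comparisons"]["consistency"] = conn.compare_arms(res["ms"], res["ss"])
    for arm in ARMS:
        report["arms"][arm]["zstat_summaries"] = res[arm].summaries
        report["arms"][arm]["power"] = {
            stratum: conn.sample_size_analysis(res[arm], z0=cfg.z0,
                                               alpha=cfg.alpha, power=cfg.power,
                                               stratum=stratum)
            for stratum in ("all", "cortical", "subcortical")
        }

    # group ICA + dual regression on pooled denoised data
    if cfg.run_ica:
        report["comparisons"]["components"] = _ica_stage(
            cfg, phantom, subjects, loose_mask, tissue, cort_mask, sub_mask)

    report = _jsonify(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)

    if save_images:
        _save_outputs(out, phantom, subjects)
    if make_plots:
        _make_plots(out, report)
    return report


def _ica_stage(cfg, phantom, subjects, loose_mask, tissue, cort_mask, sub_mask):
    denoised, arms_list = [], []
    for arm in ARMS:
        for s in subjects[arm]:
            cs = net.subject_ica(s["clean"], loose_mask,
                                 n_components=cfg.n_ica_subject,
                                 seed=derive_seed(s["seed"], 21),
                                 on_nonconvergence="warn")
            net.classify_components(cs, tissue, s["clean"].tr_vol_s)
            denoised.append(net.denoise_nonaggressive(s["clean"], cs))
            arms_list.append(arm)

    gica = net.group_ica(denoised, loose_mask, d=cfg.d_ica_group,
                         seed=derive_seed(cfg.seed, 22), arms=arms_list,
                         on_nonconvergence="warn")

    # stage-2 subject maps for every subject, per arm
    stage2 = {arm: [] for arm in ARMS}
    for vol, arm in zip(denoised, arms_list):
        _, maps = net.dual_regression(gica, vol)
        stage2[arm].append(maps)
    stage2 = {arm: np.stack(v) for arm, v in stage2.items()}

    # subcortical components: >= 50% of in-brain |map| mass in subcortical parcels
    sub_frac = []
    for i in range(gica.n_components):
        amap = np.abs(gica.maps[i])
        tot = amap[tissue].sum()
        sub_frac.append(amap[sub_mask].sum() / tot if tot > 0 else 0.0)
    sub_frac = np.array(sub_frac)
    selected = np.argsort(sub_frac)[::-1]
    selected = [int(i) for i in selected if sub_frac[i] >= 0.5]
    n_cmp = min(len(selected), 2)
    compared = selected[:n_cmp]

    out = dict(n_components=int(gica.n_components),
               subcortical_mass=[float(f) for f in sub_frac],
               subcortical_components=selected)
    if compared:
        res = net.compare_component_maps(stage2["ms"], stage2["ss"], compared,
                                         n_perm=cfg.n_perm,
                                         seed=derive_seed(cfg.seed, 23),
                                         mask=tissue, E=cfg.tfce_E, H=cfg.tfce_H)
        comp_report = {}
        for cid, (pos, neg) in res.items():
            sup = pos.one_minus_p > 0.95
            comp_report[cid] = dict(
                ms_gt_ss_subcortical_voxels=int((sup & sub_mask).sum()),
                ms_gt_ss_cortical_voxels=int((sup & cort_mask).sum()),
                max_one_minus_p=float(pos.one_minus_p.max()),
            )
        out["tests"] = comp_report
    return out


def _save_outputs(out: Path, phantom, subjects) -> None:
    _io.save_phantom(phantom, out)
    for arm, subs in subjects.items():
        for i, s in enumerate(subs):
            stem = out / f"{arm}_sub{i:02d}"
            _io.save_map(s["tsnr"].data, phantom.voxel_size,
                         f"{stem}_tsnr.nii.gz")
            pd.DataFrame(s["adj"].z).to_csv(f"{stem}_adjacency.tsv", sep="\t",
                                            index=False)


def _make_plots(out: Path, report: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cons = report["comparisons"]["consistency"]
    bins = np.array(cons["bins"])
    centers = 0.5 * (bins[:-1] + bins[1:])
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharey=True)
    for ax, stratum in zip(axes, ("all", "cortical", "subcortical")):
        ax.plot(centers, cons[stratum]["hist_a"], label="MS-EPI")
        ax.plot(centers, cons[stratum]["hist_b"], label="SS-EPI")
        ax.set_title(f"{stratum} (p={cons[stratum]['p']:.3g})")
        ax.set_xlabel("edge z-stat")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(out / "zstat_distributions.png", dpi=120)
    plt.close(fig)
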