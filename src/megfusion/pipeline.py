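"""Configuration-driven orchestration of the full synthetic study.

simulate -> decode -> RDM -> fuse -> cluster tests -> network statistics,
with per-stage outputs, a provenance manifest, and figure-style plots.
A single global seed fans out to per-stage, per-subject child seeds via
``numpy.random.SeedSequence`` spawn keys, so any stage can be rerun in
isolation and reproduce its outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fusion, io, netstats, rsa, stats
from .decoding import DecodingConfig, decode_timecourse
from .synthgen import (
    SimulationConfig,
    generate_behavior,
    generate_fmri_patterns,
    generate_meg_epochs,
)

logger = logging.getLogger("megfusion.pipeline")

MODEL_NAMES = ("recognition", "two_state")


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimulationConfig = SimulationConfig()
    decoding: DecodingConfig = DecodingConfig()
    rdm_step_ms: float = 2.5
    n_perm: int = 5000
    alpha: float = 0.05
    run_decoding: bool = True
    run_rsa: bool = True
    run_fusion: bool = True
    run_netstats: bool = True
    make_figures: bool = True
    roi_filter: dict = field(
        default_factory=lambda: {"mode": "permutation", "n_perm": 500}
    )
    seed: int = 0


def demo_config(seed: int = 0) -> PipelineConfig:
    """A desk-scale study that completes in a few minutes.

    Keeps the full 300-trial design (15 repetitions per image, so all 40
    conditions are reliably populated) but scales down sensors, voxels,
    sampling rate, subject counts, and permutation counts.
    """
    sim = SimulationConfig(
        n_subjects_meg=6,
        n_subjects_fmri=6,
        n_trials=300,
        n_sensors=48,
        n_voxels_per_roi=60,
        sfreq_hz=20.0,
        seed=seed,
    )
    dec = DecodingConfig(time_step_ms=250.0, max_resample_models=8, seed=seed)
    return PipelineConfig(
        sim=sim,
        decoding=dec,
        rdm_step_ms=100.0,
        n_perm=300,
        seed=seed,
    )


def _child_seed(seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage child seed below 2**31."""
    key = zlib.crc32(f"{stage}:{index}".encode())
    ss = np.random.SeedSequence(seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def filter_rois(
    meg_rdms: np.ndarray,
    fmri_rdms: dict[str, np.ndarray],
    criterion: dict | None = None,
    seed: int | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Drop ROIs whose RDMs never positively correlate with the MEG RDMs.

    mode="permutation" (default): an ROI is retained when its maximum
    Spearman rho over time exceeds the 95th percentile of a null built by
    permuting the fMRI RDM's condition labels (max over time per draw).
    mode="threshold": retained when max rho >= ``min_rho``.
    """
    criterion = criterion or {"mode": "permutation", "n_perm": 500}
    retained: list[str] = []
    excluded: dict[str, str] = {}
    rng = np.random.default_rng(seed)
    for roi, fmri_rdm in fmri_rdms.items():
        meg_ranks, f_ranks, _, pair_index = fusion._prepare_rank_vectors(
            meg_rdms, fmri_rdm, fmri_rdm
        )
        rho = meg_ranks @ f_ranks
        obs = float(rho.max())
        if criterion["mode"] == "threshold":
            ok = obs >= criterion["min_rho"]
            reason = f"max rho {obs:.3f} < {criterion['min_rho']}"
        elif criterion["mode"] == "permutation":
            n_perm = int(criterion.get("n_perm", 500))
            n_cond = int(np.asarray(fmri_rdm).shape[0])
            null_max = np.empty(n_perm)
            for i in range(n_perm):
                sigma = stats._pair_permutation(
                    pair_index, rng.permutation(n_cond), n_cond
                )
                null_max[i] = (meg_ranks @ f_ranks[sigma]).max()
            crit = float(np.percentile(null_max, 95.0))
            ok = obs > crit
            reason = f"max rho {obs:.3f} not above permutation criterion {crit:.3f}"
        else:
            raise ValueError(f"unknown ROI filter mode {criterion['mode']!r}")
        if ok:
            retained.append(roi)
        else:
            excluded[roi] = reason
    if not retained:
        raise RuntimeError("all ROIs excluded by the fusion filter")
    return retained, excluded


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the full synthetic study; returns the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }

    stage = "simulate"
    try:
        behaviors, meg_subjects = [], []
        for s in range(config.sim.n_subjects_meg):
            sub_cfg = config.sim.with_seed(_child_seed(config.seed, "meg_subject", s))
            behavior = generate_behavior(sub_cfg)
            epochs, ground_truth = generate_meg_epochs(sub_cfg, behavior)
            behaviors.append(behavior.assign(subject=s))
            meg_subjects.append(epochs)
        behavior_all = pd.concat(behaviors, ignore_index=True)
        behavior_all.to_csv(out / "behavior.tsv", sep="\t", index=False)
        ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        io.config_to_yaml(config.sim, out / "simulation_config.yaml")

        fmri_rdms: dict[str, np.ndarray] = {}
        for s in range(config.sim.n_subjects_fmri):
            sub_cfg = config.sim.with_seed(_child_seed(config.seed, "fmri_subject", s))
            betas, _ = generate_fmri_patterns(sub_cfg, mode="betas")
            for roi, patterns in betas.items():
                rdm = rsa.compute_rdm(patterns)
                fmri_rdms.setdefault(roi, []).append(rdm)
        fmri_rdms = {roi: np.mean(v, axis=0) for roi, v in fmri_rdms.items()}
        io.save_betas(out / "fmri_group_rdms.h5", fmri_rdms)
        manifest["stages"].append(stage)
        logger.info("simulated %d MEG subjects, %d fMRI subjects",
                    config.sim.n_subjects_meg, config.sim.n_subjects_fmri)
    except Exception:
        logger.exception("stage %r failed", stage)
        raise RuntimeError(f"pipeline stage {stage!r} failed") from None

    try:
        decoding_result = None
        if config.run_decoding:
            stage = "decode"
            accs = []
            for s, epochs in enumerate(meg_subjects):
                cfg = dataclasses.replace(
                    config.decoding, seed=_child_seed(config.seed, "decode", s)
                )
                tc = decode_timecourse(epochs, "outcome", cfg)
                accs.append(tc.balanced_accuracy_percent)
            acc = np.stack(accs)
            decoding_result = stats.cluster_sign_permutation_test(
                acc,
                chance=50.0,
                time_ms=tc.time_ms,
                n_perm=config.n_perm,
                alpha=config.alpha,
                seed=_child_seed(config.seed, "decode_test"),
            )
            pd.DataFrame(
                {
                    "time_ms": tc.time_ms,
                    "mean_accuracy": acc.mean(axis=0),
                    "significant": decoding_result.mask,
                }
            ).to_csv(out / "decoding_outcome.tsv", sep="\t", index=False)
            manifest["stages"].append(stage)

        stage = "rdm"
        subject_rdms, rdm_times = [], None
        for epochs in meg_subjects:
            rdms, rdm_times = rsa.rdm_timecourse(epochs, step_ms=config.rdm_step_ms)
            subject_rdms.append(rdms)
        subject_rdms = np.stack(subject_rdms)
        group_rdms = subject_rdms.mean(axis=0)
        io.save_rdms(out / "meg_group_rdms.h5", group_rdms, rdm_times)
        manifest["stages"].append(stage)

        if config.run_rsa:
            stage = "rsa"
            mean_r, mean_u, clustering_test = rsa.mean_group_dissimilarity_test(
                subject_rdms,
                rdm_times,
                n_perm=config.n_perm,
                alpha=config.alpha,
                seed=_child_seed(config.seed, "rsa_test"),
            )
            pd.DataFrame(
                {
                    "time_ms": rdm_times,
                    "mean_dissim_recognized": mean_r.mean(axis=0),
                    "mean_dissim_unrecognized": mean_u.mean(axis=0),
                    "clustering_significant": clustering_test.mask,
                }
            ).to_csv(out / "rsa_clustering.tsv", sep="\t", index=False)
            cat_rho = {
                oc: np.stack(
                    [rsa.category_model_correlation(s, oc) for s in subject_rdms]
                ).mean(axis=0)
                for oc in ("recognized", "unrecognized")
            }
            pd.DataFrame({"time_ms": rdm_times, **{
                f"category_rho_{k}": v for k, v in cat_rho.items()
            }}).to_csv(out / "rsa_category.tsv", sep="\t", index=False)
            manifest["stages"].append(stage)

        commonalities: dict[str, fusion.CommonalityTimecourse] = {}
        cluster_results: dict[tuple[str, str], stats.ClusterTestResult] = {}
        if config.run_fusion:
            stage = "fuse"
            retained, excluded_rois = filter_rois(
                group_rdms,
                fmri_rdms,
                config.roi_filter,
                seed=_child_seed(config.seed, "roi_filter"),
            )
            models = {name: rsa.build_model_rdm(name).values for name in MODEL_NAMES}
            rows = []
            for roi in retained:
                ct = fusion.commonality_timecourse(
                    group_rdms, fmri_rdms[roi], models, rdm_times, roi=roi
                )
                commonalities[roi] = ct
                for name in MODEL_NAMES:
                    cluster_results[(roi, name)] = stats.cluster_label_permutation_test(
                        group_rdms,
                        fmri_rdms[roi],
                        models[name],
                        time_ms=rdm_times,
                        n_perm=config.n_perm,
                        alpha=config.alpha,
                        seed=_child_seed(config.seed, f"fusion_test:{roi}:{name}"),
                    )
                    rows.extend(
                        {
                            "roi": roi,
                            "model": name,
                            "time_ms": t,
                            "C": c,
                            "R2_fusion": r2,
                            "significant": sig,
                        }
                        for t, c, r2, sig in zip(
                            rdm_times,
                            ct.c[name],
                            ct.r2_fusion,
                            cluster_results[(roi, name)].mask,
                        )
                    )
            pd.DataFrame(rows).to_csv(out / "fusion_commonality.tsv", sep="\t", index=False)
            (out / "fusion_excluded_rois.json").write_text(json.dumps(excluded_rois, indent=1))
            manifest["stages"].append(stage)

        if config.run_netstats and commonalities:
            stage = "netstats"
            assignment = netstats.NetworkAssignment(
                network={
                    roi: config.sim.roi_profiles[roi].network for roi in commonalities
                },
                excluded={},
            )
            post = rdm_times >= 0
            roi_explained = {
                name: {
                    roi: netstats.explained_fraction(ct.c[name], ct.r2_fusion)[post]
                    for roi, ct in commonalities.items()
                }
                for name in MODEL_NAMES
            }
            t_post = rdm_times[post]
            net_explained = {
                name: netstats.network_average(roi_explained[name], assignment)
                for name in MODEL_NAMES
            }
            windows = netstats.split_windows(t_post, "early_late")
            anova_out, summary_rows = {}, []
            for net in sorted({v for v in assignment.network.values()}):
                early = np.column_stack(
                    [net_explained[m][net][windows["early"]] for m in MODEL_NAMES]
                )
                late = np.column_stack(
                    [net_explained[m][net][windows["late"]] for m in MODEL_NAMES]
                )
                res = netstats.mixed_anova_2x2(early, late, MODEL_NAMES)
                anova_out[net] = {
                    "table": res.table.to_dict(orient="records"),
                    "posthoc": res.posthoc.to_dict(orient="records"),
                }
                for m in MODEL_NAMES:
                    for win, idx in windows.items():
                        summary_rows.append(
                            {
                                "network": net,
                                "model": m,
                                "window": win,
                                "median_explained_pct": float(
                                    np.nanmedian(net_explained[m][net][idx])
                                ),
                            }
                        )
            (out / "netstats_anova.json").write_text(json.dumps(anova_out, indent=1))
            pd.DataFrame(summary_rows).to_csv(
                out / "netstats_explained.tsv", sep="\t", index=False
            )

            dominance_rows = []
            for roi, ct in commonalities.items():
                prof = config.sim.roi_profiles[roi]
                planted = (
                    "two_state"
                    if prof.two_state_weight > prof.recognition_weight
                    else "recognition"
                )
                recovered = netstats.dominant_model(
                    {m: roi_explained[m][roi] for m in MODEL_NAMES}
                )
                dominance_rows.append(
                    {
                        "roi": roi,
                        "network": assignment.network[roi],
                        "planted_dominant": planted,
                        "recovered_dominant": recovered,
                        "match": planted == recovered,
                    }
                )
            pd.DataFrame(dominance_rows).to_csv(
                out / "model_dominance.tsv", sep="\t", index=False
            )
            manifest["stages"].append(stage)

        if config.make_figures:
            from . import plotting

            if decoding_result is not None:
                plotting.plot_decoding(
                    tc.time_ms, acc, decoding_result, out / "fig_decoding.png"
                )
            if commonalities:
                plotting.plot_commonality(commonalities, out / "fig_commonality.png")

    except Exception:
        logger.exception("stage %r failed", stage)
        raise RuntimeError(f"pipeline stage {stage!r} failed") from None

    from . import __version__

    manifest["version"] = __version__
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
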