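"""End-to-end orchestration.

Stages (each reads the previous stage's serialized outputs from the run
directory, so any stage can be rerun in isolation):

1. simulate   -- toy atlas, design table, per-block voxel series + motion,
                 IGT trial logs and net-advantageous scores
2. preprocess -- discard, scrub, mask, band-pass, nuisance + global regression
3. networks   -- correlation -> N = K^S threshold -> binary graph per block
4. metrics    -- whole-network summaries and DMN/FPN regional means
5. hubs       -- top-20% hub sets, Jaccard similarity, permutation test
6. stats      -- RM-ANOVAs and the AR(1) mixed model on IGT performance

A manifest records the config hash, seeds and content checksums of every
product, so identical config + seed reproduce an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .igt import default_schedule, net_advantageous, simulate_agent
from .groupstats import behavioral_anova, fit_performance_model, rm_anova_2x4
from .hubs import consistency_map, hub_set, permutation_test, similarity_matrix
from .metrics import degree_map, local_efficiency_map, network_summary, roi_mean
from .netbuild import build_network, load_edgelist
from .preprocess import build_gray_matter_mask, preprocess_block, \
    tissue_probability_volumes
from .roimasks import load_roi_table, merge_network_mask, reference_roi_table
from .synthetic import SimulationParams, default_study_atlas, simulate_study
from .timeseries import VoxelTimeSeriesSet
from .volumes import LabelInfo, LabeledVolume

log = logging.getLogger("igtnet.pipeline")


class RunManifest:
    """Content checksums and provenance of one pipeline run."""

    def __init__(self, config: PipelineConfig):
        self.record = {
            "version": __version__,
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "stages": {},
        }

    def add(self, stage: str, name: str, payload) -> None:
        self.record["stages"].setdefault(stage, {})[name] = _checksum(payload)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.record, fh, indent=1, sort_keys=True)


def _checksum(payload) -> str:
    h = hashlib.sha256()
    if isinstance(payload, np.ndarray):
        h.update(np.ascontiguousarray(payload).tobytes())
    elif isinstance(payload, pd.DataFrame):
        h.update(payload.to_csv(index=False).encode())
    elif isinstance(payload, (str, bytes)):
        h.update(payload if isinstance(payload, bytes) else payload.encode())
    else:
        h.update(json.dumps(payload, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _block_path(out: Path, sub: int, blk: int, stage: str) -> Path:
    return out / stage / f"sub{sub:02d}_block{blk:02d}.npz"


def _save_block(path: Path, ts: VoxelTimeSeriesSet, motion=None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {
        "data": ts.data,
        "voxel_index": ts.voxel_index,
        "labels": ts.labels,
        "kept": ts.kept_volume_index,
        "tr": np.array([ts.tr_seconds]),
        "provenance": np.frombuffer(
            json.dumps(
                {k: v for k, v in ts.provenance.items() if k != "label_table"}
            ).encode(), dtype=np.uint8
        ),
    }
    if motion is not None:
        arrays["motion"] = motion
    np.savez(path, **arrays)


def _load_block(path: Path, label_table=None):
    with np.load(path) as z:
        prov = json.loads(bytes(z["provenance"].tobytes()).decode())
        if label_table is not None:
            prov["label_table"] = label_table
        ts = VoxelTimeSeriesSet(
            data=z["data"],
            voxel_index=z["voxel_index"],
            labels=z["labels"],
            tr_seconds=float(z["tr"][0]),
            kept_volume_index=z["kept"],
            provenance=prov,
        )
        motion = z["motion"] if "motion" in z else None
    return ts, motion


def _save_label_table(path: Path, table: dict[int, LabelInfo]) -> None:
    payload = {
        str(c): {"name": i.name, "tissue": i.tissue, "network": i.network}
        for c, i in table.items()
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _load_label_table(path: Path) -> dict[int, LabelInfo]:
    payload = json.loads(path.read_text())
    return {int(c): LabelInfo(**info) for c, info in payload.items()}


def _sim_params(cfg: PipelineConfig, which: str) -> SimulationParams:
    s = cfg.synthetic
    if which == "rest":
        rho_w, rho_b, net = s.rest_rho_within, s.rest_rho_between, s.rest_network_rho
    else:
        rho_w, rho_b, net = s.task_rho_within, s.task_rho_between, s.task_network_rho
    return SimulationParams(
        n_timepoints=s.n_timepoints,
        tr_seconds=s.tr_seconds,
        rho_within=rho_w,
        rho_between=rho_b,
        community_rho_within=dict(net),
        ar1_coef=s.ar1_coef,
        global_signal_sd=s.global_signal_sd,
        noise_sd=s.noise_sd,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    t0 = time.time()
    atlas = default_study_atlas()
    atlas.save(out / "atlas.nii")
    _save_label_table(out / "atlas_labels.json", atlas.label_table)
    manifest.add("simulate", "atlas", atlas.labels)

    design, blocks = simulate_study(
        cfg.synthetic.n_subjects,
        atlas=atlas,
        rest=_sim_params(cfg, "rest"),
        task=_sim_params(cfg, "task"),
        orienting=_sim_params(cfg, "task"),
        seed=cfg.seed,
    )
    design.to_csv(out / "design.csv", index=False)
    manifest.add("simulate", "design", design)
    for (sub, blk), block in blocks.items():
        _save_block(_block_path(out, sub, blk, "blocks"), block.ts, block.motion)
        manifest.add("simulate", f"block_{sub}_{blk}", block.ts.data)

    # behavior: one IGT run per subject per session
    schedule = default_schedule()
    rows, trial_frames = [], []
    for sub in sorted({s for s, _ in blocks}):
        for session in range(1, 5):
            agent_seed = int(
                np.random.SeedSequence([cfg.seed, sub, session]).generate_state(1)[0]
            ) % (2**31)
            record = simulate_agent(
                schedule,
                policy=cfg.igt.policy,
                n_trials=cfg.igt.n_trials,
                seed=agent_seed,
                epsilon=cfg.igt.epsilon,
                block_index=session,
            )
            rows.append(
                {
                    "subject": sub,
                    "session": session,
                    "igt_score": net_advantageous(record),
                    "final_total": record.final_total(),
                }
            )
            tf = record.trials.copy()
            tf.insert(0, "session", session)
            tf.insert(0, "subject", sub)
            trial_frames.append(tf)
    scores = pd.DataFrame(rows)
    (out / "behavior").mkdir(exist_ok=True)
    scores.to_csv(out / "behavior" / "igt_scores.csv", index=False)
    pd.concat(trial_frames).to_csv(out / "behavior" / "trials.csv", index=False)
    manifest.add("simulate", "igt_scores", scores)
    log.info("simulate: %d blocks, %.1fs", len(blocks), time.time() - t0)


def stage_preprocess(cfg: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    t0 = time.time()
    table = _load_label_table(out / "atlas_labels.json")
    import nibabel as nib

    img = nib.load(out / "atlas.nii")
    atlas = LabeledVolume(np.asarray(img.dataobj).astype(int), img.affine, table)
    gm, wm, csf = tissue_probability_volumes(atlas)
    gm_mask = build_gray_matter_mask(gm, wm, csf, atlas)
    np.save(out / "gm_mask.npy", gm_mask)
    manifest.add("preprocess", "gm_mask", gm_mask.astype(np.uint8))

    design = pd.read_csv(out / "design.csv")
    p = cfg.preprocess
    reports = []
    for row in design.itertuples(index=False):
        ts, motion = _load_block(
            _block_path(out, row.subject, row.block_index, "blocks"), table
        )
        clean, report = preprocess_block(
            ts,
            motion,
            gm_mask,
            n_discard=p.n_discard,
            fd_threshold=p.fd_threshold_mm,
            low=p.band_low_hz,
            high=p.band_high_hz,
            include_global=p.include_global,
            filter_before_regression=p.filter_before_regression,
        )
        _save_block(_block_path(out, row.subject, row.block_index, "clean"), clean)
        report.update(subject=row.subject, block_index=row.block_index)
        reports.append(report)
        manifest.add("preprocess", f"clean_{row.subject}_{row.block_index}",
                     clean.data)
    pd.DataFrame(reports).to_csv(out / "scrub_report.csv", index=False)
    log.info("preprocess: %d blocks, %.1fs", len(reports), time.time() - t0)


def stage_networks(cfg: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    t0 = time.time()
    design = pd.read_csv(out / "design.csv")
    (out / "networks").mkdir(exist_ok=True)
    for row in design.itertuples(index=False):
        ts, _ = _load_block(_block_path(out, row.subject, row.block_index, "clean"))
        net = build_network(ts, S=cfg.threshold.S)
        base = out / "networks" / f"sub{row.subject:02d}_block{row.block_index:02d}"
        net.save_edgelist(f"{base}.edges", f"{base}.json")
        manifest.add("networks", f"net_{row.subject}_{row.block_index}",
                     net.adjacency)
    log.info("networks: %d built, %.1fs", len(design), time.time() - t0)


def _iter_networks(out: Path, design: pd.DataFrame):
    for row in design.itertuples(index=False):
        base = out / "networks" / f"sub{row.subject:02d}_block{row.block_index:02d}"
        yield row, load_edgelist(f"{base}.edges", f"{base}.json")


def stage_metrics(cfg: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    t0 = time.time()
    design = pd.read_csv(out / "design.csv")
    import nibabel as nib

    table = _load_label_table(out / "atlas_labels.json")
    img = nib.load(out / "atlas.nii")
    atlas = LabeledVolume(np.asarray(img.dataobj).astype(int), img.affine, table)
    gm_mask = np.load(out / "gm_mask.npy")
    rois = (
        load_roi_table(cfg.roi_table) if cfg.roi_table else reference_roi_table()
    )
    net_masks = {
        name: merge_network_mask(
            [r for r in rois if r.network == name], atlas, gm_mask
        ).mask
        for name in ("DMN", "FPN")
    }

    summaries, regional = [], []
    for row, net in _iter_networks(out, design):
        summ = network_summary(net)
        summaries.append(
            {
                "subject": row.subject,
                "block_index": row.block_index,
                "condition": row.condition,
                "session": row.session,
                "analyze": row.analyze,
                "n_nodes": summ.n_nodes,
                "n_components": summ.n_components,
                "achieved_K": net.spec.achieved_K if net.spec else np.nan,
                "mean_K": summ.mean_K,
                "mean_E_loc": summ.mean_E_loc,
                "E_glob": summ.E_glob,
            }
        )
        if not row.analyze:
            continue
        from .metrics import nodal_efficiency_map

        kmap = degree_map(net)
        emap = local_efficiency_map(net)
        gmap = nodal_efficiency_map(net)
        for name, mask in net_masks.items():
            regional.append(
                {
                    "subject": row.subject,
                    "block_index": row.block_index,
                    "condition": row.condition,
                    "session": row.session,
                    "network": name,
                    "K": roi_mean(kmap, mask, name),
                    "E_loc": roi_mean(emap, mask, name),
                    "E_glob": roi_mean(gmap, mask, name),
                }
            )
    summaries_df = pd.DataFrame(summaries)
    regional_df = pd.DataFrame(regional)
    summaries_df.to_csv(out / "network_summaries.csv", index=False)
    regional_df.to_csv(out / "roi_metrics.csv", index=False)
    manifest.add("metrics", "network_summaries", summaries_df)
    manifest.add("metrics", "roi_metrics", regional_df)
    log.info("metrics: %d networks, %.1fs", len(summaries), time.time() - t0)


def stage_hubs(cfg: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    t0 = time.time()
    design = pd.read_csv(out / "design.csv")
    analyzed = design[design["analyze"]]
    hubs, labels, subjects = [], [], []
    for row, net in _iter_networks(out, analyzed):
        degrees = net.adjacency.sum(axis=1)
        hubs.append(
            hub_set(degrees, fraction=cfg.hubs.fraction,
                    source={"subject": row.subject, "block": row.block_index})
        )
        labels.append(row.condition)
        subjects.append(row.subject)
    sim = similarity_matrix(hubs, labels, subjects)
    (out / "hubs").mkdir(exist_ok=True)
    sim_df = pd.DataFrame(sim.entries)
    sim_df.to_csv(out / "hubs" / "similarity.csv", index=False)
    result = permutation_test(
        sim, n_perm=cfg.hubs.n_perm, seed=cfg.seed, scheme=cfg.hubs.scheme
    )
    payload = {
        "observed_stat": result.observed_stat,
        "p_value": result.p_value,
        "n_perm": result.n_perm,
        "scheme": result.scheme,
        "min_attainable_p": result.min_attainable_p,
    }
    (out / "hubs" / "permutation.json").write_text(json.dumps(payload, indent=1))
    np.savetxt(out / "hubs" / "null_stats.csv", result.null_stats, delimiter=",")
    for condition in ("rest", "IGT"):
        rows = [h for h, lab in zip(hubs, labels) if lab == condition]
        cmap = consistency_map(rows)
        np.savetxt(out / "hubs" / f"consistency_{condition}.csv", cmap,
                   delimiter=",")
        manifest.add("hubs", f"consistency_{condition}", cmap)
    manifest.add("hubs", "similarity", sim.entries)
    manifest.add("hubs", "permutation", payload)
    log.info("hubs: stat=%.3f p=%.4f, %.1fs", result.observed_stat,
             result.p_value, time.time() - t0)


def stage_stats(cfg: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    t0 = time.time()
    summaries = pd.read_csv(out / "network_summaries.csv")
    regional = pd.read_csv(out / "roi_metrics.csv")
    scores = pd.read_csv(out / "behavior" / "igt_scores.csv")
    (out / "stats").mkdir(exist_ok=True)

    if cfg.synthetic.n_subjects < 2:
        warnings.warn("fewer than 2 subjects: group statistics skipped",
                      stacklevel=2)
        (out / "stats" / "SKIPPED.txt").write_text(
            "group statistics require >= 2 subjects\n"
        )
        return

    analyzed = summaries[summaries["analyze"]]
    anova_rows = []
    for metric in ("mean_E_loc", "E_glob"):
        tbl = analyzed.rename(columns={metric: "value"})
        res = rm_anova_2x4(tbl[["subject", "condition", "session", "value"]])
        for _, r in res.effects.iterrows():
            anova_rows.append({"analysis": f"whole_brain_{metric}", **r.to_dict()})
    # regional rest-vs-IGT ANOVAs per network and metric
    for network in ("DMN", "FPN"):
        sub = regional[regional["network"] == network]
        for metric in ("K", "E_loc", "E_glob"):
            tbl = sub.rename(columns={metric: "value"})
            res = rm_anova_2x4(tbl[["subject", "condition", "session", "value"]])
            for _, r in res.effects.iterrows():
                anova_rows.append(
                    {"analysis": f"{network}_{metric}", **r.to_dict()}
                )
    # DMN-vs-FPN comparison within each condition (network as 2-level factor)
    for condition in ("rest", "IGT"):
        sub = regional[regional["condition"] == condition]
        for metric in ("K", "E_loc", "E_glob"):
            tbl = sub.rename(columns={metric: "value"})
            res = rm_anova_2x4(
                tbl[["subject", "network", "session", "value"]],
                factor_a="network",
            )
            for _, r in res.effects.iterrows():
                anova_rows.append(
                    {"analysis": f"{condition}_DMNvsFPN_{metric}", **r.to_dict()}
                )
    anova_df = pd.DataFrame(anova_rows)
    anova_df.to_csv(out / "stats" / "anovas.csv", index=False)
    manifest.add("stats", "anovas", anova_df)

    behav = behavioral_anova(scores)
    behav.effects.to_csv(out / "stats" / "behavior_anova.csv", index=False)
    manifest.add("stats", "behavior_anova", behav.effects)

    # mixed model: IGT score ~ network metrics, per network
    igt_regional = regional[regional["condition"] == "IGT"]
    mm_rows = []
    for network in ("DMN", "FPN"):
        sub = igt_regional[igt_regional["network"] == network]
        merged = sub.merge(scores, on=["subject", "session"])
        try:
            fit = fit_performance_model(merged, network)
        except (RuntimeError, ValueError) as exc:
            warnings.warn(f"mixed model for {network} failed: {exc}", stacklevel=2)
            continue
        for _, r in fit.fixed_effects.iterrows():
            mm_rows.append(
                {
                    "network": network,
                    "term": r["term"],
                    "B": r["B"],
                    "SE": r["SE"],
                    "p": r["p"],
                    "ar1_rho": fit.ar1_rho,
                    "sigma_subject": fit.sigma_subject,
                    "sigma_resid": fit.sigma_resid,
                }
            )
    mm_df = pd.DataFrame(mm_rows)
    mm_df.to_csv(out / "stats" / "mixed_model.csv", index=False)
    manifest.add("stats", "mixed_model", mm_df)
    log.info("stats: %.1fs", time.time() - t0)


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "networks": stage_networks,
    "metrics": stage_metrics,
    "hubs": stage_hubs,
    "stats": stage_stats,
}


def run_pipeline(
    config: PipelineConfig, stages: list[str] | None = None
) -> RunManifest:
    """Run the requested stages (default: all) and write the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = RunManifest(config)
    for name in stages or list(STAGES):
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")
        try:
            STAGES[name](config, out, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    manifest.save(out / "manifest.json")
    return manifest
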