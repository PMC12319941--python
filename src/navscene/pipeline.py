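"""End-to-end orchestration: simulate -> select ROIs -> decode + contrasts -> infer.

One reproducible run from a single declarative configuration: a seeded
synthetic experiment is generated, per-subject functional ROIs are
selected from simulated localizer data, split-half Euclidean-distance
decoding and hemisphere-resolved univariate contrasts are computed per
subject and ROI, and group-level t-tests and repeated-measures ANOVAs
are collected into one tidy statistics table. A manifest (config, seed,
library versions) accompanies every output set.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contrasts import condition_means, contrast_table
from .decoding import (
    SCHEMES,
    build_hypothesis_matrix,
    decode_run_stack,
    group_decoding_test,
    room_pattern_stack,
    score_decoding,
)
from .io import write_events_tsv, write_table
from .roi import select_top_voxels, selection_statistic
from .simulate import (
    HEMISPHERES,
    SimulationConfig,
    SimulatedExperiment,
    simulate_betas,
    simulate_localizer,
)
from .stats import paired_t, rm_anova_2way, interaction_contrast_2x2

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "select_rois"]

SCENE_ROIS = ("OPA", "PPA", "MPA")

# directional prediction of each univariate contrast's group test
CONTRAST_TAILS = {
    "contra_door": 1,
    "turn_direction": 1,
    "forward_backward": 2,
    "consistency_contra_turns": 1,
    "consistency_ipsi_turns": 2,  # predicted null
}


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run."""

    simulation: SimulationConfig
    schemes: tuple[str, ...] = SCHEMES
    rois: tuple[str, ...] = ("OPA", "PPA", "MPA", "EVC")
    n_mask_voxels: int = 100
    n_roi_voxels: int = 50
    roi_gain: dict = field(default_factory=dict)
    scenario: tuple | None = None
    missing_rois: tuple[tuple[str, int], ...] = ()  # (roi, subject) pairs to drop
    run_contrasts: bool = True
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d


@dataclass
class PipelineResult:
    experiment: SimulatedExperiment
    selections: dict
    decoding_scores: pd.DataFrame
    distance_matrices: dict
    means: pd.DataFrame
    contrasts: pd.DataFrame
    stats_table: pd.DataFrame
    manifest: dict


def select_rois(config: PipelineConfig) -> dict:
    """Per (roi, hemisphere): list of per-subject selected voxel-id arrays.

    Scene ROIs rank by scenes > objects, EVC by all conditions >
    fixation, within the simulated candidate masks.
    """
    localizer = simulate_localizer(
        config.simulation, n_mask_voxels=config.n_mask_voxels, rois=config.rois
    )
    selections: dict = {}
    for (roi, hemi), per_subject in localizer.items():
        scheme = "all_gt_fixation" if roi == "EVC" else "scenes_gt_objects"
        sels = []
        for responses in per_subject:
            stat = selection_statistic(responses, scheme)
            sel = select_top_voxels(
                stat, n=config.n_roi_voxels, roi=roi, hemisphere=hemi
            )
            sels.append(sel.voxel_ids)
        selections[(roi, hemi)] = sels
    return selections


def _subject_voxels(selections: dict, roi: str, subject: int) -> dict:
    return {h: selections[(roi, h)][subject] for h in HEMISPHERES}


def _decode_all(config: PipelineConfig, experiment, room_experiment, selections):
    """Per-subject decoding scores for every ROI and scheme."""
    rows = []
    dist_store: dict = {}
    hyps = {s: build_hypothesis_matrix(s, n_rooms=config.simulation.n_rooms)
            for s in config.schemes}
    dropped = set(config.missing_rois)
    for roi in config.rois:
        for s in range(config.simulation.n_subjects):
            if (roi, s) in dropped:
                continue
            vox = _subject_voxels(selections, roi, s)
            dist = decode_run_stack(experiment.pattern_stack(s, roi, vox))
            dist_store[(roi, s)] = dist
            room_dist = None
            if "room_texture" in config.schemes:
                stacks = []
                for hemi in HEMISPHERES:
                    runs = room_experiment.usable_run_ids(s)
                    cells = room_experiment.betas[(roi, hemi)][s][runs]
                    cells = cells[:, :, vox[hemi]]
                    stacks.append(
                        room_pattern_stack(
                            cells,
                            room_experiment.cell_labels,
                            n_rooms=config.simulation.n_rooms,
                        )
                    )
                room_dist = decode_run_stack(np.concatenate(stacks, axis=-1))
                dist_store[(roi, s, "room")] = room_dist
            for scheme in config.schemes:
                score = score_decoding(
                    room_dist if scheme == "room_texture" else dist, hyps[scheme]
                )
                rows.append(
                    (s, roi, scheme, score.within_mean, score.between_mean, score.diff)
                )
    scores = pd.DataFrame(
        rows, columns=["subject", "roi", "scheme", "within_mean", "between_mean", "diff"]
    )
    return scores, dist_store


def _group_stats(config: PipelineConfig, scores: pd.DataFrame,
                 contrasts: pd.DataFrame) -> pd.DataFrame:
    """Tidy group-inference table: t-tests per ROI plus region ANOVAs."""
    rows = []

    def add(analysis, roi, stat_name, stat, df, p, correction="none", tails=None):
        rows.append({
            "analysis": analysis, "roi_or_effect": roi, "statistic": stat_name,
            "value": stat, "df": df, "p": p, "correction": correction,
            "tails": tails,
        })

    for scheme in config.schemes:
        sub = scores[scores["scheme"] == scheme]
        for roi in config.rois:
            diffs = sub.loc[sub["roi"] == roi, "diff"].to_numpy()
            if diffs.size < 3:
                continue
            res = group_decoding_test(diffs)
            add(f"decoding:{scheme}", roi, "t", res.t, res.df, res.p, tails=1)
        # region x (within, between) ANOVA over the three scene regions
        wide = sub[sub["roi"].isin(SCENE_ROIS)]
        complete = (
            wide.groupby("subject")["roi"].nunique() == len(SCENE_ROIS)
        )
        keep = complete[complete].index
        wide = wide[wide["subject"].isin(keep)]
        if wide["subject"].nunique() >= 3:
            long = wide.melt(
                id_vars=["subject", "roi"],
                value_vars=["within_mean", "between_mean"],
                var_name="cell", value_name="value",
            )
            res = rm_anova_2way(
                long, subject="subject", factors=("roi", "cell"), value="value",
                effect_names=("region", "decoding", "region:decoding"),
            )
            e = res["region:decoding"]
            add(f"decoding:{scheme}", "region:decoding ANOVA", "F",
                e.F, f"{e.df_num:g},{e.df_den:g}", e.p)
            add(f"decoding:{scheme}", "region:decoding ANOVA", "F",
                e.F, f"{e.df_num_gg:.2f},{e.df_den_gg:.2f}", e.p_gg,
                correction="greenhouse-geisser")
            for other in ("PPA", "MPA"):
                pair = long[long["roi"].isin(["OPA", other])]
                e2 = interaction_contrast_2x2(
                    pair, subject="subject", factors=("roi", "cell"), value="value"
                )
                add(f"decoding:{scheme}", f"OPA-vs-{other} 2x2", "F",
                    e2.F, f"{e2.df_num:g},{e2.df_den:g}", e2.p)

    if len(contrasts):
        for name, tails in CONTRAST_TAILS.items():
            sub = contrasts[contrasts["contrast"] == name]
            for roi in config.rois:
                diffs = sub.loc[sub["roi"] == roi, "diff"].to_numpy()
                if diffs.size < 3:
                    continue
                res = paired_t(diffs, tails=tails, direction="greater")
                add(f"contrast:{name}", roi, "t", res.t, res.df, res.p, tails=tails)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage deterministically under the configured seed."""
    sim = config.simulation
    logger.info("simulating experiment: %d subjects, %d runs, seed %d",
                sim.n_subjects, sim.n_runs, sim.seed)
    sim_mask = _mask_level_config(config)
    experiment = simulate_betas(
        sim_mask, rois=config.rois, roi_gain=config.roi_gain,
        scenario=config.scenario,
    )
    room_experiment = None
    if "room_texture" in config.schemes:
        room_experiment = simulate_betas(
            sim_mask, schedule=experiment.schedule, rois=config.rois,
            roi_gain=config.roi_gain, scenario=config.scenario,
            room_resolved=True,
        )
    logger.info("selecting top-%d voxels per hemisphere", config.n_roi_voxels)
    selections = select_rois(config)
    logger.info("decoding schemes: %s", ", ".join(config.schemes))
    scores, dists = _decode_all(config, experiment, room_experiment, selections)

    if config.run_contrasts:
        sel_arrays = {k: v for k, v in selections.items()}
        means = condition_means(
            experiment.betas, experiment.usable_runs, selections=sel_arrays
        )
        means = _drop_missing(means, config.missing_rois)
        contrasts = contrast_table(means)
    else:
        means = pd.DataFrame()
        contrasts = pd.DataFrame()

    stats = _group_stats(config, scores, contrasts)
    manifest = _manifest(config)
    result = PipelineResult(
        experiment=experiment,
        selections=selections,
        decoding_scores=scores,
        distance_matrices=dists,
        means=means,
        contrasts=contrasts,
        stats_table=stats,
        manifest=manifest,
    )
    if config.output_dir:
        _write_outputs(config, result)
    return result


def _mask_level_config(config: PipelineConfig) -> SimulationConfig:
    from dataclasses import replace

    return replace(config.simulation, n_voxels=config.n_mask_voxels)


def _drop_missing(means: pd.DataFrame, missing) -> pd.DataFrame:
    for roi, subject in missing:
        means = means[~((means["roi"] == roi) & (means["subject"] == subject))]
    return means.reset_index(drop=True)


def _manifest(config: PipelineConfig) -> dict:
    import scipy

    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True, default=str)
    return {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.simulation.seed,
        "versions": {
            "navscene": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }


def _write_outputs(config: PipelineConfig, result: PipelineResult) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_events_tsv(result.experiment.schedule, out / "events.tsv")
    write_table(result.decoding_scores, out / "decoding_scores.tsv")
    if len(result.contrasts):
        write_table(result.contrasts, out / "contrasts.tsv")
        write_table(result.means, out / "condition_means.tsv")
    write_table(result.stats_table, out / "statistics.tsv")
    for scheme in config.schemes:
        h = build_hypothesis_matrix(scheme, n_rooms=config.simulation.n_rooms)
        h.to_csv(out / f"hypothesis_{scheme}.tsv", sep="\t")
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=1, default=str)
    )
    logger.info("outputs written to %s", out)
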