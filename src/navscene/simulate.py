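"""Synthetic experiment generation with known ground truth.

Emulates the statistical structure of an event-related fMRI study of
navigational affordances (open doorway to the left, right, or both
sides) crossed with ego-motion direction (forward, backward, left turn,
right turn) in four bilateral ROIs (OPA, PPA, MPA, EVC). The generator
produces the condition table, per-run event schedules with jittered
ISIs and counterbalanced room types, run-level condition betas or BOLD
time series per subject x ROI x hemisphere, and the injected ground
truth needed to predict the sign of every downstream contrast.

Injected effect components (all in units of the within-run noise SD):

* ``affordance_contra`` -- mean boost for forward/backward conditions
  whose doorway falls in a hemisphere's contralateral visual hemifield
  (door on the left boosts the right hemisphere, and vice versa; both-
  door conditions boost both hemispheres).
* ``ego_motion_code`` -- a stable random voxel pattern per ego-motion
  direction, separating the four directions multivariately.
* ``forward_bias`` -- mean boost for forward relative to backward motion.
* ``turn_contra_bias`` -- mean boost for turns toward a hemisphere's
  contralateral hemifield (left turns boost the right hemisphere).
* ``consistency_gain`` -- extra response for contralateral turns toward
  the open doorway (consistent turns) only.
* ``room_texture_code`` -- a stable random voxel pattern per room type.

Turn-condition responses are governed by turn direction and consistency
only (the doorway-side boost applies to the six forward/backward
conditions); this makes the contralateral consistency effect dissociable
from a mere doorway preference, mirroring the ipsilateral null the
univariate consistency analysis is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ROIS",
    "HEMISPHERES",
    "SCHEDULE_COLUMNS",
    "SchedulingError",
    "SimulationConfig",
    "LocalizerDesign",
    "GroundTruth",
    "SimulatedExperiment",
    "build_condition_table",
    "condition_groups",
    "demo_effects",
    "design_summary",
    "generate_event_schedule",
    "usable_run_scenarios",
    "paper_exclusion_counts",
    "simulate_betas",
    "simulate_bold",
    "simulate_localizer",
]

ROIS = ("OPA", "PPA", "MPA", "EVC")
HEMISPHERES = ("left", "right")
SCHEDULE_COLUMNS = ("run", "onset", "duration", "trial_type", "room_type")

N_CONDITIONS = 10
STIM_DURATION_S = 2.5
ISI_MIN_S = 3.5
ISI_MAX_S = 9.5

EFFECT_FIELDS = (
    "affordance_contra",
    "ego_motion_code",
    "forward_bias",
    "turn_contra_bias",
    "consistency_gain",
    "room_texture_code",
)


class SchedulingError(ValueError):
    """Raised when events cannot be packed into the run length."""


# ---------------------------------------------------------------------------
# Condition table
# ---------------------------------------------------------------------------

def build_condition_table() -> pd.DataFrame:
    """The fixed 10-condition factorial mapping.

    Affordance (left / right / both doorways) crossed with ego-motion
    (forward, backward, left turn, right turn). Turns toward the doorway
    are consistent (7, 10); turns away from it are inconsistent (8, 9).
    """
    rows = [
        (1, "both", "forward", "not_applicable"),
        (2, "left", "forward", "not_applicable"),
        (3, "right", "forward", "not_applicable"),
        (4, "both", "backward", "not_applicable"),
        (5, "left", "backward", "not_applicable"),
        (6, "right", "backward", "not_applicable"),
        (7, "left", "left_turn", "consistent"),
        (8, "right", "left_turn", "inconsistent"),
        (9, "left", "right_turn", "inconsistent"),
        (10, "right", "right_turn", "consistent"),
    ]
    return pd.DataFrame(
        rows, columns=["condition_id", "affordance", "ego_motion", "consistency"]
    )


def condition_groups() -> dict[str, dict[str, tuple[int, ...]]]:
    """Condition-id groupings by factor, derived from the condition table."""
    tab = build_condition_table()
    out: dict[str, dict[str, tuple[int, ...]]] = {}
    for factor in ("affordance", "ego_motion", "consistency"):
        out[factor] = {
            level: tuple(sub["condition_id"])
            for level, sub in tab.groupby(factor, sort=False)
        }
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of a simulated experiment.

    Effect sizes are expressed in units of the within-run noise SD
    (``noise_sd_run``) and default to zero, so the default configuration
    is an exact null. ``seed`` fully determines every output.
    """

    seed: int
    n_subjects: int = 16
    n_runs: int = 8
    reps_per_run: int = 4
    n_voxels: int = 50
    tr: float = 2.0
    n_volumes: int = 228
    n_rooms: int = 8
    lead_in_s: float = 6.0
    trail_s: float = 10.0
    affordance_contra: float = 0.0
    ego_motion_code: float = 0.0
    forward_bias: float = 0.0
    turn_contra_bias: float = 0.0
    consistency_gain: float = 0.0
    room_texture_code: float = 0.0
    noise_sd_run: float = 1.0
    noise_sd_subject: float = 0.5
    baseline: float = 10.0
    level: str = "beta"

    def __post_init__(self) -> None:
        for name in EFFECT_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"effect magnitude {name} must be >= 0")
        for name in ("noise_sd_run", "noise_sd_subject"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.level not in ("beta", "bold"):
            raise ValueError("level must be 'beta' or 'bold'")
        if self.level == "bold" and (self.tr <= 0 or self.n_volumes <= 0):
            raise ValueError("level='bold' requires positive tr and n_volumes")
        if self.n_subjects < 1 or self.n_runs < 1 or self.n_voxels < 1:
            raise ValueError("n_subjects, n_runs and n_voxels must be positive")
        if self.reps_per_run < 0:
            raise ValueError("reps_per_run must be >= 0")
        self.seed = int(self.seed)

    @property
    def run_length_s(self) -> float:
        return self.n_volumes * self.tr

    @property
    def events_per_run(self) -> int:
        return N_CONDITIONS * self.reps_per_run

    def rng(self, stream: int) -> np.random.Generator:
        """Named deterministic random stream derived from the seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )

    def to_dict(self) -> dict:
        return asdict(self)


def demo_effects(**overrides) -> dict[str, float]:
    """Effect preset with every injected component at 1 within-run noise SD."""
    eff = {name: 1.0 for name in EFFECT_FIELDS}
    eff.update(overrides)
    return eff


@dataclass(frozen=True)
class LocalizerDesign:
    """Block-design localizer timing (reproduced as a timing check only).

    Four stimulus categories (scenes, objects, faces, scrambled) in 15 s
    blocks of five 2.8 s clips with 0.2 s gaps, four blocks per category,
    plus five 15 s fixation blocks.
    """

    clip_s: float = 2.8
    clip_isi_s: float = 0.2
    clips_per_block: int = 5
    n_categories: int = 4
    blocks_per_category: int = 4
    n_fixation_blocks: int = 5
    tr: float = 2.0
    n_volumes: int = 158

    @property
    def block_s(self) -> float:
        return self.clips_per_block * (self.clip_s + self.clip_isi_s)

    @property
    def run_s(self) -> float:
        n_blocks = self.n_categories * self.blocks_per_category + self.n_fixation_blocks
        return n_blocks * self.block_s

    @property
    def acquisition_s(self) -> float:
        return self.n_volumes * self.tr


def design_summary(config: SimulationConfig | None = None) -> dict[str, float]:
    """Printed design quantities, computed from the design objects."""
    cfg = config or SimulationConfig(seed=0)
    loc = LocalizerDesign(tr=cfg.tr)
    return {
        "localizer_block_s": loc.block_s,
        "localizer_run_s": loc.run_s,
        "localizer_acquisition_s": loc.acquisition_s,
        "experimental_acquisition_s": cfg.run_length_s,
        "events_per_run": cfg.events_per_run,
        "reps_per_condition_total": cfg.reps_per_run * cfg.n_runs,
    }


# ---------------------------------------------------------------------------
# Event schedules
# ---------------------------------------------------------------------------

def _room_assignment(cond_idx: int, run: int, rep: int, reps_per_run: int,
                     room_perm: np.ndarray) -> int:
    """Balanced rotation: each condition cycles through all rooms.

    With 8 rooms, 4 reps/run and 8 runs, every condition sees every room
    exactly reps_per_run * n_runs / n_rooms times.
    """
    n_rooms = len(room_perm)
    e = reps_per_run * run + rep
    return int(room_perm[(cond_idx + e) % n_rooms]) + 1


def generate_event_schedule(config: SimulationConfig) -> pd.DataFrame:
    """Per-run event tables with uniform jittered ISIs and balanced rooms.

    Returns a BIDS-events-style frame with columns
    (run, onset, duration, trial_type, room_type). Each condition occurs
    ``reps_per_run`` times per run in seeded random order; gaps between
    consecutive events are drawn uniformly from [3.5, 9.5] s and, if the
    draw overshoots the run, rescaled down toward the 3.5 s floor.
    """
    n_ev = config.events_per_run
    if n_ev == 0:
        return pd.DataFrame(columns=list(SCHEDULE_COLUMNS))
    min_span = (
        config.lead_in_s
        + n_ev * STIM_DURATION_S
        + (n_ev - 1) * ISI_MIN_S
        + config.trail_s
    )
    if min_span > config.run_length_s:
        raise SchedulingError(
            f"{n_ev} events need at least {min_span:.1f} s but the run is "
            f"{config.run_length_s:.1f} s"
        )
    rng = config.rng(0)
    room_perm = config.rng(1).permutation(config.n_rooms)
    budget = config.run_length_s - config.trail_s

    frames = []
    for run in range(config.n_runs):
        order = rng.permutation(np.repeat(np.arange(N_CONDITIONS), config.reps_per_run))
        isis = rng.uniform(ISI_MIN_S, ISI_MAX_S, size=n_ev - 1)
        span = config.lead_in_s + n_ev * STIM_DURATION_S + isis.sum()
        if span > budget:
            # shrink jitter toward the 3.5 s floor, preserving the bounds
            excess = span - budget
            slack = isis.sum() - (n_ev - 1) * ISI_MIN_S
            isis = ISI_MIN_S + (isis - ISI_MIN_S) * (1.0 - excess / slack)
        onsets = config.lead_in_s + np.concatenate(
            [[0.0], np.cumsum(isis + STIM_DURATION_S)]
        )
        rep_count = np.zeros(N_CONDITIONS, dtype=int)
        rooms = np.empty(n_ev, dtype=int)
        for i, c in enumerate(order):
            rooms[i] = _room_assignment(
                int(c), run, rep_count[c], config.reps_per_run, room_perm
            )
            rep_count[c] += 1
        frames.append(
            pd.DataFrame(
                {
                    "run": run,
                    "onset": onsets,
                    "duration": STIM_DURATION_S,
                    "trial_type": order + 1,
                    "room_type": rooms,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def paper_exclusion_counts() -> tuple[tuple[int, int], ...]:
    """Usable-run scenario of the source study: 12/1/3 subjects with 8/6/5 runs."""
    return ((8, 12), (6, 1), (5, 3))


def usable_run_scenarios(
    config: SimulationConfig,
    scenario: tuple[tuple[int, int], ...] | None = None,
) -> np.ndarray:
    """Usable-run counts per subject.

    ``scenario`` is a sequence of (usable_runs, n_subjects) pairs summing
    to ``config.n_subjects``; by default every subject keeps all runs.
    Subjects are assigned to scenario groups in a seeded random order.
    """
    if scenario is None:
        counts = np.full(config.n_subjects, config.n_runs, dtype=int)
    else:
        parts = []
        for runs, n in scenario:
            if runs < 2:
                raise ValueError(
                    f"usable runs must be >= 2 for split-half analysis, got {runs}"
                )
            if runs > config.n_runs:
                raise ValueError(f"scenario requests {runs} runs but only "
                                 f"{config.n_runs} exist")
            parts.append(np.full(n, runs, dtype=int))
        counts = np.concatenate(parts)
        if counts.size != config.n_subjects:
            raise ValueError(
                f"scenario covers {counts.size} subjects, expected {config.n_subjects}"
            )
        counts = counts[config.rng(5).permutation(config.n_subjects)]
    if (counts < 2).any():
        raise ValueError("usable runs must be >= 2 for split-half analysis")
    return counts


# ---------------------------------------------------------------------------
# Ground truth and beta-level simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Injected components; sufficient to predict every downstream contrast.

    ``mean_boosts[(roi, hemi)]`` is the per-condition scalar expectation
    added to the baseline (already scaled by the noise SD); pattern
    components are stored per subject as (n_subjects, n_levels, n_voxels)
    arrays, stable across runs.
    """

    config: SimulationConfig
    room_perm: np.ndarray
    mean_boosts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    subject_maps: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    ego_patterns: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    room_patterns: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    ego_direction_index: dict[int, int] = field(default_factory=dict)

    def expected_betas(self, roi: str, hemi: str) -> np.ndarray:
        """Expectation of run betas, (n_subjects, n_conditions, n_voxels).

        Rooms are balanced within each condition over a full design, so
        the room component contributes the same grand-mean pattern to
        every condition and cancels from all contrasts.
        """
        cfg = self.config
        key = (roi, hemi)
        exp = np.full(
            (cfg.n_subjects, N_CONDITIONS, cfg.n_voxels), float(cfg.baseline)
        )
        exp += self.subject_maps[key][:, None, :]
        exp += self.mean_boosts[key][None, :, None]
        dir_idx = np.array([self.ego_direction_index[c] for c in range(1, 11)])
        exp += self.ego_patterns[key][:, dir_idx, :]
        exp += self.room_patterns[key].mean(axis=1)[:, None, :]
        return exp


def _condition_boosts(config: SimulationConfig, hemi: str, roi_gain: float) -> np.ndarray:
    """Scalar mean boost per condition for one hemisphere (in signal units)."""
    tab = build_condition_table()
    sd = config.noise_sd_run
    contra_side = "left" if hemi == "right" else "right"
    contra_turn = "left_turn" if hemi == "right" else "right_turn"
    boosts = np.zeros(N_CONDITIONS)
    for i, row in tab.iterrows():
        b = 0.0
        is_turn = row.ego_motion in ("left_turn", "right_turn")
        if not is_turn and row.affordance in (contra_side, "both"):
            b += config.affordance_contra
        if row.ego_motion == "forward":
            b += config.forward_bias
        if row.ego_motion == contra_turn:
            b += config.turn_contra_bias
            if row.consistency == "consistent":
                b += config.consistency_gain
        boosts[i] = b * sd * roi_gain
    return boosts


def _make_ground_truth(
    config: SimulationConfig,
    rois: tuple[str, ...],
    roi_gain: dict[str, float],
) -> GroundTruth:
    rng = config.rng(2)
    tab = build_condition_table()
    directions = ("forward", "backward", "left_turn", "right_turn")
    dir_index = {
        int(row.condition_id): directions.index(row.ego_motion)
        for _, row in tab.iterrows()
    }
    gt = GroundTruth(
        config=config,
        room_perm=config.rng(1).permutation(config.n_rooms),
        ego_direction_index=dir_index,
    )
    sd = config.noise_sd_run
    for roi in rois:
        gain = roi_gain.get(roi, 1.0)
        for hemi in HEMISPHERES:
            key = (roi, hemi)
            gt.mean_boosts[key] = _condition_boosts(config, hemi, gain)
            gt.subject_maps[key] = rng.normal(
                0.0, config.noise_sd_subject, (config.n_subjects, config.n_voxels)
            )
            gt.ego_patterns[key] = (
                rng.standard_normal((config.n_subjects, 4, config.n_voxels))
                * config.ego_motion_code * sd * gain
            )
            gt.room_patterns[key] = (
                rng.standard_normal(
                    (config.n_subjects, config.n_rooms, config.n_voxels)
                )
                * config.room_texture_code * sd * gain
            )
    return gt


@dataclass
class SimulatedExperiment:
    """A complete simulated dataset plus its generating ground truth.

    ``betas[(roi, hemi)]`` has shape (n_subjects, n_runs, n_conditions,
    n_voxels); for room-resolved simulations the condition axis holds
    condition x room cells described by ``cell_labels``.
    """

    config: SimulationConfig
    condition_table: pd.DataFrame
    schedule: pd.DataFrame
    usable_runs: np.ndarray
    betas: dict[tuple[str, str], np.ndarray]
    ground_truth: GroundTruth
    cell_labels: pd.DataFrame | None = None  # room-resolved only

    @property
    def rois(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(roi for roi, _ in self.betas))

    def usable_run_ids(self, subject: int) -> np.ndarray:
        return np.arange(self.usable_runs[subject])

    def pattern_stack(
        self, subject: int, roi: str, voxels: dict[str, np.ndarray] | None = None
    ) -> np.ndarray:
        """Bilateral run-beta stack (usable_runs, n_conditions, 2*n_voxels).

        Concatenates the left- and right-hemisphere patterns; ``voxels``
        optionally restricts each hemisphere to selected voxel indices
        (e.g., a top-50 ROI selection).
        """
        runs = self.usable_run_ids(subject)
        halves = []
        for hemi in HEMISPHERES:
            arr = self.betas[(roi, hemi)][subject][runs]
            if voxels is not None:
                arr = arr[:, :, voxels[hemi]]
            halves.append(arr)
        return np.concatenate(halves, axis=-1)


def _room_means_by_condition(
    schedule: pd.DataFrame, n_runs: int, n_rooms: int
) -> np.ndarray:
    """Per (run, condition): mean room indicator, (n_runs, 10, n_rooms)."""
    out = np.zeros((n_runs, N_CONDITIONS, n_rooms))
    if len(schedule) == 0:
        return out
    for (run, cond), sub in schedule.groupby(["run", "trial_type"]):
        w = np.bincount(sub["room_type"].to_numpy() - 1, minlength=n_rooms)
        out[int(run), int(cond) - 1] = w / w.sum()
    return out


def simulate_betas(
    config: SimulationConfig,
    schedule: pd.DataFrame | None = None,
    rois: tuple[str, ...] = ROIS,
    roi_gain: dict[str, float] | None = None,
    scenario: tuple[tuple[int, int], ...] | None = None,
    room_resolved: bool = False,
) -> SimulatedExperiment:
    """Simulate run-level condition betas for every subject / ROI / hemisphere.

    Each run's voxels x conditions array is baseline + subject map +
    condition mean boosts + ego-motion pattern + room-texture pattern +
    iid Gaussian noise at ``noise_sd_run``. With ``room_resolved=True``
    the condition axis is expanded to the condition x room cells actually
    presented (one per event repetition), as a room-resolved GLM would
    estimate them.
    """
    if schedule is None:
        schedule = generate_event_schedule(config)
    roi_gain = roi_gain or {}
    gt = _make_ground_truth(config, rois, roi_gain)
    usable = usable_run_scenarios(config, scenario)
    rng = config.rng(3)
    dir_idx = np.array([gt.ego_direction_index[c] for c in range(1, 11)])

    if room_resolved:
        labels = (
            schedule[["run", "trial_type", "room_type"]]
            .drop_duplicates()
            .sort_values(["run", "trial_type", "room_type"])
            .reset_index(drop=True)
        )
    else:
        labels = None
        room_w = None
        if config.room_texture_code > 0:
            room_w = _room_means_by_condition(schedule, config.n_runs, config.n_rooms)

    betas: dict[tuple[str, str], np.ndarray] = {}
    for roi in rois:
        for hemi in HEMISPHERES:
            key = (roi, hemi)
            if room_resolved:
                arr = _room_resolved_betas(config, gt, key, labels, dir_idx, rng)
            else:
                base = (
                    config.baseline
                    + gt.subject_maps[key][:, None, None, :]
                    + gt.mean_boosts[key][None, None, :, None]
                    + gt.ego_patterns[key][:, dir_idx, :][:, None, :, :]
                )
                room_component = 0.0
                if room_w is not None:
                    room_component = np.einsum(
                        "rcm,smv->srcv", room_w, gt.room_patterns[key]
                    )
                noise = rng.normal(
                    0.0,
                    config.noise_sd_run,
                    (config.n_subjects, config.n_runs, N_CONDITIONS, config.n_voxels),
                )
                arr = base + room_component + noise
            betas[key] = arr
    return SimulatedExperiment(
        config=config,
        condition_table=build_condition_table(),
        schedule=schedule,
        usable_runs=usable,
        betas=betas,
        ground_truth=gt,
        cell_labels=labels,
    )


def _room_resolved_betas(config, gt, key, labels, dir_idx, rng):
    """Cells = condition x room pairs actually shown; one beta per cell."""
    n_cells_per_run = labels.groupby("run").size().iloc[0]
    arr = np.empty(
        (config.n_subjects, config.n_runs, n_cells_per_run, config.n_voxels)
    )
    for run, sub in labels.groupby("run"):
        conds = sub["trial_type"].to_numpy() - 1
        rooms = sub["room_type"].to_numpy() - 1
        cell = (
            config.baseline
            + gt.subject_maps[key][:, None, :]
            + gt.mean_boosts[key][None, conds, None]
            + gt.ego_patterns[key][:, dir_idx[conds], :]
            + gt.room_patterns[key][:, rooms, :]
        )
        noise = rng.normal(
            0.0,
            config.noise_sd_run,
            (config.n_subjects, n_cells_per_run, config.n_voxels),
        )
        arr[:, int(run)] = cell + noise
    return arr


# ---------------------------------------------------------------------------
# BOLD-level simulation
# ---------------------------------------------------------------------------

def simulate_bold(
    config: SimulationConfig,
    schedule: pd.DataFrame | None = None,
    rois: tuple[str, ...] = ("OPA",),
    roi_gain: dict[str, float] | None = None,
):
    """Simulate voxel x volume BOLD time series per subject / ROI / hemi / run.

    The time series is the event-related design matrix (boxcars convolved
    with the double-gamma HRF) times the noiseless per-voxel condition
    amplitudes, plus white Gaussian noise at ``noise_sd_run``. Returns
    ``(bold, amplitudes, ground_truth, schedule)`` where ``bold[(roi,
    hemi)]`` is (n_subjects, n_runs, n_voxels, n_volumes) and
    ``amplitudes`` holds the injected (n_subjects, n_runs, 10, n_voxels)
    condition amplitudes the GLM should recover.
    """
    from .glm import build_design_matrix  # deferred: avoids import cycle

    if config.level != "bold":
        raise ValueError("simulate_bold requires config.level='bold'")
    if schedule is None:
        schedule = generate_event_schedule(config)
    if len(schedule):
        span = (schedule["onset"] + schedule["duration"]).max()
        if span > config.run_length_s:
            raise SchedulingError(
                f"schedule spans {span:.1f} s but the run acquires only "
                f"{config.run_length_s:.1f} s"
            )
    roi_gain = roi_gain or {}
    gt = _make_ground_truth(config, rois, roi_gain)
    rng = config.rng(4)
    dir_idx = np.array([gt.ego_direction_index[c] for c in range(1, 11)])
    room_w = _room_means_by_condition(schedule, config.n_runs, config.n_rooms)

    designs = [
        build_design_matrix(
            schedule[schedule["run"] == r], config.n_volumes, config.tr,
            drift_cutoff=None, include_constant=False,
        )
        for r in range(config.n_runs)
    ]
    task_cols = [f"cond_{c}" for c in range(1, 11)]

    bold: dict[tuple[str, str], np.ndarray] = {}
    amplitudes: dict[tuple[str, str], np.ndarray] = {}
    for roi in rois:
        for hemi in HEMISPHERES:
            key = (roi, hemi)
            amp = (
                config.baseline * 0.0  # baseline absorbed by the constant regressor
                + gt.subject_maps[key][:, None, None, :]
                + gt.mean_boosts[key][None, None, :, None]
                + gt.ego_patterns[key][:, dir_idx, :][:, None, :, :]
                + np.einsum("rcm,smv->srcv", room_w, gt.room_patterns[key])
            )
            ts = np.empty(
                (config.n_subjects, config.n_runs, config.n_voxels, config.n_volumes)
            )
            for r in range(config.n_runs):
                X = designs[r][task_cols].to_numpy()  # (n_volumes, 10)
                ts[:, r] = np.einsum("tc,scv->svt", X, amp[:, r])
            ts += rng.normal(0.0, config.noise_sd_run, ts.shape)
            bold[key] = ts
            amplitudes[key] = amp
    return bold, amplitudes, gt, schedule


# ---------------------------------------------------------------------------
# Localizer simulation (for ROI selection)
# ---------------------------------------------------------------------------

LOCALIZER_CATEGORIES = ("scenes", "objects", "faces", "scrambled")


def simulate_localizer(
    config: SimulationConfig,
    n_mask_voxels: int = 100,
    scene_selectivity: float = 2.0,
    visual_gain: float = 3.0,
    noise_sd: float = 1.0,
    rois: tuple[str, ...] = ROIS,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-voxel localizer category responses within each candidate mask.

    Every mask voxel responds to all categories (``visual_gain`` over the
    fixation baseline of zero); in scene ROIs a graded scene-selective
    component (strongest at the mask core, tapering outward) rides on
    top, so ranking by scenes > objects recovers the intended top voxels.
    EVC voxels carry a graded overall visual response instead, matching
    its all-conditions > fixation selection contrast.

    Returns per (roi, hemisphere) a list of per-subject voxels x
    categories DataFrames, each carrying a ``.attrs['source'] =
    'localizer'`` provenance tag.
    """
    rng = config.rng(6)
    out: dict[tuple[str, str], pd.DataFrame] = {}
    profile = np.linspace(1.0, 0.0, n_mask_voxels)  # graded selectivity core->edge
    for roi in rois:
        for hemi in HEMISPHERES:
            resp = np.empty((config.n_subjects, n_mask_voxels, 4))
            gain = visual_gain * (
                1.0 + 0.5 * profile if roi == "EVC" else np.ones(n_mask_voxels)
            )
            resp[:] = gain[None, :, None]
            if roi != "EVC":
                resp[..., 0] += scene_selectivity * profile
            resp += rng.normal(0.0, noise_sd, resp.shape)
            for s in range(config.n_subjects):
                df = pd.DataFrame(resp[s], columns=list(LOCALIZER_CATEGORIES))
                df.attrs["source"] = "localizer"
                out.setdefault((roi, hemi), []).append(df)
    return out
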