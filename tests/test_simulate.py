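"""Synthetic experiment generator: design structure and injected signal."""

import numpy as np
import pandas as pd
import pytest

from navscene import (
    SchedulingError,
    SimulationConfig,
    build_condition_table,
    condition_groups,
    demo_effects,
    design_summary,
    generate_event_schedule,
    paper_exclusion_counts,
    simulate_betas,
    simulate_bold,
    simulate_localizer,
    usable_run_scenarios,
)
from navscene.simulate import ISI_MAX_S, ISI_MIN_S, STIM_DURATION_S


class TestConditionTable:
    def test_factorial_structure(self):
        tab = build_condition_table()
        assert len(tab) == 10
        assert list(tab["condition_id"]) == list(range(1, 11))
        groups = condition_groups()
        assert groups["ego_motion"]["forward"] == (1, 2, 3)
        assert groups["ego_motion"]["backward"] == (4, 5, 6)
        assert groups["ego_motion"]["left_turn"] == (7, 8)
        assert groups["ego_motion"]["right_turn"] == (9, 10)
        assert groups["affordance"]["both"] == (1, 4)
        assert groups["consistency"]["consistent"] == (7, 10)
        assert groups["consistency"]["inconsistent"] == (8, 9)

    def test_turn_toward_door_is_consistent(self):
        tab = build_condition_table().set_index("condition_id")
        assert tab.loc[7, "affordance"] == "left"
        assert tab.loc[7, "ego_motion"] == "left_turn"
        assert tab.loc[7, "consistency"] == "consistent"
        assert tab.loc[1, "affordance"] == "both"
        assert tab.loc[1, "ego_motion"] == "forward"
        # turns never have doorways on both sides
        turns = tab[tab["ego_motion"].isin(["left_turn", "right_turn"])]
        assert not (turns["affordance"] == "both").any()


class TestEventSchedule:
    def test_event_counts_and_timing(self):
        cfg = SimulationConfig(seed=1)
        sch = generate_event_schedule(cfg)
        assert len(sch) == 40 * cfg.n_runs
        assert (sch["duration"] == STIM_DURATION_S).all()
        per_run = sch.groupby(["run", "trial_type"]).size()
        assert (per_run == 4).all()
        assert (sch.groupby("trial_type").size() == 32).all()
        for _, run in sch.groupby("run"):
            onsets = run["onset"].to_numpy()
            assert np.all(np.diff(onsets) > 0)
            gaps = np.diff(onsets) - STIM_DURATION_S
            assert gaps.min() >= ISI_MIN_S - 1e-9
            assert gaps.max() <= ISI_MAX_S + 1e-9
            assert onsets[-1] + STIM_DURATION_S <= cfg.run_length_s

    def test_deterministic_given_seed(self):
        a = generate_event_schedule(SimulationConfig(seed=7))
        b = generate_event_schedule(SimulationConfig(seed=7))
        pd.testing.assert_frame_equal(a, b)
        c = generate_event_schedule(SimulationConfig(seed=8))
        assert not a["onset"].equals(c["onset"])

    def test_zero_reps_empty(self):
        sch = generate_event_schedule(SimulationConfig(seed=1, reps_per_run=0))
        assert len(sch) == 0

    def test_infeasible_packing_raises(self):
        with pytest.raises(SchedulingError):
            generate_event_schedule(SimulationConfig(seed=1, n_volumes=50))

    def test_room_counterbalance(self):
        sch = generate_event_schedule(SimulationConfig(seed=3))
        counts = sch.groupby(["trial_type", "room_type"]).size().unstack(fill_value=0)
        assert counts.shape == (10, 8)
        balanced = 32 / 8
        assert (np.abs(counts - balanced) <= 1).all().all()

    def test_design_summary_arithmetic(self):
        s = design_summary()
        assert s["localizer_block_s"] == 15.0
        assert s["localizer_run_s"] == 315.0
        assert s["reps_per_condition_total"] == 32


class TestUsableRuns:
    def test_study_exclusion_scenario(self):
        cfg = SimulationConfig(seed=2)
        counts = usable_run_scenarios(cfg, paper_exclusion_counts())
        assert sorted(counts, reverse=True) == [8] * 12 + [6] + [5] * 3

    def test_uniform_default(self):
        counts = usable_run_scenarios(SimulationConfig(seed=2))
        assert (counts == 8).all()

    def test_too_few_runs_rejected(self):
        cfg = SimulationConfig(seed=2)
        with pytest.raises(ValueError, match="split-half"):
            usable_run_scenarios(cfg, ((1, 16),))
        with pytest.raises(ValueError, match="covers"):
            usable_run_scenarios(cfg, ((8, 10),))


class TestBetaSimulation:
    def test_pure_baseline_when_silent(self):
        cfg = SimulationConfig(
            seed=5, n_subjects=2, n_voxels=4, noise_sd_run=0.0, noise_sd_subject=0.0
        )
        exp = simulate_betas(cfg, rois=("OPA",))
        for arr in exp.betas.values():
            assert np.allclose(arr, cfg.baseline)

    def test_determinism_bit_identical(self):
        kw = dict(seed=6, n_subjects=2, **demo_effects())
        a = simulate_betas(SimulationConfig(**kw), rois=("OPA",))
        b = simulate_betas(SimulationConfig(**kw), rois=("OPA",))
        for k in a.betas:
            np.testing.assert_array_equal(a.betas[k], b.betas[k])

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError, match="must be >= 0"):
            SimulationConfig(seed=1, affordance_contra=-0.5)

    def test_contralateral_door_boost_expectation(self):
        """Monte-Carlo mean matches the closed-form injected boost.

        In the right hemisphere, conditions with a left-side doorway
        (2, 5) should exceed right-side single-door conditions (3, 6) by
        exactly affordance_contra * noise_sd_run in expectation.
        """
        delta = 0.8
        cfg = SimulationConfig(
            seed=11, n_subjects=300, n_runs=4, n_voxels=8,
            affordance_contra=delta, noise_sd_run=1.0,
        )
        exp = simulate_betas(cfg, rois=("OPA",))
        arr = exp.betas[("OPA", "right")]  # (subj, run, cond, vox)
        contra = arr[:, :, [1, 4]].mean()  # conditions 2, 5 (0-based 1, 4)
        ipsi = arr[:, :, [2, 5]].mean()
        n_obs = cfg.n_subjects * cfg.n_runs * 2 * cfg.n_voxels
        se = np.sqrt(2 * (cfg.noise_sd_run**2 + cfg.noise_sd_subject**2) / n_obs)
        assert abs((contra - ipsi) - delta) < 3 * se

    def test_room_patterns_raise_same_room_similarity(self):
        """Same-room voxel patterns correlate more than different-room ones."""
        cfg = SimulationConfig(
            seed=12, n_subjects=40, n_runs=2, n_voxels=30, room_texture_code=1.5
        )
        exp = simulate_betas(cfg, rois=("OPA",), room_resolved=True)
        arr = exp.betas[("OPA", "left")]
        labels = exp.cell_labels
        same, diff = [], []
        for s in range(cfg.n_subjects):
            rooms = {
                r: labels.loc[labels["run"] == r, "room_type"].to_numpy()
                for r in range(2)
            }
            a, b = arr[s, 0], arr[s, 1]
            a = a - a.mean(axis=0)
            b = b - b.mean(axis=0)
            for i in range(len(rooms[0])):
                for j in range(len(rooms[1])):
                    r = np.corrcoef(a[i], b[j])[0, 1]
                    (same if rooms[0][i] == rooms[1][j] else diff).append(r)
        assert np.mean(same) > np.mean(diff) + 0.05

    def test_null_decoding_diffs_center_on_zero(self):
        """No injected signal: decoding difference has mean 0 over replicates."""
        from navscene import build_hypothesis_matrix, decode_run_stack, score_decoding

        cfg = SimulationConfig(seed=13, n_subjects=1000, n_runs=4, n_voxels=20)
        exp = simulate_betas(cfg, rois=("OPA",))
        hyp = build_hypothesis_matrix("affordance_overall")
        diffs = [
            score_decoding(decode_run_stack(exp.pattern_stack(s, "OPA")), hyp).diff
            for s in range(cfg.n_subjects)
        ]
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert abs(diffs.mean()) < 3 * se

    def test_decoding_monotone_in_effect_size(self):
        """Mean decoding diff is non-decreasing over an effect-size grid."""
        from navscene import build_hypothesis_matrix, decode_run_stack, score_decoding

        hyp = build_hypothesis_matrix("affordance_overall")
        means = []
        for effect in (0.0, 0.5, 1.0):
            cfg = SimulationConfig(
                seed=14, n_subjects=200, n_runs=4, n_voxels=20,
                affordance_contra=effect,
            )
            exp = simulate_betas(cfg, rois=("OPA",))
            diffs = [
                score_decoding(
                    decode_run_stack(exp.pattern_stack(s, "OPA")), hyp
                ).diff
                for s in range(cfg.n_subjects)
            ]
            means.append(np.mean(diffs))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0]  # grid endpoints clearly separated


class TestBoldSimulation:
    def test_volume_count_and_shapes(self):
        cfg = SimulationConfig(
            seed=21, n_subjects=1, n_runs=2, n_voxels=3, level="bold"
        )
        bold, amp, gt, sch = simulate_bold(cfg, rois=("OPA",))
        assert bold[("OPA", "left")].shape == (1, 2, 3, 228)
        assert amp[("OPA", "left")].shape == (1, 2, 10, 3)

    def test_single_event_matches_hrf_shape(self):
        """Noise-free single event: time series proportional to the HRF."""
        from navscene.glm import build_design_matrix

        sch = pd.DataFrame(
            {"run": [0], "onset": [10.0], "duration": [2.5],
             "trial_type": [1], "room_type": [1]}
        )
        X = build_design_matrix(sch, 60, 2.0, drift_cutoff=None,
                                include_constant=False)
        col = X["cond_1"].to_numpy()
        assert np.allclose(col[:5], 0)  # causal: nothing before onset
        assert col.max() > 0
        peak_t = 2.0 * col.argmax()
        assert 10 + 4 <= peak_t <= 10 + 2.5 + 7

    def test_level_validation(self):
        cfg = SimulationConfig(seed=1)
        with pytest.raises(ValueError, match="level='bold'"):
            simulate_bold(cfg)


class TestLocalizerSimulation:
    def test_provenance_and_shape(self):
        cfg = SimulationConfig(seed=31, n_subjects=2)
        loc = simulate_localizer(cfg, n_mask_voxels=40, rois=("OPA", "EVC"))
        frames = loc[("OPA", "left")]
        assert len(frames) == 2
        assert frames[0].shape == (40, 4)
        assert frames[0].attrs["source"] == "localizer"

    def test_scene_selectivity_in_scene_rois_only(self):
        cfg = SimulationConfig(seed=32, n_subjects=6)
        loc = simulate_localizer(cfg, n_mask_voxels=80, noise_sd=0.2)
        opa = pd.concat(loc[("OPA", "left")])
        evc = pd.concat(loc[("EVC", "left")])
        assert (opa["scenes"] - opa["objects"]).mean() > 0.3
        assert abs((evc["scenes"] - evc["objects"]).mean()) < 0.1
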