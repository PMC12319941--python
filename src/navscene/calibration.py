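"""Repeated-experiment sweeps: null calibration and signal recovery.

Runs many independent seeded experiments at the study's scale (16
subjects, 8 runs, 50 voxels per hemisphere ROI) and summarizes the
behavior of the group tests:

* under the null (all effect sizes zero), the one-tailed decoding test
  and the one-tailed paired t on a lateralized contrast should reject at
  the nominal alpha;
* with signal injected at one within-run noise SD, the corresponding
  decoding schemes and lateralized contrasts should be significant at
  the group level in nearly every experiment, while the consistency
  effect must appear for contralateral turns only.

Each experiment draws its own seed from a root seed, so sweeps are fully
reproducible and experiments mutually independent.
"""

from __future__ import annotations

import numpy as np

from .contrasts import (
    condition_means,
    consistency_by_field_contrast,
    contra_door_contrast,
    turn_direction_contrast,
)
from .decoding import (
    build_hypothesis_matrix,
    decode_run_stack,
    group_decoding_test,
    score_decoding,
)
from .simulate import SimulationConfig, generate_event_schedule, simulate_betas
from .stats import paired_t

__all__ = ["null_calibration", "recovery_sweep", "experiment_config"]

RECOVERY_EFFECTS = {
    "affordance_contra": 1.0,
    "ego_motion_code": 1.0,
    "turn_contra_bias": 1.0,
    "consistency_gain": 1.0,
}

# which analyses carry each injected component
RECOVERY_ANALYSES = (
    ("decoding", "affordance_overall"),
    ("decoding", "egomotion_overall"),
    ("decoding", "conflict"),
    ("contrast", "contra_door"),
    ("contrast", "turn_direction"),
    ("contrast", "consistency_contra_turns"),
)


def experiment_config(seed: int, **effects) -> SimulationConfig:
    """One study-scale experiment: 16 subjects, 8 runs, 50 voxels/hemisphere."""
    return SimulationConfig(seed=int(seed), **effects)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _subject_diffs(exp, hypothesis):
    return np.array([
        score_decoding(decode_run_stack(exp.pattern_stack(s, "OPA")), hypothesis).diff
        for s in range(exp.config.n_subjects)
    ])


def null_calibration(
    n_experiments: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    scheme: str = "affordance_overall",
) -> dict[str, float]:
    """False-positive rates of the group tests under a signal-free null.

    Each experiment simulates run betas with every effect at zero, then
    applies (i) the one-tailed group decoding test for ``scheme`` and
    (ii) a one-tailed paired t on the contralateral-door contrast.
    Returns the rejection rates and their binomial standard error.
    """
    hyp = build_hypothesis_matrix(scheme)
    template = experiment_config(0)
    schedule = generate_event_schedule(template)
    dec_hits = t_hits = 0
    for s in _child_seeds(seed, n_experiments):
        cfg = experiment_config(s)
        exp = simulate_betas(cfg, schedule=schedule, rois=("OPA",))
        dec_hits += group_decoding_test(_subject_diffs(exp, hyp)).p < alpha
        means = condition_means(exp.betas, exp.usable_runs)
        diffs = [
            contra_door_contrast(means, subj, "OPA").diff
            for subj in range(cfg.n_subjects)
        ]
        t_hits += paired_t(np.asarray(diffs), tails=1).p < alpha
    se = float(np.sqrt(alpha * (1 - alpha) / n_experiments))
    return {
        "decoding_rejection_rate": dec_hits / n_experiments,
        "paired_t_rejection_rate": t_hits / n_experiments,
        "alpha": alpha,
        "binomial_se": se,
        "n_experiments": n_experiments,
    }


def recovery_sweep(n_experiments: int = 200, seed: int = 1) -> dict:
    """Detection rates with every recovery component at 1 noise SD.

    For each simulated experiment, records whether each analysis in
    ``RECOVERY_ANALYSES`` is positive and significant (one-tailed
    p < .05) at the group level, plus the group-mean consistency effect
    for contralateral and ipsilateral turns.
    """
    hyps = {
        name: build_hypothesis_matrix(name)
        for kind, name in RECOVERY_ANALYSES if kind == "decoding"
    }
    template = experiment_config(0, **RECOVERY_EFFECTS)
    schedule = generate_event_schedule(template)
    hits = {key: 0 for key in RECOVERY_ANALYSES}
    contra_means, ipsi_means = [], []
    for s in _child_seeds(seed, n_experiments):
        cfg = experiment_config(s, **RECOVERY_EFFECTS)
        exp = simulate_betas(cfg, schedule=schedule, rois=("OPA",))
        means = condition_means(exp.betas, exp.usable_runs)
        for kind, name in RECOVERY_ANALYSES:
            if kind == "decoding":
                diffs = _subject_diffs(exp, hyps[name])
            else:
                diffs = np.array([
                    _contrast_diff(means, subj, name)
                    for subj in range(cfg.n_subjects)
                ])
            res = paired_t(diffs, tails=1)
            hits[(kind, name)] += (res.p < 0.05) and (diffs.mean() > 0)
        c_diffs, i_diffs = [], []
        for subj in range(cfg.n_subjects):
            c, i = consistency_by_field_contrast(means, subj, "OPA")
            c_diffs.append(c.diff)
            i_diffs.append(i.diff)
        contra_means.append(np.mean(c_diffs))
        ipsi_means.append(np.mean(i_diffs))
    ipsi = np.asarray(ipsi_means)
    return {
        "detection_rates": {
            f"{kind}:{name}": hits[(kind, name)] / n_experiments
            for kind, name in RECOVERY_ANALYSES
        },
        "consistency_contra_mean": float(np.mean(contra_means)),
        "consistency_ipsi_mean": float(ipsi.mean()),
        "consistency_ipsi_se": float(ipsi.std(ddof=1) / np.sqrt(ipsi.size)),
        "n_experiments": n_experiments,
    }


def _contrast_diff(means, subject, name) -> float:
    if name == "contra_door":
        return contra_door_contrast(means, subject, "OPA").diff
    if name == "turn_direction":
        return turn_direction_contrast(means, subject, "OPA").diff
    if name == "consistency_contra_turns":
        return consistency_by_field_contrast(means, subject, "OPA")[0].diff
    raise ValueError(f"unknown contrast {name!r}")
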