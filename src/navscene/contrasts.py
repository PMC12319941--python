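"""ROI-mean condition responses and hemisphere-resolved contrasts.

Univariate analyses average all voxels of an ROI within each run, then
average across runs (run-then-grand order), yielding one response per
subject x ROI x hemisphere x condition. Contrasts that hinge on the
visual hemifield of the manipulated feature (doorway side, turn
direction) are computed per hemisphere — each hemisphere's contralateral
cell drawing on the conditions whose feature lies in the opposite
hemifield — and then averaged across hemispheres; whole-field contrasts
(forward vs backward) average hemispheres first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import HEMISPHERES

__all__ = [
    "LateralizedContrast",
    "condition_means",
    "contra_door_contrast",
    "forward_backward_contrast",
    "turn_direction_contrast",
    "consistency_by_field_contrast",
    "contrast_table",
]


@dataclass(frozen=True)
class LateralizedContrast:
    """Hemisphere-averaged contralateral vs ipsilateral contrast."""

    name: str
    contra: float
    ipsi: float

    @property
    def diff(self) -> float:
        return self.contra - self.ipsi


def condition_means(
    betas: dict,
    usable_runs,
    selections: dict | None = None,
    rois=None,
) -> pd.DataFrame:
    """Long table of ROI-mean responses per subject/ROI/hemisphere/condition.

    ``betas[(roi, hemi)]`` is (n_subjects, n_runs, n_conditions,
    n_voxels); ``selections[(roi, hemi)]`` optionally restricts to
    selected voxel indices, either one array shared by all subjects or a
    per-subject list of arrays (subject-specific top-50 ROIs). Voxels
    are averaged within each usable run first, runs averaged second.
    """
    rows = []
    keys = list(betas) if rois is None else [k for k in betas if k[0] in rois]
    for (roi, hemi) in keys:
        arr = betas[(roi, hemi)]
        n_subjects = arr.shape[0]
        vox = None
        if selections is not None:
            vox = selections[(roi, hemi)]
            per_subject = isinstance(vox, (list, tuple))
        for s in range(n_subjects):
            sub = arr[s]
            if vox is not None:
                ids = np.asarray(vox[s] if per_subject else vox, dtype=int)
                if ids.size == 0:
                    raise ValueError(f"empty ROI {roi}/{hemi}")
                sub = sub[:, :, ids]
            if sub.shape[-1] == 0:
                raise ValueError(f"empty ROI {roi}/{hemi}")
            runs = np.arange(int(np.asarray(usable_runs)[s]))
            per_run = sub[runs].mean(axis=-1)  # (runs, conditions) voxel means
            resp = per_run.mean(axis=0)  # then across runs
            for c, v in enumerate(resp, start=1):
                rows.append((s, roi, hemi, c, float(v)))
    return pd.DataFrame(
        rows, columns=["subject", "roi", "hemisphere", "condition", "response"]
    )


def _subject_means(means: pd.DataFrame, subject: int, roi: str) -> dict:
    """{(hemisphere, condition): response} for one subject and ROI."""
    sub = means[(means["subject"] == subject) & (means["roi"] == roi)]
    for hemi in HEMISPHERES:
        if hemi not in set(sub["hemisphere"]):
            raise ValueError(f"missing hemisphere {hemi!r} for roi {roi!r}")
    return {
        (r.hemisphere, int(r.condition)): r.response for r in sub.itertuples()
    }


def _require(m: dict, conditions) -> None:
    missing = [
        c for c in conditions
        if any((h, c) not in m for h in HEMISPHERES)
    ]
    if missing:
        raise ValueError(f"missing condition means for conditions {missing}")


def contra_door_contrast(means: pd.DataFrame, subject: int, roi: str) -> LateralizedContrast:
    """Contralateral doors vs paintings, averaged across hemispheres.

    Single-door forward/backward conditions only ({2, 5} door left,
    {3, 6} door right). For the right hemisphere the contralateral-door
    cell averages the left-door conditions (and vice versa); the
    ipsilateral cell is the mirror assignment. diff = contra - ipsi.
    """
    m = _subject_means(means, subject, roi)
    _require(m, (2, 3, 5, 6))
    left_door, right_door = (2, 5), (3, 6)
    contra = np.mean(
        [m[("right", c)] for c in left_door] + [m[("left", c)] for c in right_door]
    )
    ipsi = np.mean(
        [m[("right", c)] for c in right_door] + [m[("left", c)] for c in left_door]
    )
    return LateralizedContrast("contra_door", float(contra), float(ipsi))


def forward_backward_contrast(means: pd.DataFrame, subject: int, roi: str) -> float:
    """Forward (1-3) minus backward (4-6) response, whole visual field.

    Hemisphere-averaged: the manipulation spans the full field, so no
    lateralization is expected.
    """
    m = _subject_means(means, subject, roi)
    _require(m, range(1, 7))
    fwd = np.mean([m[(h, c)] for h in HEMISPHERES for c in (1, 2, 3)])
    bwd = np.mean([m[(h, c)] for h in HEMISPHERES for c in (4, 5, 6)])
    return float(fwd - bwd)


def turn_direction_contrast(means: pd.DataFrame, subject: int, roi: str) -> LateralizedContrast:
    """Contralateral vs ipsilateral turns, averaged across hemispheres.

    Left turns ({7, 8}) are contralateral for the right hemisphere,
    right turns ({9, 10}) for the left hemisphere. diff = contra - ipsi.
    """
    m = _subject_means(means, subject, roi)
    _require(m, (7, 8, 9, 10))
    left_turns, right_turns = (7, 8), (9, 10)
    contra = np.mean(
        [m[("right", c)] for c in left_turns] + [m[("left", c)] for c in right_turns]
    )
    ipsi = np.mean(
        [m[("right", c)] for c in right_turns] + [m[("left", c)] for c in left_turns]
    )
    return LateralizedContrast("turn_direction", float(contra), float(ipsi))


def consistency_by_field_contrast(
    means: pd.DataFrame, subject: int, roi: str
) -> tuple[LateralizedContrast, LateralizedContrast]:
    """Consistent minus inconsistent turns, split by turn visual field.

    Among turns toward a hemisphere's contralateral field, the
    consistent condition is the turn toward the doorway (7 for the right
    hemisphere, 10 for the left) and the inconsistent one the turn away
    (8 right, 9 left); analogously for ipsilateral turns. Both values
    are hemisphere-averaged. Returned as (contralateral_turns,
    ipsilateral_turns), each with contra=consistent, ipsi=inconsistent,
    so ``diff`` is the consistency effect within that field.
    """
    m = _subject_means(means, subject, roi)
    _require(m, (7, 8, 9, 10))
    # contralateral turns: right hemi sees left turns (7 cons, 8 incons);
    # left hemi sees right turns (10 cons, 9 incons)
    cons_contra = np.mean([m[("right", 7)], m[("left", 10)]])
    incons_contra = np.mean([m[("right", 8)], m[("left", 9)]])
    # ipsilateral turns: right hemi right turns (10 cons, 9 incons); mirrored
    cons_ipsi = np.mean([m[("right", 10)], m[("left", 7)]])
    incons_ipsi = np.mean([m[("right", 9)], m[("left", 8)]])
    return (
        LateralizedContrast(
            "consistency_contra_turns", float(cons_contra), float(incons_contra)
        ),
        LateralizedContrast(
            "consistency_ipsi_turns", float(cons_ipsi), float(incons_ipsi)
        ),
    )


def contrast_table(means: pd.DataFrame) -> pd.DataFrame:
    """All contrasts for every subject x ROI present in a means table.

    Long format (subject, roi, contrast, contra, ipsi, diff); the
    whole-field forward-vs-backward contrast stores its value in ``diff``
    with contra/ipsi unset.
    """
    rows = []
    pairs = means[["subject", "roi"]].drop_duplicates().itertuples(index=False)
    for subject, roi in pairs:
        lat = [contra_door_contrast(means, subject, roi),
               turn_direction_contrast(means, subject, roi)]
        lat.extend(consistency_by_field_contrast(means, subject, roi))
        for c in lat:
            rows.append((subject, roi, c.name, c.contra, c.ipsi, c.diff))
        fb = forward_backward_contrast(means, subject, roi)
        rows.append((subject, roi, "forward_backward", np.nan, np.nan, fb))
    return pd.DataFrame(
        rows, columns=["subject", "roi", "contrast", "contra", "ipsi", "diff"]
    )
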