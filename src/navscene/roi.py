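"""Functional ROI definition: top-N voxel selection within a mask.

Fixed-size functional ROIs are the N voxels with the largest selection
statistic inside a (hand-defined or anatomical) candidate mask, per
hemisphere, with no contiguity requirement. The selection statistic is
a localizer contrast — scenes > objects for the scene-selective regions
(OPA, PPA, MPA) or all conditions > fixation for EVC — and must be
computed from localizer data, never from the experimental runs whose
patterns are later analyzed (enforced via a provenance tag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProvenanceError",
    "ROISelection",
    "selection_statistic",
    "select_top_voxels",
]

SELECTION_SCHEMES = ("scenes_gt_objects", "all_gt_fixation")


class ProvenanceError(ValueError):
    """Selection statistic computed from non-localizer data."""


@dataclass(frozen=True)
class ROISelection:
    """Top-N voxels of one ROI in one hemisphere, ordered by statistic."""

    roi: str
    hemisphere: str
    voxel_ids: np.ndarray  # ordered by statistic, descending
    statistic: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.voxel_ids)
        stat = np.asarray(self.statistic, dtype=float)
        if ids.size != stat.size:
            raise ValueError("voxel ids and statistics must align")
        if len(np.unique(ids)) != ids.size:
            raise ValueError("voxel ids must be unique")
        if ids.size > 1 and np.any(np.diff(stat) > 1e-12):
            raise ValueError("statistic must be non-increasing over the selection")
        object.__setattr__(self, "voxel_ids", ids)
        object.__setattr__(self, "statistic", stat)

    @property
    def n_selected(self) -> int:
        return int(self.voxel_ids.size)


def selection_statistic(responses: pd.DataFrame, scheme: str) -> np.ndarray:
    """Per-voxel localizer contrast used to rank voxels.

    Parameters
    ----------
    responses : DataFrame
        Voxels x categories table of localizer response amplitudes
        relative to the fixation baseline (so ``all_gt_fixation`` is the
        mean over categories). Must carry ``attrs['source'] ==
        'localizer'``: ROI selection may never consume experimental-run
        betas, which would break the independence of selection and test.
    scheme : {"scenes_gt_objects", "all_gt_fixation"}
    """
    source = responses.attrs.get("source")
    if source != "localizer":
        raise ProvenanceError(
            f"selection statistic requires localizer data, got source={source!r}"
        )
    if scheme == "scenes_gt_objects":
        for col in ("scenes", "objects"):
            if col not in responses.columns:
                raise ValueError(f"missing localizer condition {col!r}")
        stat = responses["scenes"] - responses["objects"]
    elif scheme == "all_gt_fixation":
        if responses.shape[1] == 0:
            raise ValueError("no localizer conditions present")
        stat = responses.mean(axis=1)  # responses are relative to fixation
    else:
        raise ValueError(f"unknown selection scheme {scheme!r}")
    return stat.to_numpy(dtype=float)


def select_top_voxels(
    stat_map: np.ndarray,
    mask: np.ndarray | None = None,
    n: int = 50,
    roi: str = "",
    hemisphere: str = "",
    threshold: float | None = None,
) -> ROISelection:
    """The ``n`` largest-statistic voxels within a mask.

    ``mask`` gives the candidate voxel ids (defaults to all voxels of the
    statistic map); selected voxels need not be contiguous. Ties at the
    n-th rank break toward the lowest voxel id, so selection is
    deterministic. ``threshold`` optionally drops mask voxels whose
    statistic falls below it (the map-thresholding step of a hand-drawn
    mask) before ranking.

    If the mask holds fewer than ``n`` voxels, all of them are selected
    and a warning is logged.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if mask is None:
        mask = np.arange(stat_map.size)
    mask = np.asarray(mask, dtype=int)
    if mask.size == 0:
        raise ValueError("empty mask")
    stats = stat_map[mask]
    if not np.all(np.isfinite(stats)):
        raise ValueError("statistic undefined (non-finite) on some mask voxels")
    if threshold is not None:
        keep = stats >= threshold
        mask, stats = mask[keep], stats[keep]
        if mask.size == 0:
            raise ValueError("no mask voxels survive the statistic threshold")
    if mask.size < n:
        logger.warning(
            "mask for %s/%s has %d voxels, fewer than requested n=%d; selecting all",
            roi or "?", hemisphere or "?", mask.size, n,
        )
    # sort by statistic descending, voxel id ascending on ties
    order = np.lexsort((mask, -stats))[: min(n, mask.size)]
    return ROISelection(
        roi=roi,
        hemisphere=hemisphere,
        voxel_ids=mask[order],
        statistic=stats[order],
    )
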