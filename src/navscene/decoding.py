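"""Split-half cross-validated Euclidean-distance decoding.

For each subject, the usable runs are partitioned into all possible
complementary halves; condition patterns are averaged within each half
and the Euclidean distance between every pair of conditions — including
each condition and itself — is computed *across* the two halves, then
averaged over folds. Because the halves are independent, the diagonal
(within-condition) distances are unbiased estimates of pattern
reliability rather than zero, and condition information shows up as
within-pair distances smaller than between-pair distances.

A hypothesis matrix labels every ordered condition pair as within,
between, or excluded; the decoding score is

    diff = mean(between-pair distances) - mean(within-pair distances)

over the labeled cells (each unordered pair counted once), positive
when patterns carry the hypothesized information. Six schemes are
provided: overall and generalization tests of navigational affordance
and ego-motion, the affordance/ego-motion conflict test, and room
texture (computed on room-resolved patterns).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .simulate import build_condition_table
from .stats import TTestResult, paired_t

__all__ = [
    "SCHEMES",
    "WITHIN",
    "BETWEEN",
    "EXCLUDED",
    "DecodingScore",
    "enumerate_folds",
    "cross_split_distances",
    "average_over_folds",
    "build_hypothesis_matrix",
    "score_decoding",
    "group_decoding_test",
    "decode_run_stack",
    "room_pattern_stack",
]

WITHIN, BETWEEN, EXCLUDED = "within", "between", "excluded"

SCHEMES = (
    "affordance_overall",
    "affordance_generalize",
    "egomotion_overall",
    "egomotion_generalize",
    "conflict",
    "room_texture",
)


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def enumerate_folds(usable_runs) -> list[tuple[tuple, tuple]]:
    """All unordered complementary half-partitions of the usable runs.

    Even n: all floor(n/2)-vs-floor(n/2) partitions, each counted once
    (8 runs -> 35 folds). Odd n: all floor-vs-ceil splits (5 runs -> 10
    folds of 2 vs 3).
    """
    runs = sorted(usable_runs)
    n = len(runs)
    if n < 2:
        raise ValueError(f"split-half analysis needs >= 2 usable runs, got {n}")
    k = n // 2
    folds = []
    for half_a in combinations(runs, k):
        half_b = tuple(r for r in runs if r not in half_a)
        if n % 2 == 0 and runs[0] not in half_a:
            continue  # complement already enumerated
        folds.append((half_a, half_b))
    return folds


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def cross_split_distances(half_a_means, half_b_means) -> np.ndarray:
    """Condition x condition Euclidean distances across two split halves.

    Entry (i, j) is the distance between condition i's mean pattern in
    half A and condition j's in half B, symmetrized over fold
    orientation as (d_AB + d_BA^T) / 2 so the result does not depend on
    which half is labeled A.
    """
    a = np.asarray(half_a_means, dtype=float)
    b = np.asarray(half_b_means, dtype=float)
    if a.shape != b.shape:
        raise ValueError(
            f"halves must share condition and voxel sets, got {a.shape} vs {b.shape}"
        )
    d = cdist(a, b)
    return (d + d.T) / 2.0


def average_over_folds(fold_matrices) -> np.ndarray:
    """Element-wise mean of per-fold distance matrices."""
    stack = [np.asarray(m, dtype=float) for m in fold_matrices]
    if len(stack) == 0:
        raise ValueError("no fold matrices supplied")
    shapes = {m.shape for m in stack}
    if len(shapes) > 1:
        raise ValueError(f"fold matrices differ in shape: {shapes}")
    return np.mean(stack, axis=0)


def decode_run_stack(stack: np.ndarray, folds=None) -> np.ndarray:
    """Fold-averaged cross-split distance matrix from a run-beta stack.

    ``stack`` is (n_runs, n_conditions, n_voxels). Vectorized over folds
    (batched half-averaging and pairwise distances); equals running
    :func:`cross_split_distances` per fold and :func:`average_over_folds`,
    which the test suite asserts.
    """
    stack = np.asarray(stack, dtype=float)
    n_runs = stack.shape[0]
    if folds is None:
        folds = enumerate_folds(range(n_runs))
    pos = {r: i for i, r in enumerate(sorted({r for f in folds for h in f for r in h}))}
    wa = np.zeros((len(folds), n_runs))
    wb = np.zeros((len(folds), n_runs))
    for i, (ha, hb) in enumerate(folds):
        wa[i, [pos[r] for r in ha]] = 1.0 / len(ha)
        wb[i, [pos[r] for r in hb]] = 1.0 / len(hb)
    A = np.tensordot(wa, stack, axes=(1, 0))  # (folds, cond, vox)
    B = np.tensordot(wb, stack, axes=(1, 0))
    a2 = np.sum(A * A, axis=-1)
    b2 = np.sum(B * B, axis=-1)
    ab = A @ B.transpose(0, 2, 1)
    d2 = np.clip(a2[:, :, None] + b2[:, None, :] - 2 * ab, 0.0, None)
    d = np.sqrt(d2)
    d = (d + d.transpose(0, 2, 1)) / 2.0
    return d.mean(axis=0)


def room_pattern_stack(cell_stack: np.ndarray, cell_labels: pd.DataFrame,
                       n_rooms: int = 8) -> np.ndarray:
    """Per-run room-mean patterns from room-resolved betas.

    ``cell_stack`` is (n_runs, n_cells, n_voxels) with ``cell_labels``
    giving (run, trial_type, room_type) per cell; returns (n_runs,
    n_rooms, n_voxels) where each room's pattern is the mean over the
    cells of that room within the run.
    """
    cell_stack = np.asarray(cell_stack, dtype=float)
    n_runs = cell_stack.shape[0]
    out = np.empty((n_runs, n_rooms, cell_stack.shape[2]))
    for r in range(n_runs):
        rooms = cell_labels.loc[cell_labels["run"] == r, "room_type"].to_numpy()
        for m in range(n_rooms):
            sel = rooms == m + 1
            if not sel.any():
                raise ValueError(f"room {m + 1} absent from run {r}")
            out[r, m] = cell_stack[r, sel].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Hypothesis matrices
# ---------------------------------------------------------------------------

def _pair_frame(ids) -> pd.DataFrame:
    return pd.DataFrame(EXCLUDED, index=list(ids), columns=list(ids))


def _label(h: pd.DataFrame, i, j, label: str) -> None:
    h.loc[i, j] = label
    h.loc[j, i] = label


def build_hypothesis_matrix(scheme: str, n_rooms: int = 8) -> pd.DataFrame:
    """Condition-pair labels {within, between, excluded} for one scheme.

    Returns a symmetric DataFrame indexed by condition id (room id for
    the ``room_texture`` scheme, which operates on room-mean patterns).
    Self-pairs count as within cells wherever the scheme includes the
    condition, since cross-split distances of a condition to itself are
    meaningful (the halves are independent).

    Schemes
    -------
    affordance_overall
        Conditions 1-6 (turns excluded: turning changes the affordance
        direction mid-trial). Within = pairs sharing the affordance group
        {both: 1,4; left: 2,5; right: 3,6}; between = all other pairs.
    affordance_generalize
        As above, restricted to pairs that differ in ego-motion
        (forward vs backward), so within-pairs are never the same
        stimulus class; self- and same-ego-motion pairs are excluded.
    egomotion_overall
        Groups forward {1,2,3}, backward {4,5,6}, left {7,8}, right
        {9,10}. Within = self/within-group pairs; between only the most
        closely matched pairs: forward vs backward, left vs right turn.
    egomotion_generalize
        As above, with every labeled pair additionally required to
        differ in affordance group.
    conflict
        Consistent turns {7,10} vs inconsistent turns {8,9}: within =
        within-set pairs, between = cross-set pairs.
    room_texture
        Room-mean patterns: within = same room (self-pairs), between =
        different rooms.
    """
    tab = build_condition_table().set_index("condition_id")

    if scheme == "room_texture":
        rooms = range(1, n_rooms + 1)
        h = _pair_frame(rooms)
        for i in rooms:
            for j in rooms:
                h.loc[i, j] = WITHIN if i == j else BETWEEN
        return h

    ids = range(1, 11)
    h = _pair_frame(ids)
    aff = tab["affordance"]
    ego = tab["ego_motion"]

    if scheme in ("affordance_overall", "affordance_generalize"):
        fb = [c for c in ids if ego[c] in ("forward", "backward")]
        for i, j in combinations(fb, 2):
            same_aff = aff[i] == aff[j]
            if scheme == "affordance_generalize" and ego[i] == ego[j]:
                continue  # same-ego-motion pairs excluded in the generalization test
            _label(h, i, j, WITHIN if same_aff else BETWEEN)
        if scheme == "affordance_overall":
            for i in fb:
                h.loc[i, i] = WITHIN
    elif scheme in ("egomotion_overall", "egomotion_generalize"):
        matched = {frozenset(("forward", "backward")),
                   frozenset(("left_turn", "right_turn"))}
        for i in ids:
            if scheme == "egomotion_overall":
                h.loc[i, i] = WITHIN
            for j in ids:
                if j <= i:
                    continue
                if scheme == "egomotion_generalize" and aff[i] == aff[j]:
                    continue
                if ego[i] == ego[j]:
                    _label(h, i, j, WITHIN)
                elif frozenset((ego[i], ego[j])) in matched:
                    _label(h, i, j, BETWEEN)
    elif scheme == "conflict":
        consistent = [c for c in ids if tab.loc[c, "consistency"] == "consistent"]
        inconsistent = [c for c in ids if tab.loc[c, "consistency"] == "inconsistent"]
        for group in (consistent, inconsistent):
            for i in group:
                h.loc[i, i] = WITHIN
            for i, j in combinations(group, 2):
                _label(h, i, j, WITHIN)
        for i in consistent:
            for j in inconsistent:
                _label(h, i, j, BETWEEN)
    else:
        raise ValueError(f"unknown decoding scheme {scheme!r}; known: {SCHEMES}")
    return h


# ---------------------------------------------------------------------------
# Scores and group test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecodingScore:
    """Within/between mean cross-split distances and their difference.

    ``diff = between_mean - within_mean`` (arbitrary units of Euclidean
    distance); positive values indicate more similar patterns for
    within- than between-condition pairs, i.e. decodable information.
    """

    within_mean: float
    between_mean: float

    @property
    def diff(self) -> float:
        return self.between_mean - self.within_mean


def score_decoding(distances: np.ndarray, hypothesis: pd.DataFrame) -> DecodingScore:
    """Unweighted within/between means over the labeled distance cells.

    Each unordered condition pair (including self-pairs) contributes one
    cell; the distance matrix must cover the hypothesis matrix's
    condition set.
    """
    d = np.asarray(distances, dtype=float)
    k = len(hypothesis)
    if d.shape != (k, k):
        raise ValueError(
            f"distance matrix {d.shape} does not cover the {k}-condition hypothesis"
        )
    labels = hypothesis.to_numpy()
    iu, ju = np.triu_indices(k)
    cells = labels[iu, ju]
    vals = d[iu, ju]
    within = vals[cells == WITHIN]
    between = vals[cells == BETWEEN]
    if within.size == 0 or between.size == 0:
        raise ValueError("hypothesis matrix must label at least one within "
                         "and one between pair")
    return DecodingScore(
        within_mean=float(within.mean()), between_mean=float(between.mean())
    )


def group_decoding_test(scores, tails: int = 1) -> TTestResult:
    """Group-level paired t-test of within vs between distances.

    ``scores`` is a sequence of per-subject :class:`DecodingScore` (or
    raw difference values). Equivalent to a one-sample t-test of the
    difference scores against zero, one-tailed toward diff > 0 by
    default (the directional prediction of every scheme).
    """
    diffs = np.array(
        [s.diff if isinstance(s, DecodingScore) else float(s) for s in scores]
    )
    return paired_t(diffs, tails=tails, direction="greater")
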