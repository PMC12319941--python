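# Methods

## The design being emulated

The synthetic generator reproduces the statistical skeleton of an
event-related fMRI experiment on navigationally relevant information in
dynamic scenes. Ten conditions cross navigational affordance (an open
doorway to the left, the right, or both sides) with ego-motion direction
(forward, backward, left turn, right turn); the factorial is incomplete by
construction — turns never occur with doorways on both sides, and each turn
is either *toward* its doorway (consistent: conditions 7, 10) or *away*
from it (inconsistent: 8, 9).

Per run, each condition appears 4 times (40 events of 2.5 s), with
inter-stimulus intervals drawn uniformly from 3.5–9.5 s after a 6 s lead-in
and before a ≥10 s trailing rest; 8 runs give 32 repetitions per condition.
Events are packed against a 456 s acquisition (228 volumes at TR = 2 s); if
a jitter draw overshoots, ISIs are shrunk linearly toward the 3.5 s floor,
which preserves the stated bounds. The block-design localizer (four
categories in 15 s blocks of five 2.8 s clips, 315 s runs, 158-volume /
316 s acquisitions) is reproduced as timing arithmetic only — its block
structure is used to define selection statistics, not simulated as time
series. The fixation blocks are taken to be 15 s, the value for which 16
stimulus blocks plus 5 fixation blocks exactly fill the 315 s run.

Eight room textures are rotated across conditions by
`room = perm[(condition_index + 4·run + repetition) mod 8]` with a seeded
permutation `perm`, so over a full design every condition sees every room
exactly 4 times (balanced to ±0; the qualitative counterbalancing of the
original design is not otherwise constrained).

## The response model

For subject *s*, ROI *r*, hemisphere *h*, run *k*, the simulated beta of
condition *c* at voxel *v* is

    β = baseline + m_s(v) + b_h(c)·σ + g_r·σ·[ E_(dir(c))(v) + R_(room)(v) ] + ε,
    ε ~ N(0, σ²)   (σ = noise_sd_run, white within run)

with a subject-stable voxel map `m_s ~ N(0, noise_sd_subject²)` (constant
across conditions, so it cancels from every contrast and distance), and
scalar condition boosts `b_h(c)` assembled from the effect parameters, all
expressed in units of σ:

| parameter | applies to | default |
|---|---|---|
| `affordance_contra` | forward/backward conditions whose doorway falls in hemisphere *h*'s contralateral hemifield (door left → right hemisphere; both-door conditions boost both) | 0 |
| `forward_bias` | forward conditions 1–3 | 0 |
| `turn_contra_bias` | turns toward the contralateral hemifield (left turns → right hemisphere) | 0 |
| `consistency_gain` | the *consistent* contralateral turn only (7 in the right hemisphere, 10 in the left) | 0 |
| `ego_motion_code` | a stable N(0,1) voxel pattern per ego-motion direction | 0 |
| `room_texture_code` | a stable N(0,1) voxel pattern per room type | 0 |

Defaults are zero: the out-of-the-box configuration is an exact null, and
`demo_effects()` raises every component to 1 σ. The doorway-side boost is
deliberately confined to the six forward/backward conditions; turn-condition
means are governed by turn direction and consistency alone. This makes the
contralateral consistency effect dissociable from a mere doorway preference
— with a doorway boost on turns, the ipsilateral consistency contrast would
be biased negative by construction, contradicting the observed-pattern
structure the generator is meant to emulate. At BOLD level the same
amplitudes (without the run-noise term) drive a design-matrix forward model
plus white measurement noise; prewhitening is pointless under white noise,
so estimation is plain OLS.

`GroundTruth` stores every injected component, so tests can predict each
contrast in closed form: e.g. the contralateral-door contrast has
expectation `affordance_contra·σ`, the turn contrast
`(turn_contra_bias + consistency_gain/2)·σ`, and the ipsilateral
consistency contrast exactly 0.

## GLM details

* HRF: difference of two gamma densities, shape = delay/dispersion with
  delays 6 s and 16 s, dispersions 1, undershoot ratio 6, normalized to
  unit peak; zero for t < 0. All parameters overridable per call.
* Boxcars are built on a 10×-oversampled grid (onsets are jittered, not
  TR-locked), convolved, then decimated to volume times i·TR.
* Drift: discrete-cosine basis with cutoff period 120 s (order
  ⌊2·N·TR/cutoff⌋, the SPM/nilearn convention). The filter is a projection,
  hence idempotent, and fitting filtered data with a filtered design equals
  including the drift columns in the design (Frisch–Waugh); both routes are
  exposed and tested. Note that a finite window leaks: a 200 s sinusoid
  retains ~1.2 % of its power after filtering rather than strictly < 1 %.
* Rank-deficient designs raise with the offending columns named; task
  columns default to the conditions actually present in the run.

## ROI selection

Fixed-size functional ROIs are the top-N (default 50) voxels per hemisphere
by a selection statistic inside a candidate mask, without contiguity
constraints; ties at the cutoff break toward the lower voxel id so
selection is deterministic. Scene ROIs rank by scenes − objects, EVC by the
mean localizer response (relative to fixation). Selection inputs carry a
provenance tag and must come from localizer data; passing experimental-run
betas raises, enforcing the independence that makes later tests unbiased.
Masks stand in for hand-drawn clusters; the map-threshold step of manual
definition is available as an optional statistic floor. Subjects missing an
ROI are dropped from analyses involving it, so degrees of freedom follow
the data.

## Decoding

Folds are all unordered complementary half-partitions of the usable runs
(⌊n/2⌋ vs ⌈n/2⌉; 35 folds for 8 runs, 10 for 5). Within a fold, condition
patterns (both hemispheres' selected voxels concatenated) are averaged per
half and Euclidean distances computed across halves, including each
condition against itself — across independent halves the self-distance is a
noise-floor estimate, not zero. Distances are symmetrized over fold
orientation, (d_AB + d_BA)/2, so nothing depends on which half is called A.
No multivariate noise normalization is applied: the raw Euclidean distance
is kept precisely because it mixes pattern shape and overall activation
strength.

Hypothesis matrices label unordered condition pairs:

* *affordance overall* — conditions 1–6 (turns change the affordance
  direction mid-trial and are excluded); within = same affordance group
  {1,4}, {2,5}, {3,6} including self-pairs; between = the rest.
* *affordance generalizing* — restricted to pairs differing in ego-motion,
  so within = {(1,4), (2,5), (3,6)} and self-pairs drop out.
* *ego-motion overall* — within = self/within-direction pairs; between only
  the closely matched stimulus pairs (forward vs backward; left vs right
  turn); everything else excluded.
* *ego-motion generalizing* — additionally requires the pair to differ in
  affordance group.
* *conflict* — consistent {7,10} vs inconsistent {8,9}.
* *room texture* — computed on per-room mean patterns from a room-resolved
  beta estimation (one regressor per condition × room cell); within = same
  room, between = different.

Scores are unweighted means over labeled cells, each unordered pair counted
once (groups contribute cells, not group means), and
`diff = between − within`. The vectorized per-subject fast path
(`decode_run_stack`) is tested to equal the explicit per-fold computation
to 1e-10.

## Group inference

One-tailed paired t-tests (diff > 0) per ROI and scheme; region comparisons
via fully within-subject two-way ANOVA on the (region × within/between)
table with per-effect Greenhouse–Geisser epsilon computed from the
covariance of the data projected onto each effect's orthonormal contrast
subspace. Corrected and uncorrected dfs/ps are always reported side by
side. Post hoc 2×2 interaction contrasts equal a paired t on the double
difference (F = t², verified exactly). GG deflation can only raise p when
F ≥ 1; for F < 1 it can marginally lower it — the implementation reports
the standard correction without clamping, matching pingouin. Power for the
paired design uses the exact noncentral-t distribution (noncentrality
d·√n, df n−1); two-tailed α = .05 at n = 16 gives 84.8 % power at d = 0.8
and 96.8 % at d = 1.02.

## Calibration and recovery conditions

`navscene.calibration` re-runs the full chain over many independent seeded
experiments at study scale (16 subjects, 8 runs, 50 voxels/hemisphere):
null calibration simulates with all effects at 0 and records rejection
rates of the one-tailed decoding test and the contralateral-door paired t
(nominal 0.05); the recovery sweep injects the four recovery components at
1 σ and records group-level detection rates plus the contralateral and
ipsilateral consistency effects. The acceptance suite runs 2000 null and
200 recovery experiments; the acceptance script defaults to 1000 and 100,
which keeps its end-to-end runtime around a minute while leaving binomial
uncertainty on a 5 % rate below 0.7 pp.

## What the synthetic data does and does not show

The generator matches the *assumptions* of the analysis — white run-level
noise, stable subject maps, additive lateralized effects — so passing tests
demonstrate that the pipeline is algebraically correct, statistically
calibrated under its own model, and sensitive at plausible effect sizes.
Real fMRI violates these assumptions (temporal autocorrelation, motion and
physiological artifacts, spatially correlated noise, hemodynamic
nonlinearity, imperfect ROI masks), and none of that is simulated;
consequently the suite says nothing about preprocessing quality or about
the empirical effect sizes in any real dataset. Schedule optimization is
likewise replaced by uniform jitter: design efficiency is realistic but not
optimized.

## Known limitations

* BOLD simulation and fitting assume the same HRF; HRF mismatch is not
  modeled.
* The room-resolved estimation assigns one beta per condition × room cell
  per run (single-event cells), which is noisier than the condition-level
  route; the room scheme should be compared within, not across, estimation
  modes.
* The localizer is simulated at the category-response level (per-voxel
  means), not as time series; selection statistics are therefore exact
  contrasts plus noise.
* `interaction_contrast_2x2` and the ANOVA require complete balanced
  tables; callers drop incomplete subjects first (the pipeline does this
  automatically for missing ROIs).
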