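"""Split-half fold enumeration, cross-split distances, hypothesis schemes."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from navscene import (
    SCHEMES,
    DecodingScore,
    average_over_folds,
    build_condition_table,
    build_hypothesis_matrix,
    cross_split_distances,
    decode_run_stack,
    enumerate_folds,
    group_decoding_test,
    score_decoding,
)
from navscene.decoding import BETWEEN, EXCLUDED, WITHIN


class TestEnumerateFolds:
    @pytest.mark.parametrize("n,expected", [(2, 1), (4, 3), (8, 35), (5, 10), (6, 10)])
    def test_fold_counts(self, n, expected):
        folds = enumerate_folds(range(n))
        assert len(folds) == expected
        # partitions: disjoint, exhaustive, floor/ceil sizes
        for ha, hb in folds:
            assert set(ha) | set(hb) == set(range(n))
            assert not set(ha) & set(hb)
            assert {len(ha), len(hb)} == {n // 2, n - n // 2}
        # unordered: no complement duplicates
        seen = {frozenset(map(frozenset, f)) for f in folds}
        assert len(seen) == expected

    def test_five_runs_two_vs_three(self):
        folds = enumerate_folds(range(5))
        assert all(sorted((len(a), len(b))) == [2, 3] for a, b in folds)

    def test_too_few_runs(self):
        with pytest.raises(ValueError, match=">= 2"):
            enumerate_folds([3])


class TestCrossSplitDistances:
    def test_identical_halves_zero_diagonal(self, rng):
        a = rng.normal(size=(10, 20))
        d = cross_split_distances(a, a)
        assert np.allclose(np.diag(d), 0.0)
        assert np.all(d >= 0)

    def test_three_four_five_triangle(self):
        a = np.array([[0.0, 0.0], [3.0, 4.0]])
        d = cross_split_distances(a, a)
        assert d[0, 1] == pytest.approx(5.0)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 6, 9))
        d = cross_split_distances(a, b)
        for i in range(6):
            for j in range(6):
                dij = np.sqrt(np.sum((a[i] - b[j]) ** 2))
                dji = np.sqrt(np.sum((a[j] - b[i]) ** 2))
                assert d[i, j] == pytest.approx((dij + dji) / 2)
        # orientation-symmetrized
        np.testing.assert_allclose(d, cross_split_distances(b, a).T)
        np.testing.assert_allclose(d, d.T)

    def test_voxel_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="share"):
            cross_split_distances(rng.normal(size=(5, 8)), rng.normal(size=(5, 9)))


class TestAverageOverFolds:
    def test_identity_and_mean(self, rng):
        m = rng.normal(size=(10, 10)) ** 2
        np.testing.assert_array_equal(average_over_folds([m]), m)
        np.testing.assert_allclose(average_over_folds([m, 3 * m]), 2 * m)
        stack = rng.normal(size=(7, 4, 4))
        np.testing.assert_allclose(average_over_folds(list(stack)), stack.mean(0))

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="shape"):
            average_over_folds([np.zeros((3, 3)), np.zeros((4, 4))])


class TestDecodeRunStack:
    def test_equals_per_fold_operations(self, rng):
        """The vectorized fast path reproduces the explicit per-fold route."""
        for n_runs in (5, 8):
            stack = rng.normal(size=(n_runs, 10, 12))
            folds = enumerate_folds(range(n_runs))
            mats = []
            for ha, hb in folds:
                mats.append(
                    cross_split_distances(
                        stack[list(ha)].mean(axis=0), stack[list(hb)].mean(axis=0)
                    )
                )
            np.testing.assert_allclose(
                decode_run_stack(stack), average_over_folds(mats), atol=1e-10
            )

    def test_distance_axioms(self, rng):
        d = decode_run_stack(rng.normal(size=(8, 10, 30)))
        assert np.all(d >= 0)
        np.testing.assert_allclose(d, d.T)
        # identical halves (duplicate runs): zero diagonal on a single fold
        pattern = rng.normal(size=(1, 10, 30))
        dup = np.repeat(pattern, 2, axis=0)
        # sqrt of clipped float error: diagonal vanishes to ~1e-6
        assert np.allclose(np.diag(decode_run_stack(dup)), 0.0, atol=1e-5)


class TestHypothesisMatrices:
    def test_symmetry_and_coverage(self):
        for scheme in SCHEMES:
            h = build_hypothesis_matrix(scheme)
            assert (h.to_numpy() == h.to_numpy().T).all()
            vals = set(h.to_numpy().ravel())
            assert vals <= {WITHIN, BETWEEN, EXCLUDED}
            assert WITHIN in vals and BETWEEN in vals

    def test_affordance_overall_cells(self):
        h = build_hypothesis_matrix("affordance_overall")
        assert h.loc[2, 5] == WITHIN  # same (left) affordance across ego-motion
        assert h.loc[1, 4] == WITHIN
        assert h.loc[2, 2] == WITHIN  # self-pair included
        assert h.loc[2, 3] == BETWEEN
        assert h.loc[1, 7] == EXCLUDED  # turn conditions excluded
        assert (h.loc[7:10, :] == EXCLUDED).all().all()

    def test_affordance_generalize_cells(self):
        h = build_hypothesis_matrix("affordance_generalize")
        assert h.loc[1, 4] == WITHIN
        assert h.loc[2, 5] == WITHIN
        assert h.loc[2, 4] == BETWEEN  # different affordance, different ego-motion
        assert h.loc[1, 2] == EXCLUDED  # same ego-motion excluded
        assert h.loc[2, 2] == EXCLUDED  # self-pairs excluded

    def test_egomotion_overall_cells(self):
        h = build_hypothesis_matrix("egomotion_overall")
        assert h.loc[1, 2] == WITHIN  # both forward
        assert h.loc[7, 8] == WITHIN
        assert h.loc[7, 7] == WITHIN
        assert h.loc[1, 5] == BETWEEN  # forward vs backward: matched pair
        assert h.loc[7, 9] == BETWEEN  # left vs right turn: matched pair
        assert h.loc[1, 7] == EXCLUDED  # forward vs turn not closely matched
        assert h.loc[4, 10] == EXCLUDED

    def test_egomotion_generalize_requires_affordance_change(self):
        h = build_hypothesis_matrix("egomotion_generalize")
        assert h.loc[1, 2] == WITHIN  # both:forward vs left:forward
        assert h.loc[7, 8] == WITHIN  # left vs right affordance
        assert h.loc[1, 4] == EXCLUDED  # same (both) affordance
        assert h.loc[2, 5] == EXCLUDED
        assert h.loc[7, 10] == BETWEEN
        assert h.loc[7, 9] == EXCLUDED  # both left-affordance turns

    def test_conflict_cells(self):
        h = build_hypothesis_matrix("conflict")
        assert h.loc[7, 10] == WITHIN
        assert h.loc[8, 9] == WITHIN
        assert h.loc[7, 7] == WITHIN
        assert h.loc[7, 9] == BETWEEN
        assert h.loc[7, 8] == BETWEEN
        assert (h.loc[1:6, :] == EXCLUDED).all().all()

    def test_room_texture_diagonal_within(self):
        h = build_hypothesis_matrix("room_texture", n_rooms=8)
        assert h.shape == (8, 8)
        assert (np.diag(h.to_numpy()) == WITHIN).all()
        off = h.to_numpy()[~np.eye(8, dtype=bool)]
        assert (off == BETWEEN).all()

    def test_generalize_schemes_are_consistent_subsets(self):
        """Every pair labeled in *_generalize keeps its *_overall label."""
        for base in ("affordance", "egomotion"):
            full = build_hypothesis_matrix(f"{base}_overall")
            gen = build_hypothesis_matrix(f"{base}_generalize")
            for i in full.index:
                for j in full.columns:
                    if gen.loc[i, j] != EXCLUDED:
                        assert gen.loc[i, j] == full.loc[i, j]

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="unknown"):
            build_hypothesis_matrix("banana")


class TestScoreDecoding:
    def test_constant_cells(self):
        h = build_hypothesis_matrix("conflict")
        d = np.zeros((10, 10))
        labels = h.to_numpy()
        d[labels == WITHIN] = 1.0
        d[labels == BETWEEN] = 2.0
        s = score_decoding(d, h)
        assert s.within_mean == 1.0
        assert s.between_mean == 2.0
        assert s.diff == 1.0

    def test_equal_cells_zero_diff(self, rng):
        h = build_hypothesis_matrix("egomotion_overall")
        s = score_decoding(np.full((10, 10), 4.2), h)
        assert s.diff == pytest.approx(0.0, abs=1e-12)

    def test_scale_equivariance(self, rng):
        """Scaling all patterns by c scales every score component by c."""
        stack = rng.normal(size=(8, 10, 15))
        h = build_hypothesis_matrix("affordance_overall")
        s1 = score_decoding(decode_run_stack(stack), h)
        s3 = score_decoding(decode_run_stack(3.0 * stack), h)
        assert s3.within_mean == pytest.approx(3 * s1.within_mean)
        assert s3.between_mean == pytest.approx(3 * s1.between_mean)
        assert s3.diff == pytest.approx(3 * s1.diff)

    def test_shape_must_cover_hypothesis(self):
        h = build_hypothesis_matrix("affordance_overall")
        with pytest.raises(ValueError, match="cover"):
            score_decoding(np.zeros((6, 6)), h)

    def test_degenerate_hypothesis_rejected(self):
        import pandas as pd

        h = pd.DataFrame(WITHIN, index=[1, 2], columns=[1, 2])
        with pytest.raises(ValueError, match="between"):
            score_decoding(np.ones((2, 2)), h)


class TestGroupDecodingTest:
    def test_zero_diffs_give_zero_t(self):
        res = group_decoding_test([DecodingScore(1.0, 1.0)] * 8)
        assert res.t == 0.0

    def test_matches_closed_form(self):
        diffs = np.array([1.0, 2.0, 3.0, 4.0])
        res = group_decoding_test(diffs)
        t_hand = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(4))
        assert res.t == pytest.approx(t_hand)
        assert res.df == 3
        assert res.tails == 1

    def test_power_at_strong_signal(self, rng):
        """Clear group signal detected in >= 95% of replicates."""
        hits = 0
        for _ in range(200):
            diffs = rng.normal(1.5, 1.0, size=16)  # d = 1.5
            hits += group_decoding_test(diffs).p < 0.05
        assert hits / 200 >= 0.95
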