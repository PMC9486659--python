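import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dmistroke as dm


def _mask(arr):
    return dm.VoxelMask(np.asarray(arr, dtype=bool))


def _as_map(scores):
    """Embed a flat score list into a (N, 1, 1) map with an all-true mask."""
    a = np.asarray(scores, dtype=float).reshape(-1, 1, 1)
    return a, _mask(np.ones(a.shape, bool))


def brute_force_auc(pos, neg):
    """Concordance probability: P(pos < neg) + ½ P(pos == neg); lesion
    scores are LOWER, so a concordant pair has the positive voxel below."""
    pos = np.asarray(pos)[:, None]
    neg = np.asarray(neg)[None, :]
    return ((pos < neg).sum() + 0.5 * (pos == neg).sum()) / pos.size / neg.shape[1]


class TestYouden:
    def test_published_style_operating_point(self):
        assert dm.youden(0.93, 0.94) == pytest.approx(0.87)

    def test_perfect_and_chance(self):
        assert dm.youden(1.0, 1.0) == pytest.approx(1.0)
        assert dm.youden(0.3, 0.7) == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=50)
    @given(s=st.floats(0, 1))
    def test_chance_line_is_zero(self, s):
        assert dm.youden(s, 1.0 - s) == pytest.approx(0.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dm.youden(1.2, 0.5)


class TestThresholdSegment:
    def test_below_threshold_positive(self):
        m, brain = _as_map([0.50, 0.70])
        seg = dm.threshold_segment(m, 0.620, brain)
        assert seg.data[0, 0, 0] and not seg.data[1, 0, 0]

    def test_value_above_dax_threshold_negative(self):
        m, brain = _as_map([2.5])
        assert not dm.threshold_segment(m, 2.0, brain).data.any()

    def test_minus_inf_threshold_empty(self):
        m, brain = _as_map([0.1, 0.2, 0.3])
        assert dm.threshold_segment(m, -np.inf, brain).n_voxels == 0

    def test_respects_mask(self):
        m, _ = _as_map([0.1, 0.1])
        brain = _mask([[[1]], [[0]]])
        assert dm.threshold_segment(m, 1.0, brain).n_voxels == 1


class TestCombineMasks:
    def test_idempotent(self):
        a = _mask(np.eye(3)[..., None])
        for mode in ("union", "intersection"):
            np.testing.assert_array_equal(
                dm.combine_masks(a, a, mode).data, a.data)

    def test_disjoint_union_additive(self):
        a = _mask([[[1]], [[0]], [[0]]])
        b = _mask([[[0]], [[1]], [[1]]])
        assert dm.combine_masks(a, b, "union").n_voxels == 3
        assert dm.combine_masks(a, b, "intersection").n_voxels == 0

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2 ** 12 - 1), st.integers(0, 2 ** 12 - 1))
    def test_intersection_subset_of_union(self, abits, bbits):
        bits = lambda v: np.array([(v >> k) & 1 for k in range(12)]
                                  ).reshape(3, 2, 2)
        a, b = _mask(bits(abits)), _mask(bits(bbits))
        inter = dm.combine_masks(a, b, "intersection").data
        union = dm.combine_masks(a, b, "union").data
        assert np.all(union[inter])

    def test_unknown_mode_rejected(self):
        a = _mask(np.ones((1, 1, 1)))
        with pytest.raises(ValueError, match="mode"):
            dm.combine_masks(a, a, "xor")


class TestPooledRoc:
    def test_perfect_separation(self):
        scores, brain = _as_map([0.1, 0.2, 0.8, 0.9])
        truth = _mask([[[1]], [[1]], [[0]], [[0]]])
        r = dm.pooled_roc(scores, truth, brain)
        assert r.auc == pytest.approx(1.0)
        assert r.j_max == pytest.approx(1.0)
        assert 0.2 < r.optimal_threshold <= 0.8

    def test_identical_distributions_chance_level(self):
        scores, brain = _as_map([0.5] * 10)
        truth = _mask([[[1]], [[0]]] * 5)
        r = dm.pooled_roc(scores, truth, brain)
        assert r.auc == pytest.approx(0.5)

    def test_small_instance_matches_concordance_oracle(self):
        """Eight handcrafted voxels with ties: trapezoid AUC equals the
        brute-force pairwise concordance count exactly."""
        vals = [0.3, 0.5, 0.5, 0.7, 0.4, 0.5, 0.9, 1.1]
        labs = [1, 1, 1, 1, 0, 0, 0, 0]
        scores, brain = _as_map(vals)
        truth = _mask(np.asarray(labs).reshape(-1, 1, 1))
        r = dm.pooled_roc(scores, truth, brain)
        expect = brute_force_auc([0.3, 0.5, 0.5, 0.7], [0.4, 0.5, 0.9, 1.1])
        assert r.auc == pytest.approx(expect, abs=1e-12)

    def test_random_instance_matches_concordance_oracle(self):
        rng = np.random.default_rng(0)
        vals = np.round(rng.uniform(0, 1, 600), 2)  # heavy ties
        labs = rng.uniform(size=600) < 0.3
        scores, brain = _as_map(vals)
        truth = _mask(labs.reshape(-1, 1, 1))
        r = dm.pooled_roc(scores, truth, brain)
        assert r.auc == pytest.approx(brute_force_auc(vals[labs], vals[~labs]),
                                      abs=1e-12)

    def test_jmax_consistent_with_curves(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, 500)
        labs = vals + rng.normal(0, 0.3, 500) < 0.5
        scores, brain = _as_map(vals)
        truth = _mask(labs.reshape(-1, 1, 1))
        r = dm.pooled_roc(scores, truth, brain)
        assert r.j_max == pytest.approx(
            np.max(r.sensitivity + r.specificity - 1.0), abs=1e-12)
        assert r.j_max == pytest.approx(
            dm.youden(r.sens_at_opt, r.spec_at_opt), abs=1e-12)

    def test_subject_order_invariant(self):
        rng = np.random.default_rng(2)
        maps, truths, brains = [], [], []
        for _ in range(3):
            v = rng.uniform(0, 1, 40).reshape(40, 1, 1)
            t = rng.uniform(size=40) < 0.4
            maps.append(v)
            truths.append(_mask(t.reshape(40, 1, 1)))
            brains.append(_mask(np.ones((40, 1, 1))))
        fwd = dm.pooled_roc(maps, truths, brains)
        rev = dm.pooled_roc(maps[::-1], truths[::-1], brains[::-1])
        assert fwd.auc == rev.auc and fwd.j_max == rev.j_max

    def test_empty_truth_rejected(self):
        scores, brain = _as_map([0.1, 0.2])
        truth = _mask(np.zeros((2, 1, 1)))
        with pytest.raises(ValueError, match="both classes"):
            dm.pooled_roc(scores, truth, brain)


class TestMirrorMask:
    def test_single_voxel_reflection(self):
        m = np.zeros((10, 4, 4), dtype=bool)
        m[3, 1, 2] = True
        out = dm.mirror_mask(dm.VoxelMask(m))
        assert out.data[6, 1, 2]
        assert out.n_voxels == 1

    def test_symmetric_mask_fixed_point(self):
        m = np.zeros((8, 3, 3), dtype=bool)
        m[[2, 5], 1, 1] = True
        out = dm.mirror_mask(dm.VoxelMask(m))
        np.testing.assert_array_equal(out.data, m)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(0, 2 ** 16 - 1))
    def test_voxel_count_preserved_and_involutive(self, bits):
        m = np.array([(bits >> k) & 1 for k in range(16)]).reshape(4, 2, 2)
        mk = dm.VoxelMask(m)
        out = dm.mirror_mask(mk)
        assert out.n_voxels == mk.n_voxels
        np.testing.assert_array_equal(dm.mirror_mask(out).data, mk.data)

    def test_clip_mask_applied(self):
        m = np.zeros((4, 1, 1), dtype=bool)
        m[0] = True
        clip = np.zeros((4, 1, 1), dtype=bool)  # flipped voxel not in clip
        out = dm.mirror_mask(dm.VoxelMask(m), clip_mask=dm.VoxelMask(clip))
        assert out.n_voxels == 0


class TestLesionStatistics:
    def _maps(self, shape=(10, 2, 2)):
        rng = np.random.default_rng(0)
        fr = rng.dirichlet(np.ones(3), size=shape)
        return dm.ParameterMaps(
            v_intra=fr[..., 0], v_extra=fr[..., 1], v_csf=fr[..., 2],
            d_ax_intra=rng.uniform(0, 3, shape),
            d_ax_extra=rng.uniform(0, 3, shape),
            d_rad_extra=rng.uniform(0, 1.5, shape))

    def test_constant_map_collapses(self):
        maps = self._maps()
        maps.d_ax_intra = np.full((10, 2, 2), 1.7)
        les = np.zeros((10, 2, 2), dtype=bool)
        les[:5] = True
        lesion, contra = _mask(les), _mask(~les)
        df = dm.lesion_statistics(maps, lesion, contra)
        row = df[(df.parameter == "d_ax_intra") & (df.side == "lesion")].iloc[0]
        assert row["mean"] == row.p5 == row.p95 == pytest.approx(1.7)

    def test_percentile_convention_linear_interpolation(self):
        """Values 1..100 give p5 = 5.95 and p95 = 95.05 under the linear
        interpolation convention (computed directly from its formula:
        q(p) = v_floor + frac·(v_ceil − v_floor) at rank p·(n−1))."""
        maps = self._maps(shape=(100, 1, 1))
        maps.d_ax_intra = (np.arange(100.0) + 1).reshape(100, 1, 1) / 100.0
        lesion = _mask(np.ones((100, 1, 1)))
        df = dm.lesion_statistics(maps, lesion, lesion)
        row = df[(df.parameter == "d_ax_intra") & (df.side == "lesion")].iloc[0]
        assert row.p5 * 100 == pytest.approx(5.95)
        assert row.p95 * 100 == pytest.approx(95.05)

    def test_ordering_invariant(self):
        df = dm.lesion_statistics(self._maps(), _mask(np.ones((10, 2, 2))),
                                  _mask(np.ones((10, 2, 2))))
        assert np.all(df.p5 <= df["mean"] + 1e-12)
        assert np.all(df["mean"] <= df.p95 + 1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            dm.lesion_statistics(self._maps(), _mask(np.zeros((10, 2, 2))),
                                 _mask(np.ones((10, 2, 2))))


class TestRocTable:
    def test_eight_rows_with_youden_identity(self):
        rng = np.random.default_rng(3)
        shape = (60, 1, 1)
        truth = rng.uniform(size=shape) < 0.3
        dax = np.where(truth, 1.5, 2.4) + rng.normal(0, 0.3, shape)
        adc = np.where(truth, 0.5, 0.9) + rng.normal(0, 0.15, shape)
        rater_a = _mask(truth)
        rater_b = _mask(np.roll(truth, 1, axis=0))
        table = dm.roc_table({"d_ax_intra": dax, "adc": adc},
                             dm.variant_masks(rater_a, rater_b),
                             _mask(np.ones(shape)))
        assert len(table) == 8
        assert set(table.ground_truth_variant) == set(dm.lesion.VARIANTS)
        assert np.all((table.auc >= 0) & (table.auc <= 1))
        np.testing.assert_allclose(table.j_max,
                                   table.sens + table.spec - 1.0, atol=1e-12)
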