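import numpy as np
import pytest

import mtlmorph as m
from mtlmorph.thickness import RunLengthMap
from mtlmorph.zmap import ZScoreMap


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return m.VolumeGrid(np.asarray(data, dtype=float), spacing, "t")


def _zmap(z, modality="gmv", valid=None, subject_id=None):
    z = np.asarray(z, dtype=float)
    if valid is None:
        valid = np.ones_like(z)
    return ZScoreMap(_vol(z), _vol(valid), modality, subject_id=subject_id)


def _voi(mask):
    return m.VOIMask(_vol(np.asarray(mask, dtype=np.uint8)))


class TestDefineVoi:
    def test_identical_groups_yield_empty_mask_error(self):
        vols = [_vol(np.full((6, 6, 6), 0.5))] * 3
        with pytest.raises(ValueError, match="no voxel"):
            m.define_voi(vols, vols, stat_threshold=3.0, min_cluster_voxels=1)

    def test_order_invariance_within_groups(self, rng):
        base = rng.random((8, 8, 8)) + 0.5
        ad = [_vol(base * rng.uniform(0.55, 0.65)) for _ in range(4)]
        nc = [_vol(base * rng.uniform(0.95, 1.05)) for _ in range(4)]
        a = m.define_voi(ad, nc, 3.0, 1)
        b = m.define_voi(ad[::-1], nc[::-1], 3.0, 1)
        np.testing.assert_array_equal(a.mask.data, b.mask.data)

    def test_small_clusters_removed(self, rng):
        # one big effect block + one single-voxel effect
        nc_data = np.full((12, 12, 12), 1.0)
        ad_data = nc_data.copy()
        ad_data[2:7, 2:7, 2:7] *= 0.5
        ad_data[10, 10, 10] *= 0.5
        ad = [_vol(ad_data + rng.normal(0, 0.01, ad_data.shape)) for _ in range(5)]
        nc = [_vol(nc_data + rng.normal(0, 0.01, nc_data.shape)) for _ in range(5)]
        voi = m.define_voi(ad, nc, stat_threshold=8.0, min_cluster_voxels=20)
        assert voi.mask.data[4, 4, 4] == 1
        assert voi.mask.data[10, 10, 10] == 0

    def test_requires_two_per_group(self):
        vols = [_vol(np.ones((4, 4, 4)))]
        with pytest.raises(ValueError, match=">= 2"):
            m.define_voi(vols, vols * 2)

    def test_recovers_phantom_ground_truth(self, small_study):
        # group comparison localizes the injected MTL atrophy; on this
        # reduced 40^3 grid the blobs are small relative to the 6 mm
        # smoothing kernel, so overlap is looser than at full scale
        assert small_study.voi_dice > 0.5


class TestGmvDecline:
    def test_mean_of_negative_z(self):
        z = np.zeros((3, 3, 3))
        z[0, 0, 0], z[0, 0, 1], z[0, 0, 2] = -1.0, -3.0, 2.0
        voi = np.zeros((3, 3, 3))
        voi[0, 0, :] = 1
        assert m.gmv_decline_indicator(_zmap(z), _voi(voi)) == pytest.approx(-2.0)

    def test_no_negative_scores_gives_zero(self):
        assert m.gmv_decline_indicator(_zmap(np.ones((3, 3, 3))), _voi(np.ones((3, 3, 3)))) == 0.0

    def test_linearity_in_negative_scores(self, rng):
        z = rng.normal(0, 1, (4, 4, 4))
        voi = np.ones((4, 4, 4))
        base = m.gmv_decline_indicator(_zmap(z), _voi(voi))
        doubled = np.where(z < 0, 2 * z, z)
        assert m.gmv_decline_indicator(_zmap(doubled), _voi(voi)) == pytest.approx(2 * base)

    def test_disjoint_union_is_count_weighted_mean(self, rng):
        z = rng.normal(0, 1, (6, 6, 6))
        a = np.zeros((6, 6, 6)); a[:3] = 1
        b = np.zeros((6, 6, 6)); b[3:] = 1
        za = _zmap(z)
        ia, ib = m.gmv_decline_indicator(za, _voi(a)), m.gmv_decline_indicator(za, _voi(b))
        na = np.count_nonzero(z[a.astype(bool)] < 0)
        nb = np.count_nonzero(z[b.astype(bool)] < 0)
        union = m.gmv_decline_indicator(za, _voi(a + b))
        assert union == pytest.approx((na * ia + nb * ib) / (na + nb))

    def test_empty_intersection_rejected(self):
        zm = _zmap(np.zeros((3, 3, 3)), valid=np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="intersect"):
            m.gmv_decline_indicator(zm, _voi(np.ones((3, 3, 3))))


class TestThicknessDecline:
    def _runlength(self, values, mask, subject_id=None):
        return RunLengthMap(_vol(values), _vol(mask), subject_id=subject_id)

    def test_single_voxel_normalized(self):
        z = np.zeros((3, 3, 3)); z[1, 1, 1] = -2.0
        rlv = np.zeros((3, 3, 3)); rlv[1, 1, 1] = 4.0
        mask = np.zeros((3, 3, 3)); mask[1, 1, 1] = 1
        ind = m.thickness_decline_indicator(
            _zmap(z, "thickness", valid=mask), self._runlength(rlv, mask),
            _voi(np.ones((3, 3, 3))),
        )
        assert ind == pytest.approx(-0.5)

    def test_sum_not_mean(self):
        z = np.zeros((3, 3, 3)); z[1, 1, 0] = z[1, 1, 2] = -2.0
        rlv = np.zeros((3, 3, 3)); rlv[1, 1, 0] = rlv[1, 1, 2] = 4.0
        mask = (rlv > 0).astype(float)
        ind = m.thickness_decline_indicator(
            _zmap(z, "thickness", valid=mask), self._runlength(rlv, mask),
            _voi(np.ones((3, 3, 3))),
        )
        assert ind == pytest.approx(-1.0)  # two voxels, each -0.5

    def test_thinner_cortex_contributes_more(self):
        # halving the run-length at qualifying voxels doubles each term
        z = np.full((3, 3, 3), -1.0)
        mask = np.ones((3, 3, 3))
        thick = self._runlength(np.full((3, 3, 3), 4.0), mask)
        thin = self._runlength(np.full((3, 3, 3), 2.0), mask)
        zm_ = _zmap(z, "thickness")
        voi = _voi(np.ones((3, 3, 3)))
        assert m.thickness_decline_indicator(zm_, thin, voi) == pytest.approx(
            2 * m.thickness_decline_indicator(zm_, thick, voi)
        )

    def test_subject_mismatch_rejected(self):
        mask = np.ones((3, 3, 3))
        rl = self._runlength(np.full((3, 3, 3), 2.0), mask, subject_id="s1")
        zm_ = _zmap(-np.ones((3, 3, 3)), "thickness", subject_id="s2")
        with pytest.raises(ValueError, match="does not match"):
            m.thickness_decline_indicator(zm_, rl, _voi(mask))

    def test_ncdb_mean_normalizer_option(self):
        z = np.zeros((3, 3, 3)); z[1, 1, 1] = -2.0
        rlv = np.zeros((3, 3, 3)); rlv[1, 1, 1] = 4.0
        mask = (rlv > 0).astype(float)
        ncdb_mean = _vol(np.full((3, 3, 3), 8.0))
        ind = m.thickness_decline_indicator(
            _zmap(z, "thickness", valid=mask), self._runlength(rlv, mask),
            _voi(np.ones((3, 3, 3))), normalizer="ncdb_mean", ncdb_mean=ncdb_mean,
        )
        assert ind == pytest.approx(-0.25)

    def test_union_is_plain_sum(self, rng):
        z = -rng.random((6, 6, 6))
        rlv = rng.uniform(1, 5, (6, 6, 6))
        mask = np.ones((6, 6, 6))
        a = np.zeros((6, 6, 6)); a[:2] = 1
        b = np.zeros((6, 6, 6)); b[2:] = 1
        zm_ = _zmap(z, "thickness")
        rl = self._runlength(rlv, mask)
        assert m.thickness_decline_indicator(zm_, rl, _voi(a + b)) == pytest.approx(
            m.thickness_decline_indicator(zm_, rl, _voi(a))
            + m.thickness_decline_indicator(zm_, rl, _voi(b))
        )


class TestExtent:
    @pytest.mark.parametrize("fill,expected", [(0.0, 0.0), (-3.0, 1.0)])
    def test_extremes(self, fill, expected):
        ind = m.extent_indicator(_zmap(np.full((3, 3, 3), fill)), _voi(np.ones((3, 3, 3))))
        assert ind == expected

    def test_counting_matches_known_fraction(self, rng):
        z = np.where(rng.random((10, 10, 10)) < 0.3, -5.0, 0.5)
        f = np.count_nonzero(z < -2) / z.size
        assert m.extent_indicator(_zmap(z), _voi(np.ones((10, 10, 10)))) == pytest.approx(f)

    def test_cut_is_strict(self):
        z = np.full((3, 3, 3), -2.0)  # exactly at the cut: not counted
        assert m.extent_indicator(_zmap(z), _voi(np.ones((3, 3, 3)))) == 0.0


class TestSplitByAtlas:
    def test_single_label_identity(self):
        voi = _voi(np.pad(np.ones((2, 2, 2)), 2))
        atlas = _vol(np.ones((6, 6, 6)))
        subs = m.split_by_atlas(voi, atlas, [1])
        np.testing.assert_array_equal(subs[1].mask.data, voi.mask.data)

    def test_partition_conserves_size(self):
        voi = _voi(np.ones((6, 6, 6)))
        atlas_data = np.ones((6, 6, 6)); atlas_data[3:] = 2
        subs = m.split_by_atlas(voi, _vol(atlas_data), [1, 2])
        assert subs[1].n_voxels + subs[2].n_voxels == voi.n_voxels

    def test_empty_intersection_reported_not_dropped(self):
        voi_mask = np.zeros((6, 6, 6)); voi_mask[:2] = 1
        atlas_data = np.zeros((6, 6, 6)); atlas_data[:2] = 1; atlas_data[5] = 2
        subs = m.split_by_atlas(_voi(voi_mask), _vol(atlas_data), [1, 2])
        assert subs[1] is not None and subs[2] is None

    def test_absent_label_is_error(self):
        with pytest.raises(ValueError, match="absent"):
            m.split_by_atlas(_voi(np.ones((3, 3, 3))), _vol(np.ones((3, 3, 3))), [7])

    def test_phantom_atlas_subregions_inside_blobs(self, small_study):
        labels = small_study.region_labels
        assert len(labels) == 6
        truth = small_study.truth_voi.data.astype(bool)
        atlas = small_study.atlas.data
        for label in labels:
            assert truth[atlas == label].all()
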