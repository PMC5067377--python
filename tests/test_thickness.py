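import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mtlmorph as m
from mtlmorph.thickness import DIRECTION_PAIRS, step_mm
from oracles import brute_force_run_length


def _vol(mask, spacing=(1.0, 1.0, 1.0)):
    return m.VolumeGrid(np.asarray(mask, dtype=np.uint8), spacing, "t")


class TestBinarize:
    def test_threshold_inclusive(self):
        vol = m.VolumeGrid(np.full((3, 3, 3), 0.4), (1, 1, 1), "t")
        assert m.binarize_gm(vol, 0.4).data.all()

    @pytest.mark.parametrize("value,expected", [(0.5, 1), (0.39, 0)])
    def test_constant_volumes(self, value, expected):
        vol = m.VolumeGrid(np.full((3, 3, 3), value), (1, 1, 1), "t")
        assert (m.binarize_gm(vol, 0.4).data == expected).all()

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_range(self, bad):
        vol = m.VolumeGrid(np.zeros((2, 2, 2)), (1, 1, 1), "t")
        with pytest.raises(ValueError):
            m.binarize_gm(vol, bad)


class TestRunLength:
    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(10):
            mask = rng.random((12, 12, 12)) < rng.uniform(0.2, 0.8)
            got = m.run_length_map(_vol(mask)).values.data
            np.testing.assert_array_equal(got, brute_force_run_length(mask))

    def test_matches_brute_force_anisotropic(self, rng):
        spacing = (1.0, 1.0, 1.2)
        mask = rng.random((10, 10, 10)) < 0.5
        got = m.run_length_map(_vol(mask, spacing)).values.data
        np.testing.assert_allclose(got, brute_force_run_length(mask, spacing))

    def test_isolated_voxel_is_one_min_step(self):
        mask = np.zeros((7, 7, 7))
        mask[3, 3, 3] = 1
        rl = m.run_length_map(_vol(mask, (1.0, 0.8, 1.2)))
        assert rl.values.data[3, 3, 3] == pytest.approx(0.8)

    def test_slab_interior_equals_thickness(self):
        mask = np.zeros((21, 21, 21))
        mask[:, :, 8:13] = 1  # 5 voxels thick
        rl = m.run_length_map(_vol(mask)).values.data
        assert np.all(rl[6:15, 6:15, 8:13] == 5.0)

    def test_full_grid_border_clipping(self):
        mask = np.ones((9, 9, 9))
        rl = m.run_length_map(_vol(mask)).values.data
        np.testing.assert_array_equal(rl, brute_force_run_length(mask))
        assert rl[0, 0, 0] < rl[4, 4, 4]

    def test_axis_permutation_invariance(self, rng):
        mask = rng.random((10, 10, 10)) < 0.5
        base = m.run_length_map(_vol(mask)).values.data
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            permuted = m.run_length_map(_vol(mask.transpose(perm))).values.data
            np.testing.assert_array_equal(permuted, base.transpose(perm))

    def test_mirror_invariance(self, rng):
        mask = rng.random((10, 10, 10)) < 0.5
        base = m.run_length_map(_vol(mask)).values.data
        mirrored = m.run_length_map(_vol(mask[::-1].copy())).values.data
        np.testing.assert_array_equal(mirrored, base[::-1])

    def test_erosion_never_increases_run_length(self, rng):
        from scipy import ndimage

        mask = rng.random((12, 12, 12)) < 0.6
        eroded = ndimage.binary_erosion(mask)
        full = m.run_length_map(_vol(mask)).values.data
        less = m.run_length_map(_vol(eroded)).values.data
        on = eroded
        assert np.all(less[on] <= full[on] + 1e-12)

    def test_shell_interior_near_analytic_thickness(self):
        spec = m.PhantomSpec(
            shape=(40, 40, 40),
            cortex=m.ShellCortex((20.0, 20.0, 20.0), 10.0, 14.0),
            mtl_blobs=(m.Blob((20.0, 20.0, 34.0), (3.0, 3.0, 3.0)),),
            noise_sd=0.0,
            thickness_jitter_sd_mm=0.0,
        )
        vol = m.make_subject(spec, "NC", 0.0, subj_seed=1)
        rl = m.run_length_map(m.binarize_gm(vol))
        idx = np.indices(spec.shape, float)
        r = np.sqrt(((idx - 19.5) ** 2).sum(axis=0))
        interior = (r >= 11.0) & (r <= 13.0) & rl.gm_mask.data.astype(bool)
        vals = rl.values.data[interior]
        assert np.all(np.abs(vals - 4.0) <= np.sqrt(3) + 1e-9)

    def test_rejects_non_binary_mask(self):
        with pytest.raises(ValueError, match="binary"):
            m.run_length_map(m.VolumeGrid(np.full((3, 3, 3), 2.0), (1, 1, 1), "t"))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_property_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((8, 8, 8)) < rng.uniform(0.1, 0.9)
        got = m.run_length_map(_vol(mask)).values.data
        np.testing.assert_array_equal(got, brute_force_run_length(mask))


def test_direction_set_covers_26_neighborhood():
    dirs = set(DIRECTION_PAIRS) | {tuple(-c for c in d) for d in DIRECTION_PAIRS}
    assert len(dirs) == 26
    assert step_mm((1, 1, 1), (1, 1, 1)) == pytest.approx(np.sqrt(3))
    assert step_mm((1, 1, 0), (1.0, 2.0, 1.0)) == pytest.approx(np.sqrt(5))


class TestThicknessZmap:
    def test_identical_subject_scores_zero(self, rng):
        masks = []
        base = np.zeros((12, 12, 12))
        base[:, :, 4:9] = 1
        # jittered controls: thickness varies by one voxel
        for k in range(6):
            mk = base.copy()
            if k % 2:
                mk[:, :, 9] = 1
            masks.append(_vol(mk))
        rls = [m.run_length_map(v).values for v in masks]
        model = m.build_thickness_ncdb(rls, sd_fwhm_mm=2.0)
        subj = m.run_length_map(masks[0])
        z = m.thickness_zmap(subj, model)
        valid = z.validity_mask.data.astype(bool)
        assert valid.any()
        # subject equals control 0; z reflects only the deviation from the mean
        np.testing.assert_allclose(
            z.z.data[valid],
            (subj.values.data[valid] - model.mean_img.data[valid])
            / model.sd_img.data[valid],
        )

    def test_thinner_subject_scores_negative(self):
        controls = []
        base = np.zeros((14, 14, 14))
        base[:, :, 4:10] = 1  # 6 mm
        for k in range(8):
            mk = base.copy()
            if k % 2:
                mk[:, :, 10] = 1  # half the controls 7 mm
            controls.append(_vol(mk))
        model = m.build_thickness_ncdb(
            [m.run_length_map(v).values for v in controls], sd_fwhm_mm=2.0
        )
        thin = np.zeros((14, 14, 14))
        thin[:, :, 4:9] = 1  # 5 mm subject
        z = m.thickness_zmap(m.run_length_map(_vol(thin)), model)
        core = z.z.data[5:9, 5:9, 5:8]
        valid = z.validity_mask.data[5:9, 5:9, 5:8].astype(bool)
        assert valid.any() and np.all(core[valid] < 0)

    def test_z_defined_only_inside_subject_gm(self, rng):
        base = np.zeros((10, 10, 10))
        base[:, :, 3:7] = 1
        controls = [_vol(base)] * 2
        rls = [m.run_length_map(v).values for v in controls]
        model = m.build_thickness_ncdb(rls, sd_fwhm_mm=3.0)
        subj_mask = base.copy()
        subj_mask[:, :, 6] = 0  # subject GM smaller than controls'
        z = m.thickness_zmap(m.run_length_map(_vol(subj_mask)), model)
        assert not z.validity_mask.data[:, :, 6].any()

    def test_modality_mismatch_rejected(self, rng):
        vols = [m.VolumeGrid(rng.random((5, 5, 5)), (1, 1, 1), "t") for _ in range(3)]
        gmv_model = m.build_gmv_ncdb(vols, fwhm_mm=0.0)
        mask = _vol(np.ones((5, 5, 5)))
        with pytest.raises(ValueError, match="thickness"):
            m.thickness_zmap(m.run_length_map(mask), gmv_model)
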