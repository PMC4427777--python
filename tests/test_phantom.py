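"""Phantom generator: determinism, anatomy invariants, noise and bias."""

import numpy as np
import pytest

from cerebseg import (BinaryMask, PhantomConfig, add_noise, apply_bias_field,
                      dilate, generate_phantom, make_ball_se, perturb_pose)
from cerebseg.errors import ConfigurationError, ContractError
from cerebseg.morphology import connected_components
from cerebseg.phantom import Label


class TestConfig:
    def test_grid_below_minimum_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(grid_shape=32)

    def test_unordered_tissue_means_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(csf_mean=100, gm_mean=40, wm_mean=150)

    def test_bias_amplitude_bounds(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(bias_amplitude=0.6)


class TestAnatomy:
    def test_same_seed_is_bit_identical(self):
        cfg = PhantomConfig(grid_shape=64, noise_sigma=3.0,
                            bias_amplitude=0.1, seed=5)
        a = generate_phantom(cfg)
        b = generate_phantom(cfg)
        assert np.array_equal(a.t1.data, b.t1.data)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.bias_truth.data, b.bias_truth.data)

    def test_noiseless_pure_voxels_hit_tissue_means_exactly(self, small_phantom):
        from scipy import ndimage
        case = small_phantom
        cfg = case.config
        # pure voxels: deep inside a structure, away from any interface —
        # take the interior after eroding each label region with a full
        # 3x3x3 neighbourhood so no partial-volume mixing can reach them
        cube = np.ones((3, 3, 3), dtype=bool)
        for lab, mean in ((Label.CEREBELLUM_WM, cfg.wm_mean),
                          (Label.CEREBRUM, cfg.gm_mean),
                          (Label.SINUS, cfg.sinus_mean),
                          (Label.CSF, cfg.csf_mean)):
            interior = ndimage.binary_erosion(case.labels == lab,
                                              structure=cube, border_value=0)
            if interior.any():
                assert np.allclose(case.t1.data[interior], mean), lab.name
        # cerebellar WM interior must exist so the check is not vacuous
        assert ndimage.binary_erosion(case.labels == Label.CEREBELLUM_WM,
                                      structure=cube, border_value=0).any()

    def test_cerebellar_volume_fraction_plausible(self, default_phantom):
        lab = default_phantom.labels
        ratio = np.isin(lab, (Label.CEREBELLUM_GM, Label.CEREBELLUM_WM)).sum() \
            / (lab > 0).sum()
        assert 0.08 <= ratio <= 0.20

    def test_every_voxel_has_one_label(self, small_phantom):
        assert small_phantom.labels.min() >= 0
        assert small_phantom.labels.max() <= max(Label)

    def test_pve_truth_partition_of_unity(self, small_phantom):
        case = small_phantom
        s = case.pve_truth.sum_map()
        brain = case.labels > 0
        assert np.abs(s[brain] - 1).max() <= 1e-6
        assert np.abs(s[~brain]).max() == 0

    def test_sinus_separated_from_cerebellum_by_csf(self, default_phantom):
        case = default_phantom
        t = case.config.csf_sheet_thickness
        cb = case.cerebellum_mask()
        sinus = case.sinus_mask()
        assert sinus.count() > 0
        grown = dilate(cb, make_ball_se(t))
        assert not (grown.data & sinus.data).any()
        # gap voxels adjacent to the cerebellum are CSF, except where the
        # peduncle/brain-stem bridge legitimately touches it
        rim = grown.data & ~cb.data & (case.labels > 0)
        allowed = (Label.CSF, Label.PEDUNCLE, Label.BRAINSTEM)
        assert np.isin(case.labels[rim], allowed).all()

    def test_sinus_disconnected_once_csf_removed(self, default_phantom):
        case = default_phantom
        tissue = BinaryMask((case.labels > 0) & (case.labels != Label.CSF),
                            case.affine)
        labels, _ = connected_components(tissue, 26)
        cb_comps = set(np.unique(labels[case.cerebellum_mask().data]))
        sinus_comps = set(np.unique(labels[case.sinus_mask().data]))
        assert cb_comps.isdisjoint(sinus_comps)

    def test_peduncle_bridges_stem_and_cerebellum(self, default_phantom):
        case = default_phantom
        bridge = BinaryMask(np.isin(case.labels, (Label.CEREBELLUM_GM,
                                                  Label.CEREBELLUM_WM,
                                                  Label.BRAINSTEM,
                                                  Label.PEDUNCLE)),
                            case.affine)
        labels, sizes = connected_components(bridge, 26)
        # one component containing both stem and cerebellum
        stem_ids = set(np.unique(labels[case.labels == Label.BRAINSTEM]))
        cb_ids = set(np.unique(labels[case.cerebellum_mask().data]))
        assert stem_ids & cb_ids

    def test_sinus_intensity_close_to_gray_matter(self):
        cfg = PhantomConfig()
        assert abs(cfg.sinus_mean - cfg.gm_mean) / cfg.gm_mean <= 0.10


class TestNoiseAndBias:
    def test_zero_noise_is_identity(self, small_phantom):
        out = add_noise(small_phantom.t1, 0.0, 3)
        assert np.array_equal(out.data, small_phantom.t1.data)

    def test_noise_sample_std(self):
        from cerebseg import Volume
        zeros = Volume(np.zeros((64, 64, 64)))
        out = add_noise(zeros, 5.0, 11)
        assert 4.75 <= out.data.std() <= 5.25

    def test_noise_seed_sensitivity(self, small_phantom):
        a = add_noise(small_phantom.t1, 2.0, 1)
        b = add_noise(small_phantom.t1, 2.0, 2)
        assert not np.array_equal(a.data, b.data)

    def test_zero_amplitude_bias_is_identity(self, small_phantom):
        out, bias = apply_bias_field(small_phantom.t1, 0.0, 0)
        assert np.array_equal(out.data, small_phantom.t1.data)
        assert np.all(bias.data == 1.0)

    def test_bias_bounds_on_constant_volume(self):
        from cerebseg import Volume
        const = Volume(np.full((32, 32, 32), 100.0))
        out, bias = apply_bias_field(const, 0.2, 9)
        assert out.data.min() >= 80.0 - 1e-9
        assert out.data.max() <= 120.0 + 1e-9
        assert bias.data.mean() == pytest.approx(1.0, abs=1e-12)
        assert np.abs(bias.data - 1).max() == pytest.approx(0.2, abs=1e-12)

    def test_bias_field_is_smooth(self):
        from cerebseg import Volume
        const = Volume(np.full((64, 64, 64), 1.0))
        _, bias = apply_bias_field(const, 0.2, 4)
        grads = np.gradient(bias.data)
        gmag = np.sqrt(sum(g ** 2 for g in grads))
        assert gmag.max() < 0.01   # < 1% of the mean per voxel

    def test_negative_amplitude_rejected(self, small_phantom):
        with pytest.raises(ContractError):
            apply_bias_field(small_phantom.t1, -0.1, 0)


class TestPerturbPose:
    def test_identity_transform_keeps_labels(self, small_phantom):
        out = perturb_pose(small_phantom)
        assert np.array_equal(out.labels, small_phantom.labels)

    def test_integer_translation_preserves_counts(self, small_phantom):
        out = perturb_pose(small_phantom, translation=(3, -2, 1))
        # interior structures shift on the lattice without resampling loss
        for lab in (Label.CEREBELLUM_GM, Label.CEREBELLUM_WM, Label.SINUS):
            assert (out.labels == lab).sum() == (small_phantom.labels == lab).sum()

    def test_small_rotation_roughly_preserves_cerebellum(self, default_phantom):
        out = perturb_pose(default_phantom, rotation=(10, 0, 0))
        n0 = default_phantom.cerebellum_mask().count()
        n1 = out.cerebellum_mask().count()
        assert abs(n1 - n0) / n0 < 0.03

    def test_out_of_range_parameters_rejected(self, small_phantom):
        with pytest.raises(ContractError):
            perturb_pose(small_phantom, rotation=(45, 0, 0))
        with pytest.raises(ContractError):
            perturb_pose(small_phantom, scale=0.5)

    def test_pose_is_recorded(self, small_phantom):
        out = perturb_pose(small_phantom, translation=(5, 0, 0))
        assert np.allclose(out.applied_pose[:3, 3], (5, 0, 0))
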