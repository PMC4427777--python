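"""Bias correction, brain extraction, tissue classification, PVE."""

import numpy as np
import pytest

from cerebseg import (BinaryMask, Volume, apply_bias_field, classify_tissue,
                      correct_inhomogeneity, estimate_pve, extract_brain_mask,
                      dice)
from cerebseg.errors import ContractError, DegenerateFitError
from cerebseg.morphology import connected_components
from cerebseg.phantom import Label


@pytest.fixture()
def three_class_volume(rng):
    """Well-separated synthetic Gaussians, means 40/100/150, sd 5."""
    shape = (32, 32, 32)
    classes = rng.integers(0, 3, size=shape)
    means = np.array([40.0, 100.0, 150.0])
    data = means[classes] + rng.normal(0, 5, size=shape)
    brain = BinaryMask(np.ones(shape, dtype=bool))
    return Volume(data), brain, classes


class TestBiasCorrection:
    def test_constant_input_unchanged(self):
        vol = Volume(np.full((24, 24, 24), 100.0))
        brain = BinaryMask(np.ones((24, 24, 24), dtype=bool))
        corrected, bias = correct_inhomogeneity(vol, brain, 2)
        assert np.abs(corrected.data / vol.data - 1).max() < 1e-6
        assert bias.data[brain.data].mean() == pytest.approx(1.0, abs=1e-9)

    def test_wm_cov_halved_on_biased_phantom(self, default_phantom):
        # within-tissue spread of pure WM voxels is purely bias-driven in
        # the noiseless phantom, so correction must cut it at least in half
        case = default_phantom
        biased, _ = apply_bias_field(case.t1, 0.2, 123)
        brain = case.brain_mask()
        corrected, _ = correct_inhomogeneity(biased, brain, 3)
        wm = np.isin(case.labels, (Label.CEREBELLUM_WM, Label.BRAINSTEM,
                                   Label.PEDUNCLE)) \
            & (case.pve_truth.wm.data == 1.0)
        cov_before = biased.data[wm].std() / biased.data[wm].mean()
        cov_after = corrected.data[wm].std() / corrected.data[wm].mean()
        assert cov_after <= 0.5 * cov_before

    def test_mean_intensity_preserved(self, small_phantom):
        case = small_phantom
        biased, _ = apply_bias_field(case.t1, 0.15, 77)
        brain = case.brain_mask()
        corrected, _ = correct_inhomogeneity(biased, brain, 3)
        m = brain.data
        assert corrected.data[m].mean() == pytest.approx(
            biased.data[m].mean(), rel=0.01)

    def test_inverse_consistency(self, small_phantom):
        # correcting then re-applying the estimated bias returns the input
        case = small_phantom
        biased, _ = apply_bias_field(case.t1, 0.2, 5)
        brain = case.brain_mask()
        corrected, bias = correct_inhomogeneity(biased, brain, 3)
        recon = corrected.data * bias.data
        m = brain.data
        assert np.abs(recon[m] / biased.data[m] - 1).mean() < 0.01

    def test_poly_order_contract(self, small_phantom):
        with pytest.raises(ContractError):
            correct_inhomogeneity(small_phantom.t1, small_phantom.brain_mask(), 0)

    def test_nonpositive_intensities_rejected(self):
        vol = Volume(np.zeros((8, 8, 8)))
        brain = BinaryMask(np.ones((8, 8, 8), dtype=bool))
        with pytest.raises(ValueError):
            correct_inhomogeneity(vol, brain, 2)


class TestBrainExtraction:
    def test_phantom_brain_recovered(self, default_phantom):
        case = default_phantom
        mask = extract_brain_mask(case.t1)
        assert dice(case.brain_mask(), mask) >= 0.95

    def test_single_component_no_holes(self, small_phantom):
        mask = extract_brain_mask(small_phantom.t1)
        _, sizes = connected_components(mask, 26)
        assert len(sizes) == 1
        from scipy import ndimage
        assert np.array_equal(ndimage.binary_fill_holes(mask.data), mask.data)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            extract_brain_mask(Volume(np.zeros((16, 16, 16))))


class TestClassifyTissue:
    def test_recovers_generating_classes(self, three_class_volume):
        vol, brain, classes = three_class_volume
        labels = classify_tissue(vol, brain, seed=0)
        acc = (labels.data[brain.data] == classes[brain.data] + 1).mean()
        assert acc >= 0.99
        assert np.abs(labels.class_means - [40, 100, 150]).max() <= 2.0

    def test_deterministic_per_seed(self, three_class_volume):
        vol, brain, _ = three_class_volume
        a = classify_tissue(vol, brain, seed=3)
        b = classify_tissue(vol, brain, seed=3)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.class_means, b.class_means)

    def test_empty_brain_mask_rejected(self, three_class_volume):
        vol, _, _ = three_class_volume
        empty = BinaryMask(np.zeros(vol.shape, dtype=bool))
        with pytest.raises(ContractError):
            classify_tissue(vol, empty)

    def test_degenerate_intensities_rejected(self):
        vol = Volume(np.full((10, 10, 10), 7.0))
        brain = BinaryMask(np.ones((10, 10, 10), dtype=bool))
        with pytest.raises(DegenerateFitError):
            classify_tissue(vol, brain)

    def test_noiseless_phantom_pure_voxels_recovered(self, default_phantom):
        # links the phantom to the classifier contract: in the noiseless
        # limit nearly all pure-label voxels classify correctly
        case = default_phantom
        labels = classify_tissue(case.t1, case.brain_mask(), seed=0)
        truth_class = np.zeros_like(labels.data)
        truth_class[case.labels == Label.CSF] = 1
        truth_class[np.isin(case.labels, (Label.CEREBRUM, Label.CEREBELLUM_GM,
                                          Label.SINUS))] = 2
        truth_class[np.isin(case.labels, (Label.CEREBELLUM_WM, Label.BRAINSTEM,
                                          Label.PEDUNCLE))] = 3
        pure = ((case.pve_truth.csf.data == 1) | (case.pve_truth.gm.data == 1)
                | (case.pve_truth.wm.data == 1))
        agree = (labels.data[pure] == truth_class[pure]).mean()
        assert agree >= 0.99


class TestEstimatePVE:
    @pytest.fixture()
    def fitted_labels(self, three_class_volume):
        vol, brain, _ = three_class_volume
        return vol, classify_tissue(vol, brain, seed=0)

    def test_pure_class_at_class_mean(self, fitted_labels):
        vol, labels = fitted_labels
        mu = labels.class_means
        probe = vol.with_data(np.full(vol.shape, mu[1]))
        maps = estimate_pve(probe, labels)
        inside = labels.data > 0
        assert np.all(maps.gm.data[inside] == 1.0)
        assert np.all(maps.csf.data[inside] == 0.0)
        assert np.all(maps.wm.data[inside] == 0.0)

    def test_midpoint_mixes_half_and_half(self, fitted_labels):
        vol, labels = fitted_labels
        mu = labels.class_means
        probe = vol.with_data(np.full(vol.shape, (mu[0] + mu[1]) / 2))
        maps = estimate_pve(probe, labels)
        inside = labels.data > 0
        assert np.allclose(maps.csf.data[inside], 0.5)
        assert np.allclose(maps.gm.data[inside], 0.5)

    def test_partition_of_unity_on_brain(self, fitted_labels):
        vol, labels = fitted_labels
        maps = estimate_pve(vol, labels)
        s = maps.sum_map()
        inside = labels.data > 0
        assert np.abs(s[inside] - 1).max() <= 1e-6
        assert np.all(s[~inside] == 0)

    def test_interface_error_vs_phantom_truth(self, default_phantom):
        case = default_phantom
        brain = case.brain_mask()
        labels = classify_tissue(case.t1, brain, seed=0)
        maps = estimate_pve(case.t1, labels)
        truth = case.pve_truth
        interface = brain.data & (truth.csf.data > 0) & (truth.csf.data < 1)
        err = np.abs(maps.csf.data[interface] - truth.csf.data[interface])
        assert err.mean() <= 0.05

    def test_unordered_means_rejected(self, fitted_labels):
        vol, labels = fitted_labels
        labels.class_means = labels.class_means.copy()
        bad = labels
        bad.class_means[0], bad.class_means[2] = bad.class_means[2], bad.class_means[0]
        with pytest.raises(ContractError):
            estimate_pve(vol, bad)
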