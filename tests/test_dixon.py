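"""Fat-fraction mapping, rigid multimodal registration, VOI transfer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from handquant.core import (
    BinaryMask,
    DataError,
    GeometryError,
    RegistrationError,
    RigidTransform,
    VolumeImage,
    dice_coefficient,
    transform_discrepancy,
)
from handquant.dixon import (
    RegistrationConfig,
    compute_fat_fraction,
    register_rigid,
    transfer_voi,
)
from handquant.preprocess import correct_bias_field, extract_hand_mask

from conftest import probe_points


def _pair(w, f, spacing=(1, 1, 1)):
    return (
        VolumeImage(np.asarray(w, dtype=float), spacing=spacing),
        VolumeImage(np.asarray(f, dtype=float), spacing=spacing),
    )


class TestFatFraction:
    def test_zero_fat_gives_zero(self):
        water, fat = _pair(np.full((3, 3, 3), 500.0), np.zeros((3, 3, 3)))
        assert np.all(compute_fat_fraction(water, fat).data == 0)

    def test_equal_mix_gives_500(self):
        water, fat = _pair(np.full((3, 3, 3), 123.0), np.full((3, 3, 3), 123.0))
        assert np.all(compute_fat_fraction(water, fat).data == 500)

    def test_ten_percent_fat_gives_grey_value_100(self):
        water, fat = _pair(np.full((2, 2, 2), 900.0), np.full((2, 2, 2), 100.0))
        assert np.all(compute_fat_fraction(water, fat).data == 100)

    def test_zero_denominator_flagged_invalid(self):
        w = np.zeros((2, 2, 2))
        f = np.zeros((2, 2, 2))
        w[0, 0, 0] = 10.0
        ff = compute_fat_fraction(*_pair(w, f))
        assert ff.valid.data[0, 0, 0] == 1
        assert ff.valid.count() == 1
        assert np.all(ff.data[ff.valid.data == 0] == 0)

    def test_grid_mismatch_rejected(self):
        water = VolumeImage(np.zeros((2, 2, 2)), spacing=(1, 1, 1))
        fat = VolumeImage(np.zeros((2, 2, 2)), spacing=(1, 1, 2))
        with pytest.raises(GeometryError):
            compute_fat_fraction(water, fat)

    def test_negative_inputs_rejected(self):
        water, fat = _pair(np.full((2, 2, 2), -1.0), np.zeros((2, 2, 2)))
        with pytest.raises(DataError):
            compute_fat_fraction(water, fat)

    @settings(max_examples=25, derandomize=True)
    @given(
        scale=st.floats(0.01, 100.0),
        w=st.floats(0.0, 1000.0),
        f=st.floats(0.1, 1000.0),
    )
    def test_scale_invariance(self, scale, w, f):
        water, fat = _pair(np.full((1, 1, 1), w), np.full((1, 1, 1), f))
        a = compute_fat_fraction(water, fat).data
        water2, fat2 = _pair(np.full((1, 1, 1), w * scale), np.full((1, 1, 1), f * scale))
        b = compute_fat_fraction(water2, fat2).data
        np.testing.assert_array_equal(a, b)


class TestRegistration:
    def test_self_registration_is_identity(self, default_phantom):
        t1, _, _, truth = default_phantom
        corrected, _ = correct_bias_field(t1)
        hand = extract_hand_mask(corrected)
        tfm, info = register_rigid(corrected, hand, corrected)
        disp, ang = transform_discrepancy(
            tfm, RigidTransform(), probe_points(truth)
        )
        assert disp < 0.1 and ang < 0.1

    def test_known_transform_recovered(self, default_phantom):
        t1, water, _, truth = default_phantom
        corrected, _ = correct_bias_field(t1)
        hand = extract_hand_mask(corrected)
        tfm, info = register_rigid(corrected, hand, water)
        disp, ang = transform_discrepancy(tfm, truth.transform, probe_points(truth))
        # half the coarsest voxel dimension (3 mm slices) and 1 degree
        assert disp <= 1.5
        assert ang <= 1.0

    def test_zero_overlap_raises(self):
        rng = np.random.default_rng(0)
        a = VolumeImage(rng.random((8, 16, 16)), origin=(0, 0, 0))
        hand = BinaryMask.like(a, np.ones(a.shape, dtype=np.uint8))
        far = VolumeImage(rng.random((8, 16, 16)), origin=(1000.0, 1000.0, 1000.0))
        cfg = RegistrationConfig(initialize=False)
        with pytest.raises(RegistrationError):
            register_rigid(a, hand, far, cfg)


class TestTransferVoi:
    def test_identity_transform_same_grid_is_identity(self, default_phantom):
        _, _, _, truth = default_phantom
        muscle = truth.muscle_mask()
        out = transfer_voi(muscle, RigidTransform(), truth.labels)
        np.testing.assert_array_equal(out.data, muscle.data)

    def test_single_voxel_translation_is_a_shift(self):
        data = np.zeros((4, 8, 8), dtype=np.uint8)
        data[1:3, 2:5, 3:6] = 1
        mask = BinaryMask(data, spacing=(1.0, 1.0, 2.0))
        target = VolumeImage(np.zeros((4, 8, 8)), spacing=(1.0, 1.0, 2.0))
        # transform maps target points to source: shifting sampling by +1 mm in x
        # moves mask content one voxel towards -x? No: output(p) = mask(p + t),
        # so t = +1 voxel in x makes output the mask shifted by -1 voxel.
        tfm = RigidTransform(translation_mm=(1.0, 0.0, 0.0))
        out = transfer_voi(mask, tfm, target)
        expected = np.zeros_like(data)
        expected[:, :, :-1] = data[:, :, 1:]
        np.testing.assert_array_equal(out.data, expected)

    def test_transfer_and_inverse_nearly_recovers_mask(self, default_phantom):
        _, _, _, truth = default_phantom
        muscle = truth.muscle_mask()
        tfm = RigidTransform(
            rotation_deg=(0, 0, 4.0),
            translation_mm=(1.5, -2.0, 1.0),
            center_mm=(47.5, 47.5, 34.5),
        )
        there = transfer_voi(muscle, tfm, truth.labels)
        back = transfer_voi(there, tfm.inverse(), truth.labels)
        assert dice_coefficient(back, muscle) >= 0.95

    def test_true_transform_matches_dixon_truth(self, default_phantom):
        _, _, _, truth = default_phantom
        out = transfer_voi(truth.muscle_mask(), truth.transform, truth.dixon_labels)
        assert dice_coefficient(out, truth.dixon_muscle_mask()) >= 0.95

    def test_fully_outside_warns_and_returns_empty(self, default_phantom):
        _, _, _, truth = default_phantom
        tfm = RigidTransform(translation_mm=(500.0, 500.0, 500.0))
        with pytest.warns(UserWarning):
            out = transfer_voi(truth.muscle_mask(), tfm, truth.dixon_labels)
        assert out.count() == 0


class TestFatInVoi:
    def test_mean_ff_in_transferred_voi_matches_truth(self, noise_free_phantom):
        _, water, fat, truth = noise_free_phantom
        ff = compute_fat_fraction(water, fat)
        voi = transfer_voi(truth.muscle_mask(), truth.transform, ff)
        mean_ff = ff.data[voi.as_bool()].mean()
        assert abs(mean_ff - 0.10 * 1000) <= 5.0
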