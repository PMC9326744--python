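"""Thresholding, priority adjudication, sum encoding, midline split."""
import numpy as np
import pytest

from adpkdvol.ensemble import (
    PRIORITY_ORDER,
    OrganClaims,
    adjudicate_priority,
    encode_overlaps_sum,
    infer_organ,
    run_ensemble,
    split_kidneys_midline,
    threshold_claims,
)
from adpkdvol.image_io import CANONICAL_AXCODES, LabelMap, ProbabilityMap
from adpkdvol.metrics import dsc


def claims_from_arrays(kidney, spleen, liver, threshold=0.5):
    spacing = (1.0, 1.0, 1.0)
    return OrganClaims(
        {
            "kidney": ProbabilityMap(kidney, spacing, organ="kidney"),
            "spleen": ProbabilityMap(spleen, spacing, organ="spleen"),
            "liver": ProbabilityMap(liver, spacing, organ="liver"),
        },
        threshold=threshold,
    )


class TestThreshold:
    def test_exactly_half_is_negative(self):
        c = claims_from_arrays(np.full((2, 2, 2), 0.5), np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))
        assert not threshold_claims(c)["kidney"].any()

    def test_just_above_half_is_positive(self):
        c = claims_from_arrays(np.full((2, 2, 2), 0.51), np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))
        assert threshold_claims(c)["kidney"].all()

    def test_all_zero_maps_give_empty_masks(self):
        z = np.zeros((3, 3, 3))
        masks = threshold_claims(claims_from_arrays(z, z, z))
        assert not any(m.any() for m in masks.values())


def priority_oracle(kidney, spleen, liver):
    """Brute force: per-voxel scan of the priority list."""
    out = np.zeros(kidney.shape, dtype=np.uint8)
    it = np.nditer(out, flags=["multi_index"])
    claims = {"kidney": kidney, "spleen": spleen, "liver": liver}
    for _ in it:
        idx = it.multi_index
        for name, label in PRIORITY_ORDER:
            if claims[name][idx]:
                out[idx] = label
                break
    return out


class TestAdjudication:
    def test_all_eight_claim_combinations_match_oracle(self):
        # one voxel per combination of (kidney, spleen, liver) claims
        combos = np.array([[(b >> 2) & 1, (b >> 1) & 1, b & 1] for b in range(8)], bool)
        kidney = combos[:, 0].reshape(2, 2, 2)
        spleen = combos[:, 1].reshape(2, 2, 2)
        liver = combos[:, 2].reshape(2, 2, 2)
        got = adjudicate_priority({"kidney": kidney, "spleen": spleen, "liver": liver})
        assert np.array_equal(got, priority_oracle(kidney, spleen, liver))

    def test_random_volumes_match_oracle(self):
        rng = np.random.default_rng(0)
        kidney, spleen, liver = (rng.random((6, 5, 4)) > 0.5 for _ in range(3))
        got = adjudicate_priority({"kidney": kidney, "spleen": spleen, "liver": liver})
        assert np.array_equal(got, priority_oracle(kidney, spleen, liver))

    def test_kidney_beats_liver_and_spleen_beats_liver(self):
        one = np.ones((1, 1, 1), bool)
        zero = np.zeros((1, 1, 1), bool)
        assert adjudicate_priority({"kidney": one, "liver": one})[0, 0, 0] == 1
        assert adjudicate_priority({"spleen": one, "liver": one})[0, 0, 0] == 3
        assert adjudicate_priority({"kidney": zero, "liver": zero})[0, 0, 0] == 0

    def test_no_claimed_voxel_discarded(self):
        rng = np.random.default_rng(1)
        masks = {name: rng.random((8, 8, 8)) > 0.6 for name, _ in PRIORITY_ORDER}
        out = adjudicate_priority(masks)
        union = np.zeros((8, 8, 8), bool)
        for m in masks.values():
            union |= m
        assert np.count_nonzero(out) == np.count_nonzero(union)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(2)
        masks = {name: rng.random((5, 5, 5)) > 0.5 for name, _ in PRIORITY_ORDER}
        out = adjudicate_priority(masks)
        again = adjudicate_priority(
            {"kidney": out == 1, "spleen": out == 3, "liver": out == 4}
        )
        assert np.array_equal(out, again)


class TestSumEncoding:
    def test_rk_liver_overlap_is_pink_5(self):
        rk = np.zeros((3, 3, 1), bool); rk[1, 1] = True
        liver = np.zeros((3, 3, 1), bool); liver[1, 1] = True; liver[0, 0] = True
        out, audit = encode_overlaps_sum({"right_kidney": rk, "liver": liver})
        assert out.data[1, 1, 0] == 5
        assert out.data[0, 0, 0] == 4
        assert audit.n_overlap_voxels == 1

    def test_no_overlap_equals_standard_encoding(self):
        rk = np.zeros((4, 4, 1), bool); rk[0, 0] = True
        sp = np.zeros((4, 4, 1), bool); sp[1, 1] = True
        lv = np.zeros((4, 4, 1), bool); lv[2, 2] = True
        out, audit = encode_overlaps_sum({"right_kidney": rk, "spleen": sp, "liver": lv})
        expected = np.zeros((4, 4, 1), np.uint8)
        expected[0, 0], expected[1, 1], expected[2, 2] = 1, 3, 4
        assert np.array_equal(out.data, expected)
        assert audit.n_overlap_voxels == 0

    def test_lk_spleen_collision_with_rk_liver_flagged(self):
        lk = np.zeros((2, 2, 1), bool); lk[0, 0] = True
        sp = np.zeros((2, 2, 1), bool); sp[0, 0] = True
        rk = np.zeros((2, 2, 1), bool)
        lv = np.zeros((2, 2, 1), bool)
        out, audit = encode_overlaps_sum(
            {"left_kidney": lk, "spleen": sp, "right_kidney": rk, "liver": lv}
        )
        assert out.data[0, 0, 0] == 5  # same code as RK+liver
        assert audit.has_ambiguity
        assert 5 in audit.ambiguous_codes
        assert len(audit.ambiguous_codes[5]) == 2  # two distinct pairs sum to 5


class TestMidlineSplit:
    def test_phantom_truth_sides_recovered(self, noise_free_phantom):
        truth = noise_free_phantom.truth
        merged = truth.data.copy()
        merged[merged == 2] = 1  # merge kidneys as the model output does
        out = split_kidneys_midline(merged, truth.spacing_mm, CANONICAL_AXCODES)
        assert np.array_equal(out.data, truth.data)

    def test_all_kidney_right_of_midline_gives_no_left_label(self):
        data = np.zeros((10, 4, 4), np.uint8)
        data[:4, :, :] = 1  # low first-axis index = patient right
        out = split_kidneys_midline(data, (1, 1, 1), CANONICAL_AXCODES)
        assert not (out.data == 2).any()
        assert (out.data == 1).sum() == 4 * 16

    def test_voxel_exactly_on_midline_stays_right(self):
        data = np.zeros((11, 3, 3), np.uint8)  # odd width: index 5 is the plane
        data[5, 1, 1] = 1
        out = split_kidneys_midline(data, (1, 1, 1), CANONICAL_AXCODES)
        assert out.data[5, 1, 1] == 1

    def test_partition_preserves_kidney_count(self):
        rng = np.random.default_rng(3)
        data = (rng.random((9, 6, 6)) > 0.5).astype(np.uint8)
        out = split_kidneys_midline(data, (1, 1, 1), CANONICAL_AXCODES)
        assert (out.data == 1).sum() + (out.data == 2).sum() == data.sum()

    def test_unknown_orientation_rejected(self):
        with pytest.raises(ValueError, match="orientation"):
            split_kidneys_midline(np.zeros((4, 4, 4), np.uint8), (1, 1, 1), None)

    def test_non_kidney_labels_untouched(self):
        data = np.zeros((8, 4, 4), np.uint8)
        data[7, 0, 0] = 3
        data[0, 0, 0] = 4
        out = split_kidneys_midline(data, (1, 1, 1), CANONICAL_AXCODES)
        assert out.data[7, 0, 0] == 3 and out.data[0, 0, 0] == 4


class TestEnsembleInference:
    def test_untrained_model_output_shape_and_codomain(self, noise_free_phantom):
        from adpkdvol.model import OrganCheckpoint, TrainConfig
        from adpkdvol.nn import ArchConfig, build_model
        from adpkdvol.preprocess import PreprocessConfig, AugmentConfig

        arch = ArchConfig(encoder="tiny", seed=0)
        pcfg = PreprocessConfig(train_map_size=64, train_crop_size=64, infer_size=64,
                                augment=AugmentConfig(enabled=False))
        ckpt = OrganCheckpoint("kidney", build_model(arch).state_dict(), arch, pcfg, 0.0, -1)
        prob = infer_organ(noise_free_phantom.image, ckpt)
        assert prob.grid_shape == noise_free_phantom.image.grid_shape
        assert prob.data.min() >= 0 and prob.data.max() <= 1

    def test_inference_deterministic(self, e2e_report):
        subject_img = None
        # reuse a trained checkpoint on a fresh phantom
        from adpkdvol.phantom import PhantomSpec, generate_phantom

        subject = generate_phantom(PhantomSpec(noise_sd=0.0, seed=123))
        ckpt = e2e_report.checkpoints["kidney"]
        a = infer_organ(subject.image, ckpt)
        b = infer_organ(subject.image, ckpt)
        assert np.array_equal(a.data, b.data)

    def test_trained_kidney_checkpoint_recovers_truth(self, e2e_report):
        from adpkdvol.model import binary_target
        from adpkdvol.phantom import PhantomSpec, generate_phantom

        subject = generate_phantom(PhantomSpec(noise_sd=0.0, seed=321))
        prob = infer_organ(subject.image, e2e_report.checkpoints["kidney"])
        assert dsc(prob.data > 0.5, binary_target(subject.truth, "kidney")) >= 0.8

    def test_run_ensemble_output_conventions(self, e2e_report):
        pred = e2e_report.predictions[0]
        assert set(np.unique(pred.data)) <= {0, 1, 2, 3, 4}
        assert pred.convention == "standard"

    def test_run_ensemble_heldout_dsc(self, e2e_report):
        for label, value in e2e_report.per_label_dsc.items():
            assert value >= 0.8, f"label {label} DSC {value:.3f}"
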