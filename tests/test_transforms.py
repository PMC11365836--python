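"""Intensity/rotation pretexts and augmentation policies."""

import numpy as np
import pytest
from scipy.stats import chisquare

from ivdseg import (TransformParams, apply_intensity_transform,
                    apply_rotation_pretext, augment_pretext,
                    augment_segmentation, sample_pretext)
from ivdseg.phantom import DomainSample


class TestApplyIntensityTransform:
    def test_identity_bit_equal(self, tiny_dataset, transform_params):
        v = tiny_dataset[0].volume
        out = apply_intensity_transform(v, 0, transform_params, draw_seed=3)
        assert np.array_equal(out, v)

    def test_blur_reduces_variance(self, transform_params, rng):
        for _ in range(5):
            v = rng.random((12, 12, 8)).astype(np.float32)
            out = apply_intensity_transform(v, 2, transform_params,
                                            draw_seed=int(rng.integers(1e6)))
            assert out.var() <= v.var()

    def test_noise_std_matches_drawn_sigma(self):
        # constant 0.5 volume, sigma forced to 0.1: sample std of the noise
        # is chi-distributed with SE ~ sigma/sqrt(2n); 3 SE band at n=2048
        params = TransformParams(noise_sigma_range=(0.1, 0.1), rng_seed=2)
        v = np.full((16, 16, 8), 0.5, np.float32)
        out = apply_intensity_transform(v, 1, params, draw_seed=9)
        n = v.size
        se = 0.1 / np.sqrt(2 * n)
        assert abs((out - 0.5).std() - 0.1) < 3 * se

    def test_contrast_stretches_about_midgrey(self, transform_params):
        # the saturating stretch pushes values away from 0.5 and clips
        lo = np.full((4, 4, 4), 0.3, np.float32)
        hi = np.full((4, 4, 4), 0.7, np.float32)
        ext = np.full((4, 4, 4), 0.95, np.float32)
        assert (apply_intensity_transform(lo, 3, transform_params, 1)
                < lo).all()
        assert (apply_intensity_transform(hi, 3, transform_params, 1)
                > hi).all()
        assert (apply_intensity_transform(ext, 3, transform_params, 1)
                == 1.0).all()  # saturates

    def test_outputs_in_unit_range(self, tiny_dataset, transform_params, rng):
        v = tiny_dataset[1].volume
        for cid in range(4):
            out = apply_intensity_transform(v, cid, transform_params,
                                            int(rng.integers(1e6)))
            assert out.min() >= 0.0 and out.max() <= 1.0
            assert out.shape == v.shape

    def test_unknown_class_rejected(self, tiny_dataset, transform_params):
        with pytest.raises(ValueError):
            apply_intensity_transform(tiny_dataset[0].volume, 7,
                                      transform_params, 0)

    def test_deterministic(self, tiny_dataset, transform_params):
        v = tiny_dataset[0].volume
        a = apply_intensity_transform(v, 1, transform_params, 123)
        b = apply_intensity_transform(v, 1, transform_params, 123)
        assert np.array_equal(a, b)


class TestSamplePretext:
    def test_class_marginals_uniform(self, tiny_dataset, transform_params):
        # chi-square GOF at n=4000 must not reject uniformity at alpha=0.001,
        # and each count sits in the binomial 99% band [900, 1100]
        sample = tiny_dataset[0]
        labels = [sample_pretext(sample, transform_params, seed).label
                  for seed in range(4000)]
        counts = np.bincount(labels, minlength=4)
        assert chisquare(counts).pvalue > 0.001
        assert counts.min() >= 900 and counts.max() <= 1100

    def test_label_matches_applied_transform(self, tiny_dataset,
                                             transform_params):
        for seed in range(25):
            ps = sample_pretext(tiny_dataset[0], transform_params, seed)
            redo = apply_intensity_transform(tiny_dataset[0].volume, ps.label,
                                             transform_params, seed)
            assert np.array_equal(ps.volume, redo)

    def test_mask_untouched(self, tiny_dataset, transform_params):
        sample = tiny_dataset[2]
        before = sample.mask.copy()
        for seed in range(8):
            sample_pretext(sample, transform_params, seed)
        assert np.array_equal(sample.mask, before)

    def test_deterministic(self, tiny_dataset, transform_params):
        a = sample_pretext(tiny_dataset[0], transform_params, 55)
        b = sample_pretext(tiny_dataset[0], transform_params, 55)
        assert a.label == b.label
        assert np.array_equal(a.volume, b.volume)


class TestRotationPretext:
    def test_group_closure(self, rng):
        v = rng.random((8, 8, 4)).astype(np.float32)
        for k in range(4):
            out = v
            for _ in range(4):
                out = apply_rotation_pretext(out, k)
            # k applied 4 times is k*4 quarter-turns = identity
            assert np.array_equal(out, v)

    def test_identity_and_involution(self, rng):
        v = rng.random((6, 6, 3)).astype(np.float32)
        assert np.array_equal(apply_rotation_pretext(v, 0), v)
        twice = apply_rotation_pretext(apply_rotation_pretext(v, 2), 2)
        assert np.array_equal(twice, v)

    def test_composition_inverse(self, rng):
        v = rng.random((8, 8, 4)).astype(np.float32)
        for k in range(4):
            out = apply_rotation_pretext(apply_rotation_pretext(v, k), 4 - k
                                         if k else 0)
            assert np.array_equal(out, v)

    def test_non_square_odd_rotation_rejected(self, rng):
        v = rng.random((8, 6, 4)).astype(np.float32)
        with pytest.raises(ValueError):
            apply_rotation_pretext(v, 1)
        # even turns are fine on non-square planes
        assert apply_rotation_pretext(v, 2).shape == v.shape


class TestAugmentation:
    def test_mask_stays_binary(self, tiny_dataset):
        for seed in range(10):
            out = augment_segmentation(tiny_dataset[0], seed)
            assert set(np.unique(out.mask)) <= {0, 1}
            assert out.volume.shape == tiny_dataset[0].volume.shape

    def test_zero_probability_is_identity(self, tiny_dataset):
        out = augment_segmentation(tiny_dataset[0], 3, prob=0.0)
        assert np.array_equal(out.volume, tiny_dataset[0].volume)
        assert np.array_equal(out.mask, tiny_dataset[0].mask)

    def test_rotation_preserves_foreground_count(self, tiny_dataset):
        # nearest-neighbour interpolation loss on compact ellipsoids stays
        # well under 15% of foreground voxels
        for s in tiny_dataset[:4]:
            n0 = int(s.mask.sum())
            for seed in range(5):
                out = augment_segmentation(s, seed, prob=1.0,
                                           max_brightness=0.0)
                assert abs(int(out.mask.sum()) - n0) <= 0.15 * n0

    def test_requires_mask(self, tiny_dataset):
        unlabeled = DomainSample(tiny_dataset[0].volume, None, "S", "x")
        with pytest.raises(ValueError):
            augment_segmentation(unlabeled, 0)

    def test_pretext_augment_flip_preserves_histogram(self, tiny_dataset):
        v = tiny_dataset[0].volume
        flipped = v[::-1].copy()
        h0, _ = np.histogram(v, bins=16, range=(0, 1))
        h1, _ = np.histogram(flipped, bins=16, range=(0, 1))
        assert np.array_equal(h0, h1)

    def test_pretext_augment_deterministic_and_noop(self, tiny_dataset):
        v = tiny_dataset[0].volume
        assert np.array_equal(augment_pretext(v, 5, prob=0.0), v)
        a = augment_pretext(v, 17)
        b = augment_pretext(v, 17)
        assert np.array_equal(a, b)


def test_invalid_transform_params_rejected():
    with pytest.raises(ValueError):
        TransformParams(noise_sigma_range=(0.2, 0.1))
    with pytest.raises(ValueError):
        TransformParams(blur_sigma_range=(0.0, 1.0))
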