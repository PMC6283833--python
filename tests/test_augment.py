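"""Mask construction, blending provenance, flips, Gaussian baseline, batches."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perlinaug.augment import (
    AugmentedPatch,
    ClassLabel,
    Patch,
    field_to_mask,
    gaussian_augment,
    make_batch,
    perlin_blend,
    random_flip,
)
from perlinaug.noise import NoiseField, noise_field


def _patch(fill, label, shape=(20, 20)):
    return Patch(pixels=np.full(shape, float(fill)), label=label)


def _field(values):
    return NoiseField(values=np.asarray(values, dtype=float), scale=0.1, seed=0)


class TestFieldToMask:
    def test_all_positive_field_gives_all_true(self):
        m = field_to_mask(_field(np.full((4, 4), 0.5)))
        assert m.region.all()

    def test_exact_zero_goes_to_positive_region(self):
        v = np.full((3, 3), -0.5)
        v[1, 1] = 0.0
        m = field_to_mask(_field(v))
        assert m.region[1, 1] and m.region.sum() == 1

    def test_partition_is_exhaustive(self):
        m = field_to_mask(noise_field(20, 20, scale=0.1, seed=0))
        assert int(m.region.sum()) + int((~m.region).sum()) == 400

    def test_true_fraction_near_half_over_1000_seeds(self):
        """Simplex noise is sign-symmetric in distribution, so the mean mask
        true-fraction over many seeds sits near 0.5."""
        fracs = [
            field_to_mask(noise_field(20, 20, scale=0.1, seed=s)).region.mean()
            for s in range(1000)
        ]
        assert 0.45 <= np.mean(fracs) <= 0.55


class TestPerlinBlend:
    def test_all_true_mask_returns_patch_a(self):
        a, b = _patch(10, ClassLabel.GGO), _patch(-500, ClassLabel.NORMAL)
        out = perlin_blend(a, b, field_to_mask(_field(np.ones((20, 20)))))
        assert np.array_equal(out.pixels, a.pixels)
        assert np.all(out.labels == int(ClassLabel.GGO))

    def test_identical_sources_blend_to_source(self):
        a = _patch(-800, ClassLabel.EMPHYSEMA)
        mask = field_to_mask(noise_field(20, 20, scale=0.1, seed=1))
        out = perlin_blend(a, a, mask)
        assert np.array_equal(out.pixels, a.pixels)
        assert np.all(out.labels == int(ClassLabel.EMPHYSEMA))

    def test_label_counts_match_mask_counts(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(-1, 1, (20, 20))
        # force exactly 137 non-negative pixels
        flat = np.argsort(v.ravel())
        v_sorted = np.full(400, -0.5)
        v_sorted[flat[-137:]] = 0.5
        mask = field_to_mask(_field(v_sorted.reshape(20, 20)))
        assert int(mask.region.sum()) == 137
        out = perlin_blend(_patch(1, ClassLabel.RO), _patch(2, ClassLabel.GGO), mask)
        assert int(np.sum(out.labels == int(ClassLabel.RO))) == 137
        assert int(np.sum(out.labels == int(ClassLabel.GGO))) == 263

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True)
    def test_pixel_provenance(self, seed):
        """Every output pixel is bit-identical to the source patch its label names."""
        rng = np.random.default_rng(seed)
        a = Patch(pixels=rng.uniform(-1000, 400, (20, 20)), label=ClassLabel.CONSOLIDATION)
        b = Patch(pixels=rng.uniform(-1000, 400, (20, 20)), label=ClassLabel.HONEYCOMBING)
        out = perlin_blend(a, b, field_to_mask(noise_field(20, 20, scale=0.1, seed=seed)))
        from_a = out.labels == int(a.label)
        assert np.array_equal(out.pixels[from_a], a.pixels[from_a])
        assert np.array_equal(out.pixels[~from_a], b.pixels[~from_a])

    def test_shape_mismatch_rejected(self):
        a = _patch(0, ClassLabel.NORMAL, shape=(20, 20))
        b = _patch(0, ClassLabel.GGO, shape=(10, 10))
        with pytest.raises(ValueError, match="shape"):
            perlin_blend(a, b, field_to_mask(_field(np.ones((20, 20)))))


def _find_flip_seed(want_ud, want_lr):
    probe = Patch(pixels=np.array([[1.0, 2.0], [3.0, 4.0]]), label=ClassLabel.NORMAL)
    for seed in range(10_000):
        out = random_flip(probe, seed).pixels
        ud = out[0, 0] in (3.0, 4.0)
        lr = out[0, 0] in (2.0, 4.0)
        if ud == want_ud and lr == want_lr:
            return seed
    raise AssertionError("no seed found")


class TestRandomFlip:
    def test_double_flip_is_180_rotation(self):
        seed = _find_flip_seed(True, True)
        p = Patch(pixels=np.array([[1.0, 2.0], [3.0, 4.0]]), label=ClassLabel.GGO)
        assert np.array_equal(random_flip(p, seed).pixels, [[4.0, 3.0], [2.0, 1.0]])

    def test_no_flip_seed_is_identity(self):
        seed = _find_flip_seed(False, False)
        p = Patch(pixels=np.arange(4.0).reshape(2, 2), label=ClassLabel.RO)
        assert np.array_equal(random_flip(p, seed).pixels, p.pixels)

    def test_forced_flip_is_involution(self):
        seed = _find_flip_seed(True, False)
        p = Patch(pixels=np.arange(16.0).reshape(4, 4), label=ClassLabel.RO)
        assert np.array_equal(random_flip(random_flip(p, seed), seed).pixels, p.pixels)

    def test_label_grid_flipped_with_pixels(self):
        seed = _find_flip_seed(True, True)
        ap = AugmentedPatch(
            pixels=np.arange(4.0).reshape(2, 2),
            labels=np.array([[0, 1], [2, 3]]),
            provenance=("x",),
        )
        out = random_flip(ap, seed)
        assert np.array_equal(out.labels, [[3, 2], [1, 0]])
        assert np.array_equal(out.pixels, [[3.0, 2.0], [1.0, 0.0]])

    def test_four_flip_combinations_equidistributed(self):
        probe = Patch(pixels=np.array([[1.0, 2.0], [3.0, 4.0]]), label=ClassLabel.NORMAL)
        counts = {1.0: 0, 2.0: 0, 3.0: 0, 4.0: 0}
        for seed in range(10_000):
            counts[random_flip(probe, seed).pixels[0, 0]] += 1
        for c in counts.values():
            assert abs(c / 10_000 - 0.25) < 0.02


class TestGaussianAugment:
    def test_constant_patch_unchanged(self):
        p = _patch(-800, ClassLabel.NORMAL)
        assert np.array_equal(gaussian_augment(p, 0).pixels, p.pixels)

    def test_noise_sd_is_tenth_of_patch_sd(self):
        """Added noise has sigma = std(patch)/10; Monte-Carlo over 1000 seeds
        must land within 15%."""
        rng = np.random.default_rng(0)
        base = rng.normal(0.0, 100.0, (20, 20))
        base = (base - base.mean()) / base.std() * 100.0  # exact sd 100
        p = Patch(pixels=base, label=ClassLabel.GGO)
        sds = [np.std(gaussian_augment(p, s).pixels - base) for s in range(1000)]
        assert abs(np.mean(sds) - 10.0) / 10.0 < 0.15

    def test_deterministic_in_seed(self):
        p = Patch(pixels=np.random.default_rng(3).uniform(-500, 0, (20, 20)),
                  label=ClassLabel.RO)
        assert np.array_equal(gaussian_augment(p, 7).pixels, gaussian_augment(p, 7).pixels)


class TestMakeBatch:
    @pytest.fixture()
    def pool(self):
        rng = np.random.default_rng(5)
        return [
            Patch(pixels=rng.uniform(-1000, 400, (20, 20)), label=ClassLabel(i % 6))
            for i in range(30)
        ]

    def test_batch_size_respected(self, pool):
        assert len(make_batch(pool, 16, "perlin", seed=0)) == 16

    def test_single_patch_pool_gives_uniform_labels(self, pool):
        batch = make_batch(pool[:1], 8, "perlin", seed=1)
        for item in batch:
            assert np.all(item.labels == int(pool[0].label))

    def test_perlin_items_mix_at_most_two_classes(self, pool):
        for item in make_batch(pool, 32, "perlin", seed=2):
            assert len(np.unique(item.labels)) <= 2

    def test_conventional_uniform_class_draws(self, pool):
        """1000 single-source items from a balanced 6-class pool draw each
        class with frequency 1/6 +- 0.03."""
        batch = make_batch(pool, 1000, "conventional", seed=3)
        labels = np.array([item.labels[0, 0] for item in batch])
        for c in range(6):
            assert abs(np.mean(labels == c) - 1 / 6) < 0.03

    def test_conventional_never_mixes_classes(self, pool):
        for item in make_batch(pool, 32, "conventional", seed=4):
            assert len(np.unique(item.labels)) == 1

    def test_reproducible_from_seed(self, pool):
        a = make_batch(pool, 8, "perlin", seed=9)
        b = make_batch(pool, 8, "perlin", seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.pixels, y.pixels)
            assert np.array_equal(x.labels, y.labels)

    def test_distinct_classes_option(self, pool):
        for item in make_batch(pool, 32, "perlin", seed=5, distinct_classes=True):
            a, b, _ = item.provenance
            assert a != b

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            make_batch([], 4, "perlin", seed=0)
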