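"""Phantom generation, augmentation and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from skimage.morphology import convex_hull_image

from osteoformer.config import ConfigurationError
from osteoformer.phantoms import (
    ANATOMY_TAGS,
    augment_gaussian,
    build_dataset,
    generate_dataset,
    generate_phantom,
    load_manifest,
    save_samples,
    split_dataset,
)


def flood_fill_components(mask):
    """Independent component-count oracle: explicit BFS flood fill."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    count = 0
    H, W = mask.shape
    for sy in range(H):
        for sx in range(W):
            if mask[sy, sx] and not seen[sy, sx]:
                count += 1
                stack = [(sy, sx)]
                seen[sy, sx] = True
                while stack:
                    y, x = stack.pop()
                    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < H and 0 <= nx < W and mask[ny, nx] \
                                and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
    return count


class TestGeneratePhantom:
    def test_deterministic_bit_identical(self):
        a = generate_phantom("vertebra", 256, 7)
        b = generate_phantom("vertebra", 256, 7)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    @pytest.mark.parametrize("tag", ANATOMY_TAGS)
    @pytest.mark.parametrize("size", [64, 128])
    def test_contract(self, tag, size):
        s = generate_phantom(tag, size, 3)
        assert s.image.shape == s.mask.shape == (size, size)
        assert s.image.min() >= 0 and s.image.max() <= 1
        assert set(np.unique(s.mask)) <= {0, 1}
        assert not s.augmented

    def test_hand_has_at_least_five_components(self):
        mask = generate_phantom("hand", 256, 3).mask
        assert flood_fill_components(mask) >= 5
        # the library labelling agrees with the flood-fill oracle
        assert ndimage.label(mask)[1] == flood_fill_components(mask)

    def test_hand_components_separated_by_background(self):
        mask = generate_phantom("hand", 128, 5).mask
        n = ndimage.label(mask)[1]
        assert n >= 5  # gaps of >= 1 px keep the bones disconnected

    def test_femur_single_component_and_fraction(self):
        mask = generate_phantom("femur", 128, 1).mask
        assert ndimage.label(mask)[1] == 1
        frac = mask.sum() / mask.size
        assert 0 < frac < 0.5

    @pytest.mark.parametrize("seed", [0, 4, 9])
    def test_vertebra_is_concave(self, seed):
        mask = generate_phantom("vertebra", 128, seed).mask.astype(bool)
        solidity = mask.sum() / convex_hull_image(mask).sum()
        assert solidity < 0.95

    def test_invalid_size_names_constraint(self):
        with pytest.raises(ConfigurationError, match="divisible by 32"):
            generate_phantom("femur", 100, 0)

    def test_invalid_tag_and_seed(self):
        with pytest.raises(ValueError):
            generate_phantom("skull", 64, 0)
        with pytest.raises(ValueError):
            generate_phantom("femur", 64, -1)


class TestAugment:
    def test_factor_three_triples(self):
        samples = generate_dataset(4, size=32, seed=0)
        out = augment_gaussian(samples, factor=3, seed=1)
        assert len(out) == 12

    def test_factor_one_is_identity(self):
        samples = generate_dataset(3, size=32, seed=0)
        out = augment_gaussian(samples, factor=1, seed=1)
        assert out == samples

    def test_masks_preserved_and_clipping(self):
        samples = generate_dataset(10, size=32, seed=2)
        out = augment_gaussian(samples, factor=4, sigma=0.05, seed=3)
        assert len(out) == 40
        for i, s in enumerate(out):
            src = samples[i // 4]
            assert np.array_equal(s.mask, src.mask)
            assert s.image.min() >= 0 and s.image.max() <= 1
        originals = [s for s in out if not s.augmented]
        assert originals == samples

    def test_noise_actually_perturbs(self):
        samples = generate_dataset(2, size=32, seed=2)
        out = augment_gaussian(samples, factor=2, sigma=0.05, seed=3)
        assert not np.array_equal(out[0].image, out[1].image)

    def test_bad_factor(self):
        with pytest.raises(ConfigurationError):
            augment_gaussian([], factor=0)


class TestSplit:
    def test_counts_276(self):
        samples = generate_dataset(276, size=32, seed=0)
        split = split_dataset(samples, (8, 1, 1), seed=5)
        assert (len(split.train), len(split.test), len(split.val)) == (220, 28, 28)

    def test_counts_exact_division(self):
        samples = generate_dataset(10, size=32, seed=0)
        split = split_dataset(samples, (8, 1, 1), seed=5)
        assert (len(split.train), len(split.test), len(split.val)) == (8, 1, 1)

    def test_deterministic_membership(self):
        samples = generate_dataset(13, size=32, seed=0)
        a = split_dataset(samples, (8, 1, 1), seed=5)
        b = split_dataset(samples, (8, 1, 1), seed=5)
        assert [id(s) for s in a.train] == [id(s) for s in b.train]
        assert [id(s) for s in a.test] == [id(s) for s in b.test]

    def test_disjoint_and_conserving(self):
        samples = generate_dataset(17, size=32, seed=1)
        split = split_dataset(samples, (8, 1, 1), seed=2)
        ids = [id(s) for part in (split.train, split.test, split.val) for s in part]
        assert len(ids) == len(set(ids)) == 17

    def test_errors(self):
        samples = generate_dataset(2, size=32, seed=0)
        with pytest.raises(ValueError):
            split_dataset(samples, (8, 1, 1), seed=0)
        with pytest.raises(ValueError):
            split_dataset(generate_dataset(5, size=32, seed=0), (8, 0, 1), seed=0)

    @given(n=st.integers(3, 120), seed=st.integers(0, 10))
    @settings(max_examples=25, deadline=None)
    def test_counts_sum_property(self, n, seed):
        samples = generate_dataset(3, size=32, seed=0) * ((n + 2) // 3)
        samples = samples[:n]
        split = split_dataset(samples, (8, 1, 1), seed=seed)
        assert len(split.train) + len(split.test) + len(split.val) == n


class TestBuildDataset:
    def test_leakage_free_default_augments_train_only(self):
        samples = generate_dataset(10, size=32, seed=4)
        split = build_dataset(samples, factor=3, seed=0)
        assert len(split.train) == 24 and len(split.test) == 1 and len(split.val) == 1
        assert not any(s.augmented for s in split.test + split.val)

    def test_augment_before_split_variant(self):
        samples = generate_dataset(10, size=32, seed=4)
        split = build_dataset(samples, factor=3, seed=0, augment_before_split=True)
        assert len(split) == 30
        assert (len(split.test), len(split.val)) == (3, 3)


class TestDiskRoundTrip:
    def test_png_manifest_roundtrip(self, tmp_path):
        samples = generate_dataset(6, size=32, seed=8)
        split = split_dataset(samples, (4, 1, 1), seed=0)
        manifest = save_samples(split, tmp_path)
        assert manifest.exists()
        back = load_manifest(manifest)
        assert len(back) == 6
        train_back = load_manifest(manifest, split="train")
        assert len(train_back) == len(split.train)
        for orig, loaded in zip(split.train, train_back):
            assert np.array_equal(orig.mask, loaded.mask)  # masks are bit-exact
            assert np.abs(orig.image - loaded.image).max() <= 1 / 255  # 8-bit PNG
            assert loaded.anatomy_tag == orig.anatomy_tag
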