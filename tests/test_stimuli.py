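"""Stimulus generators: band/stripe construction rules, the mirror
constructor, block upscaling, and label soundness against the exact oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirrornet.exceptions import InvalidSpecError
from mirrornet.stimuli import (
    BAND_VALUE,
    FamilySpec,
    generate_family,
    make_band_image,
    make_stripe_image,
    make_training_corpus,
    mirror_image,
    oracle_classify,
    oracle_classify_batch,
    upscale_blocks,
)


def band_cols(b):
    return slice(10 - b // 2, 10 + b // 2)


class TestBandImages:
    def test_symmetric_band4_structure(self, rng):
        img = make_band_image(4, True, "normal", np.random.default_rng(7))
        assert img.shape == (20, 20) and img.dtype == np.uint8
        assert np.all(img[:, 8:12] == BAND_VALUE)
        assert np.array_equal(img, img[:, ::-1])  # equals its own mirror

    def test_band0_has_full_flanks(self):
        img = make_band_image(0, True, "normal", np.random.default_rng(1))
        # no constant central band: with 10-wide random flanks some column
        # in the centre must deviate from 128
        assert not np.all(img[:, 9:11] == BAND_VALUE)
        assert np.array_equal(img[:, :10], img[:, 10:][:, ::-1])

    def test_nonsymmetric_fails_mirror_test(self):
        img = make_band_image(4, False, "normal", np.random.default_rng(3))
        assert oracle_classify(img, 4) == 0

    def test_dark_family_range(self, rng):
        img = make_band_image(4, False, "dark", rng)
        assert img.max() <= BAND_VALUE

    def test_normal_family_range(self, rng):
        imgs = np.stack([make_band_image(0, False, "normal", rng) for _ in range(50)])
        assert imgs.min() >= 1 and imgs.max() <= 255

    @pytest.mark.parametrize("bad", [3, -2, 20, 19])
    def test_invalid_band_size_rejected(self, bad, rng):
        with pytest.raises(InvalidSpecError):
            make_band_image(bad, True, "normal", rng)


class TestStripeImages:
    @pytest.mark.parametrize("x", [2, 4, 6, 8, 10])
    def test_structure(self, x, rng):
        img = make_stripe_image(x, True, rng)
        bg = np.delete(img, [x, 19 - x], axis=1)
        assert np.all(bg == BAND_VALUE)
        assert np.array_equal(img[:, x], img[:, 19 - x])

    def test_stripe10_adjacent_to_midline(self):
        img = make_stripe_image(10, True, np.random.default_rng(5))
        assert np.array_equal(img[:, 10], img[:, 9])

    def test_nonsymmetric_columns_differ(self):
        img = make_stripe_image(8, False, np.random.default_rng(9))
        assert np.any(img[:, 8] != img[:, 11])
        assert oracle_classify(img) == 0

    def test_invalid_position_rejected(self, rng):
        with pytest.raises(InvalidSpecError):
            make_stripe_image(3, True, rng)


class TestMirrorAndUpscale:
    def test_mirror_idempotent_on_symmetric(self, rng):
        img = make_band_image(4, True, "normal", rng)
        assert np.array_equal(mirror_image(img), img)

    def test_mirror_constant_image(self):
        img = np.full((20, 20), 7, np.uint8)
        assert np.array_equal(mirror_image(img), img)

    def test_mirror_makes_any_image_symmetric(self, rng):
        img = make_band_image(0, False, "normal", rng)
        assert oracle_classify(mirror_image(img)) == 1

    @given(st.integers(0, 2**32 - 1), st.integers(1, 4))
    @settings(max_examples=20, deadline=None)
    def test_upscale_preserves_mirror_symmetry(self, seed, block):
        img = make_band_image(6, True, "normal", np.random.default_rng(seed))
        up = upscale_blocks(img, block)
        assert up.shape == (20 * block, 20 * block)
        assert np.array_equal(up, up[:, ::-1])

    def test_upscale_identity_and_tiles(self, rng):
        img = make_band_image(2, False, "normal", rng)
        assert np.array_equal(upscale_blocks(img, 1), img)
        up = upscale_blocks(img, 2)
        tiles = up.reshape(20, 2, 20, 2)
        assert np.all(tiles == tiles[:, :1, :, :1])  # zero within-tile variance

    def test_upscale_rejects_nonpositive(self, rng):
        with pytest.raises(InvalidSpecError):
            upscale_blocks(make_band_image(0, True, "normal", rng), 0)


class TestFamiliesAndCorpus:
    def test_family_balance_and_label_soundness(self):
        spec = FamilySpec("band", band_size=4)
        fam = generate_family(spec, 40, seed=0)
        assert fam.labels.sum() == 20
        assert np.array_equal(oracle_classify_batch(fam.images, 4), fam.labels)

    def test_family_determinism(self):
        spec = FamilySpec("stripe", stripe_x=6)
        a, b = (generate_family(spec, 16, seed=3) for _ in range(2))
        assert np.array_equal(a.images, b.images)

    def test_band_constancy_across_family(self):
        fam = generate_family(FamilySpec("band", band_size=14), 100, seed=0)
        assert np.all(fam.images[:, :, band_cols(14)] == BAND_VALUE)

    def test_odd_n_rejected(self):
        with pytest.raises(InvalidSpecError):
            generate_family(FamilySpec("band", band_size=0), 5, seed=0)

    @pytest.mark.parametrize(
        "n_total,frac,n_train,n_val",
        [(4000, 0.10, 3600, 400), (2000, 0.05, 1900, 100)],
    )
    def test_corpus_split_sizes(self, n_total, frac, n_train, n_val):
        c = make_training_corpus(n_total, frac, seed=1)
        assert len(c.train_images) == n_train and len(c.val_images) == n_val
        # equal mix of the two training families overall
        sizes = np.concatenate([c.train_band_sizes, c.val_band_sizes])
        assert (sizes == 0).sum() == (sizes == 4).sum() == n_total // 2

    def test_corpus_split_disjoint_and_exhaustive(self):
        c = make_training_corpus(400, 0.10, seed=2)
        pool = np.concatenate([c.train_images, c.val_images])
        # regenerating with the same seed reproduces the same multiset
        c2 = make_training_corpus(400, 0.10, seed=2)
        assert np.array_equal(pool, np.concatenate([c2.train_images, c2.val_images]))
        assert len(pool) == 400

    def test_corpus_rejects_bad_total(self):
        with pytest.raises(InvalidSpecError):
            make_training_corpus(402, 0.1, seed=0)

    def test_spec_field_consistency(self):
        with pytest.raises(InvalidSpecError):
            FamilySpec("band", band_size=4, stripe_x=2)
        with pytest.raises(InvalidSpecError):
            FamilySpec("stripe", stripe_x=3)


class TestOracleSoundness:
    @pytest.mark.parametrize("b", [0, 2, 4, 6, 14, 16, 18])
    def test_oracle_matches_generator_labels(self, b):
        fam = generate_family(FamilySpec("band", band_size=b), 200, seed=b)
        assert np.array_equal(oracle_classify_batch(fam.images, b), fam.labels)

    def test_oracle_on_mirrored(self, rng):
        img = mirror_image(rng.integers(0, 256, (20, 20)).astype(np.uint8))
        assert oracle_classify(img, 0) == 1
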