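import numpy as np
import pytest

from foodpix.augment import (
    AugmentConfig,
    augment_pair,
    augment_training_set,
    augmented_size,
    flip_pair,
    noise_image,
    rotate_pair,
    zoom_pair,
    VARIANT_SUFFIXES,
)
from foodpix.imageset import DatasetManifest, ManifestItem, write_image, write_mask
from foodpix.segmetrics import confusion
from foodpix.synthetic import SceneSpec, generate_scene


@pytest.fixture()
def pair(registry8):
    return generate_scene(SceneSpec(width=100, height=75, seed=4), registry8)


def hist(mask, n=8):
    return np.bincount(mask.ravel(), minlength=n)


class TestRotate:
    def test_swaps_dimensions_for_quarter_turns(self, pair):
        image, mask = pair
        img90, msk90 = rotate_pair(image, mask, 90)
        assert img90.shape == (100, 75, 3)
        assert msk90.shape == (100, 75)

    def test_180_twice_is_identity(self, pair):
        image, mask = pair
        img2, msk2 = rotate_pair(*rotate_pair(image, mask, 180), 180)
        np.testing.assert_array_equal(img2, image)
        np.testing.assert_array_equal(msk2, mask)

    @pytest.mark.parametrize("angle", [90, 180, 270])
    def test_label_histogram_preserved(self, pair, angle):
        _, mask = pair
        _, rotated = rotate_pair(*pair, angle)
        np.testing.assert_array_equal(hist(rotated), hist(mask))

    def test_invalid_angle(self, pair):
        with pytest.raises(ValueError):
            rotate_pair(*pair, 45)


class TestFlip:
    def test_involution(self, pair):
        image, mask = pair
        img2, msk2 = flip_pair(*flip_pair(image, mask))
        np.testing.assert_array_equal(img2, image)
        np.testing.assert_array_equal(msk2, mask)

    def test_halves_swap(self):
        mask = np.zeros((4, 6), dtype=np.uint8)
        mask[:, :3] = 1
        mask[:, 3:] = 2
        image = np.zeros((4, 6, 3), dtype=np.uint8)
        _, flipped = flip_pair(image, mask)
        assert (flipped[:, :3] == 2).all() and (flipped[:, 3:] == 1).all()


class TestNoise:
    def test_mask_bit_identical_for_any_sigma(self, pair):
        image, mask = pair
        _, out_mask = noise_image(image, mask, sigma=25.0, seed=1)
        np.testing.assert_array_equal(out_mask, mask)

    def test_sigma_zero_is_identity(self, pair):
        image, mask = pair
        out_img, _ = noise_image(image, mask, sigma=0.0, seed=1)
        np.testing.assert_array_equal(out_img, image)

    def test_deterministic_per_seed(self, pair):
        image, mask = pair
        a, _ = noise_image(image, mask, sigma=10.0, seed=9)
        b, _ = noise_image(image, mask, sigma=10.0, seed=9)
        c, _ = noise_image(image, mask, sigma=10.0, seed=10)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_output_stays_in_byte_range(self, pair):
        image, mask = pair
        out, _ = noise_image(image, mask, sigma=80.0, seed=2)
        assert out.dtype == np.uint8


class TestZoom:
    def test_crop_window_arithmetic_500x375(self, registry8):
        # floor(0.75 * 500) = 375, floor(0.75 * 375) = 281
        image, mask = generate_scene(SceneSpec(width=500, height=375, seed=0), registry8)
        out_img, out_msk = zoom_pair(image, mask, 0.25)
        assert out_img.shape == (375, 500, 3)
        assert out_msk.shape == (375, 500)
        # the retained window is the central 281 x 375 crop, resized back:
        # corner pixels of the output come from inside the crop, not the border
        h0 = (375 - 281) // 2
        w0 = (500 - 375) // 2
        assert out_msk[0, 0] == mask[h0, w0]

    def test_border_only_class_disappears(self, registry8):
        mask = np.zeros((80, 80), dtype=np.uint8)
        mask[0:4, 0:4] = 7  # wholly inside the removed 12.5 % border (10 px)
        mask[38:42, 38:42] = 3
        image = registry8.palette()[mask]
        _, zoomed = zoom_pair(image, mask, 0.25)
        assert 7 not in np.unique(zoomed)
        assert 3 in np.unique(zoomed)

    def test_mask_labels_stay_categorical(self, pair, registry8):
        _, zoomed = zoom_pair(*pair, 0.25)
        assert set(np.unique(zoomed)) <= set(range(registry8.n_classes))

    @pytest.mark.parametrize("frac", [0.0, 0.5, 0.9])
    def test_invalid_border_fraction(self, pair, frac):
        with pytest.raises(ValueError):
            zoom_pair(*pair, frac)

    def test_small_fraction_approaches_identity(self, registry8):
        # with a tiny border fraction on an 80x80 pair the crop keeps 79x79
        # pixels, so content is nearly unchanged
        image, mask = generate_scene(
            SceneSpec(width=80, height=80, texture_sigma=0.0, seed=5), registry8
        )
        _, zoomed = zoom_pair(image, mask, 0.01)
        assert (zoomed == mask).mean() > 0.9


class TestVariantSet:
    def test_seven_variants_per_pair(self, pair):
        variants = augment_pair(*pair, AugmentConfig(), seed=0)
        assert set(variants) == set(VARIANT_SUFFIXES)
        assert len(variants) == 7

    def test_geometric_ops_commute_with_evaluation(self, registry8, rng):
        """confusion(T(pred), T(truth)) == confusion(pred, truth) for T in rotations/flips."""
        truth = rng.integers(0, 8, size=(20, 30), dtype=np.uint8)
        pred = rng.integers(0, 8, size=(20, 30), dtype=np.uint8)
        base = confusion(truth, pred, 8).n
        img = np.zeros((20, 30, 3), dtype=np.uint8)
        for transform in (
            lambda i, m: rotate_pair(i, m, 90),
            lambda i, m: rotate_pair(i, m, 180),
            lambda i, m: rotate_pair(i, m, 270),
            flip_pair,
        ):
            _, t_truth = transform(img, truth)
            _, t_pred = transform(img, pred)
            np.testing.assert_array_equal(confusion(t_truth, t_pred, 8).n, base)


class TestAugmentTrainingSet:
    def _write_pairs(self, tmp_path, registry, n, subset_tags):
        items = []
        for i, tag in enumerate(subset_tags):
            image, mask = generate_scene(
                SceneSpec(width=60, height=45, seed=i), registry
            )
            img = tmp_path / f"img{i}.png"
            msk = tmp_path / f"img{i}_mask.png"
            write_image(img, image)
            write_mask(msk, mask)
            items.append(ManifestItem(str(img), str(msk), tag))
        return DatasetManifest(items)

    def test_training_expands_sevenfold_others_untouched(self, tmp_path, registry8):
        manifest = self._write_pairs(
            tmp_path, registry8, 5,
            ["training", "training", "validation", "testing", "testing"],
        )
        out = augment_training_set(
            manifest, AugmentConfig(seed=1), registry8, tmp_path / "aug"
        )
        assert len(out) == augmented_size(2, 1, 2) == 7 * 2 + 1 + 2
        # validation/testing items pass through with original paths
        assert out.subset("validation") == manifest.subset("validation")
        assert out.subset("testing") == manifest.subset("testing")

    def test_single_training_pair_yields_seven(self, tmp_path, registry8):
        manifest = self._write_pairs(tmp_path, registry8, 1, ["training"])
        out = augment_training_set(
            manifest, AugmentConfig(seed=0), registry8, tmp_path / "aug"
        )
        assert len(out) == 7
        suffixes = {p.image.rsplit("_", 1)[-1].removesuffix(".png") for p in out.items}
        assert suffixes == set(VARIANT_SUFFIXES)

    def test_empty_training_subset_is_noop(self, tmp_path, registry8):
        manifest = self._write_pairs(tmp_path, registry8, 2, ["validation", "testing"])
        out = augment_training_set(
            manifest, AugmentConfig(seed=0), registry8, tmp_path / "aug"
        )
        assert out == manifest
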