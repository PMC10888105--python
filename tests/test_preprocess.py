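"""Cropping pipeline: grayscale, blur, Otsu, largest component, full crop."""

import numpy as np
import pytest

from swarmvote import (
    PhantomSpec,
    crop_brain,
    gaussian_blur,
    generate_phantom,
    largest_component_box,
    otsu_binarize,
    to_grayscale,
)
from swarmvote.errors import RuntimeFailure, ValidationError
from swarmvote.preprocess import otsu_threshold


def otsu_bruteforce(image):
    """Exhaustive 0-255 between-class-variance search (independent oracle)."""
    hist = np.bincount(image.ravel(), minlength=256).astype(float)
    best_t, best_var = None, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = hist[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def flood_fill_components(mask):
    """8-connected components by explicit flood fill (independent oracle)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for r0, c0 in zip(*np.nonzero(mask)):
        if seen[r0, c0]:
            continue
        stack, pix = [(r0, c0)], []
        seen[r0, c0] = True
        while stack:
            r, c = stack.pop()
            pix.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]:
                        if mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
        comps.append(pix)
    return comps


class TestToGrayscale:
    def test_single_channel_identity(self):
        img = np.arange(12, dtype=np.uint8).reshape(3, 4)
        assert to_grayscale(img) is img

    def test_uniform_rgb_maps_to_same_value(self):
        img = np.full((4, 4, 3), 77, dtype=np.uint8)
        assert np.all(to_grayscale(img) == 77)

    def test_red_brighter_than_blue_under_luma(self):
        red = np.zeros((1, 1, 3), dtype=np.uint8)
        red[..., 0] = 255
        blue = np.zeros((1, 1, 3), dtype=np.uint8)
        blue[..., 2] = 255
        # 0.299*255 = 76.245 -> 76 ; 0.114*255 = 29.07 -> 29
        assert to_grayscale(red)[0, 0] == 76
        assert to_grayscale(blue)[0, 0] == 29
        assert to_grayscale(red)[0, 0] > to_grayscale(blue)[0, 0]

    def test_unsupported_channels_rejected(self):
        with pytest.raises(ValidationError):
            to_grayscale(np.zeros((4, 4, 2), dtype=np.uint8))


class TestGaussianBlur:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 123, dtype=np.uint8)
        assert np.array_equal(gaussian_blur(img, 9), img)

    def test_kernel_size_one_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (15, 17), dtype=np.uint8)
        assert np.array_equal(gaussian_blur(img, 1), img)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValidationError):
            gaussian_blur(np.zeros((5, 5), dtype=np.uint8), 8)

    def test_single_bright_pixel_spreads_but_stays_peaked(self):
        img = np.zeros((21, 21), dtype=np.uint8)
        img[10, 10] = 255
        out = gaussian_blur(img, 9)
        assert np.unravel_index(out.argmax(), out.shape) == (10, 10)
        assert out[10, 10] < 255
        # direct convolution oracle: center weight of the normalized 9x9 kernel
        sigma = 0.3 * ((9 - 1) / 2 - 1) + 0.8
        k1 = np.exp(-0.5 * (np.arange(-4, 5) / sigma) ** 2)
        k1 /= k1.sum()
        expected = 255 * k1[4] * k1[4]
        assert out[10, 10] == round(expected)

    def test_mean_preserved_away_from_borders(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (60, 60), dtype=np.uint8)
        out = gaussian_blur(img, 9)
        inner = slice(8, -8)
        assert abs(float(out[inner, inner].mean()) - float(img[inner, inner].mean())) < 0.5


class TestOtsu:
    def test_bimodal_split(self):
        img = np.concatenate(
            [np.full(50, 10, np.uint8), np.full(50, 200, np.uint8)]
        ).reshape(10, 10)
        mask = otsu_binarize(img)
        assert np.array_equal(mask, img == 200)

    def test_constant_image_degenerate(self):
        with pytest.raises(RuntimeFailure):
            otsu_binarize(np.full((8, 8), 42, dtype=np.uint8))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_search_on_phantoms(self, seed):
        image, _ = generate_phantom(PhantomSpec(seed=seed))
        blurred = gaussian_blur(image, 9)
        assert otsu_threshold(blurred) == otsu_bruteforce(blurred)

    def test_inverted_phantom_foreground_is_background(self):
        image, _ = generate_phantom(PhantomSpec(n_noise_specks=0))
        inverted = (255 - image).astype(np.uint8)
        assert otsu_threshold(inverted) == otsu_bruteforce(inverted)
        mask = otsu_binarize(inverted)
        # bright background dominates: most pixels are foreground
        assert mask.mean() > 0.5

    def test_matches_skimage_mask_on_random_images(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(3)
        for _ in range(5):
            img = rng.integers(0, 256, (30, 30), dtype=np.uint8)
            ours = otsu_binarize(img)
            theirs = img > threshold_otsu(img, nbins=256)
            assert np.array_equal(ours, theirs)


class TestLargestComponentBox:
    def test_single_square(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:15, 20:30] = True
        box = largest_component_box(mask)
        assert (box.row_start, box.row_stop, box.col_start, box.col_stop) == (5, 15, 20, 30)

    def test_small_speck_ignored(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:15, 5:15] = True
        mask[30, 30:33] = True
        box = largest_component_box(mask)
        assert (box.row_stop, box.col_stop) == (15, 15)

    def test_equal_area_tie_goes_to_first_in_scan_order(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True  # first in row-major order
        mask[10:13, 10:13] = True
        comps = flood_fill_components(mask)
        areas = [len(c) for c in comps]
        assert areas[0] == areas[1]  # genuine tie
        box = largest_component_box(mask)
        assert (box.row_start, box.col_start) == (2, 2)

    def test_agrees_with_flood_fill_oracle(self):
        rng = np.random.default_rng(7)
        mask = rng.random((30, 30)) > 0.7
        if not mask.any():
            mask[0, 0] = True
        comps = flood_fill_components(mask)
        biggest = max(comps, key=len)
        rows = [p[0] for p in biggest]
        cols = [p[1] for p in biggest]
        box = largest_component_box(mask)
        assert box.to_dict() == {
            "row_start": min(rows),
            "row_stop": max(rows) + 1,
            "col_start": min(cols),
            "col_stop": max(cols) + 1,
        }

    def test_empty_mask_rejected(self):
        with pytest.raises(RuntimeFailure):
            largest_component_box(np.zeros((5, 5), dtype=bool))


class TestCropBrain:
    @pytest.mark.parametrize("n_specks", [0, 5])
    def test_recovers_ground_truth_box(self, n_specks):
        spec = PhantomSpec(n_noise_specks=n_specks, seed=17)
        image, gt = generate_phantom(spec)
        cropped, box = crop_brain(image)
        for edge in ("row_start", "row_stop", "col_start", "col_stop"):
            assert abs(getattr(box, edge) - getattr(gt, edge)) <= 6
        assert np.array_equal(cropped, image[box.slices()])

    def test_recrop_nearly_idempotent(self):
        image, _ = generate_phantom(PhantomSpec(n_noise_specks=3, seed=19))
        cropped, _ = crop_brain(image)
        recropped, box2 = crop_brain(cropped)
        assert box2.row_start <= 6 and box2.col_start <= 6
        assert cropped.shape[0] - box2.row_stop <= 6
        assert cropped.shape[1] - box2.col_stop <= 6

    def test_constant_image_error_propagates(self):
        with pytest.raises(RuntimeFailure):
            crop_brain(np.zeros((50, 50), dtype=np.uint8))

    def test_rgb_input_cropped_in_color(self):
        image, _ = generate_phantom(PhantomSpec(n_noise_specks=0))
        rgb = np.stack([image] * 3, axis=-1)
        cropped, box = crop_brain(rgb)
        assert cropped.ndim == 3
        assert np.array_equal(cropped, rgb[box.slices()])

    def test_margin_grows_box_within_bounds(self):
        image, _ = generate_phantom(PhantomSpec(n_noise_specks=0))
        _, tight = crop_brain(image)
        _, padded = crop_brain(image, margin=10)
        assert padded.row_start == max(0, tight.row_start - 10)
        assert padded.row_stop == min(image.shape[0], tight.row_stop + 10)
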