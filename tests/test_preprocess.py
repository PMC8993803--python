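import numpy as np
import pytest

from mammowave.image_core import GrayImage
from mammowave.preprocess import (
    ClaheParams, EnergyMap, Seam, SeamKind, apply_clahe, carve, compute_energy,
    find_min_seam, remove_seam, seam_energy,
)


# ---------------------------------------------------------------- oracles

def energy_oracle(px: np.ndarray) -> np.ndarray:
    """Loop-based central differences on a replicate-padded image."""
    h, w = px.shape
    p = np.pad(px, 1, mode="edge")
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            dx = (p[i + 1, j + 2] - p[i + 1, j]) / 2.0
            dy = (p[i + 2, j + 1] - p[i, j + 1]) / 2.0
            out[i, j] = abs(dx) + abs(dy)
    return out


def enumerate_min_vertical_seam(E: np.ndarray) -> float:
    """Exhaustive minimum over all 8-connected vertical seams."""
    h, w = E.shape
    best = np.inf

    def walk(row, col, acc):
        nonlocal best
        acc += E[row, col]
        if row == h - 1:
            best = min(best, acc)
            return
        for step in (-1, 0, 1):
            nxt = col + step
            if 0 <= nxt < w:
                walk(row + 1, nxt, acc)

    for start in range(w):
        walk(0, start, 0.0)
    return best


# ---------------------------------------------------------------- CLAHE

class TestClahe:
    def test_constant_stays_constant(self):
        out = apply_clahe(GrayImage(np.full((32, 32), 0.3)), ClaheParams(tile_grid=(2, 2)))
        assert len(np.unique(out.pixels)) == 1

    def test_output_in_unit_range(self, rng):
        out = apply_clahe(GrayImage(rng.random((40, 40))), ClaheParams(tile_grid=(4, 4)))
        assert out.pixels.min() >= 0 and out.pixels.max() <= 1

    def test_spreads_low_contrast_histogram(self, rng):
        px = 0.4 + 0.2 * rng.random((64, 64))
        out = apply_clahe(GrayImage(px), ClaheParams(clip_limit=0.02, tile_grid=(4, 4)))
        assert out.pixels.std() >= px.std()

    def test_tile_larger_than_image_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_clahe(GrayImage(rng.random((8, 8))), ClaheParams(tile_grid=(16, 16)))


# ---------------------------------------------------------------- energy

class TestEnergy:
    def test_constant_image_zero_energy(self):
        e = compute_energy(GrayImage(np.full((5, 5), 0.7)))
        assert e.total == 0
        assert np.all(e.values == 0)

    def test_2x2_matches_oracle(self):
        px = np.array([[0.0, 1.0], [0.0, 1.0]])
        e = compute_energy(GrayImage(px))
        assert np.allclose(e.values, energy_oracle(px))
        assert np.isclose(e.total, energy_oracle(px).sum())

    def test_random_images_match_oracle(self, rng):
        for _ in range(5):
            px = rng.random((6, 7))
            assert np.allclose(compute_energy(GrayImage(px)).values, energy_oracle(px))

    def test_single_bright_pixel_support(self):
        px = np.zeros((9, 9))
        px[4, 4] = 1.0
        e = compute_energy(GrayImage(px)).values
        support = {(3, 4), (5, 4), (4, 3), (4, 5), (4, 4)}
        nonzero = set(zip(*np.nonzero(e)))
        assert nonzero <= support

    def test_degenerate_image_rejected(self):
        with pytest.raises(ValueError):
            compute_energy(GrayImage(np.zeros((1, 5))))


# ---------------------------------------------------------------- seams

class TestFindMinSeam:
    def test_zero_energy_tie_breaks_to_column_zero(self):
        seam = find_min_seam(EnergyMap(np.zeros((4, 4))))
        assert np.all(seam.indices == 0)

    def test_unique_zero_column(self):
        E = np.ones((3, 3))
        E[:, 1] = 0.0
        seam = find_min_seam(EnergyMap(E))
        assert np.all(seam.indices == 1)

    @pytest.mark.parametrize("kind", [SeamKind.VERTICAL, SeamKind.HORIZONTAL])
    def test_dp_matches_exhaustive_enumeration(self, rng, kind):
        for _ in range(25):
            E = rng.random((rng.integers(2, 7), rng.integers(2, 7)))
            seam = find_min_seam(EnergyMap(E), kind)
            target = E if kind == SeamKind.VERTICAL else E.T
            assert np.isclose(seam_energy(EnergyMap(E), seam),
                              enumerate_min_vertical_seam(target))

    def test_seam_is_8_connected(self, rng):
        seam = find_min_seam(EnergyMap(rng.random((10, 10))))
        assert np.abs(np.diff(seam.indices)).max() <= 1


class TestRemoveSeam:
    def test_remove_column_zero(self):
        px = np.arange(9, dtype=float).reshape(3, 3) / 10
        out = remove_seam(GrayImage(px), Seam(SeamKind.VERTICAL, np.zeros(3, dtype=int)))
        assert np.allclose(out.pixels, px[:, 1:])

    def test_non_seam_pixels_preserved_per_row(self, rng):
        px = rng.random((5, 6))
        seam = find_min_seam(compute_energy(GrayImage(px)))
        out = remove_seam(GrayImage(px), seam)
        for i in range(5):
            row = list(px[i])
            row.pop(seam.indices[i])
            assert np.allclose(out.pixels[i], row)

    def test_vertical_removal_keeps_height(self, random_image):
        seam = find_min_seam(compute_energy(random_image))
        out = remove_seam(random_image, seam)
        assert out.shape == (random_image.height, random_image.width - 1)

    def test_shape_mismatch_rejected(self, random_image):
        with pytest.raises(ValueError):
            remove_seam(random_image, Seam(SeamKind.VERTICAL, np.zeros(3, dtype=int)))


class TestCarve:
    def test_identity(self, random_image):
        out = carve(random_image, 0, 0)
        assert np.array_equal(out.pixels, random_image.pixels)

    def test_constant_image_shape(self):
        out = carve(GrayImage(np.zeros((5, 5))), 2, 0)
        assert out.shape == (5, 3)
        assert np.all(out.pixels == 0)

    def test_shape_contract_both_directions(self, random_image):
        out = carve(random_image, 3, 2)
        assert out.shape == (14, 13)

    def test_deterministic(self, random_image):
        a = carve(random_image, 2, 2)
        b = carve(random_image, 2, 2)
        assert np.array_equal(a.pixels, b.pixels)

    def test_bright_blob_survives(self):
        # bright 4-wide blob on flat background: seams route around it
        px = np.full((12, 12), 0.2)
        px[4:8, 4:8] = 0.9
        out = carve(GrayImage(px), n_vertical=5, n_horizontal=0)
        assert (out.pixels == 0.9).sum() == 16

    def test_overcarving_rejected(self, random_image):
        with pytest.raises(ValueError):
            carve(random_image, random_image.width - 1, 0)
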