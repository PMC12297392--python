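"""Preprocessing operators against independent scalar oracles."""

import itertools

import numpy as np
import pytest

from tatha.preprocess import (
    ClaheParams, DiffusionParams, EdgeResult, EmptyRoiError, PreprocessConfig,
    PreprocessError, anisotropic_diffusion, clahe, equalize_histogram,
    extract_roi, hysteresis_edges, preprocess_pipeline, sobel_gradients,
    _clipped_lut, _quantize,
)
from tatha.synth import PhantomSpec, generate_phantom


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def diffusion_oracle(img, params):
    """Scalar-loop explicit 4-neighbour diffusion step with reflective
    boundaries and per-direction Perona-Malik conduction."""
    out = np.array(img, dtype=float)
    h, w = out.shape
    for _ in range(params.iterations):
        nxt = out.copy()
        for r in range(h):
            for c in range(w):
                flux = 0.0
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        d = out[rr, cc] - out[r, c]
                        flux += np.exp(-((d / params.kappa) ** 2)) * d
                nxt[r, c] = out[r, c] + params.lambda_step * flux
        out = nxt
    return np.clip(out, 0, 1)


def flood_fill_oracle(mag, low, high):
    """Brute-force hysteresis: BFS from strong pixels through candidates."""
    h, w = mag.shape
    cand = (mag >= low) & (mag > 0)
    keep = np.zeros((h, w), dtype=bool)
    stack = [(r, c) for r in range(h) for c in range(w)
             if mag[r, c] >= high and cand[r, c]]
    for rc in stack:
        keep[rc] = True
    while stack:
        r, c = stack.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and cand[rr, cc] \
                        and not keep[rr, cc]:
                    keep[rr, cc] = True
                    stack.append((rr, cc))
    return keep


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

class TestDiffusion:
    def test_constant_image_is_fixed_point(self):
        img = np.full((8, 8), 0.4)
        out = anisotropic_diffusion(img, DiffusionParams(iterations=7))
        np.testing.assert_array_almost_equal(out, img)

    def test_single_impulse_matches_scalar_oracle(self):
        img = np.zeros((8, 8))
        img[4, 4] = 1.0
        params = DiffusionParams(iterations=1, lambda_step=0.2, kappa=1.0)
        np.testing.assert_allclose(
            anisotropic_diffusion(img, params),
            diffusion_oracle(img, params), atol=1e-12)

    @pytest.mark.parametrize("iters", [1, 3, 10])
    def test_random_image_matches_scalar_oracle(self, rng, iters):
        img = rng.random((9, 8))
        params = DiffusionParams(iterations=iters, lambda_step=0.15, kappa=0.3)
        np.testing.assert_allclose(
            anisotropic_diffusion(img, params),
            diffusion_oracle(img, params), atol=1e-10)

    def test_conserves_total_intensity(self, rng):
        img = 0.2 + 0.6 * rng.random((16, 16))  # stays inside [0,1], no clip
        out = anisotropic_diffusion(img, DiffusionParams(iterations=25))
        assert abs(out.sum() - img.sum()) / img.sum() < 1e-6

    def test_rejects_bad_lambda_and_nonfinite(self):
        img = np.zeros((8, 8))
        with pytest.raises(PreprocessError):
            anisotropic_diffusion(img, DiffusionParams(lambda_step=0.3))
        bad = img.copy()
        bad[0, 0] = np.nan
        with pytest.raises(PreprocessError):
            anisotropic_diffusion(bad, DiffusionParams())


# ---------------------------------------------------------------------------
# histogram equalization / CLAHE
# ---------------------------------------------------------------------------

class TestEqualization:
    def test_two_valued_image_maps_to_hand_cdf(self):
        # half the pixels at 0.2, half at 0.8: CDF(low)=0.5, CDF(high)=1.0
        img = np.full((8, 8), 0.2)
        img[:, 4:] = 0.8
        out = equalize_histogram(img, levels=256)
        low, high = np.unique(out)
        assert low == pytest.approx(0.5)
        assert high == pytest.approx(1.0)

    def test_uniform_histogram_is_near_identity(self):
        levels = 16
        img = np.tile(np.arange(levels) / (levels - 1), (levels, 1))
        out = equalize_histogram(img, levels=levels)
        assert np.max(np.abs(out - img)) <= 1.0 / levels + 1e-12

    def test_mapping_is_monotone(self, rng):
        img = rng.random((12, 12))
        out = equalize_histogram(img, levels=64)
        a = img.ravel()
        b = out.ravel()
        order = np.argsort(a)
        assert np.all(np.diff(b[order]) >= -1e-12)

    def test_constant_image_unchanged(self):
        img = np.full((8, 8), 0.7)
        np.testing.assert_array_equal(equalize_histogram(img), img)


class TestClahe:
    def test_single_tile_unclipped_equals_global_equalization(self, rng):
        img = rng.random((32, 32))
        params = ClaheParams(clip_limit=1e9, tile_rows=1, tile_cols=1)
        np.testing.assert_allclose(
            clahe(img, params), equalize_histogram(img), atol=1e-12)

    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 0.3)
        out = clahe(img, ClaheParams(tile_rows=2, tile_cols=2))
        np.testing.assert_array_equal(out, img)

    def test_tile_luts_match_histogram_oracle(self, rng):
        # independent per-tile oracle: clip, redistribute, accumulate
        img = rng.random((64, 64))
        levels, clip = 32, 2.0
        bins = _quantize(img, levels)
        for tile in (bins[:32, :32], bins[:32, 32:], bins[32:, :32],
                     bins[32:, 32:]):
            hist = np.bincount(tile.ravel(), minlength=levels).astype(float)
            t_clip = clip * tile.size / levels
            excess = np.clip(hist - t_clip, 0, None).sum()
            clipped = np.minimum(hist, t_clip) + excess / levels
            oracle = np.cumsum(clipped) / clipped.sum()
            np.testing.assert_allclose(
                _clipped_lut(tile, levels, clip), oracle, atol=1e-12)

    def test_tile_larger_than_image_rejected(self):
        with pytest.raises(PreprocessError):
            clahe(np.zeros((8, 8)) + 0.5, ClaheParams(tile_rows=9, tile_cols=1))

    def test_per_tile_monotone(self, rng):
        img = rng.random((64, 64))
        out = clahe(img, ClaheParams(levels=64, clip_limit=2.0,
                                     tile_rows=2, tile_cols=2))
        # monotone within each tile's interior region
        sub_in = img[:16, :16].ravel()
        sub_out = out[:16, :16].ravel()
        order = np.argsort(sub_in)
        assert np.all(np.diff(sub_out[order]) >= -1e-9)


# ---------------------------------------------------------------------------
# Sobel + hysteresis
# ---------------------------------------------------------------------------

class TestSobel:
    def test_constant_image_zero_gradient(self):
        res = sobel_gradients(np.full((8, 8), 0.5))
        assert np.all(res.magnitude == 0)
        assert np.all(res.orientation == 0)

    def test_vertical_step_magnitude_and_orientation(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 1.0
        res = sobel_gradients(img)
        # Sobel row-sum (1+2+1) x step height across the two step columns
        interior = res.magnitude[2:-2, 4:6]
        np.testing.assert_allclose(interior, 4.0)
        np.testing.assert_allclose(res.orientation[2:-2, 4:6], 0.0, atol=1e-12)

    def test_gradient_invariant_to_constant_shift(self, rng):
        img = 0.3 * rng.random((12, 12))
        a = sobel_gradients(img)
        b = sobel_gradients(img + 0.42)
        np.testing.assert_allclose(a.magnitude, b.magnitude, atol=1e-12)

    def test_transposition_equivariance(self, rng):
        img = rng.random((12, 12))
        a = sobel_gradients(img)
        b = sobel_gradients(img.T)
        np.testing.assert_allclose(b.magnitude, a.magnitude.T, atol=1e-12)
        # partials swap under transposition, so |theta'| = pi/2 - |theta.T|
        # wherever both partial derivatives are nonzero
        generic = (np.abs(a.orientation.T) > 1e-9) & \
                  (np.abs(a.orientation.T) < np.pi / 2 - 1e-9)
        np.testing.assert_allclose(
            np.abs(b.orientation[generic]),
            np.pi / 2 - np.abs(a.orientation.T[generic]), atol=1e-9)


class TestHysteresis:
    def test_all_below_low_gives_empty_mask(self):
        res = EdgeResult(magnitude=np.full((7, 7), 0.1),
                         orientation=np.zeros((7, 7)))
        out = hysteresis_edges(res, low=0.5, high=0.8, use_nms=False)
        assert not out.edge_mask.any()

    def test_weak_tail_kept_isolated_weak_dropped(self):
        mag = np.zeros((7, 7))
        mag[3, 1] = 1.0                      # strong seed
        mag[3, 2] = mag[2, 3] = 0.4          # 8-connected weak tail
        mag[6, 6] = 0.4                      # isolated weak pixel
        res = EdgeResult(magnitude=mag, orientation=np.zeros_like(mag))
        out = hysteresis_edges(res, low=0.3, high=0.9, use_nms=False)
        assert out.edge_mask[3, 1] and out.edge_mask[3, 2] and out.edge_mask[2, 3]
        assert not out.edge_mask[6, 6]
        np.testing.assert_array_equal(out.edge_mask,
                                      flood_fill_oracle(mag, 0.3, 0.9))

    def test_all_strong_gives_full_mask(self):
        mag = np.full((6, 6), 0.9)
        res = EdgeResult(magnitude=mag, orientation=np.zeros_like(mag))
        out = hysteresis_edges(res, low=0.5, high=0.5 + 1e-9, use_nms=False)
        assert out.edge_mask.all()

    def test_exhaustive_ternary_3x3_equivalence(self):
        """Every 3x3 pattern over {0, weak, strong} matches the BFS oracle."""
        low, high = 0.3, 0.7
        values = np.array([0.0, 0.5, 1.0])
        zeros = np.zeros((3, 3))
        for digits in itertools.product(range(3), repeat=9):
            mag = values[np.array(digits)].reshape(3, 3)
            res = EdgeResult(magnitude=mag, orientation=zeros)
            out = hysteresis_edges(res, low, high, use_nms=False)
            np.testing.assert_array_equal(
                out.edge_mask, flood_fill_oracle(mag, low, high))

    def test_random_ternary_5x5_equivalence(self, rng):
        low, high = 0.3, 0.7
        values = np.array([0.0, 0.5, 1.0])
        zeros = np.zeros((5, 5))
        for _ in range(500):
            mag = values[rng.integers(0, 3, size=(5, 5))]
            res = EdgeResult(magnitude=mag, orientation=zeros)
            out = hysteresis_edges(res, low, high, use_nms=False)
            np.testing.assert_array_equal(
                out.edge_mask, flood_fill_oracle(mag, low, high))

    def test_low_ge_high_rejected(self):
        res = EdgeResult(magnitude=np.zeros((7, 7)),
                         orientation=np.zeros((7, 7)))
        with pytest.raises(PreprocessError):
            hysteresis_edges(res, low=0.5, high=0.5)


# ---------------------------------------------------------------------------
# ROI
# ---------------------------------------------------------------------------

class TestExtractRoi:
    def test_single_pixel(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 5] = True
        box = extract_roi(mask, margin=0)
        assert (box.x_min, box.x_max, box.y_min, box.y_max) == (5, 6, 3, 4)

    def test_two_corner_blobs_union_box(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[1:3, 1:3] = True
        mask[17:19, 16:19] = True
        box = extract_roi(mask, margin=0)
        rows, cols = np.nonzero(mask)   # coordinate-scan oracle
        assert box.y_min == rows.min() and box.y_max == rows.max() + 1
        assert box.x_min == cols.min() and box.x_max == cols.max() + 1
        # minimality: shrinking any side drops a foreground pixel
        assert mask[box.y_min, :].any() and mask[box.y_max - 1, :].any()
        assert mask[:, box.x_min].any() and mask[:, box.x_max - 1].any()

    def test_margin_clamps_to_image(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        box = extract_roi(mask, margin=100)
        assert (box.x_min, box.x_max, box.y_min, box.y_max) == (0, 10, 0, 10)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyRoiError):
            extract_roi(np.zeros((8, 8), dtype=bool))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class TestPipeline:
    def test_all_disabled_is_identity(self, phantom64):
        cfg = PreprocessConfig(enable_diffusion=False, enable_clahe=False,
                               enable_edges=False, enable_roi=False)
        res = preprocess_pipeline(phantom64.image, cfg)
        np.testing.assert_array_equal(res.image, phantom64.image)
        assert res.edges is None and res.roi is None

    def test_diffusion_reduces_flat_region_variance(self, speckled_flat):
        cfg = PreprocessConfig(enable_clahe=False, enable_edges=False)
        res = preprocess_pipeline(speckled_flat, cfg)
        assert res.image.var() < speckled_flat.var()

    def test_roi_without_mask_is_none(self, phantom64):
        cfg = PreprocessConfig(enable_roi=True)
        res = preprocess_pipeline(phantom64.image, cfg, mask=None)
        assert res.roi is None

    def test_roi_with_mask_contains_foreground(self, phantom64):
        cfg = PreprocessConfig(enable_roi=True, roi_margin=0,
                               enable_edges=False)
        res = preprocess_pipeline(phantom64.image, cfg, mask=phantom64.mask)
        rows, cols = np.nonzero(phantom64.mask)
        assert res.roi.y_min <= rows.min() and res.roi.y_max >= rows.max() + 1

    def test_stage_error_carries_stage_name(self):
        cfg = PreprocessConfig(
            diffusion=DiffusionParams(lambda_step=0.9))
        with pytest.raises(PreprocessError, match="diffusion"):
            preprocess_pipeline(np.zeros((8, 8)), cfg)
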