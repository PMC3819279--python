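import numpy as np
import pytest

from edgeinterp import (
    EdgeMap,
    GrayImage,
    Orientation,
    OrientationMap,
    PhantomSpec,
    TediConfig,
    build_blend_mask,
    calibrate_ratio,
    detect_edges,
    make_phantom,
    project_edges,
    resample,
    sharpen_true_edges,
    snr,
    soften_pseudo_edges,
    split_true_pseudo,
    tedi_interpolate,
)
from edgeinterp.tedi import _ALONG_EDGE_OFFSETS


class TestBlendMask:
    def test_lv_ratio_4_weights(self):
        mask = build_blend_mask(Orientation.LV, 4.0)
        w = mask.weights
        assert w[2, 2] == 0.5  # 4 / (4 + 2 + 2)
        assert w[1, 0] == 0.25  # offset (-1, -2), sqrt(4)/8
        assert w[3, 4] == 0.25  # offset (+1, +2)
        assert np.count_nonzero(w) == 3
        assert w.sum() == pytest.approx(1.0, abs=1e-15)

    def test_ratio_1_uniform(self):
        mask = build_blend_mask(Orientation.LV, 1.0)
        nz = mask.weights[mask.weights > 0]
        np.testing.assert_allclose(nz, 1.0 / 3.0, atol=1e-15)

    @pytest.mark.parametrize("o", [Orientation.RH, Orientation.LV, Orientation.RV, Orientation.LH])
    @pytest.mark.parametrize("ratio", [1.0, 2.5, 4.0, 16.0])
    def test_structure_invariants(self, o, ratio):
        mask = build_blend_mask(o, ratio)
        w = mask.weights
        assert np.count_nonzero(w) == 3
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert w[2, 2] == pytest.approx(ratio / (ratio + 2 * np.sqrt(ratio)))
        (o1r, o1c), (o2r, o2c) = _ALONG_EDGE_OFFSETS[o]
        assert w[2 + o1r, 2 + o1c] == w[2 + o2r, 2 + o2c]

    def test_symmetry_transforms(self):
        lv = build_blend_mask(Orientation.LV, 4.0).weights
        rh = build_blend_mask(Orientation.RH, 4.0).weights
        rv = build_blend_mask(Orientation.RV, 4.0).weights
        lh = build_blend_mask(Orientation.LH, 4.0).weights
        np.testing.assert_array_equal(rh, lv.T)
        np.testing.assert_array_equal(rv, lv[:, ::-1])
        np.testing.assert_array_equal(lh, rv.T)

    def test_rotated_step_symmetry_oracle(self):
        # A vertical-boundary step (RH edges) rotated 90 degrees becomes a
        # horizontal-boundary step (RV edges); the sharpening response must
        # be the rotated image of the original response.
        img = make_phantom(PhantomSpec("oriented_step", (32, 32), {"angle": 90.0}))
        em, om = detect_edges(img)
        out = sharpen_true_edges(img, em, om, 4.0)

        rot = GrayImage(np.rot90(img.pixels))
        em_r, om_r = detect_edges(rot)
        out_r = sharpen_true_edges(rot, em_r, om_r, 4.0)
        np.testing.assert_allclose(np.rot90(out.pixels), out_r.pixels, atol=1e-12)

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            build_blend_mask(Orientation.LV, 0.5)


class TestProjectEdges:
    def _maps(self, mask, labels):
        return EdgeMap(mask), OrientationMap(labels)

    def test_factor_one_identity(self, rng):
        mask = rng.random((10, 10)) < 0.2
        labels = np.where(mask, 2, 0).astype(np.int8)
        em, om = self._maps(mask, labels)
        pem, pom = project_edges(em, om, 1)
        np.testing.assert_array_equal(pem.mask, mask)
        np.testing.assert_array_equal(pom.labels, labels)

    def test_single_pixel_projection(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 5] = True
        labels = np.zeros((8, 8), dtype=np.int8)
        labels[3, 5] = int(Orientation.LH)
        pem, pom = project_edges(EdgeMap(mask), OrientationMap(labels), 2)
        assert pem.shape == (16, 16)
        assert pem.count == 1
        assert pem.mask[6, 10]
        assert pom.labels[6, 10] == int(Orientation.LH)

    @pytest.mark.parametrize("factor", [1, 2, 3, 4])
    def test_count_preserved(self, rng, factor):
        mask = rng.random((12, 9)) < 0.3
        labels = np.where(mask, 1, 0).astype(np.int8)
        pem, _ = project_edges(EdgeMap(mask), OrientationMap(labels), factor)
        assert pem.count == int(mask.sum())

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            project_edges(EdgeMap(np.zeros((4, 4), bool)), OrientationMap(np.zeros((5, 5), np.int8)), 2)


def _chebyshev_pseudo_oracle(hr_mask, true_mask, tol):
    """Brute-force double loop over Chebyshev distances."""
    true_pts = list(zip(*np.nonzero(true_mask)))
    out = np.zeros_like(hr_mask)
    for r, c in zip(*np.nonzero(hr_mask)):
        if all(max(abs(r - tr), abs(c - tc)) > tol for tr, tc in true_pts):
            out[r, c] = True
    return out


class TestSplitTruePseudo:
    def test_full_overlap_empty(self, rng):
        mask = rng.random((10, 10)) < 0.3
        em = EdgeMap(mask)
        for tol in (0, 1, 3):
            assert split_true_pseudo(em, em, tol).count == 0

    def test_empty_true_passthrough(self, rng):
        mask = rng.random((10, 10)) < 0.3
        pseudo = split_true_pseudo(EdgeMap(mask), EdgeMap(np.zeros_like(mask)), 1)
        np.testing.assert_array_equal(pseudo.mask, mask)

    @pytest.mark.parametrize("tol", [0, 1, 2])
    def test_matches_brute_force(self, rng, tol):
        for _ in range(5):
            hr = rng.random((15, 13)) < 0.25
            true = rng.random((15, 13)) < 0.08
            pseudo = split_true_pseudo(EdgeMap(hr), EdgeMap(true), tol)
            np.testing.assert_array_equal(
                pseudo.mask, _chebyshev_pseudo_oracle(hr, true, tol)
            )

    def test_disjoint_from_true(self, rng):
        hr = rng.random((20, 20)) < 0.3
        true = rng.random((20, 20)) < 0.1
        pseudo = split_true_pseudo(EdgeMap(hr), EdgeMap(true), 1)
        assert not (pseudo.mask & true).any()


def _sharpen_oracle(px, mask, labels, ratio):
    """Direct per-pixel weighted-sum loop with clamped indexing."""
    h, w = px.shape
    out = px.copy()
    s = np.sqrt(ratio)
    norm = ratio + 2 * s
    for r, c in zip(*np.nonzero(mask)):
        (o1r, o1c), (o2r, o2c) = _ALONG_EDGE_OFFSETS[Orientation(labels[r, c])]
        v1 = px[min(max(r + o1r, 0), h - 1), min(max(c + o1c, 0), w - 1)]
        v2 = px[min(max(r + o2r, 0), h - 1), min(max(c + o2c, 0), w - 1)]
        out[r, c] = (ratio * px[r, c] + s * v1 + s * v2) / norm
    return np.clip(out, 0.0, 1.0)


def _soften_oracle(px, mask):
    """Direct 8-neighbor-mean loop with clamped indexing."""
    h, w = px.shape
    out = px.copy()
    for r, c in zip(*np.nonzero(mask)):
        acc = 0.0
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                acc += px[min(max(r + dr, 0), h - 1), min(max(c + dc, 0), w - 1)]
        out[r, c] = acc / 8.0
    return out


class TestSharpen:
    def test_hand_example_lv(self):
        # center 0.8, along-edge offsets 0.4 -> (4*0.8 + 2*0.4 + 2*0.4)/8 = 0.6
        px = np.full((5, 5), 0.8)
        px[2 - 1, 2 - 2] = 0.4
        px[2 + 1, 2 + 2] = 0.4
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        labels = np.zeros((5, 5), np.int8)
        labels[2, 2] = int(Orientation.LV)
        out = sharpen_true_edges(GrayImage(px), EdgeMap(mask), OrientationMap(labels), 4.0)
        assert out.pixels[2, 2] == pytest.approx(0.6, abs=1e-15)

    def test_flat_neighborhood_invariant(self):
        px = np.full((7, 7), 0.35)
        mask = np.zeros((7, 7), bool)
        mask[3, 3] = True
        labels = np.zeros((7, 7), np.int8)
        labels[3, 3] = int(Orientation.RH)
        out = sharpen_true_edges(GrayImage(px), EdgeMap(mask), OrientationMap(labels), 4.0)
        np.testing.assert_allclose(out.pixels, 0.35, atol=1e-15)

    def test_no_marked_pixels_noop(self, random_image):
        em = EdgeMap(np.zeros(random_image.shape, bool))
        om = OrientationMap(np.zeros(random_image.shape, np.int8))
        out = sharpen_true_edges(random_image, em, om, 4.0)
        np.testing.assert_array_equal(out.pixels, random_image.pixels)

    def test_matches_loop_oracle(self, rng):
        px = rng.uniform(0, 1, size=(11, 9))
        mask = rng.random((11, 9)) < 0.3
        labels = np.where(mask, rng.integers(1, 5, size=(11, 9)), 0).astype(np.int8)
        out = sharpen_true_edges(GrayImage(px), EdgeMap(mask), OrientationMap(labels), 4.0)
        np.testing.assert_allclose(
            out.pixels, _sharpen_oracle(px, mask, labels, 4.0), atol=1e-12
        )

    def test_unlabeled_edge_pixel_rejected(self):
        mask = np.zeros((6, 6), bool)
        mask[2, 2] = True
        with pytest.raises(ValueError):
            sharpen_true_edges(
                GrayImage(np.zeros((6, 6))), EdgeMap(mask),
                OrientationMap(np.zeros((6, 6), np.int8)), 4.0,
            )


class TestSoften:
    def test_center_excluded_mean(self):
        px = np.full((3, 3), 0.4)
        px[1, 1] = 0.9
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        out = soften_pseudo_edges(GrayImage(px), EdgeMap(mask))
        assert out.pixels[1, 1] == pytest.approx(0.4, abs=1e-15)

    def test_constant_unchanged(self, constant_image):
        mask = np.zeros(constant_image.shape, bool)
        mask[::3, ::2] = True
        out = soften_pseudo_edges(constant_image, EdgeMap(mask))
        np.testing.assert_array_equal(out.pixels, constant_image.pixels)

    def test_matches_loop_oracle(self, rng):
        px = rng.uniform(0, 1, size=(7, 7))
        mask = np.zeros((7, 7), bool)
        flat = rng.choice(49, size=5, replace=False)
        mask.ravel()[flat] = True
        out = soften_pseudo_edges(GrayImage(px), EdgeMap(mask))
        np.testing.assert_allclose(out.pixels, _soften_oracle(px, mask), atol=1e-12)


class TestTediInterpolate:
    def test_constant_equals_bilinear(self, constant_image):
        out = tedi_interpolate(constant_image, TediConfig())
        base = resample(constant_image, 2, "bilinear")
        np.testing.assert_array_equal(out.pixels, base.pixels)

    def test_locality_outside_edge_sets(self):
        img = make_phantom(PhantomSpec("disk", (64, 64), {"radius": 18.0}))
        cfg = TediConfig()
        base = resample(img, 2, cfg.base_method)
        lr_em, lr_om = detect_edges(img, cfg.canny_threshold)
        hr_em, _ = detect_edges(base, cfg.canny_threshold)
        true_em, _ = project_edges(lr_em, lr_om, 2)
        pseudo = split_true_pseudo(hr_em, true_em, cfg.true_edge_tolerance)
        out = tedi_interpolate(img, cfg)
        outside = ~(true_em.mask | pseudo.mask)
        np.testing.assert_array_equal(out.pixels[outside], base.pixels[outside])

    def test_determinism(self):
        img = make_phantom(PhantomSpec("ring", (48, 48)))
        a = tedi_interpolate(img, TediConfig())
        b = tedi_interpolate(img, TediConfig())
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_output_dims_and_range(self):
        img = make_phantom(PhantomSpec("spine_band", (40, 48)))
        out = tedi_interpolate(img, TediConfig(factor=2))
        assert out.shape == (80, 96)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_factor_4_single_shot(self):
        img = make_phantom(PhantomSpec("disk", (32, 32), {"radius": 10.0}))
        out = tedi_interpolate(img, TediConfig(factor=4))
        assert out.shape == (128, 128)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            tedi_interpolate(GrayImage(np.zeros((2, 2))), TediConfig())

    def test_default_config_values(self):
        cfg = TediConfig()
        assert cfg.factor == 2
        assert cfg.canny_threshold == 0.1
        assert cfg.ratio == 4.0
        assert cfg.true_edge_tolerance == 1
        assert cfg.base_method == "bilinear"


class TestCalibrateRatio:
    def test_single_image_mean(self):
        img = make_phantom(PhantomSpec("disk", (64, 64), {"radius": 18.0}))
        rows = calibrate_ratio([img], [4.0], TediConfig())
        lr = resample(img, 0.5, "nearest")
        expected = snr(img, tedi_interpolate(lr, TediConfig()))
        assert rows == [(4.0, pytest.approx(expected))]

    def test_duplicate_ratios_identical_rows(self):
        img = make_phantom(PhantomSpec("ring", (64, 64)))
        rows = calibrate_ratio([img], [2.0, 2.0], TediConfig())
        assert rows[0] == rows[1]

    def test_empty_inputs_rejected(self):
        img = make_phantom(PhantomSpec("disk", (64, 64)))
        with pytest.raises(ValueError):
            calibrate_ratio([], [4.0])
        with pytest.raises(ValueError):
            calibrate_ratio([img], [])
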