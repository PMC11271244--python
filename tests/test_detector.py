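"""Pattern detector: rasterization, segmentation, cleanup, label init."""

import numpy as np
import pytest

from oracles import flood_fill_components, multiotsu_bruteforce, two_means_1d_bruteforce
from spannot.core import SpotTable
from spannot.detector import (Annotation, DetectorParams, add_undefined_channel,
                              binarize_dilate, build_pixel_map,
                              create_pattern_channel, detect, filter_small_components,
                              initialize_labels, multi_otsu, reject_false_positives,
                              split_positive, _exact_two_means_split)


def _grid_coords(I, J):
    ii, jj = np.meshgrid(np.arange(I), np.arange(J), indexing="ij")
    return np.stack([jj.ravel().astype(float), ii.ravel().astype(float)], axis=1)


class TestPixelMap:
    def test_integer_lattice_identity(self):
        coords = _grid_coords(3, 4)
        pm = build_pixel_map(coords)
        assert pm.shape == (3, 4)
        assert pm.mask.all()
        assert all(len(v) == 1 for v in pm.spots_of_pixel.values())

    def test_rounding_collision(self):
        coords = np.array([[0.0, 0.0], [0.2, 0.0], [1.0, 0.0], [2.0, 0.0]])
        pm = build_pixel_map(coords)  # pitch 0.5; spots 0.2 apart share a pixel
        # first two spots are closer than pitch/2 apart: same pixel
        assert tuple(pm.pixel_of_spot[0]) == tuple(pm.pixel_of_spot[1])
        assert len(pm.spots_of_pixel[tuple(pm.pixel_of_spot[0])]) == 2

    def test_hex_lattice_bruteforce(self, rng):
        rows, cols = 10, 10
        pts = []
        for i in range(rows):
            for j in range(cols):
                pts.append([j + 0.5 * (i % 2), i * np.sqrt(3) / 2])
        coords = np.asarray(pts)
        pm = build_pixel_map(coords)
        # brute-force recomputation of the pitch-normalized rounding
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        pitch = np.median(d.min(axis=1))
        shifted = (coords - coords.min(axis=0)) / pitch
        expect = np.floor(shifted + 0.5).astype(int)  # non-negative: half-away == +0.5 floor
        assert np.array_equal(pm.pixel_of_spot, expect[:, ::-1])
        assert len(pm.spots_of_pixel) == len({tuple(r) for r in expect})

    def test_coincident_fatal(self):
        with pytest.raises(ValueError):
            build_pixel_map(np.zeros((3, 2)))


class TestPatternChannel:
    def test_single_marker_passthrough(self):
        coords = _grid_coords(1, 3)
        pm = build_pixel_map(coords)
        # 3x1 image: the zero-padded median filter can alter edge values,
        # so check the pass-through semantics on a constant image
        ch = create_pattern_channel(np.array([[0.5, 0.5, 0.5]]), [0], pm)
        assert np.allclose(ch[pm.mask], 0.5)

    def test_median_fusion(self):
        coords = _grid_coords(3, 3)
        pm = build_pixel_map(coords)
        den = np.stack([np.full(9, 0.2), np.full(9, 0.4), np.full(9, 0.6)])
        ch = create_pattern_channel(den, [0, 1, 2], pm)
        assert np.allclose(ch[pm.mask], 0.4)

    def test_constant_image_filter_fixed_point(self):
        coords = _grid_coords(4, 4)
        pm = build_pixel_map(coords)
        ch = create_pattern_channel(np.full((1, 16), 0.7), [0], pm)
        # interior pixels see a full 3x3 constant window
        assert np.allclose(ch[1:3, 1:3], 0.7)

    def test_missing_marker_fatal(self, laminar_sim):
        from spannot.core import create_state
        st = create_state(laminar_sim.coords, laminar_sim.counts, laminar_sim.gene_names)
        with pytest.raises(KeyError):
            st.gene_index(["NOT_A_GENE"])


class TestMultiOtsu:
    def test_two_cluster_split(self):
        vals = np.array([0.0] * 10 + [1.0] * 10)
        img = vals.reshape(4, 5)
        mask = np.ones_like(img, bool)
        taus = multi_otsu(img, mask, n=2, nbins=32)
        assert 0.0 < taus[0] < 1.0

    @pytest.mark.parametrize("n", [2, 3])
    def test_matches_exhaustive_search(self, n, rng):
        # three well-separated clusters of continuous values
        vals = np.concatenate([rng.uniform(0.0, 0.1, 300),
                               rng.uniform(0.45, 0.55, 300),
                               rng.uniform(0.9, 1.0, 300)])
        img = vals.reshape(30, 30)
        mask = np.ones_like(img, bool)
        taus = multi_otsu(img, mask, n=n, nbins=64)
        expect, best_var = multiotsu_bruteforce(vals, classes=n, nbins=64)
        from oracles import multiotsu_variance
        assert multiotsu_variance(vals, 64, taus) == pytest.approx(best_var, abs=1e-10)
        # thresholds separate the constructed clusters
        for t in taus:
            assert 0.1 < t < 0.9

    def test_constant_channel_fatal(self):
        img = np.full((4, 4), 0.5)
        with pytest.raises(ValueError, match="degenerate"):
            multi_otsu(img, np.ones_like(img, bool), n=3)


class TestSplitAndComponents:
    def test_split_values(self):
        ch = np.array([[0.1, 0.9]])
        pos, neg = split_positive(ch, 0.5)
        assert np.allclose(pos, [[0.0, 0.9]])
        assert np.allclose(neg, [[0.1, 0.0]])

    def test_partition_identity(self, rng):
        ch = rng.random((8, 8))
        pos, neg = split_positive(ch, 0.6)
        assert np.allclose(pos + neg, ch)
        assert not np.any(split_positive(ch, 1.1)[0])

    def test_isolated_pixel_removed(self):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        assert not np.any(filter_small_components(img, min_area=2))

    def test_diagonal_pair_kept(self):
        img = np.zeros((5, 5))
        img[1, 1] = img[2, 2] = 1.0
        out = filter_small_components(img, min_area=2)
        assert np.count_nonzero(out) == 2

    def test_matches_flood_fill(self, rng):
        img = (rng.random((16, 16)) < 0.3).astype(float)
        for min_area in (2, 3, 5):
            out = filter_small_components(img, min_area=min_area)
            # every surviving component has area >= min_area (flood-fill check)
            from scipy import ndimage
            lab, n = ndimage.label(out > 0, structure=np.ones((3, 3), int))
            for k in range(1, n + 1):
                assert (lab == k).sum() >= min_area
            # removed pixels all belonged to components smaller than min_area
            lab0, n0 = ndimage.label(img > 0, structure=np.ones((3, 3), int))
            for k in range(1, n0 + 1):
                comp = lab0 == k
                kept = out[comp] > 0
                assert kept.all() if comp.sum() >= min_area else not kept.any()

    def test_component_count_oracle(self, rng):
        from scipy import ndimage
        img = rng.random((12, 12)) < 0.35
        _, n = ndimage.label(img, structure=np.ones((3, 3), int))
        assert n == flood_fill_components(img)


class TestRejectFalsePositives:
    def test_two_high_components_kept(self):
        pos = np.zeros((8, 8))
        pos[1, 1:3] = 0.9
        pos[5, 5:7] = 0.85
        neg = np.zeros((8, 8))
        neg[3, 0:4] = 0.1
        out = reject_false_positives(pos, neg, tv_weight=0.0)
        assert np.count_nonzero(out) == 4

    def test_single_component_kept_via_anchor(self):
        pos = np.zeros((6, 6))
        pos[1, 1:4] = 0.9
        neg = np.zeros((6, 6))
        neg[4, 1:4] = 0.05
        out = reject_false_positives(pos, neg, tv_weight=0.0)
        assert np.count_nonzero(out) == 3

    def test_component_at_anchor_level_removed(self):
        pos = np.zeros((8, 8))
        pos[1, 1:4] = 0.9
        pos[6, 1:3] = 0.1  # same level as the negative anchor
        neg = np.zeros((8, 8))
        neg[4, 0:5] = 0.1
        out = reject_false_positives(pos, neg, tv_weight=0.0)
        assert np.count_nonzero(out[6]) == 0
        assert np.count_nonzero(out[1]) == 3

    def test_empty_negative_skips(self):
        pos = np.zeros((4, 4))
        pos[1, 1] = 0.5
        out = reject_false_positives(pos, np.zeros((4, 4)))
        assert np.allclose(out, pos)

    def test_two_means_matches_bruteforce(self, rng):
        for _ in range(20):
            vals = rng.random(rng.integers(2, 12))
            assert np.array_equal(_exact_two_means_split(vals),
                                  two_means_1d_bruteforce(vals))


class TestBinarizeDilate:
    def test_radius_zero_identity(self):
        pos = np.zeros((5, 5))
        pos[2, 2] = 0.7
        mask = np.ones((5, 5), bool)
        assert np.array_equal(binarize_dilate(pos, mask, 0), pos > 0)

    def test_single_pixel_disk(self):
        pos = np.zeros((5, 5))
        pos[2, 2] = 1.0
        mask = np.ones((5, 5), bool)
        out = binarize_dilate(pos, mask, 1)
        # brute-force disk-1 dilation: cross neighborhood
        expect = np.zeros((5, 5), bool)
        for di, dj in [(0, 0), (0, 1), (0, -1), (1, 0), (-1, 0)]:
            expect[2 + di, 2 + dj] = True
        assert np.array_equal(out, expect)

    def test_monotone_in_radius(self, rng):
        pos = (rng.random((12, 12)) < 0.1).astype(float)
        mask = np.ones((12, 12), bool)
        prev = binarize_dilate(pos, mask, 0)
        for r in (1, 2, 3):
            cur = binarize_dilate(pos, mask, r)
            assert np.all(cur | ~prev)  # superset
            prev = cur


class TestFeaturesAndLabels:
    def test_mask_zero_gives_zero(self):
        ch = np.random.default_rng(0).random((6, 6))
        params = DetectorParams(sharpen_amount=0, gaussian_sigma=0, tv_weight=0)
        from spannot.detector import extract_feature
        out = extract_feature(ch, np.zeros((6, 6)), np.ones((6, 6), bool), params)
        assert not np.any(out)

    def test_masked_product_oracle(self, rng):
        ch = rng.random((8, 8))
        mask = rng.random((8, 8)) < 0.5
        params = DetectorParams(sharpen_amount=0, gaussian_sigma=0, tv_weight=0)
        from spannot.detector import extract_feature
        out = extract_feature(ch, mask, np.ones((8, 8), bool), params)
        raw = ch * mask
        expect = (raw - raw.min()) / (raw.max() - raw.min())
        assert np.allclose(out, expect)

    def test_undefined_channel_values(self):
        F = np.zeros((2, 2, 2))
        F[0, 0] = [0.2, 0.4]
        mask = np.ones((2, 2), bool)
        out = add_undefined_channel(F, mask, u=0.5)
        assert out.shape == (2, 2, 3)
        assert out[0, 0, 2] == pytest.approx(0.5 - 0.3)
        assert out[1, 1, 2] == pytest.approx(0.5)  # empty-evidence pixel
        out2 = add_undefined_channel(np.full((2, 2, 2), 0.9), mask, u=0.5)
        assert np.all(out2[..., 2] == 0.0)  # clipped

    def test_argmax_and_tiebreak(self):
        coords = _grid_coords(1, 2)
        pm = build_pixel_map(coords)
        F = np.zeros((1, 2, 2))
        F[0, 0] = [0.1, 0.9]
        F[0, 1] = [0.5, 0.5]
        ann = initialize_labels(F, pm, ["a", "b"])
        assert ann.labels[0] == 1
        assert ann.labels[1] == 0  # tie -> lowest index

    def test_argmax_bruteforce_on_bands(self, rng):
        coords = _grid_coords(20, 20)
        pm = build_pixel_map(coords)
        F = rng.random((20, 20, 3))
        ann = initialize_labels(F, pm, list("abc"))
        for s, (i, j) in enumerate(pm.pixel_of_spot):
            assert ann.labels[s] == int(np.argmax(F[i, j]))


class TestEndToEnd:
    def test_noiseless_bands_recovered_exactly(self):
        """Disjoint indicator bands per marker must be labeled perfectly."""
        I, J, R = 24, 24, 3
        coords = _grid_coords(I, J)
        truth = (np.repeat(np.arange(I), J) * R) // I
        denoised = np.zeros((R, I * J))
        for r in range(R):
            denoised[r, truth == r] = 1.0
        state = SpotTable(
            spot_ids=np.array([f"s{k}" for k in range(I * J)], dtype=object),
            coords=coords, counts=np.ones((R, I * J), dtype=np.int64),
            gene_names=np.array([f"m{r}" for r in range(R)], dtype=object),
            denoised=denoised,
        )
        markers = {f"p{r}": [f"m{r}"] for r in range(R)}
        params = DetectorParams(n_thresholds=2, dilation_radius=1,
                                sharpen_amount=0, gaussian_sigma=0, tv_weight=0)
        ann = detect(state, markers, params=params)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, ann.labels) == 1.0

    def test_background_stays_zero(self, laminar_sim):
        from spannot.core import create_state, denoise, size_factors
        sim = laminar_sim
        # keep an L-shaped subset of spots so the raster has background
        keep = (sim.coords[:, 0] < 15) | (sim.coords[:, 1] < 15)
        st = create_state(sim.coords[keep], sim.counts[:, keep], sim.gene_names)
        st.size_factors = size_factors(st.counts)
        st.denoised = denoise(st.counts, coords=st.coords, sf=st.size_factors)
        ann = detect(st, sim.markers)
        stack = ann.stack
        bg = ~build_pixel_map(st.coords).mask
        assert not np.any(stack.pattern_image[bg])
        assert not np.any(stack.feature_image[bg])
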