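"""Histogram/GLCM feature extraction against independent oracles.

The co-occurrence accumulator is checked three ways: the hand-worked
two-level example, a brute-force double loop over pixel pairs on random
masked images, and skimage's ``graycomatrix`` on full-mask images.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.feature import graycomatrix

from ctbonetex import (
    ConfigurationError,
    CTSlice,
    GLCM,
    QuantizedROI,
    ROIFragmentedError,
    ROIMask,
    ROITooSmallError,
    SimConfig,
    build_change_design,
    compute_glcm,
    extract_feature_vector,
    feature_index,
    feature_names,
    glcm_statistics,
    histogram_features,
    histogram_statistics,
    quantize_roi,
    render_slice_stack,
)
from ctbonetex.features import FeatureVector, LEVEL_COUNTS, N_FEATURES


def _slice(arr):
    return CTSlice(hu=np.asarray(arr, dtype=float))


def _full_mask(shape):
    return ROIMask(mask=np.ones(shape, dtype=bool))


# ---------------------------------------------------------------------------
# first-order statistics

class TestHistogram:
    def test_two_point_sample_hand_computed(self):
        """{0,0,100,100}: mean 50, sample sd 100/√3, skew 0, entropy 1 bit."""
        stats = histogram_statistics(np.array([0.0, 0.0, 100.0, 100.0]))
        assert stats[0] == pytest.approx(50.0)
        assert stats[1] == pytest.approx(57.735026919)
        assert stats[2] == pytest.approx(0.0, abs=1e-12)
        assert stats[4] == pytest.approx(1.0)

    def test_moments_match_direct_formulas(self, rng):
        x = rng.normal(100, 30, size=400)
        mean, sd, skew, kurt, _ = histogram_statistics(x)
        assert mean == pytest.approx(x.mean())
        assert sd == pytest.approx(x.std(ddof=1))
        c = x - x.mean()
        assert skew == pytest.approx((c**3).mean() / x.std(ddof=1) ** 3)
        assert kurt == pytest.approx((c**4).mean() / x.std(ddof=1) ** 4)

    def test_constant_roi_degenerate_convention(self):
        slc = _slice(np.full((8, 8), 200.0))
        np.testing.assert_array_equal(
            histogram_features(slc, _full_mask((8, 8))),
            [200.0, 0.0, 0.0, 0.0, 0.0],
        )

    def test_translation_invariance(self, rng):
        hu = rng.normal(100, 40, size=(8, 8))
        mask = _full_mask((8, 8))
        base = histogram_features(_slice(hu), mask)
        shifted = histogram_features(_slice(hu + 37.0), mask)
        assert shifted[0] == pytest.approx(base[0] + 37.0)
        np.testing.assert_allclose(shifted[1:], base[1:], rtol=1e-9)

    def test_small_roi_rejected(self):
        m = np.zeros((8, 8), dtype=bool)
        m[0, :5] = True
        with pytest.raises(ROITooSmallError):
            histogram_features(_slice(np.zeros((8, 8))), ROIMask(mask=m))


# ---------------------------------------------------------------------------
# quantization

class TestQuantize:
    def test_two_level_bin_edges(self):
        hu = np.zeros((8, 8))
        hu[0, :4] = [0.0, 49.0, 50.0, 100.0]
        q = quantize_roi(_slice(hu), _full_mask((8, 8)), n=2)
        assert list(q.levels[0, :4]) == [1, 1, 2, 2]

    def test_constant_roi_all_level_one(self):
        q = quantize_roi(_slice(np.full((8, 8), 7.0)), _full_mask((8, 8)), n=32)
        assert set(q.levels.ravel()) == {1}

    def test_levels_within_range_even_when_n_exceeds_pixels(self, rng):
        hu = rng.normal(size=(8, 8))
        q = quantize_roi(_slice(hu), _full_mask((8, 8)), n=128)
        assert q.levels.min() >= 1 and q.levels.max() <= 128

    def test_extremes_map_to_end_levels(self, rng):
        hu = rng.normal(100, 50, size=(16, 16))
        q = quantize_roi(_slice(hu), _full_mask((16, 16)), n=16)
        assert q.levels[np.unravel_index(hu.argmin(), hu.shape)] == 1
        assert q.levels[np.unravel_index(hu.argmax(), hu.shape)] == 16

    def test_outside_roi_is_sentinel_zero(self):
        m = np.zeros((8, 8), dtype=bool)
        m[:4] = True
        q = quantize_roi(_slice(np.arange(64.0).reshape(8, 8)), ROIMask(mask=m), 4)
        assert (q.levels[4:] == 0).all() and (q.levels[:4] > 0).all()

    def test_n_below_two_rejected(self):
        with pytest.raises(ConfigurationError):
            quantize_roi(_slice(np.zeros((8, 8))), _full_mask((8, 8)), n=1)


# ---------------------------------------------------------------------------
# co-occurrence accumulation

def brute_force_glcm(levels, n, direction):
    """Independent pair-counting oracle: explicit double loop."""
    dr, dc = (0, 1) if direction == "horizontal" else (1, 0)
    counts = np.zeros((n, n), dtype=int)
    rows, cols = levels.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if r2 < rows and c2 < cols and levels[r, c] > 0 and levels[r2, c2] > 0:
                counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
    return counts


WORKED_LEVELS = np.array(
    [[1, 1, 2, 2], [1, 1, 2, 2], [2, 2, 1, 1], [2, 2, 1, 1]]
)


class TestGLCM:
    def test_worked_two_level_example(self):
        g = compute_glcm(QuantizedROI(levels=WORKED_LEVELS, n=2), "horizontal")
        np.testing.assert_array_equal(g.counts, [[4, 2], [2, 4]])
        np.testing.assert_allclose(
            g.probs, [[1 / 3, 1 / 6], [1 / 6, 1 / 3]], atol=1e-15
        )

    def test_horizontal_equals_vertical_of_transpose(self, rng):
        levels = rng.integers(0, 5, size=(7, 9))
        h = compute_glcm(QuantizedROI(levels=levels, n=4), "horizontal")
        v = compute_glcm(QuantizedROI(levels=levels.T, n=4), "vertical")
        np.testing.assert_array_equal(h.counts, v.counts)

    def test_constant_image_single_entry(self):
        g = compute_glcm(QuantizedROI(levels=np.ones((5, 5), int), n=3), "vertical")
        assert g.probs[0, 0] == 1.0
        assert g.counts.sum() == g.counts[0, 0]

    def test_asymmetric_no_reverse_accumulation(self):
        levels = np.array([[1, 2]])
        g = compute_glcm(QuantizedROI(levels=levels, n=2), "horizontal")
        assert g.counts[0, 1] == 1 and g.counts[1, 0] == 0

    def test_fully_fragmented_roi_raises(self):
        levels = np.zeros((4, 4), dtype=int)
        levels[::2, ::2] = 1  # isolated pixels, no distance-1 pair
        with pytest.raises(ROIFragmentedError):
            compute_glcm(QuantizedROI(levels=levels, n=2), "horizontal")

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        rows=st.integers(2, 6),
        cols=st.integers(2, 6),
        n=st.integers(2, 4),
        direction=st.sampled_from(["horizontal", "vertical"]),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_matches_brute_force_oracle(self, rows, cols, n, direction, seed):
        rng = np.random.default_rng(seed)
        levels = rng.integers(0, n + 1, size=(rows, cols))  # 0 = out of ROI
        q_levels = levels.copy()
        try:
            g = compute_glcm(QuantizedROI(levels=q_levels, n=n), direction)
        except ROIFragmentedError:
            assert brute_force_glcm(levels, n, direction).sum() == 0
            return
        np.testing.assert_array_equal(g.counts, brute_force_glcm(levels, n, direction))
        assert g.probs.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("direction,angle", [("horizontal", 0), ("vertical", np.pi / 2)])
    def test_full_mask_matches_skimage(self, rng, direction, angle):
        """Cross-check against graycomatrix on unmasked images."""
        img = rng.integers(1, 9, size=(12, 12))
        g = compute_glcm(QuantizedROI(levels=img, n=8), direction)
        ref = graycomatrix(
            (img - 1).astype(np.uint8), [1], [angle], levels=8, symmetric=False
        )[:, :, 0, 0]
        np.testing.assert_array_equal(g.counts, ref)


# ---------------------------------------------------------------------------
# GLCM statistics

class TestGLCMStatistics:
    def test_worked_example_values(self):
        probs = np.array([[1 / 3, 1 / 6], [1 / 6, 1 / 3]])
        g = GLCM(counts=(probs * 12).astype(int), probs=probs,
                 direction="horizontal", n=2)
        contrast, corr, energy, homog, var = glcm_statistics(g)
        assert contrast == pytest.approx(1 / 3)
        assert corr == pytest.approx(1 / 3)
        assert energy == pytest.approx(5 / 18)
        assert homog == pytest.approx(5 / 6)
        assert var == pytest.approx(1 / 4)

    def test_single_entry_degenerate(self):
        probs = np.zeros((4, 4))
        probs[0, 0] = 1.0
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 9
        g = GLCM(counts=counts, probs=probs, direction="horizontal", n=4)
        np.testing.assert_allclose(glcm_statistics(g), [0, 0, 1, 1, 0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(n=st.integers(2, 6), seed=st.integers(0, 2**31 - 1))
    def test_statistic_bounds(self, n, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 10, size=(n, n))
        if counts.sum() == 0:
            counts[0, 0] = 1
        probs = counts / counts.sum()
        g = GLCM(counts=counts, probs=probs, direction="horizontal", n=n)
        contrast, corr, energy, homog, var = glcm_statistics(g)
        assert contrast >= 0
        assert abs(corr) <= 1 + 1e-12
        assert 0 < energy <= 1 + 1e-12
        assert 0 < homog <= 1 + 1e-12
        assert var >= 0


# ---------------------------------------------------------------------------
# indexing and assembly

class TestFeatureIndex:
    def test_histogram_slots(self):
        assert [feature_index("histogram", k=k) for k in range(1, 6)] == [1, 2, 3, 4, 5]

    def test_glcm_corner_cases(self):
        assert feature_index("glcm", l=1, m=1, n=1) == 6
        assert feature_index("glcm", l=2, m=4, n=5) == 45

    def test_bijective_onto_1_45(self):
        seen = {feature_index("histogram", k=k) for k in range(1, 6)}
        seen |= {
            feature_index("glcm", l=l, m=m, n=n)
            for l in (1, 2) for m in range(1, 5) for n in range(1, 6)
        }
        assert seen == set(range(1, 46))
        assert len(feature_names()) == 45

    @pytest.mark.parametrize(
        "kwargs", [{"k": 0}, {"k": 6}, {"l": 3, "m": 1, "n": 1},
                   {"l": 1, "m": 5, "n": 1}, {"l": 1, "m": 1, "n": 6}]
    )
    def test_out_of_range_rejected(self, kwargs):
        kind = "histogram" if "k" in kwargs else "glcm"
        with pytest.raises(ConfigurationError):
            feature_index(kind, **kwargs)


class TestExtraction:
    def test_vector_has_45_entries(self, rng):
        slc = _slice(rng.normal(200, 80, size=(16, 16)))
        fv = extract_feature_vector(slc, _full_mask((16, 16)))
        assert fv.values.shape == (N_FEATURES,)
        assert np.all(np.isfinite(fv.values))

    def test_exactly_eight_glcm_constructions(self, rng, monkeypatch):
        import ctbonetex.features as F

        calls = []
        original = F.compute_glcm

        def counting(q, direction):
            calls.append((q.n, direction))
            return original(q, direction)

        monkeypatch.setattr(F, "compute_glcm", counting)
        slc = _slice(rng.normal(200, 80, size=(16, 16)))
        F.extract_feature_vector(slc, _full_mask((16, 16)))
        assert len(calls) == 8
        assert {n for n, _ in calls} == set(LEVEL_COUNTS)

    def test_constant_roi_composition(self):
        slc = _slice(np.full((8, 8), 123.0))
        fv = extract_feature_vector(slc, _full_mask((8, 8)))
        expected = [123.0, 0, 0, 0, 0] + [0, 0, 1, 1, 0] * 8
        np.testing.assert_allclose(fv.values, expected)

    def test_hu_shift_leaves_glcm_features_unchanged(self, rng):
        hu = rng.normal(200, 80, size=(16, 16))
        mask = _full_mask((16, 16))
        a = extract_feature_vector(_slice(hu), mask).values
        b = extract_feature_vector(_slice(hu + 250.0), mask).values
        np.testing.assert_allclose(b[5:], a[5:], rtol=1e-9)

    def test_pure_function_of_inputs(self, rng):
        hu = rng.normal(200, 80, size=(16, 16))
        mask = _full_mask((16, 16))
        a = extract_feature_vector(_slice(hu), mask).values
        b = extract_feature_vector(_slice(hu.copy()), mask).values
        np.testing.assert_array_equal(a, b)

    def test_texture_sensitivity_between_bmc_arms(self):
        """Homogeneity (n=16, horizontal) separates low/high BMC arms.

        The two-sample comparison over 100 renders per arm is the signal
        the downstream regression relies on.  The arms are chosen with
        asymmetric bone fractions (0.25 vs 0.50): |i−j|-based adjacency
        statistics are nearly invariant under swapping the bone and
        marrow phases, so fractions mirrored around 0.5 would coincide.
        """
        from scipy import stats as sps

        from ctbonetex import circular_trabecular_roi

        cfg = SimConfig(seed=0)
        rng = np.random.default_rng(7)
        j_homog = feature_index("glcm", l=1, m=1, n=4)
        arms = {}
        for bmc in (10.0, 15.0):
            vals = []
            for _ in range(100):
                vol = render_slice_stack(bmc, cfg, rng)
                slc = vol[2]
                roi = circular_trabecular_roi(slc)
                vals.append(extract_feature_vector(slc, roi)[j_homog])
            arms[bmc] = vals
        p = sps.ttest_ind(arms[10.0], arms[15.0]).pvalue
        assert p < 0.01


class TestChangeDesign:
    def test_concatenation_and_target(self, rng):
        fv1 = FeatureVector(values=rng.normal(size=45))
        fv2 = FeatureVector(values=rng.normal(size=45))
        cd = build_change_design(fv1, fv2, y1=15.0, y2=14.2)
        assert cd.values.shape == (90,)
        np.testing.assert_array_equal(cd.values[:45], fv1.values)
        np.testing.assert_array_equal(cd.values[45:], fv2.values)
        assert cd.target == pytest.approx(-0.8)

    def test_no_change_case(self, rng):
        fv = FeatureVector(values=rng.normal(size=45))
        cd = build_change_design(fv, fv, 15.0, 15.0)
        assert cd.target == 0.0
        np.testing.assert_array_equal(cd.values[:45], cd.values[45:])

    def test_swapping_timepoints_negates_target(self, rng):
        fv1 = FeatureVector(values=rng.normal(size=45))
        fv2 = FeatureVector(values=rng.normal(size=45))
        assert build_change_design(fv1, fv2, 15.0, 14.0).target == pytest.approx(
            -build_change_design(fv2, fv1, 14.0, 15.0).target
        )
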