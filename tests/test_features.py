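"""Texture matrices and feature families against hand examples and oracles."""

import numpy as np
import pytest

from lge_radiomics.core import DegenerateSliceError, QuantizedROI, SliceROI
from lge_radiomics.features import (
    ExtractionConfig,
    extract_patient_features,
    extract_slice_features,
    firstorder_features,
    glcm,
    glcm_features,
    gldm,
    gldm_features,
    glrlm,
    glrlm_features,
    glszm,
    glszm_features,
    ngtdm,
    ngtdm_features,
)
from lge_radiomics.features.matrices import RunLengthMatrix

from .conftest import random_quantized
from . import oracles


def make_q(levels, n_levels=None, mask=None):
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    if n_levels is None:
        n_levels = max(2, int(levels.max()))
    return QuantizedROI(levels, mask, n_levels)


class TestGLCM:
    def test_hand_example_horizontal(self):
        q = make_q([[1, 1], [1, 2]])
        m = glcm(q, directions=((0, 1),))
        assert m.p[0, 0] == pytest.approx(0.5)
        assert m.p[0, 1] == pytest.approx(0.25)
        assert m.p[1, 0] == pytest.approx(0.25)

    def test_constant_roi_is_point_mass(self):
        q = make_q(np.full((4, 4), 3), n_levels=4)
        m = glcm(q)
        assert m.p[2, 2] == pytest.approx(1.0)
        f = glcm_features(m)
        assert f["Autocorrelation"] == pytest.approx(9.0)  # g^2 with g = 3
        assert f["DifferenceEntropy"] == pytest.approx(0.0)

    def test_hand_example_features(self):
        q = make_q([[1, 1], [1, 2]])
        f = glcm_features(glcm(q, directions=((0, 1),)))
        assert f["Autocorrelation"] == pytest.approx(1.5)
        assert f["DifferenceEntropy"] == pytest.approx(1.0)  # bits

    def test_checkerboard_features(self):
        board = np.indices((6, 6)).sum(axis=0) % 2 + 1
        f = glcm_features(glcm(make_q(board, mask=np.ones((6, 6), bool)),
                               directions=((0, 1),)))
        assert f["Autocorrelation"] == pytest.approx(2.0)
        assert f["DifferenceEntropy"] == pytest.approx(0.0)

    def test_matches_brute_force_on_random_rois(self, rng):
        for _ in range(20):
            q = random_quantized(rng)
            try:
                m = glcm(q)
            except DegenerateSliceError:
                continue
            brute = oracles.glcm_brute(q.levels, q.mask, q.n_levels)
            assert np.allclose(m.p, brute)

    def test_difference_margin_sums_to_one(self, rng):
        q = random_quantized(rng, n_levels=6)
        p = glcm(q).p
        k = np.abs(np.subtract.outer(np.arange(6), np.arange(6)))
        p_diff = np.bincount(k.ravel(), weights=p.ravel())
        assert p_diff.sum() == pytest.approx(1.0)

    def test_isolated_pixels_flagged_degenerate(self):
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = mask[4, 4] = False
        mask[2, 2] = True
        levels = np.where(mask, 1, 0)
        with pytest.raises(DegenerateSliceError):
            glcm(QuantizedROI(levels, mask, 2))

    def test_agrees_with_scikit_image(self, rng):
        """Cross-check against an independent established GLCM extractor."""
        from skimage.feature import graycomatrix, graycoprops

        img = rng.integers(0, 5, (12, 12))
        q = make_q(img + 1, n_levels=5, mask=np.ones((12, 12), bool))
        m = glcm(q, directions=((0, 1),))
        sk = graycomatrix(img.astype(np.uint8), [1], [0], levels=5,
                          symmetric=True, normed=True)[:, :, 0, 0]
        assert np.allclose(m.p, sk)
        f = glcm_features(m)
        assert f["Contrast"] == pytest.approx(
            graycoprops(graycomatrix(img.astype(np.uint8), [1], [0], levels=5,
                                     symmetric=True, normed=True), "contrast")[0, 0]
        )


class TestNGTDM:
    def test_constant_roi_has_zero_differences(self):
        t = ngtdm(make_q(np.full((4, 4), 2), n_levels=3))
        assert np.allclose(t.s, 0.0)
        assert ngtdm_features(t)["Complexity"] == pytest.approx(0.0)

    def test_two_by_two_hand_enumeration(self):
        t = ngtdm(make_q([[1, 2], [1, 2]]))
        assert t.s[0] == pytest.approx(4 / 3)
        assert t.s[1] == pytest.approx(4 / 3)
        assert list(t.n) == [2, 2]
        assert t.n_valid == 4
        assert ngtdm_features(t)["Complexity"] == pytest.approx(2 / 3)

    def test_matches_brute_force_on_random_rois(self, rng):
        for _ in range(20):
            q = random_quantized(rng)
            try:
                t = ngtdm(q)
            except DegenerateSliceError:
                continue
            s, n, p, n_valid = oracles.ngtdm_brute(q.levels, q.mask, q.n_levels)
            assert np.allclose(t.s, s)
            assert np.array_equal(t.n, n)
            assert t.n_valid == n_valid

    def test_complexity_is_linear_in_s(self):
        t = ngtdm(make_q([[1, 2], [1, 2]]))
        c1 = ngtdm_features(t)["Complexity"]
        t.s = 3.0 * t.s
        assert ngtdm_features(t)["Complexity"] == pytest.approx(3.0 * c1)


class TestRunZoneDependence:
    def test_constant_roi_long_run_emphasis(self):
        q = make_q(np.ones((4, 4)), n_levels=2)
        m = glrlm(q, directions=((0, 1),))
        assert m.counts.sum() == 4  # 4 rows, one run each
        assert glrlm_features(
            RunLengthMatrix(m.counts, m.n_levels, m.n_voxels, 1)
        )["LongRunEmphasis"] == pytest.approx(16.0)

    def test_constant_roi_single_zone_entropy(self):
        q = make_q(np.ones((4, 4)), n_levels=2)
        f = glszm_features(glszm(q))
        assert f["ZoneEntropy"] == pytest.approx(0.0)

    @pytest.mark.parametrize("family,build,brute", [
        ("glrlm", glrlm, oracles.glrlm_brute),
        ("glszm", glszm, oracles.glszm_brute),
        ("gldm", gldm, oracles.gldm_brute),
    ])
    def test_matches_brute_force_on_random_rois(self, rng, family, build, brute):
        for _ in range(20):
            q = random_quantized(rng)
            try:
                m = build(q)
            except DegenerateSliceError:
                continue
            expected = brute(q.levels, q.mask, q.n_levels)
            assert np.array_equal(m.counts, expected), family


class TestFirstOrder:
    def test_basic_statistics(self):
        vals = np.array([0.0, 0.5, 1.0])
        q = make_q([[1, 2, 2]], n_levels=2, mask=np.ones((1, 3), bool))
        f = firstorder_features(vals, q)
        assert f["Mean"] == pytest.approx(0.5)
        assert f["Range"] == pytest.approx(1.0)
        assert f["Median"] == pytest.approx(0.5)

    def test_constant_values_have_zero_spread(self):
        vals = np.zeros(9)
        q = make_q(np.ones((3, 3)), n_levels=2)
        f = firstorder_features(vals, q)
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0
        assert f["Entropy"] == 0.0


class TestPatientAggregation:
    @pytest.fixture
    def slice_pair(self, rng):
        from lge_radiomics.synthetic import generate_ring_mask, generate_texture

        mask = generate_ring_mask(32, (1.0, 1.0), (8.0, 14.0))
        return [generate_texture(mask, 1.0, s) for s in (1, 2)]

    def test_replicated_slice_equals_single_slice(self, slice_pair):
        cfg = ExtractionConfig(image_types=("original",), families=("glcm", "ngtdm"))
        single = extract_slice_features(slice_pair[0], cfg)
        replicated = extract_patient_features([slice_pair[0]] * 3, cfg)
        for name in single:
            assert replicated[name] == pytest.approx(single[name])

    def test_two_slices_average(self, slice_pair):
        cfg = ExtractionConfig(image_types=("original",), families=("glcm",))
        a = extract_slice_features(slice_pair[0], cfg)
        b = extract_slice_features(slice_pair[1], cfg)
        combined = extract_patient_features(slice_pair, cfg)
        for name in a:
            assert combined[name] == pytest.approx((a[name] + b[name]) / 2)

    def test_slice_order_invariance(self, slice_pair):
        cfg = ExtractionConfig(image_types=("original",), families=("ngtdm",))
        fwd = extract_patient_features(slice_pair, cfg)
        rev = extract_patient_features(slice_pair[::-1], cfg)
        assert fwd == rev

    def test_all_degenerate_slices_excludes_patient(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True  # isolated pixel: no neighbour pairs
        roi = SliceROI(np.where(mask, 0.5, 0.0), mask)
        with pytest.raises(DegenerateSliceError, match="excluded"):
            extract_patient_features([roi], ExtractionConfig(image_types=("original",)))

    def test_full_vector_finite_with_stable_names(self, slice_pair):
        f1 = extract_slice_features(slice_pair[0])
        f2 = extract_slice_features(slice_pair[1])
        assert f1.keys() == f2.keys()
        assert len(f1) > 900
        assert all(np.isfinite(v) for v in f1.values())


def test_stack_normalization_shares_intensity_bounds(rng):
    """Per-stack normalization uses one min/max for all of a patient's slices."""
    from lge_radiomics.synthetic import generate_ring_mask, generate_texture

    mask = generate_ring_mask(32, (1.0, 1.0), (8.0, 14.0))
    bright = generate_texture(mask, 1.0, 1, mean=400.0, sd=30.0)
    dim = generate_texture(mask, 1.0, 2, mean=200.0, sd=30.0)
    cfg_slice = ExtractionConfig(image_types=("original",), families=("firstorder",))
    cfg_stack = ExtractionConfig(image_types=("original",), families=("firstorder",),
                                 normalization="stack")
    per_slice = extract_patient_features([bright, dim], cfg_slice)
    per_stack = extract_patient_features([bright, dim], cfg_stack)
    # per-slice: every slice spans [0, 1], so the slice-averaged Maximum is 1
    assert per_slice["original_firstorder_Maximum"] == pytest.approx(1.0)
    # per-stack: the dim slice only reaches partway up the shared range
    assert per_stack["original_firstorder_Maximum"] < 1.0 - 1e-6
    assert per_stack["original_firstorder_Mean"] != pytest.approx(
        per_slice["original_firstorder_Mean"]
    )
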