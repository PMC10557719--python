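"""Colocalization tests: Pearson, Costes thresholds/randomization, Otsu,
overlap fractions — each against an independent oracle or exact arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bmquant import coloc, synthetic
from bmquant.errors import (
    ArgumentError,
    DegenerateHistogramError,
    DegenerateMaskError,
    UndefinedCorrelationError,
)
from bmquant.types import ImagePair


def _rand_img(seed, shape=(20, 20), levels=256):
    return np.random.default_rng(seed).integers(0, levels, shape).astype(float)


class TestPearson:
    def test_identity_and_anticorrelation(self):
        x = _rand_img(0)
        assert coloc.pearson_r(x, x) == pytest.approx(1.0)
        assert coloc.pearson_r(x, -x + 42.0) == pytest.approx(-1.0)

    def test_hand_worked_four_pixel_value(self):
        # direct evaluation of the product-moment formula gives 0.6
        ch1 = np.array([[1.0, 2.0], [3.0, 4.0]])
        ch2 = np.array([[2.0, 1.0], [4.0, 3.0]])
        assert coloc.pearson_r(ch1, ch2) == pytest.approx(0.6)

    @given(
        a=st.floats(0.1, 50), b=st.floats(-100, 100),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance_and_antisymmetry(self, a, b, seed):
        x, y = _rand_img(seed), _rand_img(seed + 1)
        r = coloc.pearson_r(x, y)
        assert coloc.pearson_r(a * x + b, y) == pytest.approx(r, abs=1e-9)
        assert coloc.pearson_r(x, a * y + b) == pytest.approx(r, abs=1e-9)
        assert coloc.pearson_r(-x, y) == pytest.approx(-r, abs=1e-9)

    def test_constant_channel_and_too_few_pixels(self):
        x = _rand_img(1)
        with pytest.raises(UndefinedCorrelationError):
            coloc.pearson_r(x, np.full_like(x, 3.0))
        mask = np.zeros_like(x, dtype=bool)
        mask[0, 0] = True
        with pytest.raises(ArgumentError):
            coloc.pearson_r(x, x, mask)


class TestCostesThresholds:
    def test_perfectly_colocalized_is_degenerate(self):
        x = _rand_img(2)
        pair = ImagePair(x, 2.0 * x)
        t1, t2, slope, intercept, degenerate = coloc.costes_thresholds(pair)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert degenerate
        assert t1 == pytest.approx(x.min())

    def test_independent_pair_postcondition(self):
        pair, _ = synthetic.gen_correlated_pair(shape=(48, 48), rho=0.0, seed=4)
        t1, t2, slope, intercept, degenerate = coloc.costes_thresholds(pair)
        assert not degenerate
        below = (pair.ch1 < t1) & (pair.ch2 < t2)
        assert coloc.pearson_r(pair.ch1[below], pair.ch2[below]) <= 1e-12
        # thresholds sit near the channel maxima for independent noise
        assert t1 > np.quantile(pair.ch1, 0.5)

    def test_matches_exhaustive_scan(self):
        # oracle: brute-force the highest candidate with sub-threshold r <= 0
        pair, _ = synthetic.gen_correlated_pair(shape=(24, 24), rho=0.3, seed=8)
        t1, t2, slope, intercept, degenerate = coloc.costes_thresholds(pair)
        x, y = pair.ch1.ravel(), pair.ch2.ravel()
        best = None
        for cand in np.unique(x)[::-1]:
            c2 = slope * cand + intercept
            sel = (x < cand) & (y < c2)
            if sel.sum() < 2 or np.ptp(x[sel]) == 0 or np.ptp(y[sel]) == 0:
                continue
            if np.corrcoef(x[sel], y[sel])[0, 1] <= 0:
                best = (cand, c2)
                break
        assert best is not None and not degenerate
        assert t1 == pytest.approx(best[0])
        assert t2 == pytest.approx(best[1])

    @pytest.mark.parametrize("rho", [0.0, 0.4, 0.8])
    def test_postcondition_property_over_random_pairs(self, rho):
        for seed in range(10):
            pair, _ = synthetic.gen_correlated_pair(
                shape=(32, 32), rho=rho, seed=seed
            )
            t1, t2, _, _, degenerate = coloc.costes_thresholds(pair)
            if degenerate:
                continue
            below = (pair.ch1 < t1) & (pair.ch2 < t2)
            assert coloc.pearson_r(pair.ch1[below], pair.ch2[below]) <= 1e-12


class TestRandomization:
    def test_identical_channels_minimum_p(self):
        x = _rand_img(3, shape=(30, 30))
        pair = ImagePair(x, x.copy())
        p = coloc.costes_randomization_test(pair, n=100, block=5, seed=0)
        assert p == pytest.approx(1.0 / 101.0)

    def test_zero_randomizations_rejected(self):
        x = _rand_img(4)
        with pytest.raises(ArgumentError):
            coloc.costes_randomization_test(ImagePair(x, x), n=0)

    def test_too_small_roi_rejected(self):
        x = _rand_img(5, shape=(8, 8))
        with pytest.raises(ArgumentError):
            coloc.costes_randomization_test(ImagePair(x, x), n=10, block=5)

    def test_deterministic_given_seed(self):
        pair, _ = synthetic.gen_correlated_pair(shape=(40, 40), rho=0.2, seed=6)
        p1 = coloc.costes_randomization_test(pair, n=50, seed=42)
        p2 = coloc.costes_randomization_test(pair, n=50, seed=42)
        assert p1 == p2


class TestColocAnalysis:
    def test_identical_channels(self):
        x = _rand_img(7, shape=(30, 30))
        res = coloc.coloc_analysis(ImagePair(x, x.copy()), n_rand=100, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0 / 101.0)
        assert res.degenerate

    def test_recovers_generator_correlation(self):
        pair, _ = synthetic.gen_correlated_pair(shape=(128, 128), rho=0.8, seed=9)
        res = coloc.coloc_analysis(pair, n_rand=20, seed=1)
        assert res.r_all == pytest.approx(0.8, abs=0.05)

    def test_empty_roi_rejected(self):
        x = _rand_img(8)
        pair = ImagePair(x, x, roi_mask=np.zeros_like(x, dtype=bool))
        with pytest.raises(ArgumentError):
            coloc.coloc_analysis(pair)


def _otsu_bruteforce(vals):
    """Independent oracle: exhaustive between-class-variance argmax over the
    256 equal-width bin edges, computed from the raw pixel values."""
    lo, hi = vals.min(), vals.max()
    edges = np.linspace(lo, hi, coloc.N_OTSU_BINS + 1)
    best_t, best_v = None, -np.inf
    for t in edges[1:-1]:
        c0, c1 = vals[vals < t], vals[vals >= t]
        if len(c0) == 0 or len(c1) == 0:
            continue
        w0 = len(c0) / len(vals)
        v = w0 * (1 - w0) * (c0.mean() - c1.mean()) ** 2
        if v > best_v + 1e-12:  # strict improvement: ties keep the lower t
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_bimodal_delta_case(self):
        img = np.repeat([0.0, 255.0], 50).reshape(10, 10)
        t = coloc.otsu_threshold(img)
        assert 0.0 < t < 255.0
        assert (img >= t).sum() == 50

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_bruteforce_oracle(self, seed):
        img = _rand_img(seed, shape=(30, 30))
        assert coloc.otsu_threshold(img) == pytest.approx(
            _otsu_bruteforce(img.ravel()), abs=1e-9
        )

    def test_close_to_skimage_on_eight_bit(self):
        # independent library cross-check; dialects differ by < one bin width
        from skimage.filters import threshold_otsu

        img = _rand_img(33, shape=(40, 40))
        binw = np.ptp(img) / coloc.N_OTSU_BINS
        assert abs(coloc.otsu_threshold(img) - threshold_otsu(img)) <= 2 * binw

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            coloc.otsu_threshold(np.full((10, 10), 7.0))


class TestOverlapFraction:
    def _pair_from_masks(self, m1, m2):
        # bright where mask, dim elsewhere: Otsu recovers the masks exactly
        ch1 = np.where(m1, 200.0, 10.0)
        ch2 = np.where(m2, 200.0, 10.0)
        return ImagePair(ch1, ch2)

    def test_identical_channels_full_overlap(self):
        x = _rand_img(10, shape=(30, 30))
        res = coloc.overlap_fraction(ImagePair(x, x.copy()))
        assert res.frac_ch1 == 1.0 and res.frac_ch2 == 1.0

    def test_nested_masks(self):
        m1 = np.zeros((20, 20), dtype=bool)
        m1[5:15, 5:15] = True  # 100 px
        m2 = np.zeros_like(m1)
        m2[5:15, 5:10] = True  # 50 px, subset covering half of m1
        res = coloc.overlap_fraction(self._pair_from_masks(m1, m2))
        assert res.frac_ch1 == pytest.approx(0.5)
        assert res.frac_ch2 == pytest.approx(1.0)

    def test_disjoint_masks(self):
        m1 = np.zeros((20, 20), dtype=bool)
        m1[2:8, 2:8] = True
        m2 = np.zeros_like(m1)
        m2[12:18, 12:18] = True
        res = coloc.overlap_fraction(self._pair_from_masks(m1, m2))
        assert res.frac_ch1 == 0.0 and res.frac_ch2 == 0.0

    def test_channel_swap_symmetry(self):
        pair, _ = synthetic.gen_correlated_pair(shape=(32, 32), rho=0.5, seed=12)
        a = coloc.overlap_fraction(pair)
        b = coloc.overlap_fraction(ImagePair(pair.ch2, pair.ch1))
        assert a.frac_ch1 == pytest.approx(b.frac_ch2)
        assert a.frac_ch2 == pytest.approx(b.frac_ch1)

    def test_monotone_in_intersection(self):
        m1 = np.zeros((20, 20), dtype=bool)
        m1[5:15, 5:15] = True
        fracs = []
        for w in (7, 10, 13):
            m2 = np.zeros_like(m1)
            m2[5:15, 5:5 + w] = True
            res = coloc.overlap_fraction(self._pair_from_masks(m1, m2))
            fracs.append(res.frac_ch1)
        assert fracs == sorted(fracs)

    def test_product_dialect_identical_channels(self):
        x = _rand_img(13, shape=(30, 30))
        res = coloc.overlap_fraction(ImagePair(x, x.copy()), dialect="product")
        assert res.area_overlap <= min(res.area_ch1, res.area_ch2)
        assert res.frac_ch1 > 0

    def test_masks_helper_empty_mask_error(self):
        m = np.zeros((10, 10), dtype=bool)
        full = np.ones_like(m)
        with pytest.raises(DegenerateMaskError) as exc:
            coloc.overlap_from_masks(m, full)
        assert exc.value.area_ch1 == 0
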