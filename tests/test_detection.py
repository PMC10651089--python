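import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import gaussian_blob_stack
from psfqc.detection import (
    DEFAULT_SCALES,
    FeaturePeak,
    build_scale_space,
    exclude_close_peaks,
    find_peaks,
    li_threshold,
)
from psfqc.errors import DegenerateInputError
from psfqc.stack_io import ImageStack


def analytic_char_scale_oracle(sigma_blob, scales=DEFAULT_SCALES, n_dense=4000):
    """Dense scan of the adjacent-scale DOG response of an analytic 3D
    Gaussian blob: blurring with kernel s multiplies the peak by
    (sb^2/(sb^2+s^2))^(3/2); scan the response of a ratio-sqrt(2) difference
    over a dense log grid of s and report the band centre of the maximum."""
    k = math.sqrt(2.0)
    s = np.geomspace(scales[0], scales[-1] / k, n_dense)

    def peak_after_blur(width):
        return (sigma_blob**2 / (sigma_blob**2 + width**2)) ** 1.5

    response = peak_after_blur(s) - peak_after_blur(k * s)
    s_best = s[np.argmax(response)]
    return s_best * k**0.5  # geometric centre of the maximising band


class TestScaleSpace:
    def test_constant_stack_has_zero_dog(self):
        st_ = ImageStack(np.full((8, 32, 32), 7.0))
        ss = build_scale_space(st_)
        np.testing.assert_allclose(ss.dog_max_projection, 0.0, atol=1e-9)

    def test_energy_conservation_per_blurred_copy(self, single_blob):
        from psfqc.detection import _blur

        total = single_blob.data.sum()
        for s in DEFAULT_SCALES:
            assert _blur(single_blob.data, s).sum() == pytest.approx(total, rel=1e-6)

    @pytest.mark.parametrize("sigma_blob", [2.0, 3.0, 6.0])
    def test_characteristic_scale_tracks_blob_size(self, sigma_blob):
        stack = gaussian_blob_stack(
            shape=(31, 64, 64), centers=((15, 32, 32),),
            sigma_xy=sigma_blob, sigma_z=sigma_blob, background=0.0,
        )
        ss = build_scale_space(stack)
        expected = analytic_char_scale_oracle(sigma_blob)
        # agreement within one scale step (factor sqrt(2)) of the dense oracle
        assert abs(math.log(ss.characteristic_scale / expected)) <= math.log(math.sqrt(2)) + 1e-9

    def test_two_separated_blobs_give_two_dog_maxima(self):
        stack = gaussian_blob_stack(
            shape=(15, 48, 48), centers=((7, 24, 14), (7, 24, 34)), sigma_xy=2.0, sigma_z=2.0
        )
        peaks = find_peaks(build_scale_space(stack))
        assert len(peaks) == 2
        found = sorted((p.y, p.x) for p in peaks)
        assert all(abs(y - 24) <= 1 for y, _ in found)
        assert abs(found[0][1] - 14) <= 1 and abs(found[1][1] - 34) <= 1


class TestLiThreshold:
    def test_separates_two_level_values(self):
        t = li_threshold([1, 1, 1, 9, 9, 9])
        assert 1 < t < 9

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            li_threshold([5.0] * 10)

    def test_near_binary_keeps_foreground(self):
        values = np.array([1e-9] * 500 + [800.0] * 40)
        assert li_threshold(values) < 800.0

    def test_matches_exhaustive_cross_entropy_oracle(self):
        rng = np.random.default_rng(7)
        values = np.concatenate([
            rng.normal(100, 10, 9000).clip(1), rng.normal(1000, 80, 1000).clip(1)
        ])
        t_impl = li_threshold(values)

        # brute force: minimise the cross-entropy criterion over every
        # candidate threshold (midpoints between distinct sorted values)
        v = np.sort(values)
        uniq = np.unique(v)
        candidates = (uniq[:-1] + uniq[1:]) / 2
        best_t, best_ce = None, np.inf
        for t in candidates:
            below, above = v[v <= t], v[v > t]
            if below.size == 0 or above.size == 0:
                continue
            ce = -(below.sum() * np.log(below.mean()) + above.sum() * np.log(above.mean()))
            if ce < best_ce:
                best_ce, best_t = ce, t
        # the fixed point selects the same background/foreground split as the
        # exhaustive optimum (both land within the same inter-class bin)
        assert np.sum(v <= t_impl) == np.sum(v <= best_t)

    def test_agrees_with_reference_implementation(self):
        skimage_filters = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(11)
        values = np.concatenate([rng.poisson(30, 5000), rng.poisson(400, 500)]).astype(float)
        t_impl = li_threshold(values)
        t_ref = skimage_filters.threshold_li(values)
        # both thresholds fall in the inter-mode gap: the induced foreground /
        # background split of the sample is identical
        assert np.sum(values <= t_impl) == np.sum(values <= t_ref)

    def test_intensity_scale_equivariance(self):
        rng = np.random.default_rng(2)
        values = rng.gamma(2.0, 50.0, 5000)
        assert li_threshold(values * 3.5) == pytest.approx(3.5 * li_threshold(values), rel=1e-5)


class TestFindPeaks:
    def test_single_blob_found_at_centre(self, single_blob):
        peaks = find_peaks(build_scale_space(single_blob))
        assert len(peaks) == 1
        p = peaks[0]
        assert abs(p.z - 10) <= 1 and abs(p.y - 24) <= 1 and abs(p.x - 24) <= 1

    def test_background_jitter_yields_no_strong_peaks(self):
        rng = np.random.default_rng(0)
        st_ = ImageStack(100.0 + rng.normal(0, 1e-3, (8, 32, 32)))
        peaks = find_peaks(build_scale_space(st_))
        # pure noise: nothing resembling a feature survives fitting anyway,
        # but the detector must not crash and responses must be tiny
        assert all(p.response < 1e-2 for p in peaks)

    def test_truncated_to_200_strongest(self):
        centers = []
        for gy in range(16):
            for gx in range(16):
                if len(centers) < 250:
                    centers.append((12, 16 + 16 * gy, 16 + 16 * gx))
        stack = gaussian_blob_stack(
            shape=(25, 272, 272), centers=centers, sigma_xy=1.5, sigma_z=2.5, background=0.0
        )
        peaks = find_peaks(build_scale_space(stack))
        assert len(peaks) == 200

    def test_axially_separated_coincident_blobs_detected_separately(self):
        sigma_z = 2.0
        stack = gaussian_blob_stack(
            shape=(27, 40, 40),
            centers=((8, 20, 20), (18, 20, 20)),  # dz = 10 > 2 sigma_z
            sigma_xy=2.0, sigma_z=sigma_z,
        )
        peaks = find_peaks(build_scale_space(stack))
        zs = sorted(p.z for p in peaks)
        assert len(peaks) == 2
        assert abs(zs[0] - 8) <= 1 and abs(zs[1] - 18) <= 1

    def test_detection_intensity_scale_invariant(self, single_blob):
        coords = [(p.z, p.y, p.x) for p in find_peaks(build_scale_space(single_blob))]
        scaled = ImageStack(single_blob.data * 37.0)
        coords_scaled = [(p.z, p.y, p.x) for p in find_peaks(build_scale_space(scaled))]
        assert coords == coords_scaled


def brute_force_exclusion(points, min_sep=5.0):
    keep = []
    for i, (yi, xi) in enumerate(points):
        if all(
            math.hypot(yi - yj, xi - xj) >= min_sep
            for j, (yj, xj) in enumerate(points) if j != i
        ):
            keep.append(i)
    return keep


class TestExcludeClosePeaks:
    def test_pair_within_five_pixels_both_removed(self):
        peaks = [FeaturePeak(0, 10, 10, 5.0), FeaturePeak(0, 10, 14, 4.0)]
        assert exclude_close_peaks(peaks) == []

    def test_single_peak_unchanged(self):
        peaks = [FeaturePeak(0, 10, 10, 5.0)]
        assert exclude_close_peaks(peaks) == peaks

    def test_collinear_chain_all_removed(self):
        peaks = [FeaturePeak(0, 10, x, 1.0) for x in (0, 4, 8)]
        assert exclude_close_peaks(peaks) == []

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 30), st.integers(0, 30)),
            min_size=0, max_size=12, unique=True,
        )
    )
    def test_matches_pairwise_brute_force(self, points):
        peaks = [FeaturePeak(0, y, x, 1.0) for y, x in points]
        survivors = exclude_close_peaks(peaks)
        expected = [peaks[i] for i in brute_force_exclusion(points)]
        assert survivors == expected

    @settings(max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 30), st.integers(0, 30)),
            min_size=0, max_size=12, unique=True,
        ),
        st.randoms(use_true_random=False),
    )
    def test_idempotent_and_order_independent(self, points, rnd):
        peaks = [FeaturePeak(0, y, x, 1.0) for y, x in points]
        once = exclude_close_peaks(peaks)
        assert exclude_close_peaks(once) == once
        shuffled = list(peaks)
        rnd.shuffle(shuffled)
        assert set(exclude_close_peaks(shuffled)) == set(once)
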