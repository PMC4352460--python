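"""Otsu, ISODATA and GLCM/IDM threshold selection."""

import warnings
from collections import Counter

import numpy as np
import pytest

from vesselthresh import threshold
from vesselthresh.threshold import (
    Histogram,
    binarize,
    compute_glcm,
    idm_feature,
    idm_threshold,
    isodata_threshold,
    otsu_threshold,
    quantize,
    variance_decomposition,
)

# ------------------------------------------------------------- oracles


def otsu_brute_force(hist: Histogram) -> tuple[int, np.ndarray]:
    """Exhaustive scan of the between-class variance over all cuts."""
    p = hist.probabilities
    x = hist.bin_centers
    n = p.size
    sigma_b = np.zeros(n - 1)
    for t in range(n - 1):
        w1 = p[: t + 1].sum()
        w2 = 1.0 - w1
        if w1 <= 0 or w2 <= 0:
            continue
        mu1 = (p[: t + 1] * x[: t + 1]).sum() / w1
        mu2 = (p[t + 1:] * x[t + 1:]).sum() / w2
        sigma_b[t] = w1 * w2 * (mu1 - mu2) ** 2
    # first cut attaining the maximum (tolerance handles the exact
    # plateaus that empty bins create, where rounding noise differs)
    peak = sigma_b.max()
    first = int(np.argmax(sigma_b >= peak - 1e-12 * max(1.0, peak)))
    return first, sigma_b


def glcm_pair_enumeration(q: np.ndarray, d: int, phi: int, n_levels: int):
    """Independent GLCM oracle: enumerate every ordered pixel pair."""
    dr, dc = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}[phi]
    dr, dc = dr * d, dc * d
    H, W = q.shape
    counter: Counter = Counter()
    for r in range(H):
        for c in range(W):
            for sr, sc in ((dr, dc), (-dr, -dc)):
                r2, c2 = r + sr, c + sc
                if 0 <= r2 < H and 0 <= c2 < W:
                    counter[(q[r, c], q[r2, c2])] += 1
    C = np.zeros((n_levels, n_levels), dtype=np.int64)
    for (i, j), count in counter.items():
        C[i, j] = count
    return C


def random_mixture_histogram(rng: np.random.Generator, n_bins: int = 256) -> Histogram:
    """Histogram of a random 1-3 component Gaussian mixture on [0, 1]."""
    n_comp = rng.integers(1, 4)
    samples = []
    for _ in range(n_comp):
        mu = rng.uniform(0.1, 0.9)
        sd = rng.uniform(0.01, 0.15)
        samples.append(rng.normal(mu, sd, size=rng.integers(200, 2000)))
    values = np.clip(np.concatenate(samples), 0.0, 1.0)
    return Histogram.from_image(values.reshape(1, -1), n_bins=n_bins)


# ---------------------------------------------------------------- Otsu


class TestOtsu:
    def test_two_delta_masses_tie_breaks_low(self):
        counts = np.zeros(256)
        counts[50] = counts[200] = 100
        hist = Histogram(counts, np.arange(256.0))
        _, sigma_b = otsu_brute_force(hist)
        assert np.allclose(sigma_b[50:200], sigma_b[50])  # flat optimum
        assert otsu_threshold(hist) == 50.0

    def test_two_separated_gaussians(self, rng):
        """The cut lands between the two modes.  With tight components
        the between-class variance is flat across the empty gap, so the
        smallest-t tie-break settles at the gap's lower edge — the same
        cut an independent library implementation picks."""
        values = np.clip(np.concatenate([
            rng.normal(0.3, 0.02, 4000), rng.normal(0.7, 0.02, 4000)
        ]), 0, 1)
        hist = Histogram.from_image(values.reshape(1, -1))
        t = otsu_threshold(hist)
        assert 0.32 < t < 0.68  # separates the modes
        t_idx, _ = otsu_brute_force(hist)
        assert t == hist.bin_centers[t_idx]

        from skimage.filters import threshold_otsu

        assert abs(t - threshold_otsu(values, nbins=256)) < 1.5 / 256

    def test_uniform_histogram_cuts_at_midpoint(self):
        hist = Histogram(np.ones(256), np.arange(256.0))
        t = otsu_threshold(hist)
        t_idx, sigma_b = otsu_brute_force(hist)
        assert t == hist.bin_centers[t_idx]
        assert abs(t - 127.5) <= 0.5  # lower of the two central optima

    def test_matches_exhaustive_scan_on_random_mixtures(self, rng):
        for _ in range(25):
            hist = random_mixture_histogram(rng)
            t_idx, sigma_b = otsu_brute_force(hist)
            assert otsu_threshold(hist) == hist.bin_centers[t_idx]

    def test_variance_decomposition_identity(self, rng):
        for _ in range(10):
            hist = random_mixture_histogram(rng)
            total, sw, sb = variance_decomposition(hist)
            assert np.abs(total - (sw + sb)).max() < 1e-9

    def test_affine_rescaling_equivariance(self, rng):
        """Relabeling bin centers affinely moves the cut the same way."""
        hist = random_mixture_histogram(rng)
        t = otsu_threshold(hist)
        hist2 = Histogram(hist.counts, 2.0 * hist.bin_centers + 3.0)
        assert otsu_threshold(hist2) == pytest.approx(2.0 * t + 3.0)

    def test_degenerate_single_bin_rejected(self):
        counts = np.zeros(16)
        counts[3] = 10
        with pytest.raises(ValueError):
            otsu_threshold(Histogram(counts, np.arange(16.0)))


# ------------------------------------------------------------- ISODATA


class TestIsodata:
    def test_equal_delta_masses_converges_in_one_step(self):
        counts = np.zeros(256)
        centers = np.linspace(0, 1, 256)
        counts[np.argmin(np.abs(centers - 0.2))] = 50
        counts[np.argmin(np.abs(centers - 0.8))] = 50
        t = isodata_threshold(Histogram(counts, centers), t0=0.5)
        assert t == pytest.approx(0.5, abs=1e-3)

    @pytest.mark.parametrize("t0", [0.25, 0.4, 0.6, 0.75])
    def test_unequal_delta_masses_fixed_point_independent_of_t0(self, t0):
        """75%/25% masses at 0.2/0.8: partition means are always 0.2 and
        0.8 for any cut between them, so the fixed point is 0.5."""
        counts = np.zeros(256)
        centers = np.linspace(0, 1, 256)
        counts[np.argmin(np.abs(centers - 0.2))] = 75
        counts[np.argmin(np.abs(centers - 0.8))] = 25
        t = isodata_threshold(Histogram(counts, centers), t0=t0)
        assert t == pytest.approx(0.5, abs=1e-3)

    def test_returned_value_is_a_fixed_point(self, rng):
        for _ in range(20):
            hist = random_mixture_histogram(rng)
            t = isodata_threshold(hist)
            x, p = hist.bin_centers, hist.probabilities
            low = x <= t
            m1 = (p[low] * x[low]).sum() / p[low].sum()
            m2 = (p[~low] * x[~low]).sum() / p[~low].sum()
            tol = 0.5 * np.diff(x).min()
            assert abs(t - 0.5 * (m1 + m2)) < tol

    def test_within_one_bin_of_exhaustive_fixed_point(self, rng):
        """Every bin is tried as the cut; bins whose intermean update
        stays within tolerance are the fixed points."""
        hist = random_mixture_histogram(rng)
        x, p = hist.bin_centers, hist.probabilities
        bin_w = np.diff(x).min()
        fixed = []
        for t in x:
            low = x <= t
            if p[low].sum() == 0 or p[~low].sum() == 0:
                continue
            m1 = (p[low] * x[low]).sum() / p[low].sum()
            m2 = (p[~low] * x[~low]).sum() / p[~low].sum()
            if abs(0.5 * (m1 + m2) - t) <= 0.5 * bin_w + 1e-12:
                fixed.append(t)
        t_ret = isodata_threshold(hist)
        assert any(abs(t_ret - t) <= bin_w + 1e-12 for t in fixed)

    def test_affine_rescaling_equivariance(self, rng):
        hist = random_mixture_histogram(rng)
        t = isodata_threshold(hist)
        hist2 = Histogram(hist.counts, 2.0 * hist.bin_centers + 3.0)
        assert isodata_threshold(hist2) == pytest.approx(2.0 * t + 3.0, abs=1e-9)


# ------------------------------------------------------------ GLCM/IDM


class TestGLCM:
    def test_two_by_two_hand_enumeration(self):
        q = np.array([[0, 0], [1, 1]])
        C, R = compute_glcm(q, d=1, phi_deg=0, n_levels=2)
        np.testing.assert_array_equal(C, [[2, 0], [0, 2]])
        assert R == 4

    def test_constant_image_single_entry(self):
        q = np.full((8, 8), 3, dtype=int)
        for phi in threshold.ORIENTATIONS_DEG:
            C, R = compute_glcm(q, d=2, phi_deg=phi, n_levels=8)
            assert C[3, 3] == R and C.sum() == R

    def test_counts_sum_to_pair_count(self, rng):
        q = rng.integers(0, 16, (20, 20))
        for d in (1, 3):
            for phi in threshold.ORIENTATIONS_DEG:
                C, R = compute_glcm(q, d, phi, 16)
                assert C.sum() == R
                np.testing.assert_array_equal(C, C.T)
                np.testing.assert_array_equal(
                    C.sum(axis=0), C.sum(axis=1)
                )

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(3):
            q = rng.integers(0, 16, (16, 16))
            for d in (1, 2):
                for phi in threshold.ORIENTATIONS_DEG:
                    C, _ = compute_glcm(q, d, phi, 16)
                    np.testing.assert_array_equal(
                        C, glcm_pair_enumeration(q, d, phi, 16)
                    )

    def test_offset_beyond_extent_rejected(self):
        with pytest.raises(ValueError):
            compute_glcm(np.zeros((3, 3), int), d=3, phi_deg=0, n_levels=2)


class TestIDMFeature:
    def test_point_masses(self):
        p = np.zeros((8, 8))
        p[0, 0] = 1.0
        assert idm_feature(p) == 1.0
        p = np.zeros((8, 8))
        p[3, 3] = 1.0
        assert idm_feature(p, "plus") == pytest.approx(1.0 / 37.0)
        assert idm_feature(p, "minus") == 1.0

    def test_uniform_matrix_hand_sum(self):
        p = np.full((4, 4), 1.0 / 16.0)
        expected = sum(
            (1.0 / 16.0) / (1.0 + (i + j) ** 2)
            for i in range(4) for j in range(4)
        )
        assert idm_feature(p) == pytest.approx(expected, abs=1e-15)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError):
            idm_feature(np.ones((4, 4)))


class TestIDMThreshold:
    def test_constant_image_degenerates_to_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = idm_threshold(np.full((32, 32), 0.5))
        np.testing.assert_array_equal(res.r_phi, np.zeros(4))
        assert res.threshold == 0.0

    def test_threshold_is_max_plus_mean_of_ranges(self, rng):
        img = rng.random((48, 48))
        res = idm_threshold(img)
        assert res.threshold == pytest.approx(
            res.r_phi.max() + res.r_phi.mean(), abs=1e-15
        )
        np.testing.assert_allclose(
            res.r_phi, res.F.max(axis=0) - res.F.min(axis=0), atol=1e-15
        )

    def test_matches_straight_line_recomputation(self, default_phantom, rng):
        """Th reproduced end to end by the brute-force GLCM/IDM oracle
        on the quantized phantom image."""
        img = default_phantom.image[96:160, 96:160]  # small crop, real texture
        res = idm_threshold(img, n_levels=16)
        q = quantize(img, 16)
        F = np.zeros((4, 4))
        for a, d in enumerate((1, 2, 3, 4)):
            for b, phi in enumerate(threshold.ORIENTATIONS_DEG):
                C = glcm_pair_enumeration(q, d, phi, 16)
                p = C / C.sum()
                F[a, b] = sum(
                    p[i, j] / (1.0 + (i + j) ** 2)
                    for i in range(16) for j in range(16)
                )
        r = F.max(axis=0) - F.min(axis=0)
        assert res.threshold == pytest.approx(r.max() + r.mean(), abs=1e-12)

    def test_transposition_invariance(self, rng):
        """Transposing the image swaps the 0/90-degree columns of F
        (the diagonals are axis-fixed); the threshold is unchanged."""
        img = rng.random((40, 40))
        a = idm_threshold(img)
        b = idm_threshold(img.T)
        perm = [2, 1, 0, 3]  # 0<->90, 45 and 135 self-paired
        np.testing.assert_allclose(a.F, b.F[:, perm], atol=1e-12)
        assert a.threshold == pytest.approx(b.threshold, abs=1e-12)

    def test_range_axis_option(self, rng):
        img = rng.random((40, 40))
        col = idm_threshold(img, range_axis="column")
        row = idm_threshold(img, range_axis="row")
        np.testing.assert_allclose(
            row.r_phi, col.F.max(axis=1) - col.F.min(axis=1), atol=1e-15
        )


class TestBinarize:
    def test_polarity_contract(self):
        img = np.array([[0.2, 0.8], [0.8, 0.2]])
        np.testing.assert_array_equal(
            binarize(img, 0.5, "bright"), img > 0.5
        )
        np.testing.assert_array_equal(
            binarize(img, 0.5, "dark"), img < 0.5
        )
        assert not binarize(np.full((3, 3), 0.1), 0.5, "bright").any()
        assert binarize(np.full((3, 3), 0.6), 0.5, "bright").all()
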