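"""Evaluation statistics: Gaussian FWHM fitting, line profiles, ΔF/F with
neuropil subtraction, SNR, and rank-based tests against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from cmatsim import (
    TraceSet,
    compare_groups,
    dff,
    fit_fwhm,
    image_extent_um,
    line_profile,
    snr,
)
from cmatsim.metrics import GAUSS_FWHM_FACTOR
from cmatsim.phantoms import Volume


def synthetic_gaussian_volume(sigma_lat, sigma_axi, lat_pitch=0.0542,
                              axi_pitch=0.27, half_lat=None, half_axi=None):
    half_lat = half_lat or min(6 * sigma_lat, 3.5 * sigma_lat + 1.0)
    half_axi = half_axi or min(6 * sigma_axi, 3.5 * sigma_axi + 1.0)
    nl = int(2 * half_lat / lat_pitch) | 1
    na = int(2 * half_axi / axi_pitch) | 1
    x = (np.arange(nl) - nl // 2) * lat_pitch
    z = (np.arange(na) - na // 2) * axi_pitch
    gx = np.exp(-(x**2) / (2 * sigma_lat**2)).astype(np.float32)
    gz = np.exp(-(z**2) / (2 * sigma_axi**2)).astype(np.float32)
    data = gz[:, None, None] * gx[None, :, None] * gx[None, None, :]
    center = np.array([(nl // 2 + 0.5) * lat_pitch,
                       (nl // 2 + 0.5) * lat_pitch,
                       (na // 2 + 0.5) * axi_pitch])
    return Volume(data, lat_pitch, axi_pitch), center


class TestFitFwhm:
    def test_closed_form_on_sampled_gaussian(self):
        vol, center = synthetic_gaussian_volume(1.0, 2.0)
        meas = fit_fwhm(vol, [center], window_um=4.0, axial_window_um=10.0)
        assert not meas.excluded[0]
        assert meas.lateral_mean == pytest.approx(GAUSS_FWHM_FACTOR, rel=0.005)
        assert meas.axial_mean == pytest.approx(2 * GAUSS_FWHM_FACTOR, rel=0.005)

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.0, 5.0])
    def test_bias_below_one_percent_at_reference_sampling(self, sigma):
        vol, center = synthetic_gaussian_volume(sigma, sigma)
        meas = fit_fwhm(vol, [center], window_um=3 * sigma,
                        axial_window_um=3 * sigma + 1)
        assert meas.lateral_mean == pytest.approx(
            GAUSS_FWHM_FACTOR * sigma, rel=0.01
        )
        assert meas.axial_mean == pytest.approx(
            GAUSS_FWHM_FACTOR * sigma, rel=0.01
        )

    def test_coordinate_scaling_scales_fwhm(self):
        vol, center = synthetic_gaussian_volume(1.0, 1.0)
        scaled = Volume(vol.data, vol.lateral_pitch * 2, vol.axial_pitch * 2)
        a = fit_fwhm(vol, [center], window_um=4.0, axial_window_um=6.0)
        b = fit_fwhm(scaled, [center * 2], window_um=8.0, axial_window_um=12.0)
        assert b.lateral_mean == pytest.approx(2 * a.lateral_mean, rel=1e-6)

    def test_degenerate_bead_flagged_and_excluded(self):
        data = np.zeros((5, 31, 31))
        data[2, 15, 15] = 1.0  # sub-pixel impulse: FWHM < 2 px
        vol = Volume(data, 0.1, 0.27)
        meas = fit_fwhm(vol, [(1.55, 1.55, 0.675)])
        assert meas.excluded[0]
        assert math.isnan(meas.lateral_mean)

    def test_summary_over_several_beads(self):
        vol, center = synthetic_gaussian_volume(1.0, 1.5)
        meas = fit_fwhm(vol, [center, center], window_um=4.0, axial_window_um=8.0)
        assert meas.lateral_sd == pytest.approx(0.0, abs=1e-9)
        assert len(meas.lateral_fwhm) == 2


class TestLineProfile:
    def test_constant_image(self):
        img = np.full((20, 30), 3.3)
        prof = line_profile(img, (2, 2), (15, 25))
        assert np.allclose(prof, 3.3)

    def test_axis_aligned_line_reproduces_row(self):
        img = np.arange(100, dtype=float).reshape(10, 10)
        prof = line_profile(img, (4, 0), (4, 9))
        assert np.allclose(prof, img[4, :])

    def test_disk_chord_width(self):
        n = 101
        c = np.arange(n) - n // 2
        X, Y = np.meshgrid(c, c)
        disk = (np.hypot(X, Y) <= 20).astype(float)
        prof = line_profile(disk, (10, 10), (90, 90))
        # diagonal through the center: plateau length = diameter
        plateau = (prof > 0.5).sum()
        assert plateau == pytest.approx(40, abs=1.5)

    def test_normalization_and_degenerate_endpoints(self):
        img = np.arange(25, dtype=float).reshape(5, 5)
        prof = line_profile(img, (0, 0), (4, 4), normalize=True)
        assert prof.min() == 0.0 and prof.max() == 1.0
        with pytest.raises(ValueError, match="degenerate"):
            line_profile(img, (2, 2), (2, 2))


class TestDff:
    def test_constant_traces_give_zero(self):
        ts = TraceSet(cell=np.full(50, 2.0), neuropil=np.full(50, 1.0))
        out = dff(ts)
        assert np.allclose(out, 0.0)

    def test_percentile_baseline_linear_interpolation(self):
        # F = [1, 1, 1, 3]: 25th percentile at rank 0.25·3 = 0.75 → 1.0
        ts = TraceSet(cell=np.array([1.0, 1, 1, 3]), neuropil=np.zeros(4))
        out = dff(ts)
        assert np.allclose(out, [0, 0, 0, 2])

    def test_gain_invariance(self):
        rng = np.random.default_rng(8)
        cell = 100 + rng.gamma(2.0, 5.0, 200)
        neu = 50 + rng.gamma(2.0, 2.0, 200)
        a = dff(TraceSet(cell=cell, neuropil=neu))
        b = dff(TraceSet(cell=7.3 * cell, neuropil=7.3 * neu))
        assert np.allclose(a, b)

    def test_degenerate_baseline_raises(self):
        ts = TraceSet(cell=np.ones(20), neuropil=np.full(20, 2.0))
        with pytest.raises(ValueError, match="baseline"):
            dff(ts)


def snr_oracle(x):
    """Independent direct-formula SNR implementation."""
    x = np.asarray(x, dtype=float)
    q90 = np.percentile(x, 90.0)
    top = [v for v in x if v >= q90]
    rest = [v for v in x if v < q90]
    m = sum(top) / len(top)
    mean_rest = sum(rest) / len(rest)
    var = sum((v - mean_rest) ** 2 for v in rest) / (len(rest) - 1)
    return m / math.sqrt(var)


class TestSnr:
    def test_constant_series_is_degenerate(self):
        with pytest.raises(ValueError):
            snr(np.ones(100))

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 0.05, 500)
        x[:50] += 0.5
        assert snr(3.7 * x) == pytest.approx(snr(x), rel=1e-12)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.0, 0.05, 1000)
        x[900:] = 0.5 + rng.normal(0.0, 0.02, 100)  # transient plateau
        assert snr(x) == pytest.approx(snr_oracle(x), rel=1e-12)

    def test_interval_reading_uses_best_window(self):
        x = np.zeros(100)
        x[40:50] = 1.0
        x += np.linspace(0, 1e-3, 100)  # break exact ties
        v = snr(x, interval_based=True)
        w = snr(x)
        assert v > 0 and w > 0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            snr(np.arange(5))


def mannwhitney_p_oracle(a, b):
    """Exhaustive permutation two-sided p for the rank-sum statistic."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n1 = len(a)
    mu = n1 * (len(pooled) - n1) / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
    return hits / total


class TestCompareGroups:
    def test_identical_paired_samples_give_p_one(self):
        a = np.array([1.0, 2, 3, 4])
        with pytest.warns(UserWarning):
            stat, p = compare_groups(a, a, paired=True)
        assert p == 1.0

    def test_unpaired_small_sample_matches_enumeration(self):
        a, b = [1.0, 2, 3], [4.0, 5, 6]
        stat, p = compare_groups(a, b)
        assert p == pytest.approx(mannwhitney_p_oracle(np.array(a), np.array(b)))
        assert p == pytest.approx(2 / 20)  # extreme split of C(6,3)=20

    def test_enumeration_handles_ties(self):
        a, b = [1.0, 2, 2, 3], [2.0, 4, 4]
        stat, p = compare_groups(a, b)
        assert p == pytest.approx(mannwhitney_p_oracle(np.array(a), np.array(b)))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 6)
        s1, p1 = compare_groups(a, b)
        s2, p2 = compare_groups(np.exp(a), np.exp(b))
        assert s1 == s2 and p1 == p2

    def test_paired_exact_enumeration(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 1, 5, 7, 9])
        stat, p = compare_groups(a, b, paired=True)
        # oracle: enumerate all 2^n sign assignments of |d| ranks
        from scipy.stats import rankdata

        d = a - b
        ranks = rankdata(np.abs(d))
        mu = len(d) * (len(d) + 1) / 4
        w_obs = ranks[d > 0].sum()
        hits = 0
        for signs in itertools.product([False, True], repeat=len(d)):
            w = ranks[np.array(signs)].sum()
            hits += abs(w - mu) >= abs(w_obs - mu) - 1e-12
        assert p == pytest.approx(hits / 2 ** len(d))

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.8, 1, 30)
        _, p = compare_groups(a, b)
        from scipy.stats import mannwhitneyu

        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue)
        assert p < 0.05

    def test_paired_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="equal length"):
            compare_groups([1, 2], [1, 2, 3], paired=True)


class TestImageGeometry:
    def test_reference_bead_stack_extent(self):
        # 1200 px at 0.0542 µm/pixel span 65 µm (rounded)
        assert round(image_extent_um(1200, 0.0542)) == 65
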