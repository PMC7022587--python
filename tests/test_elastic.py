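"""Elastic-scan analysis: windowing, MSD fits, binning, force constants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipodyn.elastic import (
    FORCE_CONSTANT_COEFF,
    ElasticScan,
    bin_ramp,
    fit_force_constants,
    fit_msd,
    fit_msd_series,
    gaussian_validity,
    normalize_scan,
    select_q_window,
)
from lipodyn.instruments import IN13_LIKE, IN16_LIKE
from lipodyn.simulate import MsdModel, make_elastic_dataset


def scan_from_msd(msd, q, temperature=300.0, i0=1.0, sigma=0.0):
    q = np.asarray(q, dtype=float)
    return ElasticScan(temperature, q, i0 * np.exp(-msd * q**2 / 6.0), np.full(q.size, sigma))


class TestSelectQWindow:
    def test_thermal_backscattering_window(self):
        scan = scan_from_msd(0.5, [0.3, 0.6, 1.0, 2.0, 2.3])
        out = select_q_window(scan, IN13_LIKE)
        assert list(out.q) == [0.6, 1.0, 2.0]

    def test_window_containing_all_points_is_identity(self):
        scan = scan_from_msd(0.5, [0.6, 1.0, 2.0])
        out = select_q_window(scan, IN13_LIKE)
        assert np.array_equal(out.q, scan.q)
        assert np.array_equal(out.intensity, scan.intensity)

    def test_window_excluding_all_points_errors(self):
        scan = scan_from_msd(0.5, [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="window too narrow"):
            select_q_window(scan, IN13_LIKE)

    def test_windowing_is_idempotent_for_fitting(self):
        scan = scan_from_msd(1.3, [0.3, 0.6, 0.9, 1.4, 1.9, 2.4])
        once = select_q_window(scan, IN13_LIKE)
        assert fit_msd(once) == fit_msd(select_q_window(once, IN13_LIKE))


class TestFitMsd:
    def test_recovers_ambient_msd_on_thermal_grid(self):
        """Noise-free generation at the 305 K value (2.1 A^2) refits exactly."""
        scan = scan_from_msd(2.1, IN13_LIKE.q_grid, temperature=305.0)
        msd, _ = fit_msd(scan)
        assert msd == pytest.approx(2.1, abs=1e-9)

    def test_flat_scan_gives_zero(self):
        scan = scan_from_msd(0.0, IN13_LIKE.q_grid)
        assert fit_msd(scan)[0] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_fit_matches_regression_oracle_within_three_sigma(self):
        rng = np.random.default_rng(42)
        q = np.array(IN13_LIKE.q_grid)
        inten = np.exp(-1.5 * q**2 / 6.0)
        sigma = 0.01 * np.sqrt(inten)
        noisy = inten + rng.normal(0, 1, q.size) * sigma
        scan = ElasticScan(300.0, q, noisy, sigma)
        msd, msd_sig = fit_msd(scan)
        # independent closed-form weighted regression on the same points
        x, y = q**2, np.log(noisy)
        w = (noisy / sigma) ** 2
        W, X, Y = w.sum(), (w * x).sum(), (w * y).sum()
        XX, XY = (w * x * x).sum(), (w * x * y).sum()
        slope = (W * XY - X * Y) / (W * XX - X * X)
        assert msd == pytest.approx(-6.0 * slope, rel=1e-9)
        assert abs(msd - 1.5) < 3 * msd_sig

    def test_invariant_under_intensity_scaling(self):
        scan = scan_from_msd(0.8, IN13_LIKE.q_grid)
        scaled = ElasticScan(scan.temperature, scan.q, 37.5 * scan.intensity, scan.sigma)
        assert fit_msd(scan)[0] == pytest.approx(fit_msd(scaled)[0], rel=1e-12)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_msd(ElasticScan(300.0, np.array([0.6, 1.0, 1.4]), np.array([1.0, -0.1, 0.5]), np.zeros(3)))


class TestFitMsdProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        msd=st.floats(0.0, 3.0),
        i0=st.floats(0.1, 100.0),
    )
    def test_noise_free_round_trip_for_any_msd_and_i0(self, msd, i0):
        """fit_msd inverts the Gaussian model exactly, independent of I0."""
        scan = scan_from_msd(msd, IN13_LIKE.q_grid, i0=i0)
        fitted, _ = fit_msd(scan)
        assert fitted == pytest.approx(msd, abs=1e-8)


class TestGaussianValidity:
    @pytest.mark.parametrize(
        "msd,q,expected",
        [(0.4, 2.0, True), (2.1, 2.06, False), (0.0, 2.0, True)],
    )
    def test_pointwise_threshold(self, msd, q, expected):
        scan = scan_from_msd(msd, [q])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask, frac = gaussian_validity(msd, scan)
        assert bool(mask[0]) is expected
        assert frac == (1.0 if expected else 0.0)


class TestBinRamp:
    def test_full_ramp_occupies_58_bins(self):
        # brute-force count of occupied 5 K bins for 0.3 K sampling over 20-310 K
        temps = np.arange(20.0, 310.0, 0.3)
        expected = len({int((t - 20.0) // 5.0) for t in temps})
        assert expected == 58
        scans = [scan_from_msd(0.1, [0.6, 1.0], temperature=t) for t in temps]
        assert len(bin_ramp(scans, 5.0)) == 58

    def test_single_scan_passes_through(self):
        scan = scan_from_msd(0.7, [0.6, 1.0, 1.5], temperature=100.0)
        (out,) = bin_ramp([scan], 5.0)
        assert np.array_equal(out.intensity, scan.intensity)
        assert out.temperature == pytest.approx(102.5)  # bin center

    def test_intensities_averaged_within_bin(self):
        q = np.array([1.0])
        a = ElasticScan(100.0, q, np.array([2.0]), np.array([0.0]))
        b = ElasticScan(101.0, q, np.array([4.0]), np.array([0.0]))
        (out,) = bin_ramp([a, b], 5.0)
        assert out.intensity[0] == pytest.approx(3.0)


class TestNormalizeScan:
    def test_identity_references(self):
        scan = scan_from_msd(0.5, [0.6, 1.0, 1.5])
        q = scan.q
        van = ElasticScan(300.0, q, np.ones_like(q), np.zeros_like(q))
        out = normalize_scan(scan, vanadium=van, transmission=1.0)
        assert np.allclose(out.intensity, scan.intensity)

    def test_arithmetic(self):
        q = np.array([1.0])
        scan = ElasticScan(300.0, q, np.array([10.0]), np.zeros(1))
        empty = ElasticScan(300.0, q, np.array([2.0]), np.zeros(1))
        van = ElasticScan(300.0, q, np.array([4.0]), np.zeros(1))
        out = normalize_scan(scan, empty, van, 1.0)
        assert out.intensity[0] == pytest.approx(2.0)

    def test_mismatched_grid_rejected(self):
        scan = scan_from_msd(0.5, [0.6, 1.0, 1.5])
        van = ElasticScan(300.0, np.array([0.7, 1.0, 1.5]), np.ones(3), np.zeros(3))
        with pytest.raises(ValueError, match="Q grid"):
            normalize_scan(scan, vanadium=van)

    def test_zero_vanadium_rejected(self):
        scan = scan_from_msd(0.5, [0.6, 1.0, 1.5])
        van = ElasticScan(300.0, scan.q, np.array([1.0, 0.0, 1.0]), np.zeros(3))
        with pytest.raises(ValueError, match="vanadium"):
            normalize_scan(scan, vanadium=van)


class TestForceConstants:
    def test_piecewise_series_returns_generating_constants(self):
        """Slopes 0.00276/k with k = {1.00, 0.25, 0.15} N/m round trip."""
        model = MsdModel((200.0, 250.0), (1.00, 0.25, 0.15))
        temps = np.array(IN13_LIKE.temperatures)
        from lipodyn.elastic import MsdSeries

        series = MsdSeries(temps, model.msd(temps), np.zeros_like(temps), np.ones_like(temps))
        segs = fit_force_constants(series, (200.0, 250.0))
        assert segs.force_constants == pytest.approx([1.00, 0.25, 0.15], rel=1e-9)

    def test_inverse_relation_slope_times_constant(self):
        t = np.linspace(20, 300, 40)
        s = 0.004
        from lipodyn.elastic import MsdSeries

        series = MsdSeries(t, 0.05 + s * (t - 20), np.zeros_like(t), np.ones_like(t))
        segs = fit_force_constants(series, (150.0,))
        for seg in segs.segments:
            assert seg.force_constant * seg.slope == pytest.approx(FORCE_CONSTANT_COEFF)

    def test_noisy_segments_within_two_stderr_of_ols_oracle(self):
        rng = np.random.default_rng(7)
        model = MsdModel((200.0, 250.0), (1.0, 0.25, 0.15))
        t = np.array(IN13_LIKE.temperatures)
        noisy = model.msd(t) + rng.normal(0, 0.01, t.size)
        from lipodyn.elastic import MsdSeries

        series = MsdSeries(t, noisy, np.zeros_like(t), np.ones_like(t))
        segs = fit_force_constants(series, (200.0, 250.0))
        for seg, k_true in zip(segs.segments, (1.0, 0.25, 0.15)):
            sel = (t >= seg.t_low) & (t <= seg.t_high)
            slope_ols = np.polyfit(t[sel], noisy[sel], 1)[0]  # independent OLS oracle
            assert seg.slope == pytest.approx(slope_ols, rel=1e-9)
            assert abs(seg.force_constant - k_true) < 2 * seg.stderr + 1e-12

    def test_force_constants_inversely_ordered_with_slopes(self):
        segs = fit_force_constants(
            fit_msd_series(
                make_elastic_dataset(IN13_LIKE, MsdModel((200.0, 250.0), (1.13, 0.49, 0.067)))[0],
                IN13_LIKE,
            ),
            (200.0, 250.0),
        )
        slopes = [s.slope for s in segs.segments]
        ks = segs.force_constants
        assert np.argsort(slopes).tolist() == np.argsort(ks)[::-1].tolist()

    def test_rigid_segment_flagged(self):
        from lipodyn.elastic import MsdSeries

        t = np.linspace(20, 300, 30)
        msd = np.where(t < 150, 0.5, 0.5 - 0.001 * (t - 150))
        series = MsdSeries(t, msd, np.zeros_like(t), np.ones_like(t))
        segs = fit_force_constants(series, (150.0,))
        assert segs.segments[1].force_constant is None
        assert segs.segments[1].flag == "rigid/undefined"


class TestRoundTrip:
    @pytest.mark.parametrize(
        "constants",
        [(1.00, 0.25, 0.15), (1.13, 0.49, 0.067), (0.88, 0.17, 0.12)],
        ids=["spherical-thermal", "discoidal-thermal", "spherical-cold"],
    )
    def test_noise_free_generation_refits_exactly(self, constants):
        model = MsdModel((200.0, 250.0), constants)
        scans, temps, truth = make_elastic_dataset(IN13_LIKE, model)
        series = fit_msd_series(scans, IN13_LIKE)
        assert np.max(np.abs(series.msd - truth) / np.maximum(truth, 1e-12)) < 1e-9
        segs = fit_force_constants(series, (200.0, 250.0))
        assert segs.force_constants == pytest.approx(list(constants), rel=1e-6)
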