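"""Gradient pipeline: background, staging, binning, splines, fits, trends."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import CubicSpline

from shhadapt import (
    CohortSpec,
    GradientProfile,
    fit_exponential,
    generate_cohort,
    locate_source_boundary,
    subtract_background,
    trend_vs_size,
)
from shhadapt.gradient_quant import (
    LinearCalibration,
    band_timecourse,
    bin_profiles,
    build_ramps_from_profiles,
    profiles_from_frame,
    profiles_to_frame,
    smooth_spline,
    stage_by_dv_length,
    stereotype_timecourse,
)


def make_profile(intensity, background=0.0, dv_length=None, **kw):
    intensity = np.asarray(intensity, float)
    x = np.arange(len(intensity), dtype=float)
    return GradientProfile(
        positions=x,
        intensity=intensity,
        background=background,
        dv_length=dv_length if dv_length is not None else float(len(intensity)),
        **kw,
    )


class TestBackgroundAndStaging:
    def test_zero_background_is_identity(self):
        p = make_profile([5.0, 4.0, 3.0])
        out = subtract_background(p)
        assert np.array_equal(out.intensity, p.intensity)

    def test_profile_equal_to_background_goes_to_zero(self):
        p = make_profile([7.0, 7.0, 7.0], background=7.0)
        assert np.all(subtract_background(p).intensity == 0.0)

    def test_known_background_recovered_within_noise(self, rng):
        spec = CohortSpec()
        from shhadapt.synthetic_data import generate_profile

        prof, truth = generate_profile(spec, rng, dv_length=200.0)
        clean = subtract_background(prof)
        # dorsal-most 20% carries essentially no signal: mean residual there
        # should sit near zero within the additive noise scale
        tail = clean.intensity[int(0.8 * len(clean.intensity)) :]
        add_sd = spec.additive_noise_frac * spec.max_expected_amplitude
        assert abs(tail.mean()) < 3 * add_sd

    def test_identity_calibration(self):
        cal = LinearCalibration(slope=1.0, intercept=0.0)
        stage, extrapolated = stage_by_dv_length(123.0, cal)
        assert stage == 123.0 and not extrapolated

    def test_calibration_recovery_and_extrapolation_flag(self, rng):
        dv = rng.uniform(80, 400, 50)
        stages = dv / 10.0 + rng.normal(0, 1.0, 50)
        cal = LinearCalibration.fit(dv, stages)
        assert cal.slope == pytest.approx(0.1, rel=0.15)
        _, flag = stage_by_dv_length(2 * dv.max(), cal)
        assert flag

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            LinearCalibration(slope=0.0, intercept=3.0)


class TestBinning:
    def test_single_profile_mean_with_undefined_ci(self):
        p = make_profile(np.full(100, 5.0), dv_length=100.0)
        out = bin_profiles([p])
        assert np.allclose(out["mean"], 5.0)
        assert out["ci_lo"].isna().all()
        assert (out["n"] == 1).all()

    def test_two_profiles_average(self):
        a = make_profile(np.full(100, 2.0), dv_length=100.0)
        b = make_profile(np.full(100, 4.0), dv_length=100.0)
        out = bin_profiles([a, b])
        assert np.allclose(out["mean"], 3.0)
        assert (out["n"] == 2).all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            bin_profiles([])

    def test_ci_covers_generating_mean(self, rng):
        """Student-t 95% intervals on bin means achieve near-nominal
        coverage across replicate cohorts of flat noisy profiles."""
        mu, sd, n_prof = 10.0, 2.0, 8
        hits = total = 0
        for _ in range(150):
            profs = [
                make_profile(mu + sd * rng.standard_normal(50), dv_length=50.0)
                for _ in range(n_prof)
            ]
            out = bin_profiles(profs)
            ok = (out["ci_lo"] <= mu) & (mu <= out["ci_hi"])
            hits += int(ok.sum())
            total += len(out)
        assert hits / total >= 0.93

    def test_relative_position_binning(self):
        # intensity equal to relative position => bin means near bin centres
        x = np.arange(0.0, 200.0)
        p = GradientProfile(x, x / 200.0, 0.0, 200.0)
        out = bin_profiles([p])
        assert np.allclose(out["mean"], out["position_frac"], atol=0.01)


class TestSmoothSpline:
    def test_linear_knots_reproduced(self):
        x = np.arange(0.0, 10.0)
        grid, vals = smooth_spline(x, 3.0 * x + 1.0)
        assert np.allclose(vals, 3.0 * grid + 1.0, atol=1e-9)

    def test_cubic_polynomial_reproduced_exactly(self):
        x = np.arange(0.0, 8.0)
        f = lambda t: 0.5 * t**3 - 2 * t**2 + t - 4
        grid, vals = smooth_spline(x, f(x))
        assert np.allclose(vals, f(grid), atol=1e-8)

    def test_passes_through_knots_and_matches_reference_spline(self, rng):
        x = np.linspace(0, 40, 9)
        y = rng.normal(size=9)
        grid, vals = smooth_spline(x, y, step=0.1)
        ref = CubicSpline(x, y)(grid)
        knot_idx = np.searchsorted(grid, x)
        for xi, yi in zip(x, y):
            assert vals[np.argmin(np.abs(grid - xi))] == pytest.approx(yi, abs=1e-9)
        assert np.allclose(vals, ref)

    def test_few_knots_fall_back_to_linear(self):
        with pytest.warns(RuntimeWarning, match="knots"):
            grid, vals = smooth_spline([0.0, 1.0, 2.0], [0.0, 2.0, 4.0])
        assert np.allclose(vals, 2.0 * grid)


class TestBoundary:
    def test_peak_position_found(self):
        y = np.exp(-((np.arange(100.0) - 8.0) ** 2) / 20.0)
        assert locate_source_boundary(np.arange(100.0), y) == 8.0

    def test_monotone_decreasing_boundary_at_origin(self):
        assert locate_source_boundary(np.arange(50.0), np.exp(-np.arange(50.0))) == 0.0

    def test_plateau_tie_broken_ventrally(self):
        y = np.zeros(30)
        y[10:20] = 5.0
        assert locate_source_boundary(np.arange(30.0), y) == 10.0

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            locate_source_boundary(np.arange(10.0), np.zeros(10))


class TestFitExponential:
    def _noiseless(self, c0=100.0, lam=20.0, peak=8.0, dv=200.0):
        x = np.arange(0.0, dv + 0.5)
        y = np.where(
            x >= peak,
            c0 * np.exp(-(x - peak) / lam),
            c0 * np.exp(-((x - peak) ** 2) / 32.0),
        )
        return GradientProfile(x, y, 0.0, dv)

    def test_noiseless_recovery_is_exact(self):
        fit = fit_exponential(self._noiseless())
        assert fit.C0 == pytest.approx(100.0, rel=1e-6)
        assert fit.lam == pytest.approx(20.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.boundary_position == pytest.approx(8.0, abs=1.0)

    def test_scale_equivariance(self):
        p = self._noiseless()
        base = fit_exponential(p)
        scaled = fit_exponential(
            GradientProfile(p.positions, 37.0 * p.intensity, 0.0, p.dv_length)
        )
        assert scaled.C0 == pytest.approx(37.0 * base.C0, rel=1e-9)
        assert scaled.lam == pytest.approx(base.lam, rel=1e-9)

    def test_loglinear_init_equals_full_fit_without_noise(self):
        p = self._noiseless()
        x = p.positions[(p.positions >= 8.0) & (p.positions <= 100.0)] - 8.0
        y = 100.0 * np.exp(-x / 20.0)
        slope, intercept = np.polyfit(x, np.log(y), 1)
        fit = fit_exponential(p, boundary=8.0)
        assert -1.0 / slope == pytest.approx(fit.lam, rel=1e-9)
        assert np.exp(intercept) == pytest.approx(fit.C0, rel=1e-9)

    def test_too_few_points_rejected(self):
        p = make_profile([0.0, 1.0, 0.5, 0.2, 0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="positive points"):
            fit_exponential(p, boundary=6.0)

    def test_cohort_recovery_median_error_below_ten_percent(self):
        errs = []
        for seed in range(20):
            profiles, truth = generate_cohort(CohortSpec(n_embryos=30), seed)
            for prof, (_, row) in zip(profiles, truth.iterrows()):
                fit = fit_exponential(subtract_background(prof))
                errs.append(abs(fit.lam - row["lambda_um"]) / row["lambda_um"])
        assert np.median(errs) < 0.10


class TestTrendVsSize:
    def test_exact_linear_amplitude(self):
        from shhadapt.gradient_quant import ExponentialFit

        dv = np.array([100.0, 200.0, 300.0, 400.0])
        fits = [
            ExponentialFit(C0=2.0 * d, lam=20.0, r_squared=1.0,
                           boundary_position=8.0, n_points=50)
            for d in dv
        ]
        out = trend_vs_size(fits, dv)
        assert out["C0"].r_squared == pytest.approx(1.0)
        assert out["C0"].slope == pytest.approx(2.0)
        assert out["lambda"].slope == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_points_identical_fit(self):
        from shhadapt.gradient_quant import ExponentialFit

        dv = [100.0, 200.0, 300.0]
        fits = [
            ExponentialFit(C0=d + 5, lam=20.0, r_squared=1.0,
                           boundary_position=8.0, n_points=50)
            for d in dv
        ]
        a = trend_vs_size(fits, dv)
        b = trend_vs_size(fits + fits, dv + dv)
        assert a["C0"].slope == pytest.approx(b["C0"].slope)
        assert a["C0"].intercept == pytest.approx(b["C0"].intercept)

    def test_constant_regressor_rejected(self):
        from shhadapt.gradient_quant import ExponentialFit

        fits = [
            ExponentialFit(C0=1.0, lam=20.0, r_squared=1.0,
                           boundary_position=8.0, n_points=50)
            for _ in range(3)
        ]
        with pytest.raises(ValueError, match="constant"):
            trend_vs_size(fits, [100.0, 100.0, 100.0])


class TestStereotyping:
    def test_exact_linear_band_series_recovered(self):
        t = np.array([10.0, 20.0, 30.0, 40.0])
        rows = []
        for lo, hi, slope, icept in ((0.0, 0.1, 3.0, -6.0), (0.1, 0.2, 1.0, 2.0)):
            for ti in t:
                rows.append(
                    {"band_lo": lo, "band_hi": hi, "time_h": ti,
                     "mean": slope * ti + icept}
                )
        f1, f2 = stereotype_timecourse(pd.DataFrame(rows))
        assert f1.slope == pytest.approx(3.0)
        assert f1.intercept == pytest.approx(-6.0)
        assert f1.zero_crossing == pytest.approx(2.0)
        assert f2.slope == pytest.approx(1.0)

    def test_nonpositive_slope_rejected(self):
        rows = [
            {"band_lo": 0.0, "band_hi": 0.1, "time_h": t, "mean": 10.0 - t}
            for t in (1.0, 2.0, 3.0)
        ]
        with pytest.raises(ValueError, match="not increasing"):
            stereotype_timecourse(pd.DataFrame(rows), bands=((0.0, 0.1),))

    def test_synthetic_cohort_ventral_band_rises_faster(self):
        profiles, _ = generate_cohort(CohortSpec(), 7)
        _, _, stereo = build_ramps_from_profiles(profiles)
        assert stereo[0].slope > stereo[1].slope > 0


class TestProfileIO:
    def test_frame_roundtrip(self, rng):
        profiles, _ = generate_cohort(CohortSpec(n_embryos=4), 0)
        df = profiles_to_frame(profiles)
        back = profiles_from_frame(df)
        assert len(back) == len(profiles)
        orig = {p.embryo_id: p for p in profiles}
        for p in back:
            q = orig[p.embryo_id]
            assert np.allclose(p.intensity, q.intensity)
            assert p.dv_length == q.dv_length

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            profiles_from_frame(pd.DataFrame({"position_um": [1.0]}))
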