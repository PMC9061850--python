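import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from amykin.kinetics import (
    KineticsConfig,
    NoGrowthError,
    ThTCurve,
    align_replicates,
    build_dose_series,
    compare_normalization,
    derivative,
    extract_parameters,
    segment_growth,
    smooth,
)
from amykin.synthetic import AssayDesign, default_aggregation_model, generate_tht_assay

from conftest import logistic


def make_curve(t, y, **meta):
    return ThTCurve(t=np.asarray(t, float), y=np.asarray(y, float), **meta)


class TestSmooth:
    def test_constant_series_unchanged(self):
        t = np.linspace(0, 10, 100)
        c = make_curve(t, np.full(100, 7.5))
        assert np.allclose(smooth(c).y, 7.5)

    def test_linear_series_unchanged_everywhere(self):
        # symmetric windows (full or shrunk) average a line to itself
        t = np.linspace(0, 10, 100)
        c = make_curve(t, 3.0 * t + 1.0)
        assert np.allclose(smooth(c).y, c.y)

    def test_impulse_matches_brute_force_window_mean(self):
        t = np.arange(100.0)
        y = np.zeros(100)
        y[50] = 1.0
        got = smooth(make_curve(t, y), window=11).y
        # brute-force oracle: mean over the centered (possibly shrunk) window
        expected = np.array(
            [
                np.mean(y[i - min(5, i, 99 - i): i + min(5, i, 99 - i) + 1])
                for i in range(100)
            ]
        )
        assert np.allclose(got, expected)
        assert got[50] == pytest.approx(1 / 11)

    def test_window_longer_than_series_rejected(self):
        c = make_curve(np.arange(60.0), np.arange(60.0))
        with pytest.raises(ValueError, match="window"):
            smooth(c, window=61)

    def test_even_window_rejected(self):
        c = make_curve(np.arange(60.0), np.arange(60.0))
        with pytest.raises(ValueError, match="odd"):
            smooth(c, window=10)


class TestDerivative:
    def test_exact_on_linear(self):
        t = np.linspace(0, 5, 80)
        assert np.allclose(derivative(t, 2.0 * t), 2.0)

    def test_exact_on_quadratic_uniform_grid(self):
        # (t+h)^2 - (t-h)^2 = 4th -> quotient = 2t exactly
        t = np.linspace(0, 5, 101)
        d = derivative(t, t**2)
        assert np.allclose(d[1:-1], 2.0 * t[1:-1], atol=1e-12)

    def test_sine_accuracy(self):
        t = np.arange(0, 6.28, 0.01)
        d = derivative(t, np.sin(t))
        assert np.max(np.abs(d[2:-2] - np.cos(t[2:-2]))) < 1e-3

    def test_non_increasing_time_rejected(self):
        t = np.array([0.0, 1.0, 1.0, 2.0] + list(np.arange(3, 70.0)))
        with pytest.raises(ValueError, match="increasing"):
            derivative(t, t)

    def test_second_derivative_of_quadratic_is_constant(self):
        t = np.linspace(0, 5, 101)
        # index 3..n-4: the stencil then only touches first-derivative
        # values that are themselves symmetric (exact on a quadratic)
        d2 = derivative(t, derivative(t, t**2))
        assert np.allclose(d2[3:-3], 2.0, atol=1e-10)


class TestSegmentGrowth:
    def test_linear_ramp_starts_immediately(self):
        t = np.linspace(0, 10, 200)
        seg = segment_growth(t, np.full(200, 3.0))
        assert seg.start_index == 0
        assert seg.lag_time == t[0]

    def test_logistic_crossings_match_closed_form(self):
        # d1 of A/(1+e^{-k(t-t0)}) is (Ak/4) sech^2(k(t-t0)/2); the 5%
        # crossings sit at t0 +/- (2/k) arccosh(sqrt(20))
        A, k, t0 = 1000.0, 2.0, 10.0
        t = np.linspace(0, 30, 3001)
        d1 = (A * k / 4.0) / np.cosh(k * (t - t0) / 2.0) ** 2
        seg = segment_growth(t, d1)
        off = (2.0 / k) * math.acosh(math.sqrt(20.0))
        dt = t[1] - t[0]
        assert t[seg.start_index] == pytest.approx(t0 - off, abs=2 * dt)
        assert t[seg.end_index] == pytest.approx(t0 + off, abs=2 * dt)

    def test_first_crossing_wins_with_pre_max_noise_spike(self):
        t = np.arange(0, 100.0)
        d1 = np.zeros(100)
        d1[20] = 0.6          # early spike above threshold
        d1[25] = 0.01         # dip below threshold
        d1[40:60] = np.linspace(0.1, 1.0, 20)  # main growth
        seg = segment_growth(t, d1)
        # brute-force scan of the documented rule
        thr = 0.05 * d1.max()
        start = next(i for i in range(100) if d1[i] >= thr)
        assert seg.start_index == start == 20

    def test_flat_curve_raises_no_growth(self):
        t = np.arange(0, 100.0)
        with pytest.raises(NoGrowthError):
            segment_growth(t, np.zeros(100))

    def test_never_recrossing_falls_back_to_last_index(self):
        t = np.arange(0, 100.0)
        d1 = np.linspace(0.1, 1.0, 100)  # still growing at the end
        seg = segment_growth(t, d1)
        assert seg.end_index == 99

    @given(st.integers(0, 2**32 - 1))
    def test_equals_brute_force_scan_on_random_curves(self, seed):
        """Property: segmentation equals a linear scan of the quoted rule."""
        rng = np.random.default_rng(seed)
        n = 120
        t = np.arange(n, dtype=float)
        d1 = rng.normal(0.2, 0.5, n)
        d1[rng.integers(10, n - 10)] = 2.0  # ensure positive unique-ish max
        seg = segment_growth(t, d1)
        thr = 0.05 * d1.max()
        start = next(i for i in range(n) if d1[i] >= thr)
        imax = int(np.argmax(d1))
        end = next((i for i in range(imax + 1, n) if d1[i] <= thr), n - 1)
        assert (seg.start_index, seg.end_index) == (start, end)


class TestAlignReplicates:
    def _triplet(self, shifts):
        t = np.linspace(0, 30, 601)
        return [
            ThTCurve(t=t, y=logistic(t - s), condition="c", replicate=i)
            for i, s in enumerate(shifts)
        ]

    def test_identical_curves_zero_shifts(self):
        curves = self._triplet([0.0, 0.0, 0.0])
        _, shifts = align_replicates(curves)
        assert np.allclose(shifts, 0.0, atol=1e-9)

    def test_recovers_constructed_shifts(self):
        curves = self._triplet([-1.0, 0.0, 1.0])
        aligned, shifts = align_replicates(curves)
        assert shifts == pytest.approx([1.0, 0.0, -1.0], abs=0.06)
        assert sum(shifts) == pytest.approx(0.0, abs=1e-9)
        # post-alignment lags agree with each other within one grid step
        cfg = KineticsConfig()
        lags = [extract_parameters(c, cfg).lag_time for c in aligned]
        assert max(lags) - min(lags) <= 2 * (curves[0].t[1] - curves[0].t[0])

    def test_mean_lag_preserved(self):
        curves = self._triplet([-0.8, 0.3, 0.9])
        aligned, _ = align_replicates(curves)
        cfg = KineticsConfig()
        before = np.mean([extract_parameters(c, cfg).lag_time for c in curves])
        after = np.mean([extract_parameters(c, cfg).lag_time for c in aligned])
        assert after == pytest.approx(before, abs=0.1)

    def test_flat_replicate_skips_alignment_with_warning(self):
        t = np.linspace(0, 30, 601)
        curves = self._triplet([0.0])[:1] + [
            ThTCurve(t=t, y=np.zeros(601), condition="c", replicate=1)
        ]
        with pytest.warns(UserWarning, match="no\\s+growth"):
            out, shifts = align_replicates(curves)
        assert shifts == [0.0, 0.0]


class TestExtractParameters:
    def test_logistic_closed_forms(self, logistic_curve):
        curve, p = logistic_curve
        params = extract_parameters(curve)
        assert params.max_growth_rate == pytest.approx(
            p["A"] * p["k"] / 4.0, rel=0.01
        )
        assert params.plateau_height == pytest.approx(p["A"], rel=0.01)
        off = (2.0 / p["k"]) * math.acosh(math.sqrt(20.0))
        assert params.lag_time == pytest.approx(p["t0"] - off, abs=0.1)

    def test_constant_curve_reports_undefined_not_zero(self):
        t = np.linspace(0, 10, 100)
        params = extract_parameters(ThTCurve(t=t, y=np.full(100, 5.0)))
        assert not params.defined
        assert math.isnan(params.max_growth_rate)
        assert "no growth" in params.undefined_reason

    def test_provenance_indices_recorded(self, logistic_curve):
        curve, _ = logistic_curve
        params = extract_parameters(curve)
        prov = params.provenance
        assert prov["start_index"] <= prov["argmax_d1_index"] <= prov["end_index"]
        assert params.growth_duration >= 0

    def test_rates_scale_linearly_with_fluorescence_units(self, logistic_curve):
        """Dimensional analysis: y -> c*y multiplies all rates by c."""
        curve, _ = logistic_curve
        c = 3.7
        scaled = ThTCurve(t=curve.t, y=c * curve.y)
        a, b = extract_parameters(curve), extract_parameters(scaled)
        for name in ("max_growth_rate", "average_growth_rate",
                     "initial_growth_rate", "plateau_height",
                     "acceleration_max"):
            assert getattr(b, name) == pytest.approx(
                c * getattr(a, name), rel=1e-9
            )
        for name in ("lag_time", "growth_duration"):
            assert getattr(b, name) == pytest.approx(getattr(a, name))

    def test_rates_scale_inversely_with_time_units(self, logistic_curve):
        curve, _ = logistic_curve
        c = 2.0
        stretched = ThTCurve(t=c * curve.t, y=curve.y)
        a, b = extract_parameters(curve), extract_parameters(stretched)
        assert b.max_growth_rate == pytest.approx(a.max_growth_rate / c, rel=1e-6)
        assert b.lag_time == pytest.approx(c * a.lag_time, rel=1e-6)
        assert b.growth_duration == pytest.approx(c * a.growth_duration, rel=1e-6)
        assert b.acceleration_max == pytest.approx(
            a.acceleration_max / c**2, rel=1e-6
        )


class TestDoseSeries:
    def test_two_points_are_the_endpoints(self):
        assert build_dose_series(n=2).tolist() == [1 / 5000, 1.0]

    def test_three_steps_below_equimolar_is_one_to_seventeen(self):
        """The default ten-point series has 1:17 three log steps below 1:1."""
        ratios = build_dose_series()
        denominator = 1.0 / ratios[-4]
        assert denominator == pytest.approx(5000 ** (3 / 9), rel=1e-12)
        assert round(denominator) == 17

    def test_log_spacing_exact(self):
        ratios = build_dose_series()
        steps = np.diff(np.log(ratios))
        assert np.allclose(steps, math.log(5000) / 9)

    def test_control_prepended(self):
        ratios = build_dose_series(include_control=True)
        assert len(ratios) == 11
        assert ratios[0] == 0.0

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            build_dose_series(n=1)
        with pytest.raises(ValueError):
            build_dose_series(ratio_min=2.0, ratio_max=1.0)


@pytest.fixture(scope="module")
def dataset():
    design = AssayDesign(
        n_ratios=4, n_replicates=2, noise_sd=0.0, lag_jitter_sd=0.0,
        t_grid=np.arange(0.0, 72.0, 0.2), rng_seed=7,
    )
    return generate_tht_assay(default_aggregation_model(), design)


class TestCompareNormalization:

    def test_scale_free_parameters_identical(self, dataset):
        cmp = compare_normalization(dataset)
        for name in ("lag_time", "growth_duration"):
            raw = cmp.raw.set_index(["ratio", "replicate"])[name]
            norm = cmp.normalized.set_index(["ratio", "replicate"])[name]
            assert np.allclose(raw, norm, equal_nan=True)

    def test_normalized_plateau_is_one(self, dataset):
        plateaus = cmp_plateaus = compare_normalization(dataset).normalized[
            "plateau_height"
        ]
        assert np.all(plateaus.dropna() <= 1.0 + 1e-9)
        assert np.all(plateaus.dropna() > 0.8)

    def test_monotone_trend_gives_perfect_rank_correlation(self, dataset):
        cmp = compare_normalization(dataset)
        assert cmp.rank_correlation["max_growth_rate"] == pytest.approx(1.0)
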