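import numpy as np
import pandas as pd
import pytest

from conftest import make_series
from phenodesert import filtering
from phenodesert.filtering import (
    FilterConfig,
    MaxFilter,
    NightFilter,
    SnowNightFilter,
    apply_filter_chain,
    max_filter,
    moving_average_3day,
    night_filter,
    snow_threshold_from_cdf,
    spline_filter,
)


class TestNightFilter:
    def test_removes_below_threshold(self):
        s = make_series([1, 2, 3], [0.15, 0.35, 0.19])
        out, rep = night_filter(s, 0.2)
        assert out["gcc"].tolist() == [0.35]
        assert rep.n_removed_night == 2

    def test_identity_when_all_above(self):
        s = make_series([1, 2, 3], [0.3, 0.4, 0.25])
        out, rep = night_filter(s, 0.2)
        assert len(out) == 3 and rep.n_removed_night == 0

    def test_boundary_value_retained(self):
        s = make_series([1], [0.2])
        out, _ = night_filter(s, 0.2)
        assert len(out) == 1  # strictly "below" is removed

    def test_idempotent(self, rng):
        s = make_series(np.arange(50), rng.uniform(0.1, 0.4, 50))
        once, _ = night_filter(s, 0.2)
        twice, rep2 = night_filter(once, 0.2)
        pd.testing.assert_frame_equal(once, twice)
        assert rep2.n_removed == 0

    def test_all_removed_warns(self):
        s = make_series([1, 2], [0.1, 0.05])
        with pytest.warns(UserWarning, match="empty"):
            out, _ = night_filter(s, 0.2)
        assert len(out) == 0


def _exhaustive_breakpoint_oracle(values, min_left, min_right):
    """Single-breakpoint two-line RSS minimization by brute polyfit."""
    y = np.sort(values)
    n = len(y)
    x = np.arange(1, n + 1) / n

    def rss(xs, ys):
        if len(xs) < 2:
            return 0.0
        coef = np.polyfit(xs, ys, 1)
        return float(((ys - np.polyval(coef, xs)) ** 2).sum())

    best_k, best = None, np.inf
    for k in range(min_left, n - min_right + 1):
        r = rss(x[:k], y[:k]) + rss(x[k:], y[k:])
        if r < best - 1e-15:
            best, best_k = r, k
    return best_k, best, rss(x, y)


class TestSnowThreshold:
    def test_recovers_threshold_in_gap(self, rng):
        snow = rng.uniform(0.20, 0.26, 30)
        clean = rng.uniform(0.30, 0.36, 170)
        s = make_series(np.arange(200), np.concatenate([snow, clean]))
        thr = snow_threshold_from_cdf(s)
        assert thr is not None and 0.26 <= thr <= 0.30

    def test_matches_exhaustive_rss_oracle(self, rng):
        # a clear two-population sample: the accepted breakpoint index must
        # equal the exhaustive single-split RSS minimizer
        vals = np.concatenate([rng.uniform(0.20, 0.26, 40),
                               rng.uniform(0.31, 0.36, 160)])
        y = np.sort(vals)
        n = len(y)
        m = max(20, int(np.ceil(0.5 * n)))
        min_left = max(5, int(np.ceil(0.05 * m)))
        min_right = max(5, int(np.ceil(0.15 * m)))
        k_oracle, _, _ = _exhaustive_breakpoint_oracle(y[:m], min_left, min_right)
        thr = snow_threshold_from_cdf(vals)
        assert thr == pytest.approx(0.5 * (y[k_oracle - 1] + y[k_oracle]))

    def test_single_uniform_population_gives_none(self, rng):
        vals = rng.uniform(0.30, 0.36, 200)
        assert snow_threshold_from_cdf(vals) is None

    def test_clean_seasonal_series_gives_none(self, wet_meadow_series):
        df, _ = wet_meadow_series
        assert snow_threshold_from_cdf(df) is None

    def test_fewer_than_20_samples_gives_none(self, rng):
        assert snow_threshold_from_cdf(rng.uniform(0.2, 0.4, 19)) is None

    def test_constant_series_gives_none(self):
        assert snow_threshold_from_cdf(np.full(50, 0.33)) is None

    def test_recovery_rate_over_spec_regime(self):
        # snow fraction 10-30%, separation >= 0.04: threshold in the gap
        # in >= 90% of simulated series
        rng = np.random.default_rng(99)
        ok = 0
        n_runs = 100
        for _ in range(n_runs):
            n_snow = int(rng.uniform(0.10, 0.30) * 200)
            sep = rng.uniform(0.04, 0.08)
            snow = rng.uniform(0.30 - sep - 0.06, 0.30 - sep, n_snow)
            clean = rng.uniform(0.30, 0.36, 200 - n_snow)
            thr = snow_threshold_from_cdf(np.concatenate([snow, clean]))
            if thr is not None and snow.max() < thr < clean.min():
                ok += 1
        assert ok >= 0.9 * n_runs


class TestSnowNightFilter:
    def test_removes_snow_band(self, rng):
        snow = rng.uniform(0.20, 0.26, 30)
        clean = rng.uniform(0.30, 0.36, 170)
        s = make_series(np.arange(200), np.concatenate([snow, clean]))
        f = SnowNightFilter()
        out = f.fit_transform(s)
        assert len(out) == 170
        assert out["gcc"].min() >= 0.30
        assert f.report_.snow_threshold is not None

    def test_fallback_equals_night_filter(self, rng):
        vals = rng.uniform(0.15, 0.36, 100)
        s = make_series(np.arange(100), vals)
        f = SnowNightFilter()
        out = f.fit_transform(s)
        assert f.breakpoint_ is None
        expected, _ = night_filter(s, 0.2)
        pd.testing.assert_frame_equal(out, expected)

    def test_floor_applies_when_breakpoint_below(self, rng):
        # breakpoint near 0.16 < 0.2: the fixed night floor still rules
        low = rng.uniform(0.05, 0.12, 40)
        clean = rng.uniform(0.22, 0.30, 160)
        s = make_series(np.arange(200), np.concatenate([low, clean]))
        f = SnowNightFilter().fit(s)
        assert f.breakpoint_ is not None and f.breakpoint_ < 0.2
        assert f.threshold_ == 0.2


class TestSplineFilter:
    def test_single_downward_outlier_removed(self):
        doy = np.repeat(np.arange(1, 16), 2)
        gcc = np.full(30, 0.33)
        gcc[13] = 0.25
        out, rep = spline_filter(make_series(doy, gcc))
        assert rep.n_removed_spline == 1
        assert out["gcc"].min() == pytest.approx(0.33)

    def test_smooth_series_untouched(self):
        doy = np.arange(1, 41)
        gcc = 0.32 + 0.0005 * doy
        out, rep = spline_filter(make_series(doy, gcc))
        assert rep.n_removed_spline == 0 and len(out) == 40

    def test_upward_outliers_kept(self):
        doy = np.repeat(np.arange(1, 16), 2)
        gcc = np.full(30, 0.33)
        gcc[13] = 0.41
        out, rep = spline_filter(make_series(doy, gcc))
        assert rep.n_removed_spline == 0 and len(out) == 30

    def test_two_dips_removed_within_two_iterations(self, rng):
        doy = np.arange(1, 101)
        noise = rng.normal(0, 0.002, 100)
        gcc = 0.33 + noise
        gcc[30] -= 5 * 0.002
        gcc[70] -= 5 * 0.002
        out, rep = spline_filter(make_series(doy, gcc))
        kept_doy = set(out["doy"])
        assert 31 not in kept_doy and 71 not in kept_doy

    def test_too_few_samples_identity_with_warning(self):
        s = make_series([1, 2, 3], [0.3, 0.31, 0.32])
        with pytest.warns(UserWarning, match="spline filter skipped"):
            out, _ = spline_filter(s)
        assert len(out) == 3


class TestMaxFilter:
    def test_three_point_percentile_convention(self):
        s = make_series([5, 5, 5], [0.30, 0.32, 0.40])
        out = max_filter(s)
        row = out[out["doy"] == 5]
        assert row["gcc"].item() == pytest.approx(0.384)  # linear interpolation

    def test_constant_series(self):
        s = make_series(np.repeat([1, 2, 3, 4], 3), 0.31 * np.ones(12))
        out = max_filter(s)
        assert np.allclose(out["gcc"], 0.31)
        assert out["doy"].tolist() == [1, 2, 3, 4]

    def test_single_sample_window(self):
        s = make_series([10], [0.35])
        out = max_filter(s)
        assert out["gcc"].tolist() == [0.35]

    def test_empty_series(self):
        out = max_filter(make_series([], []))
        assert len(out) == 0

    def test_matches_brute_force_oracle(self, rng):
        doy = rng.integers(1, 40, 150)
        gcc = rng.uniform(0.25, 0.45, 150)
        s = make_series(doy, gcc)
        out = max_filter(s, window_days=3, percentile=90)
        for _, row in out.iterrows():
            sel = (doy >= row.doy - 1) & (doy <= row.doy + 1)
            assert row.gcc == pytest.approx(np.percentile(gcc[sel], 90))

    def test_never_exceeds_window_max(self, rng):
        doy = rng.integers(1, 30, 120)
        gcc = rng.uniform(0.2, 0.5, 120)
        out = max_filter(make_series(doy, gcc))
        for _, row in out.iterrows():
            sel = (doy >= row.doy - 1) & (doy <= row.doy + 1)
            assert row.gcc <= gcc[sel].max() + 1e-12


class TestMovingAverage:
    def test_edges_use_available_subset(self):
        np.testing.assert_allclose(moving_average_3day([1, 2, 3, 4]),
                                   [1.5, 2, 3, 3.5])

    def test_constant_identity(self):
        np.testing.assert_allclose(moving_average_3day([2.0] * 6), [2.0] * 6)

    def test_gap_uses_present_values(self):
        s = pd.Series([1.0, 3.0], index=pd.to_datetime(["2015-01-01", "2015-01-03"]))
        sm = moving_average_3day(s)
        # day 2 is absent; each present day averages itself with the gap skipped
        np.testing.assert_allclose(sm.to_numpy(), [1.0, 3.0])


class TestFilterChain:
    def test_canonical_order_enforced(self, wet_meadow_series):
        df, _ = wet_meadow_series
        with pytest.raises(ValueError, match="canonical"):
            apply_filter_chain(df, order=("max", "spline", "snow_night"))
        out, _ = apply_filter_chain(df, order=("max", "spline", "snow_night"),
                                    allow_reorder=True)
        assert len(out)

    def test_chain_produces_daily_series_and_report(self, wet_meadow_series):
        df, _ = wet_meadow_series
        out, rep = apply_filter_chain(df)
        assert out["doy"].is_unique
        assert rep.n_input == len(df)
        assert rep.days_retained == out["doy"].nunique()

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = FilterConfig(night_threshold=0.25, spline_outlier_sd=3.0)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert FilterConfig.from_yaml(tmp_path / "cfg.yaml") == cfg

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(night_threshold=1.5)
        with pytest.raises(ValueError):
            FilterConfig(max_filter_window=2)
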