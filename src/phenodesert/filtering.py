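"""Filter chain for sub-daily chromatic series.

The canonical order, applied before any curve fitting, is

    (snow/)night  ->  spline  ->  max

The night filter drops samples with GCC below a fixed threshold (0.2 by
default; poorly exposed, dark or abnormal-white-balance frames). The
snow/night filter replaces the fixed threshold with a data-driven one found
as the first breakpoint of a segmented regression of sorted GCC on its
empirical cumulative fraction: ephemeral snow produces a distinct low-GCC
population that breaks the linearity of the CDF in its lower range. The
spline filter removes strong downward outliers around a GCV smoothing
spline (greenness drops, not spikes, are the artifact at these sites), and
the max filter summarizes each day by the 90th percentile of the retained
sub-daily values over a centered 3-day window, producing a daily series.

All filters are sklearn-style transformers over the series DataFrame
produced by :mod:`phenodesert.imagery` (columns timestamp/doy/gcc/...);
module-level functions wrap them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import make_smoothing_spline
from sklearn.base import BaseEstimator

from phenodesert._segmented import SEGMENTED_RATIO_CRIT, segmented_breakpoints

CANONICAL_ORDER = ("snow_night", "spline", "max")


@dataclass
class FilterConfig:
    """Tunable settings of the filter chain (GCC units / days)."""

    night_threshold: float = 0.2
    max_filter_window: int = 3
    max_filter_percentile: float = 90.0
    snow_filter_enabled: bool = True
    breakpoint_min_segment_fraction: float = 0.15
    spline_outlier_sd: float = 2.0
    spline_iterations: int = 2

    def __post_init__(self):
        if not 0 < self.night_threshold < 1:
            raise ValueError("night_threshold must lie in (0, 1)")
        if self.max_filter_window < 1 or self.max_filter_window % 2 == 0:
            raise ValueError("max_filter_window must be odd and >= 1")
        if not 0 < self.max_filter_percentile < 100:
            raise ValueError("max_filter_percentile must lie in (0, 100)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class FilterReport:
    """Sample accounting for a filter run (sums to n_input - n_retained)."""

    n_input: int = 0
    n_removed_night: int = 0
    n_removed_snow: int = 0
    n_removed_spline: int = 0
    snow_threshold: float | None = None
    days_retained: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_removed_night + self.n_removed_snow + self.n_removed_spline

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterReport":
        return cls(**json.loads(Path(path).read_text()))

    def merged(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            n_input=self.n_input or other.n_input,
            n_removed_night=self.n_removed_night + other.n_removed_night,
            n_removed_snow=self.n_removed_snow + other.n_removed_snow,
            n_removed_spline=self.n_removed_spline + other.n_removed_spline,
            snow_threshold=self.snow_threshold if self.snow_threshold is not None
            else other.snow_threshold,
            days_retained=other.days_retained or self.days_retained,
        )


def _fractional_doy(df: pd.DataFrame) -> np.ndarray:
    """Day-of-year plus time of day, from timestamps when present."""
    if "timestamp" in df.columns and df["timestamp"].notna().all():
        ts = pd.to_datetime(df["timestamp"])
        return (ts.dt.dayofyear + (ts.dt.hour + ts.dt.minute / 60.0) / 24.0).to_numpy()
    return df["doy"].to_numpy(dtype=float)


def _warn_if_empty(df: pd.DataFrame, name: str) -> None:
    if len(df) == 0:
        warnings.warn(f"{name} removed every sample; series is empty")


class NightFilter(BaseEstimator):
    """Remove sub-daily samples with GCC strictly below a fixed threshold."""

    def __init__(self, threshold: float = 0.2):
        self.threshold = threshold

    def fit(self, series: pd.DataFrame, y=None):
        self.threshold_ = float(self.threshold)
        return self

    def transform(self, series: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "threshold_"):
            self.fit(series)
        keep = series["gcc"] >= self.threshold_  # strictly "below" is removed
        out = series[keep].reset_index(drop=True)
        self.report_ = FilterReport(n_input=len(series),
                                    n_removed_night=int((~keep).sum()),
                                    days_retained=out["doy"].nunique() if len(out) else 0)
        _warn_if_empty(out, "night filter")
        return out

    def fit_transform(self, series: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(series).transform(series)


def snow_threshold_from_cdf(
    series: pd.DataFrame | np.ndarray,
    min_segment_fraction: float = 0.15,
    ratio_crit: float = SEGMENTED_RATIO_CRIT,
    lower_fraction: float = 0.5,
) -> float | None:
    """Data-driven snow/night GCC threshold from a CDF breakpoint.

    Sorts GCC ascending, regresses the sorted values on the normalized rank
    (empirical cumulative fraction) and searches for piecewise-linear
    breakpoints (up to three segments). Snow contamination shows as a
    divergence from linearity in the *lower range* of the CDF, so the
    search is restricted to the lowest ``lower_fraction`` of the sample:
    the upper range of a clean seasonal series is itself curved and would
    otherwise mask the contamination break. The threshold is the GCC value
    at the first (smallest-rank) breakpoint — the midpoint between the
    last sample of the first segment and the first sample of the second.
    Returns None when fewer than 20 samples are available or no breakpoint
    passes the model-selection rule (see :mod:`phenodesert._segmented`).
    """
    gcc = np.asarray(series["gcc"] if isinstance(series, pd.DataFrame) else series,
                     dtype=float)
    gcc = gcc[np.isfinite(gcc)]
    n = len(gcc)
    if n < 20:
        return None
    y = np.sort(gcc)
    if y[0] == y[-1]:  # constant series: no breakpoint to find
        return None
    m = max(20, int(np.ceil(lower_fraction * n)))
    y = y[:m]
    x = np.arange(1, m + 1) / n
    breaks = segmented_breakpoints(
        x, y, min_segment_fraction=min_segment_fraction, ratio_crit=ratio_crit)
    if not breaks:
        return None
    k = breaks[0]
    return float(0.5 * (y[k - 1] + y[k]))


class SnowNightFilter(BaseEstimator):
    """Variable night filter: threshold learned from the GCC CDF breakpoint.

    ``fit`` learns ``threshold_`` as max(floor, breakpoint); when no
    breakpoint is supported the filter falls back to the fixed night filter
    at ``floor`` (default 0.2). The floor is never undercut: the snow filter
    augments, not replaces, the night filter.
    """

    def __init__(self, floor: float = 0.2, min_segment_fraction: float = 0.15):
        self.floor = floor
        self.min_segment_fraction = min_segment_fraction

    def fit(self, series: pd.DataFrame, y=None):
        bp = snow_threshold_from_cdf(series, self.min_segment_fraction)
        self.breakpoint_ = bp
        self.threshold_ = max(self.floor, bp) if bp is not None else self.floor
        return self

    def transform(self, series: pd.DataFrame) -> pd.DataFrame:
        keep = series["gcc"] >= self.threshold_
        out = series[keep].reset_index(drop=True)
        n_night = int((series["gcc"] < self.floor).sum())
        self.report_ = FilterReport(
            n_input=len(series),
            n_removed_night=n_night,
            n_removed_snow=int((~keep).sum()) - n_night,
            snow_threshold=self.breakpoint_,
            days_retained=out["doy"].nunique() if len(out) else 0,
        )
        _warn_if_empty(out, "snow/night filter")
        return out

    def fit_transform(self, series: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(series).transform(series)


class SplineFilter(BaseEstimator):
    """Iterative smoothing-spline rejection of downward GCC outliers.

    Fits a cubic smoothing spline (GCV-selected smoothing unless ``lam`` is
    given) to GCC against fractional day-of-year and removes samples whose
    residual falls below -(outlier_sd x residual SD). Upward excursions are
    never removed: at these sites artifacts (snow, shadow, exposure) depress
    greenness. Runs ``iterations`` passes. Series with fewer than 10 samples
    or spanning fewer than 5 distinct days pass through unchanged.
    """

    def __init__(self, outlier_sd: float = 2.0, iterations: int = 2,
                 lam: float | None = None):
        self.outlier_sd = outlier_sd
        self.iterations = iterations
        self.lam = lam

    def fit(self, series: pd.DataFrame, y=None):
        return self

    def transform(self, series: pd.DataFrame) -> pd.DataFrame:
        n_input = len(series)
        out = series.reset_index(drop=True)
        if n_input < 10 or out["doy"].nunique() < 5:
            warnings.warn("spline filter skipped: too few samples/days")
            self.report_ = FilterReport(n_input=n_input,
                                        days_retained=out["doy"].nunique())
            return out
        removed = 0
        for _ in range(self.iterations):
            t = _fractional_doy(out)
            g = out["gcc"].to_numpy(dtype=float)
            resid = g - self._smooth(t, g)
            sd = resid.std()
            if sd == 0:
                break
            keep = resid >= -self.outlier_sd * sd
            if keep.all():
                break
            removed += int((~keep).sum())
            out = out[keep].reset_index(drop=True)
        self.report_ = FilterReport(n_input=n_input, n_removed_spline=removed,
                                    days_retained=out["doy"].nunique())
        _warn_if_empty(out, "spline filter")
        return out

    def fit_transform(self, series: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(series).transform(series)

    def _smooth(self, t: np.ndarray, g: np.ndarray) -> np.ndarray:
        # make_smoothing_spline needs strictly increasing x: average duplicates
        order = np.argsort(t)
        tu, inv = np.unique(t[order], return_inverse=True)
        gu = np.zeros_like(tu)
        np.add.at(gu, inv, g[order])
        counts = np.bincount(inv)
        gu /= counts
        spl = make_smoothing_spline(tu, gu, lam=self.lam)
        return spl(t)


class MaxFilter(BaseEstimator):
    """Daily aggregation: windowed upper-percentile of sub-daily GCC.

    For each calendar day d with at least one retained sample in the
    centered window [d - w//2, d + w//2], outputs the ``percentile`` (linear
    interpolation between order statistics) of all sub-daily GCC in the
    window. Days with no samples in the window are missing. Output is a
    daily series (columns doy, gcc, n_samples).
    """

    def __init__(self, window_days: int = 3, percentile: float = 90.0):
        self.window_days = window_days
        self.percentile = percentile

    def fit(self, series: pd.DataFrame, y=None):
        return self

    def transform(self, series: pd.DataFrame) -> pd.DataFrame:
        if len(series) == 0:
            return pd.DataFrame(columns=["doy", "gcc", "n_samples"])
        half = self.window_days // 2
        doy = series["doy"].to_numpy(dtype=int)
        gcc = series["gcc"].to_numpy(dtype=float)
        rows = []
        for d in range(doy.min(), doy.max() + 1):
            sel = (doy >= d - half) & (doy <= d + half)
            if not sel.any():
                continue
            rows.append({"doy": d,
                         "gcc": float(np.percentile(gcc[sel], self.percentile)),
                         "n_samples": int(sel.sum())})
        return pd.DataFrame(rows)

    def fit_transform(self, series: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.transform(series)


def night_filter(series: pd.DataFrame, threshold: float = 0.2):
    f = NightFilter(threshold)
    out = f.fit_transform(series)
    return out, f.report_


def snow_night_filter(series: pd.DataFrame, config: FilterConfig | None = None):
    cfg = config or FilterConfig()
    if not cfg.snow_filter_enabled:
        return night_filter(series, cfg.night_threshold)
    f = SnowNightFilter(floor=cfg.night_threshold,
                        min_segment_fraction=cfg.breakpoint_min_segment_fraction)
    out = f.fit_transform(series)
    return out, f.report_


def spline_filter(series: pd.DataFrame, config: FilterConfig | None = None):
    cfg = config or FilterConfig()
    f = SplineFilter(outlier_sd=cfg.spline_outlier_sd, iterations=cfg.spline_iterations)
    out = f.fit_transform(series)
    return out, f.report_


def max_filter(series: pd.DataFrame, window_days: int = 3, percentile: float = 90.0) -> pd.DataFrame:
    return MaxFilter(window_days, percentile).fit_transform(series)


def apply_filter_chain(
    series: pd.DataFrame,
    config: FilterConfig | None = None,
    order: Sequence[str] = CANONICAL_ORDER,
    allow_reorder: bool = False,
):
    """Run the full chain (snow/)night -> spline -> max on a sub-daily series.

    The canonical order is enforced; pass ``allow_reorder=True`` to run an
    explicitly different order. Returns (daily series, merged FilterReport).
    """
    cfg = config or FilterConfig()
    order = tuple(order)
    if order != CANONICAL_ORDER and not allow_reorder:
        raise ValueError(
            f"filter order {order} differs from the canonical {CANONICAL_ORDER}; "
            "pass allow_reorder=True to override")
    report = FilterReport(n_input=len(series))
    out = series
    for stage in order:
        if stage == "snow_night":
            out, rep = snow_night_filter(out, cfg)
            report = report.merged(rep)
        elif stage == "night":
            out, rep = night_filter(out, cfg.night_threshold)
            report = report.merged(rep)
        elif stage == "spline":
            out, rep = spline_filter(out, cfg)
            report = report.merged(rep)
        elif stage == "max":
            out = max_filter(out, cfg.max_filter_window, cfg.max_filter_percentile)
        else:
            raise ValueError(f"unknown filter stage {stage!r}")
    report.n_input = len(series)
    report.days_retained = int(out["doy"].nunique()) if len(out) else 0
    return out, report


def moving_average_3day(values, window: int = 3):
    """Centered moving mean of a daily environmental series; gaps allowed.

    ``values`` may be a pandas Series (indexed by date or day number, gaps
    allowed) or an array. Edge days and days adjacent to gaps average over
    whatever neighbors exist.
    """
    if isinstance(values, pd.Series):
        s = values.copy()
        if isinstance(s.index, pd.DatetimeIndex):
            full = pd.date_range(s.index.min(), s.index.max(), freq="D")
        else:
            full = pd.RangeIndex(int(s.index.min()), int(s.index.max()) + 1)
        dense = s.reindex(full)
        sm = dense.rolling(window, center=True, min_periods=1).mean()
        return sm.reindex(s.index)
    arr = pd.Series(np.asarray(values, dtype=float))
    return arr.rolling(window, center=True, min_periods=1).mean().to_numpy()
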