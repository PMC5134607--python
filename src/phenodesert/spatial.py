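"""Per-pixel ("spatiotemporal") phenology mapping.

Each pixel's daily GCC trajectory is fitted with a cubic regression spline
(per-pixel series are too noisy for stable double-logistic fits) and
phenophases are extracted with the same line-intersection geometry used for
ROI-averaged fits. Pixels whose UD or RD falls outside a histogram window
(defaults DOY 50-170 for UD, 170-330 for RD) are classed as interspace;
the rest are vegetation, for which GSL = RD - UD is mapped. Interspace
pixels are further split into bare ground versus woody material / shadow by
a single mean changepoint on the CDF of their seasonal GCC ranges.

No uncertainty ensemble is computed per pixel: with thousands of pixels the
replicate refits are prohibitive and the histogram filtering plays the role
of the plausibility check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline
from sklearn.base import BaseEstimator

from phenodesert._segmented import MEAN_SPLIT_RATIO_CRIT, sorted_mean_changepoint
from phenodesert.fitting import phenophases_from_curve
from phenodesert.imagery import ROI, TimestampedImage, chromatic_coordinates

CLASS_EXCLUDED = "excluded"
CLASS_VEGETATION = "vegetation"
CLASS_INTERSPACE = "interspace"
CLASS_UNCLASSIFIED = "unclassified"


@dataclass
class PixelTrajectorySet:
    """Daily GCC per pixel over an ROI bounding box.

    ``gcc`` has shape (n_days, H, W) with NaN for missing samples; ``valid``
    marks pixels with at least 20 daily values. ``offset`` maps local (row,
    col) back to full-image coordinates.
    """

    days: np.ndarray
    gcc: np.ndarray
    valid: np.ndarray
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if self.gcc.ndim != 3 or len(self.days) != self.gcc.shape[0]:
            raise ValueError("gcc must be (n_days, H, W) matching days")

    @property
    def shape(self) -> tuple[int, int]:
        return self.gcc.shape[1:]


def extract_pixel_trajectories(
    images: list[TimestampedImage],
    roi: ROI,
    daily_percentile: float = 90.0,
    min_days: int = 20,
) -> PixelTrajectorySet:
    """Per-pixel daily GCC from an image stack (upper-percentile per day).

    Sub-daily per-pixel GCC values are aggregated to daily resolution with
    the same upper-percentile convention as the max filter. Zero-DN pixels
    yield missing values.
    """
    r0, r1, c0, c1 = roi.bounding_box()
    submask = roi.mask[r0:r1, c0:c1]
    by_day: dict[int, list[np.ndarray]] = {}
    for im in images:
        cc = chromatic_coordinates(im.pixels[r0:r1, c0:c1].astype(float))
        g = cc[..., 0]
        g = np.where(submask, g, np.nan)
        by_day.setdefault(im.doy, []).append(g)
    days = np.array(sorted(by_day))
    stack = np.full((len(days), r1 - r0, c1 - c0), np.nan)
    for i, d in enumerate(days):
        sub = np.stack(by_day[d])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stack[i] = np.nanpercentile(sub, daily_percentile, axis=0)
    valid = np.isfinite(stack).sum(axis=0) >= min_days
    return PixelTrajectorySet(days=days, gcc=stack, valid=valid, offset=(r0, c0))


@dataclass
class HistogramWindow:
    """Admissible DOY bounds for per-pixel UD and RD."""

    ud_min: float = 50.0
    ud_max: float = 170.0
    rd_min: float = 170.0
    rd_max: float = 330.0

    def __post_init__(self):
        if not (self.ud_min < self.ud_max <= self.rd_max and self.rd_min < self.rd_max):
            raise ValueError("require ud_min < ud_max <= rd_max and rd_min < rd_max")


def automatic_window(ud: np.ndarray, rd: np.ndarray, n_mad: float = 2.0,
                     bin_width: float = 5.0, min_half_width: float = 10.0) -> HistogramWindow:
    """Data-driven histogram window: histogram mode +/- n_mad x MAD.

    An automated stand-in for choosing the predominant bell of the UD/RD
    histograms by eye; the manual window remains the default. The half-width
    never shrinks below ``min_half_width`` days so a very tight date cluster
    does not truncate its own tails.
    """
    def bounds(v):
        v = v[np.isfinite(v)]
        edges = np.arange(v.min(), v.max() + bin_width, bin_width)
        if len(edges) < 2:
            return v.min() - bin_width, v.max() + bin_width
        hist, edges = np.histogram(v, bins=edges)
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        half = max(n_mad * np.median(np.abs(v - np.median(v))), min_half_width)
        return mode - half, mode + half
    ud_lo, ud_hi = bounds(np.asarray(ud, dtype=float))
    rd_lo, rd_hi = bounds(np.asarray(rd, dtype=float))
    rd_hi = max(rd_hi, ud_hi)
    return HistogramWindow(ud_lo, ud_hi, rd_lo, rd_hi)


@dataclass
class PhenoMap:
    """Per-pixel phenophase grids with class labels and validity masks."""

    ud: np.ndarray
    sd: np.ndarray
    dd: np.ndarray
    rd: np.ndarray
    gsl: np.ndarray
    gcc_range: np.ndarray
    class_label: np.ndarray  # dtype object/str
    offset: tuple[int, int] = (0, 0)

    def to_dataframe(self) -> pd.DataFrame:
        h, w = self.ud.shape
        rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        return pd.DataFrame({
            "row": rows.ravel() + self.offset[0],
            "col": cols.ravel() + self.offset[1],
            "ud": self.ud.ravel(), "sd": self.sd.ravel(),
            "dd": self.dd.ravel(), "rd": self.rd.ravel(),
            "gsl": self.gsl.ravel(), "gcc_range": self.gcc_range.ravel(),
            "class": self.class_label.ravel(),
        })


def _pixel_spline(x: np.ndarray, y: np.ndarray, df_bounds=(6, 30)):
    """Cubic regression spline with ~n/8 degrees of freedom (bounded)."""
    df = int(np.clip(len(x) / 8, df_bounds[0], df_bounds[1]))
    n_interior = max(df - 4, 1)
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    knots = np.quantile(x, qs)
    knots = knots[(knots > x[0]) & (knots < x[-1])]
    return LSQUnivariateSpline(x, y, t=knots, k=3)


def fit_per_pixel(
    trajectories: PixelTrajectorySet,
    df_bounds: tuple[int, int] = (6, 30),
    grid_step: float = 0.25,
    min_signal_factor: float = 12.0,
) -> PhenoMap:
    """Spline fit + phenophase extraction for every valid pixel.

    A pixel whose spline fit fails or whose curve shows no interior
    green-up/senescence is marked excluded; the map is always returned.
    GSL is RD - UD wherever both are defined (it may be negative for noisy
    pixels before histogram filtering — exactly the artifact the window
    filter removes).

    Pixels with no detectable seasonal signal are excluded before any date
    is extracted: when the smoothed seasonal range falls below
    ``min_signal_factor`` times the spline's own sampling noise floor
    (residual SD x sqrt(df/n)), the "trajectory" is indistinguishable from
    smoothing noise and any phenophase drawn from it would be arbitrary.
    Such pixels keep their (small) gcc_range but carry no dates. Set
    ``min_signal_factor=0`` to disable the screen.
    """
    h, w = trajectories.shape
    grids = {k: np.full((h, w), np.nan) for k in ("ud", "sd", "dd", "rd", "gsl", "gcc_range")}
    labels = np.full((h, w), CLASS_EXCLUDED, dtype=object)
    t_dense = np.arange(trajectories.days.min(), trajectories.days.max() + grid_step,
                        grid_step)
    for r in range(h):
        for c in range(w):
            if not trajectories.valid[r, c]:
                continue
            y = trajectories.gcc[:, r, c]
            ok = np.isfinite(y)
            x = trajectories.days[ok].astype(float)
            try:
                spl = _pixel_spline(x, y[ok], df_bounds)
                yd = spl(t_dense)
                resid_sd = float((y[ok] - spl(x)).std())
                df = int(np.clip(len(x) / 8, df_bounds[0], df_bounds[1]))
                noise_floor = resid_sd * np.sqrt(df / len(x))
                if yd.max() - yd.min() < min_signal_factor * noise_floor:
                    grids["gcc_range"][r, c] = float(yd.max() - yd.min())
                    continue
                ph = phenophases_from_curve(t_dense, yd, spl.derivative()(t_dense))
            except Exception:
                continue
            grids["gcc_range"][r, c] = float(yd.max() - yd.min())
            if not (np.isfinite(ph.ud) and np.isfinite(ph.rd)):
                continue
            for k in ("ud", "sd", "dd", "rd"):
                grids[k][r, c] = getattr(ph, k)
            grids["gsl"][r, c] = ph.rd - ph.ud
            labels[r, c] = CLASS_UNCLASSIFIED
    return PhenoMap(ud=grids["ud"], sd=grids["sd"], dd=grids["dd"], rd=grids["rd"],
                    gsl=grids["gsl"], gcc_range=grids["gcc_range"],
                    class_label=labels, offset=trajectories.offset)


def filter_histogram(pheno_map: PhenoMap, window: HistogramWindow | None = None) -> PhenoMap:
    """Classify pixels by the UD/RD histogram window.

    Pixels with UD inside [ud_min, ud_max] and RD inside [rd_min, rd_max]
    become vegetation; other fitted pixels become interspace. GSL is kept
    only for vegetation pixels, where the window bounds (ud_max <= rd_max,
    rd_min >= ud bounds) make negative GSL impossible.
    """
    win = window or HistogramWindow()
    out = PhenoMap(ud=pheno_map.ud.copy(), sd=pheno_map.sd.copy(),
                   dd=pheno_map.dd.copy(), rd=pheno_map.rd.copy(),
                   gsl=pheno_map.gsl.copy(), gcc_range=pheno_map.gcc_range.copy(),
                   class_label=pheno_map.class_label.copy(), offset=pheno_map.offset)
    fitted = out.class_label != CLASS_EXCLUDED
    veg = (fitted
           & (out.ud >= win.ud_min) & (out.ud <= win.ud_max)
           & (out.rd >= win.rd_min) & (out.rd <= win.rd_max))
    inter = fitted & ~veg
    out.class_label[veg] = CLASS_VEGETATION
    out.class_label[inter] = CLASS_INTERSPACE
    out.gsl[~veg] = np.nan
    if not veg.any():
        warnings.warn("histogram window left no vegetation pixels")
    return out


def gcc_range_map(
    trajectories: PixelTrajectorySet,
    smoothed: bool = True,
    df_bounds: tuple[int, int] = (6, 30),
) -> np.ndarray:
    """Per-pixel seasonal GCC range (annual max - min).

    With ``smoothed=True`` (default) the range is taken on the spline-
    smoothed daily curve so single-sample spikes do not set the extremes;
    ``smoothed=False`` uses the raw daily values.
    """
    h, w = trajectories.shape
    out = np.full((h, w), np.nan)
    for r in range(h):
        for c in range(w):
            if not trajectories.valid[r, c]:
                continue
            y = trajectories.gcc[:, r, c]
            ok = np.isfinite(y)
            x = trajectories.days[ok].astype(float)
            yy = y[ok]
            if smoothed:
                try:
                    spl = _pixel_spline(x, yy, df_bounds)
                    yy = spl(x)
                except Exception:
                    continue
            out[r, c] = float(yy.max() - yy.min())
    return out


@dataclass
class InterspaceSplit:
    """Two-way split of interspace GCC ranges: bare ground vs woody/shadow."""

    split_value: float | None
    classes: dict = field(default_factory=dict)  # name -> {median, p10, p90, n}

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def split_interspace(
    range_values: np.ndarray,
    ratio_crit: float = MEAN_SPLIT_RATIO_CRIT,
) -> InterspaceSplit:
    """Changepoint split of interspace seasonal ranges on their CDF.

    Values are sorted ascending (the CDF ordering) and a single mean
    changepoint is sought by exhaustive within-segment SSE minimization.
    The lower segment is bare ground, the upper woody material / shadow.
    When no changepoint is supported, a single class is reported.
    """
    v = np.asarray(range_values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("need at least 2 interspace values")
    if len(v) < 20:
        warnings.warn("fewer than 20 interspace pixels; split is fragile")

    def summary(a):
        return {"median": float(np.median(a)), "p10": float(np.percentile(a, 10)),
                "p90": float(np.percentile(a, 90)), "n": int(len(a))}

    k, vs = sorted_mean_changepoint(v, min_segment=1, ratio_crit=ratio_crit)
    if k is None:
        return InterspaceSplit(split_value=None, classes={"interspace": summary(vs)})
    split = float(0.5 * (vs[k - 1] + vs[k]))
    return InterspaceSplit(split_value=split,
                           classes={"bare_ground": summary(vs[:k]),
                                    "woody_shadow": summary(vs[k:])})


class PixelPhenologyMapper(BaseEstimator):
    """End-to-end spatiotemporal phenology: splines, window filter, split.

    ``fit`` computes the per-pixel phenophase map (``map_``), applies the
    histogram window (manual bounds by default, automatic mode optional),
    attaches the smoothed per-pixel GCC ranges and splits the interspace
    class (``interspace_split_``).
    """

    def __init__(self, window: HistogramWindow | None = None, auto_window: bool = False,
                 df_bounds: tuple[int, int] = (6, 30)):
        self.window = window
        self.auto_window = auto_window
        self.df_bounds = df_bounds

    def fit(self, trajectories: PixelTrajectorySet, y=None):
        raw = fit_per_pixel(trajectories, df_bounds=self.df_bounds)
        self.raw_map_ = raw
        if self.auto_window:
            win = automatic_window(raw.ud[np.isfinite(raw.ud)],
                                   raw.rd[np.isfinite(raw.rd)])
        else:
            win = self.window or HistogramWindow()
        self.window_ = win
        self.map_ = filter_histogram(raw, win)
        inter = self.map_.gcc_range[self.map_.class_label == CLASS_INTERSPACE]
        inter = inter[np.isfinite(inter)]
        self.interspace_split_ = (split_interspace(inter) if len(inter) >= 2
                                  else InterspaceSplit(split_value=None))
        return self

    def transform(self, trajectories: PixelTrajectorySet) -> pd.DataFrame:
        if not hasattr(self, "map_"):
            self.fit(trajectories)
        return self.map_.to_dataframe()
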