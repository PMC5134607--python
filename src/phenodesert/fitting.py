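"""Double-logistic phenology fitting and phenophase extraction.

Daily greenness is modeled with the Gu-style double logistic

    y(t) = y0 + a1 / (1 + exp(-(t - t1)/b1))^c1
              - a2 / (1 + exp(-(t - t2)/b2))^c2

where y0 is the baseline GCC, a1/a2 the recovery and senescence amplitudes,
t1/t2 the inflection days of year, b1/b2 rate scales (days) and c1/c2 shape
exponents. Phenophase dates follow the line-intersection geometry: the
recovery line is tangent to the curve at the maximum of dy/dt and the
senescence line at the minimum; the baseline and maxline are horizontal
lines through the curve minimum and maximum over the data span. Then

    UD (upturn)        = recovery line  x  baseline
    SD (stabilization) = recovery line  x  maxline
    DD (downturn)      = senescence line x plateau line
    RD (recession)     = senescence line x baseline
    GSL                = RD - UD

where the plateau line is an ordinary least-squares line through the fitted
values between SD and the provisional DD (senescence x maxline): mid-season
greendown would otherwise bias DD late. Phenophase dates are summarized from
an uncertainty ensemble (residual-resampling refits), not from the single
best fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

GU_PARAM_NAMES = ("y0", "a1", "a2", "t1", "t2", "b1", "b2", "c1", "c2")

_EXP_CLIP = 50.0


def _logistic_term(t, ti, bi, ci):
    u = np.exp(np.clip(-(np.asarray(t, dtype=float) - ti) / bi, -_EXP_CLIP, _EXP_CLIP))
    return (1.0 + u) ** (-ci), u


def gu_model(t, y0, a1, a2, t1, t2, b1, b2, c1, c2):
    """Evaluate the double-logistic greenness curve at day-of-year t."""
    f1, _ = _logistic_term(t, t1, b1, c1)
    f2, _ = _logistic_term(t, t2, b2, c2)
    return y0 + a1 * f1 - a2 * f2


def gu_derivative(t, y0, a1, a2, t1, t2, b1, b2, c1, c2):
    """Analytic dy/dt of :func:`gu_model`."""
    f1, u1 = _logistic_term(t, t1, b1, c1)
    f2, u2 = _logistic_term(t, t2, b2, c2)
    d1 = a1 * c1 * u1 * (1.0 + u1) ** (-c1 - 1.0) / b1
    d2 = a2 * c2 * u2 * (1.0 + u2) ** (-c2 - 1.0) / b2
    return d1 - d2


def _gu_jacobian(theta, t, y):
    y0, a1, a2, t1, t2, b1, b2, c1, c2 = theta
    f1, u1 = _logistic_term(t, t1, b1, c1)
    f2, u2 = _logistic_term(t, t2, b2, c2)
    g1 = (1.0 + u1) ** (-c1 - 1.0)
    g2 = (1.0 + u2) ** (-c2 - 1.0)
    J = np.empty((len(t), 9))
    J[:, 0] = 1.0
    J[:, 1] = f1
    J[:, 2] = -f2
    J[:, 3] = -a1 * c1 * u1 * g1 / b1
    J[:, 4] = a2 * c2 * u2 * g2 / b2
    J[:, 5] = -a1 * c1 * u1 * g1 * (t - t1) / b1 ** 2
    J[:, 6] = a2 * c2 * u2 * g2 * (t - t2) / b2 ** 2
    J[:, 7] = -a1 * f1 * np.log1p(u1)
    J[:, 8] = a2 * f2 * np.log1p(u2)
    return J


@dataclass
class Phenophases:
    """Point-estimate phenophase dates and curve geometry for one fit."""

    ud: float
    sd: float
    dd: float
    rd: float
    gsl: float
    baseline: float
    maxline: float
    plateau_slope: float
    plateau_intercept: float
    min_gcc: float
    max_gcc: float
    flags: list[str] = field(default_factory=list)

    @property
    def range_gcc(self) -> float:
        return self.max_gcc - self.min_gcc

    @property
    def complete(self) -> bool:
        return all(np.isfinite(v) for v in (self.ud, self.sd, self.dd, self.rd))


@dataclass
class PhenophaseSet:
    """Ensemble-summarized phenophases: medians with 10th-90th intervals."""

    ud: float
    sd: float
    dd: float
    rd: float
    gsl: float
    ci_lower: dict = field(default_factory=dict)
    ci_upper: dict = field(default_factory=dict)
    baseline: float = np.nan
    maxline: float = np.nan
    plateau_slope: float = np.nan
    plateau_intercept: float = np.nan
    min_gcc: float = np.nan
    max_gcc: float = np.nan

    @property
    def range_gcc(self) -> float:
        return self.max_gcc - self.min_gcc


def phenophases_from_curve(
    t_grid: np.ndarray,
    y_grid: np.ndarray,
    dy_grid: np.ndarray | None = None,
    edge_fraction: float = 0.05,
) -> Phenophases:
    """Line-intersection phenophases from a curve sampled on a dense grid.

    Works for any smooth seasonal curve (double-logistic fit or spline).
    The derivative extrema are sought strictly inside the span, excluding an
    ``edge_fraction`` band at each end where smoothing splines wiggle; an
    extremum pinned to the band boundary means the curve has no interior
    green-up or senescence, and the corresponding phenophases are NaN and
    flagged rather than extrapolated.
    """
    t = np.asarray(t_grid, dtype=float)
    y = np.asarray(y_grid, dtype=float)
    dy = np.gradient(y, t) if dy_grid is None else np.asarray(dy_grid, dtype=float)
    flags: list[str] = []
    ymin, ymax = float(y.min()), float(y.max())
    edge = max(1, int(edge_fraction * len(t)))
    lo, hi = edge, len(t) - edge

    i_up = lo + int(np.argmax(dy[lo:hi]))
    i_dn = lo + int(np.argmin(dy[lo:hi]))
    ud = sd = dd = rd = np.nan
    plateau_slope = plateau_intercept = np.nan

    up_ok = dy[i_up] > 0 and lo < i_up < hi - 1
    dn_ok = dy[i_dn] < 0 and lo < i_dn < hi - 1
    if not up_ok:
        flags.append("no-greenup")
    if not dn_ok:
        flags.append("no-senescence")

    if up_ok:
        s = dy[i_up]
        ud = t[i_up] + (ymin - y[i_up]) / s
        sd = t[i_up] + (ymax - y[i_up]) / s
    if dn_ok:
        s = dy[i_dn]
        dd0 = t[i_dn] + (ymax - y[i_dn]) / s  # provisional: senescence x maxline
        rd = t[i_dn] + (ymin - y[i_dn]) / s
        dd = dd0
        if up_ok and np.isfinite(sd) and dd0 > sd:
            sel = (t >= sd) & (t <= dd0)
            if sel.sum() >= 2:
                plateau_slope, plateau_intercept = np.polyfit(t[sel], y[sel], 1)
                denom = plateau_slope - s
                if abs(denom) > 1e-12:
                    # senescence line: y = y[i_dn] + s (t - t[i_dn])
                    dd = (y[i_dn] - s * t[i_dn] - plateau_intercept) / denom
                    if not (sd <= dd <= rd):
                        dd = dd0
                        flags.append("plateau-intersection-out-of-range")
            else:
                flags.append("plateau-too-short")

    gsl = rd - ud if np.isfinite(rd) and np.isfinite(ud) else np.nan
    return Phenophases(ud=float(ud), sd=float(sd), dd=float(dd), rd=float(rd),
                       gsl=float(gsl), baseline=ymin, maxline=ymax,
                       plateau_slope=float(plateau_slope),
                       plateau_intercept=float(plateau_intercept),
                       min_gcc=ymin, max_gcc=ymax, flags=flags)


class GuDoubleLogistic(BaseEstimator):
    """Least-squares Gu double-logistic fit with multi-start initialization.

    Initialization: y0 at the 5th percentile of the data, both amplitudes at
    the 5th-95th percentile spread, inflections where the data first/last
    cross the midpoint, rate scales of 10 days and unit shape exponents —
    robust for low-amplitude signals — plus ``n_restarts`` jittered restarts
    drawn with a fixed seed. Bounds keep rates and shapes positive.

    Fitted attributes: ``params_`` (dict), ``popt_`` (array in
    GU_PARAM_NAMES order), ``fitted_values_``, ``residuals_``, ``rmse_``,
    ``converged_``, ``degenerate_`` (flat fit: amplitude below 1e-3).
    """

    def __init__(self, n_restarts: int = 5, seed: int = 0, max_nfev: int = 400):
        self.n_restarts = n_restarts
        self.seed = seed
        self.max_nfev = max_nfev

    # -- initialization ----------------------------------------------------
    def _initial_guesses(self, t, y, rng):
        p5, p95 = np.percentile(y, [5, 95])
        amp = max(p95 - p5, 1e-4)
        mid = p5 + 0.5 * amp
        above = y >= mid
        t1 = t[above][0] if above.any() else t[len(t) // 3]
        t2 = t[above][-1] if above.any() else t[2 * len(t) // 3]
        if t2 <= t1:
            t1, t2 = np.percentile(t, [30, 70])
        base = np.array([p5, amp, amp, t1, t2, 10.0, 10.0, 1.0, 1.0])
        guesses = [base]
        for _ in range(self.n_restarts):
            g = base.copy()
            g[3] += rng.uniform(-15, 15)
            g[4] += rng.uniform(-15, 15)
            g[5:7] *= rng.uniform(0.5, 2.0, 2)
            g[1:3] *= rng.uniform(0.7, 1.3, 2)
            guesses.append(g)
        return guesses

    def _bounds(self, t):
        span = t.max() - t.min()
        lo = [0.0, 0.0, 0.0, t.min() - 0.5 * span, t.min() - 0.5 * span,
              0.5, 0.5, 0.05, 0.05]
        hi = [1.0, 0.5, 0.5, t.max() + 0.5 * span, t.max() + 0.5 * span,
              120.0, 120.0, 20.0, 20.0]
        return np.array(lo), np.array(hi)

    # -- fitting -----------------------------------------------------------
    def fit(self, t, y, x0: np.ndarray | None = None):
        """Fit to day-of-year t and daily GCC y.

        ``x0`` (optional) replaces the multi-start schedule with a single
        warm start — used by the uncertainty replicates.
        """
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(t) & np.isfinite(y)
        t, y = t[ok], y[ok]
        if len(t) < 20:
            raise ValueError("need >= 20 daily values to fit")
        if t.max() - t.min() < 120:
            raise ValueError("need a span of >= 120 days to fit a season")
        lo, hi = self._bounds(t)
        rng = np.random.default_rng(self.seed)
        guesses = ([np.clip(np.asarray(x0, dtype=float), lo, hi)]
                   if x0 is not None else self._initial_guesses(t, y, rng))

        def resid(theta):
            return gu_model(t, *theta) - y

        def jac(theta):
            return _gu_jacobian(theta, t, y)

        best = None
        for g in guesses:
            g = np.clip(g, lo, hi)
            try:
                res = least_squares(resid, g, jac=jac, bounds=(lo, hi),
                                    method="trf", max_nfev=self.max_nfev)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("all optimizer starts failed")

        self.t_, self.y_ = t, y
        self.popt_ = best.x
        self.params_ = dict(zip(GU_PARAM_NAMES, best.x))
        self.fitted_values_ = gu_model(t, *best.x)
        self.residuals_ = y - self.fitted_values_
        self.rmse_ = float(np.sqrt(np.mean(self.residuals_ ** 2)))
        self.converged_ = bool(best.success and np.all(np.isfinite(self.fitted_values_)))
        self.degenerate_ = bool(self.fitted_values_.max() - self.fitted_values_.min() < 1e-3)
        return self

    def predict(self, t):
        return gu_model(np.asarray(t, dtype=float), *self.popt_)

    def derivative(self, t):
        return gu_derivative(np.asarray(t, dtype=float), *self.popt_)

    def params_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"params": {k: float(v) for k, v in self.params_.items()},
             "rmse": self.rmse_, "converged": self.converged_,
             "degenerate": self.degenerate_}, indent=2))


def fit_gu(daily_series: pd.DataFrame | tuple, n_restarts: int = 5,
           seed: int = 0) -> GuDoubleLogistic:
    """Fit the double-logistic model to a daily series (doy/gcc columns)."""
    if isinstance(daily_series, pd.DataFrame):
        t = daily_series["doy"].to_numpy(dtype=float)
        y = daily_series["gcc"].to_numpy(dtype=float)
    else:
        t, y = daily_series
    return GuDoubleLogistic(n_restarts=n_restarts, seed=seed).fit(t, y)


def extract_phenophases(fit: GuDoubleLogistic, grid_step: float = 0.02) -> Phenophases:
    """Point-estimate phenophases of a converged fit via line intersections.

    The curve and its analytic derivative are evaluated on a dense grid over
    the data span; a fit whose derivative extrema sit at the span edges
    yields partial results with flags, never extrapolated dates.
    """
    if not getattr(fit, "converged_", False):
        warnings.warn("extracting phenophases from a non-converged fit")
    t = np.arange(fit.t_.min(), fit.t_.max() + grid_step, grid_step)
    return phenophases_from_curve(t, fit.predict(t), fit.derivative(t))


@dataclass
class UncertaintyEnsemble:
    """Residual-resampling replicate fits and their phenophases."""

    replicates: pd.DataFrame  # columns ud, sd, dd, rd, gsl + parameters
    residual_envelope: tuple[float, float]
    n_requested: int
    n_failed: int

    @property
    def n_replications(self) -> int:
        return len(self.replicates)

    def to_csv(self, path: str | Path) -> None:
        self.replicates.to_csv(path, index=False)


def estimate_uncertainty(
    fit: GuDoubleLogistic,
    n: int = 1000,
    seed: int | None = None,
    max_failure_fraction: float = 0.2,
) -> UncertaintyEnsemble:
    """Phenophase uncertainty by uniform residual resampling.

    Each replicate perturbs every observation by an independent draw from
    Uniform(min residual, max residual) of the original fit, refits the
    double logistic (warm-started at the original parameters) and extracts
    phenophases. Replicates that fail to converge are dropped and counted;
    more than ``max_failure_fraction`` failures raises.
    """
    if n < 2:
        raise ValueError("need at least 2 replications")
    rng = np.random.default_rng(seed)
    lo, hi = float(fit.residuals_.min()), float(fit.residuals_.max())
    refitter = GuDoubleLogistic(n_restarts=0, seed=0, max_nfev=fit.max_nfev)
    rows = []
    n_failed = 0
    for _ in range(n):
        y_pert = fit.y_ + rng.uniform(lo, hi, size=len(fit.y_))
        try:
            rep = refitter.fit(fit.t_, y_pert, x0=fit.popt_)
        except Exception:
            n_failed += 1
            continue
        if not rep.converged_:
            n_failed += 1
            continue
        ph = extract_phenophases(rep)
        row = {"ud": ph.ud, "sd": ph.sd, "dd": ph.dd, "rd": ph.rd, "gsl": ph.gsl,
               "min_gcc": ph.min_gcc, "max_gcc": ph.max_gcc}
        row.update({k: float(v) for k, v in rep.params_.items()})
        rows.append(row)
    if n_failed > max_failure_fraction * n:
        raise RuntimeError(f"{n_failed}/{n} uncertainty replicates failed to converge")
    return UncertaintyEnsemble(replicates=pd.DataFrame(rows),
                               residual_envelope=(lo, hi),
                               n_requested=n, n_failed=n_failed)


def phenophase_confidence(
    ensemble: UncertaintyEnsemble,
    point: Phenophases | None = None,
) -> PhenophaseSet:
    """Median and 10th/90th-percentile phenophases from the ensemble.

    GSL is summarized per replicate (RD - UD within each replicate, then the
    median), so the reported GSL can differ from median RD minus median UD
    by a day when the replicate distributions are skewed.
    """
    reps = ensemble.replicates
    if len(reps) < 2:
        raise ValueError("need >= 2 surviving replicates")
    med, lo, hi = {}, {}, {}
    for k in ("ud", "sd", "dd", "rd", "gsl"):
        vals = reps[k].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        med[k] = float(np.median(vals)) if len(vals) else np.nan
        lo[k] = float(np.percentile(vals, 10)) if len(vals) else np.nan
        hi[k] = float(np.percentile(vals, 90)) if len(vals) else np.nan
    ps = PhenophaseSet(ud=med["ud"], sd=med["sd"], dd=med["dd"], rd=med["rd"],
                       gsl=med["gsl"], ci_lower=lo, ci_upper=hi)
    if point is not None:
        ps.baseline = point.baseline
        ps.maxline = point.maxline
        ps.plateau_slope = point.plateau_slope
        ps.plateau_intercept = point.plateau_intercept
        ps.min_gcc = point.min_gcc
        ps.max_gcc = point.max_gcc
    return ps


SUMMARY_COLUMNS = ["site", "ud", "ud_unc", "sd", "sd_unc", "dd", "dd_unc",
                   "rd", "rd_unc", "gsl", "gsl_unc", "min_gcc", "max_gcc",
                   "range_gcc"]


def summarize_roi(site: str, fit: GuDoubleLogistic, phen: PhenophaseSet) -> dict:
    """One summary record per ROI: dates +/- half the 10th-90th interval,
    annual min/max of the fitted curve and their range."""
    rec = {"site": site}
    for k in ("ud", "sd", "dd", "rd", "gsl"):
        rec[k] = getattr(phen, k)
        lo, hi = phen.ci_lower.get(k, np.nan), phen.ci_upper.get(k, np.nan)
        rec[f"{k}_unc"] = 0.5 * (hi - lo)
    rec["min_gcc"] = phen.min_gcc
    rec["max_gcc"] = phen.max_gcc
    rec["range_gcc"] = phen.range_gcc
    return rec
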