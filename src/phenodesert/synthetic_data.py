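"""Synthetic phenocam data with known ground truth.

Generates sub-daily GCC series, snow contamination and whole rendered image
stacks that emulate a semi-arid phenocam deployment: five frames per day
between 08:00 and 18:00, vegetation pixels following low-amplitude
double-logistic seasonal trajectories (amplitudes 0.01-0.06 over baselines
near 0.31-0.33), flat noisy interspace, optional high-variance woody/shadow
pixels, and ephemeral winter snow events that depress GCC into a distinct
low band. Every generator returns the ground truth alongside the data so
each processing stage can be benchmarked without field imagery.

The phenophase truth is computed by a dense-grid numerical oracle
(:func:`phenophase_oracle`) that is deliberately self-contained: it shares
no code with the extraction geometry in :mod:`phenodesert.fitting`, so
fitting-module tests against it are not circular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from phenodesert.fitting import gu_model

#: wet-meadow-like seasonal parameters (amplitude 0.062 over baseline 0.327)
WET_MEADOW_PARAMS = dict(y0=0.327, a1=0.062, a2=0.062, t1=140.0, t2=235.0,
                         b1=7.0, b2=12.0, c1=1.0, c2=1.0)

#: pinyon-like low-amplitude evergreen parameters (amplitude ~0.019)
PINYON_PARAMS = dict(y0=0.333, a1=0.019, a2=0.019, t1=135.0, t2=280.0,
                     b1=9.0, b2=14.0, c1=1.0, c2=1.0)

CLASS_INTERSPACE, CLASS_VEGETATION, CLASS_WOODY = 0, 1, 2


def phenophase_oracle(gu_params: dict, t_span=(1.0, 365.0), step: float = 0.02) -> dict:
    """Ground-truth phenophases of a noiseless double-logistic curve.

    Dense-grid numerical computation: finite-difference derivative, tangent
    lines at the derivative extrema, horizontal base/max lines at the curve
    extremes, plateau line fit between SD and the provisional DD. Returns a
    dict with ud/sd/dd/rd/gsl/min_gcc/max_gcc.
    """
    t = np.arange(t_span[0], t_span[1] + step, step)
    y = gu_model(t, **gu_params)
    dy = np.gradient(y, t)
    ymin, ymax = y.min(), y.max()
    iu, idn = int(np.argmax(dy)), int(np.argmin(dy))
    su, sdn = dy[iu], dy[idn]
    if su <= 0 or sdn >= 0:
        raise ValueError("curve has no green-up or no senescence in the span")
    ud = t[iu] + (ymin - y[iu]) / su
    sd = t[iu] + (ymax - y[iu]) / su
    dd0 = t[idn] + (ymax - y[idn]) / sdn
    rd = t[idn] + (ymin - y[idn]) / sdn
    dd = dd0
    sel = (t >= sd) & (t <= dd0)
    if sel.sum() >= 2:
        pslope, pint = np.polyfit(t[sel], y[sel], 1)
        denom = pslope - sdn
        if abs(denom) > 1e-12:
            cand = (y[idn] - sdn * t[idn] - pint) / denom
            if sd <= cand <= rd:
                dd = cand
    return {"ud": float(ud), "sd": float(sd), "dd": float(dd), "rd": float(rd),
            "gsl": float(rd - ud), "min_gcc": float(ymin), "max_gcc": float(ymax)}


def _oracle_or_none(params: dict, t_span) -> dict | None:
    """Oracle phenophases, or None when the span holds no full transition."""
    try:
        return phenophase_oracle(params, t_span)
    except ValueError:
        return None


def _sample_times(days, samples_per_day: int, start_hour: float, end_hour: float,
                  year: int):
    hours = np.linspace(start_hour, end_hour, samples_per_day)
    times, fdoy = [], []
    for d in days:
        for h in hours:
            times.append(datetime(year, 1, 1) + timedelta(days=int(d) - 1, hours=float(h)))
            fdoy.append(d + h / 24.0)
    return times, np.array(fdoy)


def generate_gcc_series(
    gu_params: dict,
    days=(1, 365),
    noise_sigma: float = 0.003,
    samples_per_day: int = 5,
    seed: int | None = None,
    start_hour: float = 8.0,
    end_hour: float = 18.0,
    year: int = 2015,
    roi_name: str = "synthetic",
):
    """Sub-daily GCC series from a double-logistic curve plus Gaussian noise.

    Returns (series DataFrame in the imagery schema, truth dict). The truth
    carries the generating parameters and the oracle phenophases of the
    noiseless curve. Parameters that push GCC outside (0, 1) raise.
    """
    day_arr = np.arange(int(days[0]), int(days[1]) + 1)
    times, fdoy = _sample_times(day_arr, samples_per_day, start_hour, end_hour, year)
    clean = gu_model(fdoy, **gu_params)
    if clean.min() <= 0 or clean.max() >= 1:
        raise ValueError("parameters produce GCC outside (0, 1)")
    rng = np.random.default_rng(seed)
    gcc = clean + rng.normal(0.0, noise_sigma, size=len(fdoy))
    rcc = (1.0 - gcc) * 0.52          # red slightly above blue, as at dry sites
    bcc = 1.0 - gcc - rcc
    df = pd.DataFrame({
        "timestamp": times,
        "doy": np.floor(fdoy).astype(int),
        "roi": roi_name,
        "gcc": gcc, "rcc": rcc, "bcc": bcc,
        "n_pixels": 1,
    })
    truth = {"params": dict(gu_params), "noise_sigma": noise_sigma,
             "phenophases": _oracle_or_none(gu_params, (days[0], days[1]))}
    return df, truth


def inject_snow(
    series: pd.DataFrame,
    event_spans,
    gcc_low: float = 0.20,
    gcc_high: float = 0.27,
    fraction: float = 1.0,
    seed: int | None = None,
):
    """Contaminate samples inside day spans with a low snow GCC band.

    ``event_spans`` is a list of (start_doy, end_doy) inclusive spans;
    overlapping spans are merged with a warning. Within the spans, each
    sample is snowed with probability ``fraction`` and its GCC redrawn from
    Uniform(gcc_low, gcc_high). Returns a copy with a boolean ``snow``
    label column retained for filter benchmarking.
    """
    spans = sorted((float(a), float(b)) for a, b in event_spans)
    merged: list[list[float]] = []
    for a, b in spans:
        if merged and a <= merged[-1][1]:
            warnings.warn("overlapping snow spans merged")
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    out = series.copy()
    out["snow"] = False
    if not merged:
        return out
    rng = np.random.default_rng(seed)
    doy = out["doy"].to_numpy(dtype=float)
    in_span = np.zeros(len(out), dtype=bool)
    for a, b in merged:
        in_span |= (doy >= a) & (doy <= b)
    snowed = in_span & (rng.random(len(out)) < fraction)
    out.loc[snowed, "gcc"] = rng.uniform(gcc_low, gcc_high, int(snowed.sum()))
    out.loc[snowed, "rcc"] = (1.0 - out.loc[snowed, "gcc"]) * 0.52
    out.loc[snowed, "bcc"] = 1.0 - out.loc[snowed, "gcc"] - out.loc[snowed, "rcc"]
    out["snow"] = snowed
    return out


def whiten_image(pixels: np.ndarray, dn: int = 230) -> np.ndarray:
    """Snow-on-frame model: brightness elevated, chromatics flattened to 1/3."""
    return np.full_like(pixels, dn)


@dataclass
class SceneSpec:
    """Layout and dynamics of a synthetic camera scene."""

    height: int = 20
    width: int = 20
    class_map: np.ndarray | None = None          # codes 0/1/2; default: center patch
    vegetation_params: dict = field(default_factory=lambda: dict(WET_MEADOW_PARAMS))
    interspace_level: float = 0.315
    woody_level: float = 0.32
    woody_range: float = 0.45                    # shadow-driven day-to-day swing
    noise_sigma: float = 0.003
    images_per_day: int = 5
    day_range: tuple[int, int] = (1, 365)
    snow_spans: list = field(default_factory=list)
    brightness: int = 450                        # target R+G+B digital-number sum
    seed: int = 0
    year: int = 2015

    def __post_init__(self):
        if self.class_map is None:
            cm = np.zeros((self.height, self.width), dtype=np.int8)
            r0, r1 = self.height // 4, 3 * self.height // 4
            c0, c1 = self.width // 4, 3 * self.width // 4
            cm[r0:r1, c0:c1] = CLASS_VEGETATION
            self.class_map = cm
        else:
            self.class_map = np.asarray(self.class_map, dtype=np.int8)
            if self.class_map.shape != (self.height, self.width):
                raise ValueError("class_map shape must match (height, width)")


def _class_trajectory(spec: SceneSpec, code: int, fdoy: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    if code == CLASS_VEGETATION:
        return gu_model(fdoy, **spec.vegetation_params)
    if code == CLASS_WOODY:
        # slow large-amplitude shadow swings: smooth random walk around level
        walk = np.cumsum(rng.normal(0, spec.woody_range / 40.0, len(fdoy)))
        walk -= walk.mean()
        walk = np.clip(walk, -spec.woody_range / 2, spec.woody_range / 2)
        return spec.woody_level + walk
    return np.full(len(fdoy), spec.interspace_level)


def generate_pixel_trajectories(spec: SceneSpec):
    """Per-pixel daily GCC stack + truth, without rendering image files.

    Returns (days, gcc stack of shape (n_days, H, W), truth dict). The truth
    holds the class map and the oracle phenophases of the vegetation class.
    """
    rng = np.random.default_rng(spec.seed)
    days = np.arange(spec.day_range[0], spec.day_range[1] + 1)
    fdoy = days.astype(float)
    stack = np.empty((len(days), spec.height, spec.width))
    base = {code: _class_trajectory(spec, code, fdoy, rng)
            for code in np.unique(spec.class_map)}
    for code, traj in base.items():
        sel = spec.class_map == code
        noise = rng.normal(0, spec.noise_sigma, (len(days), int(sel.sum())))
        stack[:, sel] = traj[:, None] + noise
    truth = {
        "class_map": spec.class_map.copy(),
        "vegetation_phenophases": _oracle_or_none(
            spec.vegetation_params, (float(days[0]), float(days[-1]))),
    }
    return days, stack, truth


def _dn_from_chromatics(gcc: np.ndarray, brightness: int):
    """Solve 8-bit (R, G, B) from target gcc at fixed total brightness."""
    gcc = np.clip(gcc, 0.0, 1.0)
    rcc = (1.0 - gcc) * 0.52
    g = np.clip(np.round(gcc * brightness), 0, 255)
    r = np.clip(np.round(rcc * brightness), 0, 255)
    b = np.clip(brightness - g - r, 0, 255)
    return np.stack([r, g, b], axis=-1).astype(np.uint8)


def render_scene(spec: SceneSpec, outdir: str | Path, fmt: str = "png"):
    """Write timestamped frames realizing each pixel's chromatic trajectory.

    Frames are named ``scene_%Y_%m_%d_%H%M.<fmt>``; PNG (lossless) keeps the
    chromatic round-trip error within DN quantization (<= 1/255 per channel).
    Truth maps (class map CSV and vegetation phenophase truth) are written
    alongside. Returns (list of frame paths, truth dict).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    days = np.arange(spec.day_range[0], spec.day_range[1] + 1)
    times, fdoy = _sample_times(days, spec.images_per_day, 8.0, 18.0, spec.year)
    base = {code: _class_trajectory(spec, code, fdoy, rng)
            for code in np.unique(spec.class_map)}
    snow_days = set()
    for a, b in spec.snow_spans:
        snow_days.update(range(int(a), int(b) + 1))
    paths = []
    noise = {code: rng.normal(0, spec.noise_sigma,
                              (len(fdoy), int((spec.class_map == code).sum())))
             for code in base}
    for i, ts in enumerate(times):
        gcc = np.empty((spec.height, spec.width))
        for code, traj in base.items():
            sel = spec.class_map == code
            gcc[sel] = traj[i] + noise[code][i]
        frame = _dn_from_chromatics(gcc, spec.brightness)
        if int(np.floor(fdoy[i])) in snow_days:
            frame = whiten_image(frame)
        name = f"scene_{ts.strftime('%Y_%m_%d_%H%M')}.{fmt}"
        path = outdir / name
        Image.fromarray(frame, mode="RGB").save(path)
        paths.append(path)
    truth = {
        "class_map": spec.class_map.copy(),
        "vegetation_phenophases": _oracle_or_none(
            spec.vegetation_params, (float(days[0]), float(days[-1]))),
    }
    np.savetxt(outdir / "truth_class_map.csv", spec.class_map, fmt="%d", delimiter=",")
    if truth["vegetation_phenophases"] is not None:
        pd.DataFrame([truth["vegetation_phenophases"]]).to_csv(
            outdir / "truth_vegetation_phenophases.csv", index=False)
    return paths, truth
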