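# phenodesert

Phenocam image processing for **low-amplitude vegetation signals** — the
kind produced by semi-arid shrublands, evergreen conifer canopies and cold
desert meadows, where the whole seasonal greenness cycle may span only
0.01–0.06 units of the green chromatic coordinate.

Repeat digital cameras record 8-bit RGB digital numbers (DN). Greenness is
summarized per region of interest (ROI) by the green chromatic coordinate

```
GCC = G_DN / (R_DN + G_DN + B_DN)
```

with RCC and BCC defined analogously. At sparse-vegetation sites this signal
is fragile: ephemeral snow, shadows and exposure artifacts depress GCC by
more than the seasonal amplitude itself. phenodesert provides the full
processing chain:

- **imagery** — timestamped JPEG/PNG loading, polygon ROI masks (pixel
  centers, boundary inclusive), ROI-averaged or per-pixel chromatic
  extraction (ratio-of-means by default).
- **filtering** — the canonical chain *(snow/)night → spline → max*:
  a fixed night threshold (GCC < 0.2), an **automated snow/night filter**
  that finds a data-driven threshold as the first breakpoint of a segmented
  regression on the lower range of the GCC CDF (snow forms a distinct low
  population that breaks the CDF's linearity), an iterative smoothing-spline
  filter for downward outliers, and a 3-day moving-window 90th-percentile
  ("max") filter that yields a daily series. Plus a 3-day moving average for
  environmental covariates.
- **fitting** — the Gu-style double logistic
  `y(t) = y0 + a1/(1+exp(-(t-t1)/b1))^c1 - a2/(1+exp(-(t-t2)/b2))^c2`
  fitted by bounded least squares with multi-start initialization;
  phenophase dates by line intersection (recovery/senescence tangents at the
  derivative extrema, baseline/maxline at the curve extremes, a plateau line
  between SD and DD to handle mid-season greendown): **UD** (upturn),
  **SD** (stabilization), **DD** (downturn), **RD** (recession),
  **GSL = RD − UD**. Uncertainty by uniform residual resampling (1000
  replicate refits by default) with 10th–90th percentile intervals; reported
  dates are ensemble medians, not the single best fit.
- **spatial** — per-pixel ("spatiotemporal") phenology: regression-spline
  fits per pixel, phenophase maps, UD/RD histogram-window filtering that
  separates vegetation from interspace, GCC-range maps, and a changepoint
  split of the interspace into bare ground vs woody material/shadow.
- **synthetic_data** — generators for everything above with analytic ground
  truth (dense-grid phenophase oracle), including rendered image stacks.
- **cli** — `phenodesert simulate|extract|filter|fit|spatial|all`.

Filter and fit steps are sklearn-style estimators (`NightFilter`,
`SnowNightFilter`, `SplineFilter`, `MaxFilter`, `GuDoubleLogistic`,
`PixelPhenologyMapper`) with `fit`/`transform`/`predict` and trailing-
underscore fitted attributes; module-level functions wrap them.

## Worked example

Simulate a wet-meadow-like year (amplitude 0.062 over a 0.327 baseline,
5 frames/day, noise σ = 0.003 GCC) with ephemeral winter snow, then run the
filter chain and the fit:

```python
from phenodesert import synthetic_data as sd, filtering, fitting

series, truth = sd.generate_gcc_series(sd.WET_MEADOW_PARAMS,
                                       noise_sigma=0.003, seed=42)
series = sd.inject_snow(series, [(1, 100), (330, 365)], fraction=0.4, seed=43)

daily, report = filtering.apply_filter_chain(series)
fit = fitting.fit_gu(daily, seed=0)
ens = fitting.estimate_uncertainty(fit, n=1000, seed=0)
phen = fitting.phenophase_confidence(ens, fitting.extract_phenophases(fit))

print(f"snow threshold: {report.snow_threshold:.3f}  "
      f"removed: {report.n_removed_snow} snow / {report.n_removed_spline} spline")
for k in ("ud", "sd", "dd", "rd"):
    print(f"{k.upper()} {getattr(phen, k):5.1f}  "
          f"({phen.ci_lower[k]:.1f}-{phen.ci_upper[k]:.1f})")
print(f"GSL {phen.gsl:.1f} days   GCC range {phen.range_gcc:.3f}")
```

which prints:

```
snow threshold: 0.294  removed: 260 snow / 62 spline
UD 125.2  (124.6-125.9)
SD 152.8  (152.2-153.4)
DD 212.8  (211.9-213.7)
RD 259.7  (258.9-260.4)
GSL 134.4 days   GCC range 0.061
```

The snow filter learned a 0.294 GCC threshold from the CDF breakpoint —
above the snow band (≤ 0.27) and below the clean winter baseline (≈ 0.32) —
and removed 260 contaminated samples. The fitted phenophases sit within a
day or two of the generator's analytic truth (UD 126.0, SD 153.7, DD 213.7,
RD 259.0, GSL 133.0), and the parenthesized ranges are the 10th–90th
percentiles of the 1000-replicate uncertainty ensemble.

The same pipeline from the shell:

```sh
phenodesert all --out run/ --height 10 --width 10 --seed 1
```

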