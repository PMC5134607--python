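# Methods

This note documents the models, numerical choices and open design decisions
behind phenodesert, and what the synthetic-data benchmarks do and do not
establish about real camera deployments.

## Chromatic coordinates and ROI conventions

Greenness is the green chromatic coordinate GCC = G/(R+G+B) of 8-bit digital
numbers; RCC and BCC are analogous, so the three coordinates sum to one and
are invariant to a common brightness rescaling of a pixel. Pixel coordinates
are 0-based (row, col), origin top-left; a pixel belongs to a polygon ROI
when its center lies inside or on the boundary (implemented with exact
geometric predicates, tested against a brute-force point-in-polygon scan).
Zero-DN pixels carry no chromatic information and are excluded, never
clamped; the excluded fraction is logged.

Two ROI-averaging conventions exist in the field. The default is
*ratio of means* — the chromatic coordinate of the per-channel mean DN —
because a mean of per-pixel ratios lets dark pixels (tiny denominators, high
variance) dominate. *Mean of ratios* is available via
`extract_chromatic(..., convention="mean-of-ratios")`.

Timestamps are local camera time parsed from filenames; cameras run a fixed
clock, so no DST handling is attempted.

## Filter chain

The chain is applied in the fixed order **(snow/)night → spline → max**
(`apply_filter_chain` refuses other orders unless explicitly overridden):

1. **Night filter** removes samples with GCC strictly below a threshold
   (default 0.2 GCC): poorly exposed, dark or white-balance-skewed frames.
   Samples exactly at the threshold are retained.
2. **Snow/night filter** replaces the fixed threshold with a data-driven
   one. Sorted GCC is regressed on its empirical cumulative fraction;
   ephemeral snow produces a distinct low-GCC population that appears as a
   breakpoint in the lower range of this CDF. The search is restricted to
   the lowest 50% of the sample: the upper range of a clean seasonal series
   is itself curved (the quantile function of a bimodal baseline/peak
   mixture) and would otherwise mask the contamination break. The threshold
   is the midpoint between the last sample of the first segment and the
   first sample of the second — the least arbitrary value inside the gap.
   The learned threshold never undercuts the fixed night floor (0.2): the
   snow filter augments, not replaces, the night filter. With no supported
   breakpoint the filter degrades to the fixed night filter.
3. **Spline filter** iteratively (default 2 passes) fits a cubic smoothing
   spline (GCV-selected smoothing via `scipy.interpolate.make_smoothing_spline`;
   the `lam` parameter is exposed for manual control) and removes samples
   whose residual is below −2 SD. Only downward outliers are removed:
   at these sites artifacts depress greenness, they do not inflate it.
4. **Max filter** reduces to daily resolution: for each calendar day with
   at least one retained sample in the centered 3-day window, the 90th
   percentile (linear interpolation between order statistics — the
   convention matters for 3-point windows) of all sub-daily GCC in the
   window. Edge days use the truncated window.

Environmental covariate series get a centered 3-day moving mean with edges
and gaps averaging over whatever neighbors exist, consistent with the 3-day
image window.

### Breakpoint model selection

Segmented regression on sorted values cannot use iid-error penalties:
order-statistic deviations are strongly autocorrelated, and BIC/SIC accept a
spurious two-segment model on perfectly homogeneous data with probability
near one (measured: 100% false positives on sorted uniform samples of 200).
Model selection therefore uses an **RSS-ratio rule**: a split is accepted
only when it reduces the residual sum of squares of the local segment by a
calibrated factor. The critical ratios were calibrated on homogeneous nulls
against two-population mixtures in the regimes this package targets:

- CDF breakpoint (lower-range search): nulls — sorted uniform, Gaussian and
  clean seasonal series — reach ratios of at most ~40; snow mixtures with
  ≥ 0.04 GCC separation and 10–30% contamination stay above ~98.
  Critical ratio **50**.
- Mean changepoint on sorted values (interspace split): unimodal nulls stay
  below ~6; bimodal bare-ground/woody mixtures exceed ~28. Critical ratio
  **10**.

The minimum breakpoint segment sizes are asymmetric: the lower (first)
segment may be as small as 5% of the sample — snow contamination can be a
small fraction — while the upper segment must hold the configured
`min_segment_fraction` (default 15%), which is where spurious tail breaks
would otherwise appear. Up to three segments are searched by recursive
binary segmentation; the smallest-rank accepted breakpoint defines the
threshold, and equal-RSS ties resolve to the smallest threshold.

## Double-logistic model and phenophases

Daily GCC is modeled as

    y(t) = y0 + a1 (1 + e^{-(t-t1)/b1})^{-c1} − a2 (1 + e^{-(t-t2)/b2})^{-c2}

with baseline y0 (GCC), amplitudes a1/a2 (GCC), inflections t1/t2 (DOY),
rate scales b1/b2 (days, > 0) and shape exponents c1/c2 (> 0). Fitting is
bounded trust-region least squares with an analytic Jacobian. Initialization:
y0 at the 5th percentile, both amplitudes at the 5th–95th spread, t1/t2 at
the first/last midpoint crossings, b = 10 d, c = 1, plus five jittered
restarts drawn from a fixed seed — multi-start matters for low-amplitude
signals where the loss surface is shallow. A fit whose curve spans less than
10⁻³ GCC is flagged degenerate. Preconditions: ≥ 20 daily values spanning
≥ 120 days (anything less cannot constrain a seasonal cycle).

Phenophases come from the line-intersection geometry: the recovery line is
tangent to the curve at the maximum of dy/dt, the senescence line at the
minimum; the baseline and maxline are horizontal at the fitted curve's
minimum and maximum over the data span (the fitted minimum, not a pre-season
data statistic). UD = recovery ∩ baseline, SD = recovery ∩ maxline,
RD = senescence ∩ baseline. For DD, a **plateau line** is first fit by OLS
through the fitted values between SD and the provisional DD (senescence ∩
maxline), in a single pass; the final DD is senescence ∩ plateau. With
mid-season greendown the plateau line lies below the maxline at the
senescence crossing, so the adjusted DD falls at or after the provisional
one — it tracks the curve's visible departure from the plateau trend rather
than a maxline the curve no longer attains.

Derivative extrema are located on a dense grid (0.02-day steps for the
double logistic, 0.25 for per-pixel splines) restricted to the interior of
the span: a 5% edge band is excluded because smoothing splines wiggle at the
boundary, and an extremum pinned to the band edge is flagged (`no-greenup`,
`no-senescence`) rather than extrapolated. Phenophases of flagged curves are
NaN; GSL = RD − UD is only defined when both ends are.

### Uncertainty

Each of n replicates (default 1000; scaled studies use 200) perturbs every
observation by an independent draw from Uniform(min residual, max residual)
of the original fit, refits warm-started at the original parameters, and
extracts phenophases. Replicates that fail to converge are dropped and
counted; more than 20% failures aborts. Reported dates are the ensemble
medians with 10th–90th percentile intervals; **GSL is summarized per
replicate** (median of within-replicate RD − UD), which is why a reported
GSL can differ from median RD minus median UD by a day for skewed ensembles.
On noiseless input the residual envelope collapses and all replicates are
identical — intervals of width zero, by construction.

## Per-pixel (spatiotemporal) analysis

Per-pixel daily trajectories are aggregated from sub-daily per-pixel GCC by
the same 90th-percentile convention as the max filter. Each valid pixel
(≥ 20 daily values) gets a cubic regression spline with approximately n/8
degrees of freedom bounded to [6, 30] — the upper bound matters: 20 df on a
full-year series means ~23-day knot spacing, which under-resolves a 7-day
green-up and biases UD by more than a day against the ROI-average fit on
homogeneous scenes; 30 df (~14-day spacing) brings the two within half a
day. Full double-logistic fits per pixel fail too often on single-pixel
noise to be usable, and no uncertainty ensemble is computed per pixel (the
cost scales with pixel count; the histogram filter plays the plausibility
role instead).

Before dates are extracted, a **signal-detectability screen** excludes
pixels whose smoothed seasonal range falls below 12× the spline's sampling
noise floor (residual SD × sqrt(df/n)): such a "trajectory" is
indistinguishable from smoothing noise and any date drawn from it would be
arbitrary. On flat-noise scenes ~0.3% of pixels leak through the screen,
while 0.02-amplitude vegetation keeps a ~2× margin above it. Set
`min_signal_factor=0` to disable.

Pixels are classified by the **histogram window**: vegetation requires UD
within [50, 170] and RD within [170, 330] DOY (defaults; the bounds are
inputs). Pixels outside either window — diffuse noise-wiggle dates,
including the RD-before-UD cases that produce negative GSL — become
interspace, and GSL is only mapped for vegetation, where the window bounds
make negative values impossible. An automatic window (histogram mode ±
max(2×MAD, 10 days)) is available for scenes without a manual choice; it is
this package's own construction and the manual window remains the default.

Per-pixel seasonal GCC range is max − min of the spline-smoothed curve by
default (raw extremes are available) so single-sample spikes do not set the
range. The interspace class is split into bare ground (lower) vs woody
material/shadow (upper) by a single mean changepoint on the CDF ordering of
the ranges, with the ratio rule above; when no changepoint is supported a
single class is reported with its median and 10th–90th percentiles.

## Synthetic data

The generators emulate the deployment regime the package targets: five
frames per day between 08:00 and 18:00 local time over a calendar year;
vegetation following double-logistic trajectories with amplitudes
0.016–0.062 GCC over baselines near 0.31–0.33 (wet-meadow-like and
pinyon-like presets included); flat interspace near 0.315; Gaussian sample
noise σ = 0.003 GCC; snow as a distinct low band (Uniform(0.20, 0.27) by
default) injected into day spans — ephemeral spring pulses plus dense
late-year cover — or, in rendered frames, whole-frame whitening (R≈G≈B, so
GCC → 1/3, below the > 1/3 vegetated baselines). Rendered frames realize a
target (gcc, rcc) at fixed brightness R+G+B = 450, giving quantization
error ≤ 0.5/450 per coordinate; PNG output keeps the round trip lossless.

Ground-truth phenophases come from a dense-grid numerical oracle
(`phenophase_oracle`) that is deliberately self-contained — finite
differences and explicit line intersections, sharing no code with the
extraction path — so recovery tests are not circular.

What the benchmarks do **not** show: the generators use stationary Gaussian
noise, a single unimodal season, geometrically exact (unshifted) frames and
a step-function snow model. Real deployments add camera shifts, exposure
drift, lens flare, partially snow-covered frames and (in monsoon climates)
bimodal seasons; the double logistic cannot represent bimodality, and the
filters are not tested against correlated multi-day artifacts other than
snow. Passing tests establish correctness of the algorithms under the
stated regime, not robustness to every field condition.

## Reported-summary identities

The per-ROI summary table reports UD/SD/DD/RD medians ± half the 10th–90th
interval, GSL, and the fitted curve's annual minimum, maximum and range
(range = max − min). The acceptance script verifies the arithmetic
identities on the published medians only for rows where the printed medians
are internally consistent (per-replicate GSL summarization makes
median-RD − median-UD differ from the reported GSL by a day in some rows).

## Problem sizes in the test and acceptance studies

Recovery and power studies use 20 noiseless curves, 100 contaminated series,
50 coverage repeats × 200 replications, and 20×20-pixel scenes; these sizes
give stable pass/fail margins (measured recovery 100%, coverage 90–100%,
classification ≥ 99%) while keeping a full run near one minute on one CPU.
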