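# Methods

## Problem and data model

A track-while-scan avian radar reports per-scan detections ("plots")
associated into tracks. To verify how far out a target of known radar
cross section (RCS) is detectable, a calibrated UAV flies known patterns
through the coverage while its GPS records truth positions at 1 Hz. The
analysis consumes two streams per flight test: the GPS track (time, planar
x/y in projected metres, altitude AGL) and the radar plots (time, planar
position in the radar frame). All geometry is 2-D; ranges are horizontal
ground ranges and altitude never enters range or bearing. Bearings are
degrees clockwise from grid north.

## Clock synchronization

The two clocks differ by an unknown per-test offset `T`. For a candidate
`T`, each radar plot is paired with the GPS position linearly interpolated
at the shifted time, and the regression `D² = β₀ + β₁ΔR² + β₂ΔB²` is
fitted by ordinary least squares (`D` pair distance, `ΔR` range
difference, `ΔB = sin(α/2)(R_radar + R_gps)` the transverse term from the
bearing difference `α`). The score of `T` is the Gaussian log-likelihood
of this fit — maximizing it over `T` is equivalent to minimizing the
residual variance of `D²`. The search is a 1-s grid over the window
(default [0, 120] s) followed by bounded golden-section refinement to
10⁻³ s on the bracketing interval; grid ties break toward the smaller
offset.

Two deliberate choices: GPS positions are interpolated (radar plot times
never are), and the objective is the *total* log-likelihood with a
minimum-pairs guard (n ≥ 5). The number of usable pairs varies with `T`
because plots shifted outside the GPS span are dropped; with the
residual-variance scale of real data (tens of m²·m² at the optimum) the
per-pair likelihood dominates the pair-count effect, and recovery tests
confirm sub-half-second accuracy at 5–10 m plot noise. Offsets are
estimated per flight test; a global offset would hide inter-test clock
drift.

## Scan opportunities and nondetections

Expected detection opportunities are laid out every `60/scan_rate`
seconds (22.5 scans/min → 2.667 s) from the first to the last detection
of a test. An opportunity with a paired plot within ± half the scan
interval is a detection; all others are nondetections. Truth positions at
every opportunity are GPS interpolants (a radar-interpolant option would
leave nondetections without positions at track gaps, so GPS truth is the
default). Per-opportunity covariates: range and bearing from the radar,
tortuosity `S = 1 − (cos ΔH + 1)/2` of the truth trajectory at the
opportunity cadence (undefined at ends), and orientation.

Orientation compares the course over ground with the radial direction
from the radar: `along` when `|cos α| > cos 45°`, else `across`; the tie
`|cos α| = cos 45°` is classified `across` (the inequality is strict).
Whether the published covariate measured the angle against the radial or
the beam tangent is ambiguous; both readings are selectable
(`mode="radial"` default, `"tangent"` swaps the classes).

## Clutter

Ground clutter is modelled as the set of terrain cells in line-of-sight
of the antenna. The viewshed samples the terrain profile under each
sightline at half-cell steps with bilinear interpolation; nodata blocks
(with a warning). Earth curvature and refraction are ignored by default —
at ≤4 km the curvature drop is `d²/2R_e < 1.3 m` and a 4/3-Earth option
exists. Clutter membership of a flight position is evaluated at its
ground projection (the mask is a 2-D GIS layer); cells are half-open
`[x, x+cs) × [y, y+cs)`. A pre-computed mask can be supplied directly,
bypassing terrain, since observer/target heights and DEM resolution of an
external GIS workflow are often not reproducible.

## Screening

Take-off/landing altitudes (terrain obscuration) and sharp turns (tracker
stress) degrade detection for reasons unrelated to range. Thresholds are
found by segmented regression: observations are ranked into 50
equal-count bins on the covariate, per-bin detection rates computed, and
every interior bin edge scored as a breakpoint of a two-segment
piecewise-constant model by total sum of squared residuals; the
minimum-SSR edge wins, ties resolving toward retaining more data. Binned
rates (rather than raw 0/1 outcomes) are used because rate steps are the
quantity of interest; the piecewise-constant form is the simplest model
consistent with a partitioning threshold. The cumulative standard
deviation of binned rates is emitted as a plotting diagnostic only.
Exclusions drop altitude below / tortuosity above threshold; undefined
tortuosity at track ends is retained (only positive evidence excludes).

## Detection model

`logit(Pd_ij) = x_ij'β + u_j`, `u_j ~ N(0, σ²)` per track. The marginal
likelihood integrates `u` out per track by adaptive Gauss–Hermite
quadrature: 15 nodes recentred at the per-track mode (Newton iteration on
the scalar conditional) and scaled by the Laplace curvature. The check
against brute-force numerical integration holds to better than 10⁻⁴, and
fits agree with R's `lme4::glmer` (nAGQ=15) to ~10⁻³ on coefficients,
standard errors, σ and log-likelihood. Optimization is BFGS on
`(β_scaled, log σ)` with covariate columns scaled to unit order;
convergence is declared at gradient norm 10⁻⁶ on the scaled problem
(the gradient is numerically differenced, which bounds the attainable
tolerance near 10⁻⁵–10⁻⁶). The Wald covariance is the inverse observed
information, computed by central differences at the optimum.

Derived quantities:

* **Detection range**: solve `x'β = logit(pd)` for range at reference
  covariates (along-beam, tortuosity 0, outside clutter — the published
  convention is implicit; these defaults are configurable), CI by the
  delta method. The 0.5 default threshold reflects the tracker's
  tolerance of losing every other detection.
* **Clutter contrast**: Pd outside vs inside clutter at a reference
  range, which defaults to the mean observed range of the fitted data
  (the published contrast is clearly not evaluated at range 0; the value
  used is recorded in the result). The reduction CI is delta-method on
  the log-ratio; point CIs are logit-scale intervals mapped through the
  inverse logit.
* **Blip/scan ratio**: detections/opportunities in left-closed 25-m bins;
  the automated stand-in for the traditional visual read takes the first
  bin where a 5-bin centred moving average stays below threshold for 3
  bins. Note this read carries binomial jitter of roughly ±130 m at
  2–3×10³ opportunities; the model-based range is the primary estimate.

Range enters linearly on the logit scale (the processed output of a
tracker does not follow the raw `R⁻⁴` law); detection theory
(Swerling-1 + radar equation) is kept for extrapolation, not for the
within-campaign fit.

## RCS and extrapolation

Conversions: `RCS[m²] = 10^{dBm²/10}`. Swerling-1 per-scan detection:
`Pd = Pfa^{1/(1+SNR)}` (Pfa default 10⁻⁶); SNR scales as `(r_ref/r)⁴`.
The calibrated range `R_d` at reference RCS `RCS_d` extrapolates to
`R_i = (10^{RCS_i/10}/10^{RCS_d/10})^{1/4} R_d`. Uncertainty bounds use
the quartiles of the reference-target calibration: the 75th percentile
gives the lower bound (a hotter reference implies the same range was
easier), the 25th the upper. Bird RCS from mass uses the equivalent
water-sphere: 65% water content, density 1 g/cm³, optical-region sphere
factor 0.56, no frequency dependence. The shipped species RCS table is a
convenience fixture of published S-band group values; masses are user
inputs otherwise.

## Synthetic campaigns

The generator's model is exactly the analysis model, run generatively, so
recovery is well-posed: waypoint flights resampled at constant speed and
1 Hz, cruise altitude 70 m with a 1.2 m/s take-off/landing ramp,
opportunities at the scan cadence, true
`Pd = logistic(β₀ + β_r·R + β_c·clutter + β_o·across + β_t·S + u)`,
Bernoulli draws, isotropic Gaussian plot noise (5 m), per-test offsets
uniform in [10, 110] s. Two additional truth terms give the screens a
real signature: logit penalties (−4) below 27 m AGL and above tortuosity
0.33, emulating terrain obscuration of low flight and tracker failure on
sharp turns — outside the screened region the fitted model is correctly
specified. Default truth: `β₀ = 3.136`, `β_r = −0.00134 /m` (Pd = 0.5 at
2,340 m), `β_c = −0.615`, `β_o = −0.3`, `β_t = −0.5`, `σ = 0.4`.

The default campaign is 7 range flights (two out-and-back radial cycles,
200–3,100 m, ≈230 opportunities each) and 6 clutter flights zig-zagging
through a sector whose clutter is two annular bands — an analytic mask
standing in for a GIS viewshed, chosen so each clutter track mixes in/out
cells and along/across segments, keeping the clutter and orientation
effects identified within tracks. Everything is a deterministic function
of (config, seed).

What the simulator does **not** emulate: aspect-dependent RCS lobes,
weather and dynamic clutter, tracker track-association failures beyond
the tortuosity penalty, GPS error, or scan-time jitter (off by default —
the cadence is treated as regular). Passing recovery tests therefore
demonstrates the statistical machinery, not robustness to these field
effects. Optional model-violation toggles (e.g. zero penalties, other
β values) support sensitivity checks.

## Numerical conventions

Zero range maps to bearing 0; coincident points give undefined course and
tortuosity (NaN, excluded by callers); turning angles wrap to
(−180°, 180°]; segmented-regression breakpoints are reported at bin
edges; detection-range CIs are clipped at 0; complete separation or wild
coefficient scales mark a fit non-converged rather than raising.

## Known limitations

* The blip/scan crossing read is noisy at realistic campaign sizes (see
  above); treat it as the traditional cross-check it replaces.
* Wald/delta CIs can be optimistic with few tracks (7–13 here); a seeded
  parametric bootstrap is a natural extension and is not implemented.
* The offset estimator assumes a constant offset per test; clock drift
  within a flight is out of scope.
* Reproduction of the original field campaign's numbers requires its raw
  data export (GPS + radar CSVs under `data/study/`), which is not
  distributable with the package; the corresponding test states this
  explicitly when the data is absent.
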