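# Methods

This note documents the models behind `ribotrace`, the defaults and why
they were chosen, the numerical decisions that affect results, and what the
synthetic-data generator does and does not emulate.

## Signal model of a microchip-CE trace

A trace is fluorescence vs migration time on a uniform grid (default 70 s
at 20 Hz, 1400 points). Migration time is modelled log-linearly in RNA
size,

    t(s) = t_ref + b · log10(s / s_ref),

with defaults `t_ref = 49 s` at `s_ref = 2000 nt` and `b = 23.3 s/decade`.
These three numbers jointly place a 2000 nt construct at 49 s, a 4000 nt
HMW species at ~56 s and the fragment smear at roughly 31–45 s — the
characteristic geometry of a short microchip separation of a vaccine-scale
mRNA. A log-linear law is the simplest monotone migration model consistent
with those anchors; the ladder fit keeps its residuals so curvature on a
real instrument would be visible rather than silently absorbed.

A generated sample trace contains:

* a **lower marker** (internal standard) at 19 s, fixed area 30 signal·s,
  σ = 0.4 s — present in every injection, excluded from all analyte
  denominators;
* a **main peak** at `t(construct_size)`, σ = 0.4 s, area proportional to
  `concentration × intact_fraction`;
* a **fragment smear**: 15 Gaussians (σ = 0.8 s) at sizes geometrically
  spaced over [150 nt, 0.7 × construct]. The lower bound sits at 150 nt
  rather than deeper into the small-fragment range so the smallest
  component (~22.8 s) stays clear of the marker exclusion window; fragments
  that co-migrate with the marker are unmeasurable by construction in this
  assay geometry;
* an optional **HMW species** at twice the construct size (σ = 1.2 s),
  representing incompletely denatured structure. It appears only when the
  preparation is non-denaturing (formamide < 40% v/v and unheated);
  otherwise its share of the signal folds into the main peak, conserving
  total area — heating removes the artifact, it does not destroy mRNA;
* **detector noise**: additive white Gaussian noise (default SD 1.0 signal
  units) plus polynomial baseline drift (default: linear, 2 units over the
  run), all driven by one seed per trace.

Total non-marker area is `100 signal·s per (µg/mL) × concentration ×
f(Brij)`, with `f` a linear detergent response normalised to 1 at 10% w/v
Brij (1.35 at 1.25%, 0.8 at 15%). The detergent affects only the overall
scale, never the percentages — the documented dye-binding/viscosity
signal-loss phenomenon reduced to its analytically relevant consequence.
Peak widths were set so adjacent ladder rungs are baseline-resolved; the
ladder defaults to eight transcripts at 200, 500, 1000, 1500, 2000, 3000,
4000, 6000 nt (config, not constants — commercial ladder compositions
vary).

### Stability studies

`simulate_stability_study` applies first-order decay to the intact
fraction,

    I(T, t) = I0 · exp(−k(T) · t),    k(T) = exp(lnA − Ea·10³/(R·T)),

with `Ea = 74.8 kJ/mol` by default and `lnA = 25.712` (1/day), anchoring
the refrigerated (4 °C) rate at ~10 integrity points lost from 80% over 90
days (k ≈ 1.17×10⁻³/day). An activation energy plus a single-temperature
anchor cannot reproduce every temperature's timeline simultaneously; the
4 °C observation was chosen as the anchor because it is the one used for
shelf-life extrapolation. The fragment smear gains exactly the area the
main peak loses, so total analyte area is conserved across all (T, t) —
degradation redistributes signal, it does not remove it. Ground-truth
integrity curves are returned alongside the traces for parameter-recovery
testing. Default design: −20, 4, 25, 37, 45, 60 °C pulled at 0, 4, 7, 14,
30, 60, 90 days. Temperatures are °C at every interface and converted once
(T_K = T_C + 273.15) at the kinetics boundary.

## Baseline and integration

The baseline is a straight line through robust (median) levels of two
peak-free anchor windows — the pre-marker region (first 12 s) and the
post-run tail (last 5 s). Noise SD is 1.4826 × MAD of the anchor residuals.
A linear baseline exactly absorbs constant offsets and linear drift;
higher-order drift leaves a residual that the tests bound.

Regions on the baseline-corrected, zero-clipped signal:

* fragment region: from the calibrated time of 100 nt (clipped at the
  marker exclusion edge) to the **dropped line**;
* main region: dropped line to the **upper cut**;
* HMW region: upper cut to end of run.

The dropped line is the local signal minimum within ±15% (in size) of
0.75 × construct size, falling back to exactly 0.75 × when no interior
minimum exists; the upper cut applies the same rule at 1.5 × construct
size. No placement rule is published for vendor integration software, so
this valley-plus-deterministic-fallback rule is the package's own, chosen
to be reproducible and to degrade gracefully on featureless signals.

Numerical decisions:

* all three region areas are read off a single cumulative trapezoid
  integral, so they partition the total exactly and the percentages sum to
  100 at machine precision;
* negative excursions are clipped to zero before integration (areas must
  be non-negative; a documented divergence risk vs vendor software);
* the marker exclusion zone is ±2.4 s (6 σ) around the detected marker
  apex, making the marker's tail contribution to analyte areas negligible
  (< 10⁻⁸ relative);
* noise SDs below 10⁻⁹ of the signal maximum are treated as exactly zero,
  so noiseless traces keep machine-precision code paths (no smoothing, an
  exact log-parabolic apex);
* a trace is flagged `no-signal` when no point beyond 5 σ of the marker
  exceeds max(3 × noise SD, 10⁻³ × marker height); percentages are then
  reported as missing, never as zero;
* the HMW region is always reported, even when empty, so result schemas
  are stable.

Known bias: fragment components adjacent to the dropped line leak part of
their tail into the main region, so the measured % main runs ~0.5–1.5
points above/below truth depending on composition (visible in the README
example: 80% programmed, 79.3% measured). The bias is shared across a
stability series and largely cancels in `ln I(t)/I(0)`, which is why
kinetic parameters recover to well under 2% through the full noisy
pipeline.

## Peak detection and size calibration

Peaks are local maxima of the baseline-corrected signal (Savitzky–Golay
smoothed, window 11 / order 3, only when noise is present) with prominence
≥ 2% of the signal maximum and S/N ≥ 3. Apexes are refined by parabolic
interpolation — on log-signal for noiseless data, where it is exact for
Gaussians. Bounds are the nearest flanking local minima.

The ladder fit excludes the lower marker (earliest peak in the 15–22 s
window) and regresses apex time on log10(size). Extra candidate peaks are
dropped by keeping the n largest by area (with a warning); missing peaks
abort calibration listing the detected times. The calibration is a
straight line, not a spline: eight points do not support more flexibility,
and the generator's migration law is exactly log-linear, so residuals
directly expose any real-instrument curvature. Sizes outside the ladder's
span are reported but flagged as extrapolated.

## Qualification statistics

* **Recovery**: theoretical purity of a designed mixture is the
  mix-fraction-weighted arithmetic mean of the component purities
  (equal-concentration assumption, the standard design); a
  concentration-weighted option exists. Recovery = observed/theoretical ×
  100.
* **Precision**: %CV with the sample (n−1) SD — the small-n replicate
  convention.
* **Linearity**: OLS of total area on concentration; R² as squared Pearson
  correlation, defined as 0 for a flat response.
* **LOD/LOQ**: lowest concentrations reaching S/N 3 and 10, interpolated
  linearly in log-concentration because dilution series are geometric. A
  series entirely above (below) threshold is flagged `<min` (`>max`)
  rather than extrapolated.
* **Specificity**: pass iff every empty-LNP blank is flagged `no-signal`.
* **Purity-level LOQ**: the percentage readout needs a quantifiable
  fragment region, not just a detectable main peak. A broad smear's
  height-based S/N understates how well its area is determined, so the
  criterion is the integrated S/N — region area over the white-noise
  contribution to that area (noise SD × Δt × √n points) — at threshold 10.
  This is a separate reported quantity with its own definition; it is not
  the peak-level LOQ.

## Kinetics

`fit_first_order` regresses `ln I(t)/I(0)` on time; the default
**initial-rate** mode uses the first three positive timepoints (the rate
before depletion effects), **full-curve** uses all of them and is the mode
of choice for synthetic validation. Points at 0% integrity are excluded
(log undefined) and counted, so fully degraded series are visibly
censored. Negative fitted rates are clamped to zero with a warning.

`fit_arrhenius` regresses ln k on 1/T; Ea = −slope·R/1000 in kJ/mol. When
per-temperature standard errors of k are available (they are, from the
first-order fits), the regression is weighted least squares with known
variances, parameter covariance (XᵀWX)⁻¹: the scatter of ln k about the
line is then the propagated rate-constant uncertainty, which the weights
encode, and cold-temperature rates with huge relative errors are naturally
down-weighted instead of distorting the slope. Plain OLS (residual-based
SEs) is used when no uncertainties are supplied. R² is always reported on
the unweighted points. When replicate studies are supplied, the
study-level spread of Ea is the honest uncertainty and can be computed by
fitting each study separately.

`predict_time_to_loss` implements both extrapolation conventions and never
mixes them: first-order, `t = −ln(1 − loss)/k`; zero-order, `t = loss ×
start/rate` with the rate in percentage points per day. From the same
refrigerated observation (10 points lost from 80% over 90 days) these give
~592 and 360 days to 50% loss respectively — a factor the reporting keeps
explicit because a constant-points-per-day reading of slow early decay is
common in stability practice even when the underlying chemistry is
first-order.

## What the generator does not emulate

Electrokinetic injection bias, Joule heating, dye-binding chemistry and
run-to-run migration drift beyond the single marker offset are not
modelled; detergent and denaturation effects are reduced to their area
consequences. Real fragment smears need not be 15-component Gaussian
mixtures, real migration laws need not be exactly log-linear, and real
noise is not exactly white. Passing tests therefore demonstrate that the
analysis correctly recovers the quantities its model class defines — not
that vendor-software integration of a particular instrument's traces would
be numerically reproduced.

## Problem sizes

Monte-Carlo suites use 100 seeds throughout (blank specificity, linearity,
S/N tracking, noisy ladder calibration, Arrhenius coverage); stability
studies use the full 6 × 7 design; traces are 1400 points. The complete
test battery runs in well under a minute on one core.
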