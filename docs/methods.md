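# Methods

## Scope and model

The pipeline analyses direction tuning of single units recorded under
drifting gratings with and without optogenetic manipulation of PV+
interneurons. Firing-rate tuning is modelled as a two-harmonic von Mises
function in the exponential form

R(θ) = exp(a0 + κ(cos 2(θ−φ) − 1) + v(cos(θ−φ) − 1)),

which is strictly positive, peak-anchored (R(φ) = e^{a0} when κ, v > 0) and
flexible enough to capture asymmetric direction tuning because the two
harmonics do not force the secondary peak to sit exactly 180° away. The
preferred and non-preferred orientations are therefore defined as the
global maximum and minimum of the fitted curve rather than at fixed angular
offsets.

One printed form of the half-bandwidth reference level is ambiguous between
"midpoint of fitted max and min" and "half of the fitted max"; the midpoint
convention R_NP + (R_P − R_NP)/2 is used, as it is the only reading that
always lies between the curve's extremes.

Circular variance is computed on the raw trial-mean rates for the
selectivity screen (CV > 0.96 excludes a unit) and on the fitted curve for
effect metrics. Folding to orientation (direction mod 180°) happens inside
the CV; fitting operates on the full 0–360° direction domain.

## Effect classification

The classifier works on the difference ΔT and ratio RT of the
lower-firing-rate versus higher-firing-rate fitted curves, a convention
that makes PV activation and inactivation symmetric (the low-rate curve is
the laser curve under activation but the control curve under inactivation).
ΔT and its derivatives are evaluated on the smooth difference of the two
fitted curves, never on raw rates, which would be noise-dominated.

The sign tests at θ_P are computed scale-free: the second (fourth)
finite-difference derivative of ΔT is divided by the magnitude of the
matching derivative of the high-rate curve. For any smooth map f from the
high-rate to the low-rate curve, ΔT″(θ_P) = (f′ − 1)·T″_high(θ_P), so the
normalised statistic equals gain − 1 for a pure gain change (positive,
because the peak curvature is negative) and is negative for a tuned,
sharpening effect. This removes the dependence on the unit's absolute rate
and curvature that makes raw-derivative thresholds ill-conditioned. The
dead zone is ±0.1 for the second-derivative statistic and 0.05 for the
quartic one; within it the quartic sign decides (flat-topped, Mexican-hat
ΔT counts as non-linear, matching the flat-at-peak rule).

For downward-peak units, the multiplicative ratio
MR = FrC_NP/FrC_P − FrL_NP/FrL_P decides between a pure gain change and
"other". The operation-level default threshold is |MR| < 0.02. The
pipeline, however, screens at |MR| < 0.1: under the default study
conditions (10 Poisson trials per direction, ~20 Hz peak rates) the
sampling spread of MR for an exactly multiplicative unit is about ±0.05, so
the tighter cutoff would reject roughly a third of true gain-change samples
per intensity and, because the unit label requires the same call at every
intensity, almost all of them at the unit level. The 0.1 value was
calibrated once on a gain-change-only cohort and is exposed as
`analyze_cohort(mr_threshold=...)`.

Unit labels require unanimity across intensities (DM or NL), a mixture of
both calls gives MIX, anything else (including unmatched waveforms, which
are an input flag, not re-derived) is unclassified. The control curve of a
unit is fitted from control trials pooled across intensities — the visual
stimulus is identical in every control block, so pooling only reduces
estimator variance — while ΔFr always uses the per-intensity control mean.

## Threshold linear model

R_laser = max(0, a·R_control + b), fitted by nonlinear least squares on
fitted-curve samples at the stimulus directions, initialised from the
unrectified ordinary-least-squares line. Rectification is included for PV
activation and omitted for inactivation (laser responses there only move
up). Fits are unweighted; R² is 1 − SS_res/SS_tot on the laser rates. The
model sharpens tuning only through the iceberg effect, which is what the
model comparison exploits.

## Escape-rate I/O model

rate = exp(β(u − ϑ)). The transform's absolute parameters are not
identifiable from a single curve — any (β₀, ϑ₀) baseline merely shifts and
scales the inferred membrane curve, and the fitted (β, ϑ) compensate
exactly (verified to 1e-9 in the tests) — so the higher-rate curve is
inverted under the convention β = 1, ϑ = 0 after normalising rates to peak
1 and flooring at 1e-3 of peak (the inverse transform needs positive
rates). Fitting (β, ϑ) to the low-rate curve uses bounded least squares on
rates with a log-linear regression start plus multi-starts at
β ∈ {0.5, 1, 2, 4}; exponential fits are sensitive to initialisation.

For the NL pathway the membrane curve is first gain-scaled around the
resting potential: u_rest is the inverse transform of the (peak-normalised)
spontaneous rate, and TML = α(TMC − u_rest) + u_rest. Re-adding u_rest
after scaling makes rest a fixed point of the gain; the alternative (not
re-adding) is a pure offset absorbed by ϑ and was not adopted. α is
estimated from the same cohort as 1 + mean ΔFr of granular-layer units at
that intensity (the granular population shows gain changes, and its output
is the extra-granular drive), defaulting to 1 when no granular units exist.
Whether the fit's independent variable for NL units should be the scaled
(TML) or unscaled (TMC) membrane curve is exposed as
`analyze_cohort(nl_fit_mode=...)`, default TML. When no measured
spontaneous rate is supplied the minimum of the fitted control curve is
used as a proxy.

## Synthetic cohorts

The generator realises both laser mechanisms exactly: control rates are the
von Mises curve (equivalently, the escape-rate transform of a membrane
curve under the baseline convention); D/M units get a threshold shift,
which is exactly multiplicative in rate space; NL units get a β-steepening
plus a ϑ-drop on an α-scaled membrane drive. Trial spike counts are Poisson
with mean rate × 1 s — the standard stand-in for cortical count
variability, and it makes parameter-recovery targets well-posed.

Defaults emulate the recording protocol and sample: 24 directions, 10
repeats per condition, 1 s stimuli; ~8% opsin-tagged PV+ units (rate
effects sign-flipped, no tuning change) and ~20% non-selective units
(κ = v = 0); 70% D/M in the granular layer and 70% NL extra-granularly;
κ ∈ [0.4, 1.2] and v ∈ [0, 0.3], chosen so the cohort's OSI (~0.4–0.85),
CV (~0.55–0.85) and HBW (~30–43°) cover the reported population ranges;
peak rates log-normal around 20 Hz; spontaneous rates log-normal around
2 Hz, floored at 0.1 Hz (the inverse transform of zero is undefined).

The laser-intensity ladder is parameterised by its target ΔFr — the proxy
used throughout for manipulation strength — with four rungs per direction
(activation: −0.15, −0.40, −0.60, −0.80; inactivation: +0.15, +0.50,
+0.80, +1.50, the last being the "extra-high" regime, which exists only for
rate increases). For NL units the ladder's β-scale is the net exponent
change seen by the downstream fit; since the α-compression of the membrane
drive and the intrinsic steepening compose multiplicatively, the intrinsic
steepening applied is β-scale/α. The threshold drop is then solved in
closed form so the mean rate hits the target ΔFr exactly. Trial counts per
intensity are configurable rather than fixed, since interleaved-intensity
protocols do not pin them.

What the generator does not emulate: spike timing (counts only), waveform
shape and spike-sorting artefacts, eye-movement-driven nonstationarity,
contrast/SF/TF dependence, unit-to-unit rate correlations, and any mixed
or intermediate effect mechanism. Passing tests therefore show that the
analysis recovers the two postulated mechanisms under Poisson variability
at realistic rates — not that real cortical data contain only these
mechanisms.

The laminar fixtures plant a current sink (band-limited transient with a
Gaussian depth profile and distance-increasing latency) and optionally a
coherence band (shared 20–35 Hz signal over a contact range); both are
recovered by construction and serve the layer-assignment stage.

## Laminar assignment

The CSD is the negative finite-difference second spatial derivative of the
1–100 Hz zero-phase band-passed, trial-averaged LFP, z-scored per contact
against the pre-stimulus baseline (a kernel-based CSD estimator would
change smoothness, not the sink location/timing the criteria use). Edge
contacts are undefined (NaN); numerically-zero CSD columns are kept at
z = 0 rather than amplified by the baseline normalisation. Neighbour
coherence uses the trial-ensemble magnitude-squared coherence estimator in
equal-length stimulus and baseline windows, baseline-subtracted. Sink
latency is the first crossing below −2 z after stimulus onset.

The top of cortex is one contact above the most superficial spiking
contact; the white-matter border is the first contact beyond 1.6 mm from
the top whose evoked multi-unit rate falls below 30% of the column median
(fallback: 1.9 mm). The granular band is the ~325 µm window (300–350 µm,
rounded to contact spacing, configurable) maximising an equally weighted
composite of four z-scored depth profiles — evoked rate, short
inter-spike interval, neighbour coherence, early sink — because no
weighting among these criteria is specified; weights are configurable. If
every profile is flat the band defaults to the geometric middle of the
cortex with a warning.

## Population statistics

Units recorded at several intensities enter regressions as independent
rows (as the source analyses do); paired tests are two-sided Wilcoxon
signed-rank; ΔFr bins are L (0–33%), M (33–66%), H (66–100%) on magnitude
and XH (>100%, increases only). Population-average curves are normalised
to each curve's peak and circularly aligned, using the control-condition
preferred orientation for both conditions of a unit (the manipulation does
not move the preferred orientation). Degenerate paired tests (all
differences zero) return p = 1.

## Numerical choices

* Rates are floored at 1e-9 Hz inside the von Mises fit; κ, v < 1e-6 counts
  as flat; R² is clipped to [0, 1].
* The von Mises fit multi-starts φ at the grid argmax and its antipode;
  extrema are refined by bounded scalar minimisation after a 0.5° scan;
  half-bandwidth crossings use bisection (1e-10 tolerance).
* RT is masked where the high-rate curve is below 0.5 Hz; an everywhere-flat
  ΔT (max |ΔT| < 1e-6 Hz) is unclassifiable.
* Dense fitted-curve grids use 0.1° steps.
* CSV outputs round-trip byte-identically when read with
  `read_table` (float_precision="round_trip").

## Problem sizes

Cohort-level tests and the end-to-end checks run 200 units × 4 intensities
× 24 directions × 10 trials (≈ 384k trial rows, ~20 s for the full
analysis on one core); statistical-calibration checks use 1000 replicates
at n = 500. The analytic targets are instantaneous.

## Known limitations

* The classifier's MR screen and derivative dead zones are calibrated to
  the default noise level; markedly different trial counts or rates warrant
  re-calibration (both are exposed as parameters).
* The I/O fit assumes the high-rate curve is noiseless once fitted; very
  weak or near-flat units propagate fit error into β, ϑ.
* Layer assignment assumes a single contiguous cortical column with one
  granular band; no six-layer parcellation, no histological registration.
* Regressions treat repeated units as independent by default; a
  cluster-robust standard error (`metric_regression(cluster=...)`) is
  available for sensitivity analyses but there is no mixed-effects
  modelling and no multiple-comparison correction.
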