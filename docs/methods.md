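# Methods

This note documents the models, algorithms and design choices behind
`trnapore`, in the spirit of the methods documentation that simulation and
statistics packages ship alongside their APIs.

## Signal model and synthetic squiggle generator

The generator (`trnapore.synthetic_squiggle`) emulates a single-channel
alpha-hemolysin recording of adapter-ligated RNA:

* **Open channel.** One level per trace, drawn uniformly from the open
  channel band (default 68.0–72.5 pA), held between blockade events.
* **Blockade events.** Each planted event is an ordered sequence of
  piecewise-constant states: abasic marker states (levels inside
  33.5–36.5 pA), low-current RNA states (levels below 26.5 pA), and
  mid-range adapter/RNA states. Event templates exist for the four marker
  categories (both markers, leading only, trailing only, other). The
  leading (5') marker is rendered long (≈30–80 ms) and the trailing (3')
  marker short (≈3–8 ms), reflecting the faster translocation after the
  duplex is unzipped; the qualifying low state is ≥15 ms. Within-event
  sub-state dwells beyond the marker/low minimums are free parameters of
  the generator and are drawn from fixed log-uniform ranges.
* **Dwell times.** Blockade durations follow log-normal populations
  parameterised in log10 seconds. A `DwellModel` stores the population
  log10 mean, the SEM of that mean for a reference sample, and the
  reference sample size (default 200), so the population SD is
  `sem * sqrt(n_reference)`. The module ships the characterised
  populations: adapter alone 10^−3.9±0.04 s; adapted tRNA-fMet
  10^−2.6±0.06 s (no Mg²⁺) and 10^−1.4±0.1 s (5 mM Mg²⁺); adapted RNA
  hairpin 10^−3.2±0.02 s; hairpin + polymerase 10^−2.9±0.09 s (unbound
  fraction) and 10^0.43±0.03 s (braked fraction).
* **Noise and filtering.** White Gaussian noise is added at the digitiser
  rate (default 100 kHz), then the trace is passed through a causal
  4-pole low-pass Bessel filter at 5 kHz emulating the instrument's
  analog stage. The default noise SD (3.0 pA pre-filter) yields ≈1 pA
  post-filter RMS, typical of these recordings.
* **Placement.** Inter-event gaps are exponential at the configured event
  rate, floored at 10 ms so the open channel can re-establish; 10%
  open-channel padding is appended. Events with explicit positions are
  checked for overlap and rejected with a diagnostic.
* **Ground truth.** The manifest records half-open sample bounds of every
  state of every event on the unfiltered plant, plus the event's truth
  category and class label.

The generator makes no attempt to model electrophoresis physics, enzyme
stepping kinetics, Mg²⁺-dependent fold stabilisation beyond its effect on
dwell times, or 1/f and pore-gating noise: its noise is white-plus-filter
only, and its states are ideal levels. Passing tests on this synthetic
signal therefore demonstrate correctness of the *analysis* (detection,
segmentation, rule classification, statistics), not performance on real
traces, whose state levels drift, flicker and overlap bands.

A feature-level generator (`make_two_class_cohort`) draws region I–III
(duration, mean current) features directly. Default calibration: regions I
and III share one model across both classes (region I: 10^−1.1 s,
SD 0.15 log10; 33.0 ± 1.0 pA; region III: 10^−2.2 s, SD 0.2; 35.0 ±
0.8 pA), while region II differs (class A: 10^0.30 s, 26.0 ± 1.5 pA;
class B: 10^0.55 s, 29.0 ± 1.5 pA; SD 0.25 log10 both). The region II
separation (≈1 SD in log-duration, 2 SD in current) puts the Bayes-optimal
accuracy near 0.87, so the cross-validated region II accuracy lands in the
high 80s (percent) while regions I/III sit at chance — the qualitative
pattern a real two-species experiment shows, at a desk-scale n of 80
events per class.

## Filtering

`bessel_lowpass` designs the filter from the analog Bessel prototype
(magnitude-normalised, so the requested cutoff is the −3 dB point; default
2 kHz, 4 poles) via bilinear transform, and applies it causally,
initialised at the steady state of the first sample so constant input is
preserved from sample 0. A zero-phase mode (forward–backward) exists for
use inside the pipeline, where re-filtering must not add a second timing
delay. The low-frequency group delay of the causal design (≈6.7 samples at
5 kHz/100 kHz) is exposed for boundary correction.

## Event detection

Detection is threshold-based with an explicit open-channel state machine:

1. The open channel is *established* when the trailing 1 ms moving
   average lies inside the open band — a debounce that also enforces ≥1 ms
   of validated open channel between consecutive events.
2. An event *opens* at the first sample below the entry cutoff
   (default 55 pA; 45 pA is the stricter alternative) after establishment.
3. An event *closes* at the last upward cutoff crossing before the
   current re-enters the open band; the re-entry itself marks the event
   self-terminating. Closing on the cutoff rather than on the open-band
   re-entry gives both boundaries the same threshold timing: the open-band
   crossing sits at 92–99% of the rising step, so its delay varies with
   the random open level (up to ~15 samples), while the cutoff crossing is
   mid-step and tight.
4. Events cut off by the end of the trace are flagged not self-terminated;
   events shorter than the minimum duration (default 0.1 ms) and events
   containing negative current (voltage-reversal ejection) are discarded.

Because the analog anti-aliasing stage delays every threshold crossing by
its (flat) group delay, detected boundaries are corrected by that constant
when the trace metadata records the analog filter cutoff (the simulator
writes it; the correction can be overridden or disabled). With correction,
planted-event boundaries are recovered within ≤2 samples at default noise;
the pipeline's acceptance checks require ≤5.

Long-event selection keeps self-terminating events with duration >1 s,
the population analysed for marker patterns.

## Band segmentation

Marker rules apply to segment *means*, not raw samples, so samples are
provisionally labelled from a 0.5 ms moving-average level with 0.5 pA
hysteresis at the band edges (leaving the marker or low band requires the
smoothed level to move beyond the edge by the hysteresis; entering from
MID uses the plain thresholds). Run boundaries are then snapped onto the
raw signal: around each smoothed boundary, the first raw sample closer to
the following run's mean than to the preceding run's mean becomes the
boundary, which recovers exact transitions on noise-free input and is
unbiased under symmetric noise.

Runs shorter than their band minimum (markers 2 ms, low 10 ms) are
relabelled MID. Sub-minimum MID runs (<1 ms) flanked by two band runs are
merged, shortest first, into the neighbour with the closer mean (earlier
neighbour on ties) — this removes both noise flicker inside a long marker
and the transition slivers the smoothing creates between bands, while MID
runs at the event edges are always kept. Finally, any surviving
marker/low segment whose raw mean violates its band definition is demoted
to MID. The resulting segments tile the event exactly, adjacent segments
differ in band, and every marker/low segment satisfies its mean and
duration invariants by construction.

## Marker-rule classification

A *qualifying marker* is a marker segment with mean in 33.5–36.5 pA and
duration ≥2 ms; a *qualifying low* has mean <26.5 pA and duration ≥10 ms.
With M the number of qualifying markers:

* `LEADING_AND_TRAILING`: M = 2, at least one qualifying low strictly
  between the two markers, and the trailing marker *proximal to
  termination* — its end within the final 10% of the event or within
  50 ms of the end, whichever window is larger. Proximity is not
  quantified in the source description; these constants are this
  package's choice and are configurable.
* `LEADING_ONLY`: M = 1 with every qualifying low after the marker.
* `TRAILING_ONLY`: M = 1 with every qualifying low before the marker.
* `OTHER`: everything else (no markers, >2 markers, or a marker pattern
  without its required low). MID segments are tolerated anywhere.

Classification is a pure function of the segment list, the event duration
and the config; a brute-force oracle that evaluates these predicates
directly on plain tuples agrees with the implementation on 10,000 random
band sequences straddling all qualification thresholds.

Complete-translocation selection keeps `LEADING_AND_TRAILING` events with
exactly two qualifying markers.

**Percentage rounding.** Category tables report one-decimal percentages by
largest-remainder (Hamilton) apportionment: each share is floored at 0.1%
resolution and the leftover tenths go to the largest fractional
remainders, so the printed column always sums to exactly 100.0% and each
entry differs from the exact share by at most 0.1. Plain round-half is
used for isolated fractions (`fraction_pct`).

## Region I–III features

For a complete translocation, region I = [event start, end of leading
marker), region II = [end of leading marker, start of trailing marker),
region III = [start of trailing marker, event end). The pre-marker adapter
signal is assigned to region I and the post-marker exit to region III so
that the three regions are a partition of the event — where exactly the
hand-measured regions began is not specified in the source analysis, and
this choice is the one that makes durations additive. Each region is
summarised by duration and arithmetic mean current of its raw samples.

## Discrimination

Features are (log10 duration, mean pA) per region; no scaling beyond the
log10 transform is applied by default (an optional standardise flag
z-scores features internally and folds the scaling back into the reported
boundary). The boundary is a soft-margin linear SVM (hinge loss, C = 10),
fit with scikit-learn's C-SVC; a kernlab (`ksvm`, `vanilladot`, C = 10,
unscaled) reference fit is used as an independent cross-check in the test
suite and agrees with the fitted boundary to within 5%.

Cross-validation: per repeat, the data are freshly shuffled and split into
five groups whose sizes differ by at most one; each group is held out once.
Fifty repeats give 250 balanced-accuracy scores; the mean and SD (ddof 1)
are reported together with the boundary fit on the full data. Folds whose
training or test split lacks a class are skipped with a warning, since
balanced accuracy is undefined there; at the default cohort size (n = 160)
this does not occur. A single integer seed drives all shuffles, so a fixed
seed reproduces the report exactly.

Population statistics: `population_log_stats` returns the mean and SEM of
log10 durations; `compare_populations` is a two-tailed Welch (unequal
variance) t-test on log10 durations — the plain "two-tailed t-test" is
underspecified, and Welch is the safer default for dwell populations of
unequal spread. Two degenerate zero-variance samples compare to p = 1 when
equal and p = 0 when not.

## Pipeline and reproducibility

`run_pipeline` validates a YAML config against an explicit schema
(unknown keys and inconsistent thresholds are rejected with the offending
key paths), then runs simulate → filter (2 kHz, zero-phase by default) →
detect → select (>1 s) → segment → classify → tabulate → region features →
discriminate, writing every table through `signal_io` plus a provenance
record (config hash, seed, package version, stage counts — no wall-clock
values, so identical config + seed give byte-identical artifacts). One
master seed derives all stage seeds (each below 2³¹).

## Problem sizes

The shipped checks use desk-scale problems chosen to exercise every stage
at full operating parameters (100 kHz sampling, 5 kHz analog emulation):
300 planted short blockades for detection recovery; a 372-event long-event
cohort planted with the observed dual-abasic category composition
(102/160/25/85), simulated in chunks of 47 events to cap memory; 80 events
per class for the discrimination cohort; 10⁴ draws per dwell model; and
200 events per arm for the dwell-population comparison.

## Known limitations

* Real traces violate the ideal-level assumption (state flicker, baseline
  drift, correlated pore noise); segmentation constants (0.5 ms smoothing,
  0.5 pA hysteresis, 1 ms MID minimum) were chosen for the synthetic noise
  model and would need re-tuning on instrument data.
* The marker proximity window and the region partition convention are this
  package's own quantifications of qualitative rules.
* Only two-class, linear-boundary discrimination is implemented; no
  multiclass extension, nonlinear kernels, or probability calibration.
* Vendor electrophysiology containers (e.g. ABF) are not parsed natively;
  traces must be converted to the columnar text or HDF5 interchange
  formats.
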