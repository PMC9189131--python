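# Methods

This note documents the models, conventions, and parameter choices behind
the package, in the order the pipeline runs.

## Locomotor scoring by frame subtraction

Consecutive frames of the behavior channel are subtracted and the
**absolute** difference is used — movement produces intensity changes of
both signs, and the absolute value makes the score symmetric under
contrast inversion. A pixel counts as *changed* when its absolute
difference **strictly** exceeds the calibrated threshold.

**Threshold calibration.** All consecutive-pair difference images of a
worm-free (empty-chamber) recording are pooled into one sample of pixel
values; the threshold is `mean + 5·SD` with the population (ddof = 0)
standard deviation. At the recommended ≥ 2000 calibration frames the
population/sample distinction is negligible (relative difference
< 3·10⁻⁵); population SD is used because the pooled pixels are treated
as the complete calibration population.

**Activity rule.** A time point is locomotor-active when the
changed-pixel count strictly exceeds 100 (chamber mode). In
artificial-dirt (plate) mode, a time point is quiescent when the count is
strictly below 1% of the worm's body size in pixels; body size is
estimated per recording as the median over frames of the Otsu-foreground
pixel count, since the original measurement procedure is not specified.
A recording whose median "foreground" covers more than 25% of the image
is rejected as worm-free — Otsu bisects pure noise near its mean, so an
empty chamber produces exactly that signature.

**Frame alignment.** N frames give N−1 difference images. The state of
pair (i, i+1) is assigned to frame i+1 and frame 0 inherits frame 1's
state, so the activity trace has the stack's length. This convention is
also what the synthetic renderer produces physically: the worm's position
at frame i+1 differs from frame i exactly when frame i+1 is a motion
frame, so recovery on noise-free rendered video is exact rather than
off-by-one at transitions.

## Bout segmentation

Intervals are half-open `[start, end)` in 0-based frames; seconds are
exact multiples of 1/fps. A **sleep bout** is a maximal quiescent run
lasting **strictly longer** than 6 s (61+ frames at 10 fps; a 6.0-s run
is motion). All other frames — active runs and sub-threshold quiescent
runs — merge into **motion bouts**, so motion segments separated by a
short quiescent run coalesce. The output always tiles the recording with
strictly alternating kinds.

For Ca²⁺ analyses, bouts are additionally filtered: duration strictly
greater than 12 s, and bouts touching the recording start or end are
dropped (their durations are truncated and untrustworthy). The
strict-vs-inclusive reading of the 12-s boundary is genuinely ambiguous
in the source conventions; strict is the default and `keep_equal=True`
selects the inclusive reading. Note the deliberate asymmetry with the
6-s sleep rule, which is strict in both readings.

**Fraction of quiescence** uses non-overlapping windows anchored at
t = 0 (1.5 min for imaging, 10 min for plate behavior); the trailing
partial window is reported with its own frame count. **Lethargus
detection** takes the longest contiguous run of windows with fraction ≥
an entry threshold, extends it outward while the fraction stays ≥ an
exit threshold, and accepts it if it spans a minimum duration (defaults
0.05 / 0.05 / 20 min). These are conventions, not measurements, and all
three are exposed in the API.

## Ratiometric Ca²⁺ traces

R = GCaMP/RFP per frame; R₀ = arithmetic mean of R over the session;
ΔR/R₀ = (R − R₀)/R₀. Two identities follow and are enforced by tests:
the session mean of ΔR/R₀ is exactly 0, and ΔR/R₀ is invariant under
multiplying either raw channel by a positive constant. Tracking dropouts
(NaN frames) are excluded from every mean, never interpolated; the
dropped count is reported. No detrending or bleach correction is
applied.

**Motion-active classification.** Because the session mean of ΔR/R₀ is
identically zero, reading "exceeds the session average by 20%"
multiplicatively is degenerate. The rule is therefore implemented
additively: a neuron is motion-active when its motion-bout mean ΔR/R₀
strictly exceeds the session mean by more than 0.20 absolute ΔR/R₀
units. The margin is a parameter.

## Bout-aligned analyses

* **Aligned averages**: traces aligned at bout start on the native frame
  grid; per-time-point mean, SEM (ddof = 1, defined for n ≥ 2), and n;
  time points with n ≤ 10 omitted (strict "10 or less").
* **Duration-normalized profiles**: each bout's trace is linearly
  resampled onto a fixed grid of G = 100 **cell midpoints**
  (j + 0.5)/G over [0, 1]. Midpoints give each quartile exactly G/4
  points and make quartile means of a linear signal exact (0.125 and
  0.875 for a 0→1 ramp), which endpoint grids do not. "Quartile" here is
  quartile of normalized time: Q1 = [0, 0.25), Q4 = [0.75, 1]. The
  paired Q4 > Q1 comparison uses the one-sided Wilcoxon signed-rank
  test with each bout as the pairing unit; bouts are pooled across
  sessions by default (animal-level aggregation is available by passing
  per-animal session lists separately).
* **Transition windows**: mean signal over the 12 s before vs after
  SM/MS transitions, restricted to transitions whose flanking bouts both
  pass the 12-s/edge filters and contain the full window; the paired
  summary uses a paired t test.
* **Peak vs latency**: each motion bout's trace is smoothed with a
  centered moving average (window = round(1 s × fps) frames, forced
  odd, edges truncated rather than padded); the peak is the maximum with
  ties resolved to the earliest frame; latency runs from bout start.
  OLS of peak on latency with Pearson r and 95% CIs. Because the
  truncated edge smoothing subtracts the same constant from every
  bout's final-frame value, a noise-free linear ramp yields slope =
  ramp rate and r = 1 exactly — a useful algebraic check.
* **Cumulative locomotor activity**: running sum of changed-pixel counts
  within each motion bout, with the R² of a straight-line fit as a
  linearity diagnostic (R² is NaN for a constant curve).

Hypothesis tests themselves (Wilcoxon, Mann-Whitney U, t tests,
Kolmogorov–Smirnov, two-way ANOVA with Sidak-corrected contrasts) are
delegated to scipy/statsmodels; these modules only define which samples
enter which test. The Sidak correction 1 − (1 − p)ᵐ is computed via
`expm1`/`log1p` to remain monotone for very small p.

## Sleep homeostasis

Every sleep bout with an immediately preceding motion bout yields one
(prior-motion duration, sleep duration) pair; pairs involving an
edge-truncated bout are excluded. The homeostatic gain is the OLS slope
of sleep on prior motion duration. The binned comparison splits pairs at
the pooled median of prior motion durations by default (values equal to
an edge fall in the upper bin, the `numpy.digitize` convention); custom
edges are accepted. With one genotype the across-bin comparison is a
one-way ANOVA (a two-sample t test for two bins); with several, a
two-way ANOVA supplies the genotype × bin interaction and Sidak-corrected
pairwise contrasts per bin. Pairs are pooled across animals by default,
matching how bout-level n is usually reported.

## Optogenetics

Sleep bouts in this protocol are quiescent runs **strictly longer than
5 s** (not 6 s). The latency is measured from stimulation onset to the
start of the first qualifying sleep bout in the re-segmented
post-stimulation trace; recordings ending without one are right-censored
and flagged. Stimulation-aligned locomotion traces are smoothed with a
centered 2.5-s moving average for display/averaging, but the per-event
summary — the mean locomotion over the 5 s after onset — is computed on
the raw trace so that hand-checkable cases are exact. The 5-s summary
window follows the figure-level convention; the alternative 10-s window
mentioned in running text is available via `summary_window`.

## The synthetic-data generator

The generator emulates the study conditions, not arbitrary data:

* **Bout schedules** alternate motion/sleep starting with motion.
  Motion durations are log-normal (positive, right-skewed, matching
  observed bout-duration histograms) with arithmetic mean
  `motion_mean = 30 s` and log-scale SD 0.6. Sleep duration =
  `max(min_bout, sleep_base + gain × prior motion + N(0, σ))` with
  defaults 10 s base, gain 0.5, σ = 2 s, floor 7 s — the floor keeps
  every simulated sleep bout detectable under the 6-s rule. The last
  bout is truncated at the recording end. Frame i takes the kind of the
  bout containing time i/fps.
* **Ca²⁺**: latent C integrates dC/dt = ramp_rate during motion and
  dC/dt = −C/decay_tau during sleep by forward Euler at the frame rate,
  evaluated run-wise in closed form (arithmetic ramp / geometric decay)
  — algebraically identical to the per-frame update, and unit-tested
  against a naive Euler loop. Defaults ramp_rate = 0.1 ΔR/R₀ units/s
  and decay_tau = 3 s give peak amplitudes ≈ 3 over a mean motion bout
  — within the GCaMP6s dynamic range, yielding a motion-bout ΔR/R₀
  enrichment comfortably above the 0.20 classification margin and a
  fast decay at sleep entry, as the ALA phenotype requires. Forward
  Euler requires decay_tau > 1/fps; the generator rejects smaller
  values. Channels: GCaMP = 100 + 100·C + N(0, 2); RFP = 100 + N(0, 2).
* **Video**: the worm is a filled disc of exactly `worm_area` pixels
  (600 by default in a 128×128 frame, with background 50, worm 150,
  pixel noise SD 2 — absolute levels are irrelevant because the
  threshold is recalibrated per recording). On motion frames the center
  moves `jitter_px` = 4 px in a random direction, reflected at the
  borders; directions whose reflected net displacement falls below
  0.75·jitter are re-drawn so a moving worm always moves visibly (a worm
  slides along a wall rather than compressing into it). Sleep frames are
  static. A matched worm-free noise stack is produced for calibration.
* **Optogenetics**: `baseline_hazard` is the per-second probability of
  the motion→sleep transition, converted per frame as
  p = 1 − (1 − h)^(1/fps); during the 10-s effect window the treated
  group's per-second hazard is multiplied by `stim_hazard_multiplier`
  (clamped at 1). Treated and control trial *i* share one uniform
  stream (common random numbers), so a multiplier of 1 reproduces the
  control group draw-for-draw and multiplier sweeps are paired. This
  deliberately makes a null *between-group* comparison degenerate; for
  type-I-error calibration set `common_random_numbers=False` to draw
  the groups independently. Trials are capped at 5 per simulated
  animal, matching the experimental protocol.

All randomness flows from one seeded `numpy` Generator per operation;
identical seeds give bit-identical outputs.

### What the generator does *not* emulate

Worm posture and body-shape change (the blob is a rigid disc, adequate
for frame differencing but not for posture analysis); pharyngeal
pumping; photobleaching and focus drift in the fluorescence channels;
tracking dropouts (supported by the analysis as NaN frames but not
generated by default); multi-neuron circuit structure; and
between-animal variability in generative parameters. Tests passing on
synthetic data therefore validate the pipeline's correctness and
statistical calibration under the stated model, not robustness to every
artifact of real recordings.

## Problem sizes and determinism in the validation suite

Simulation-based checks use sizes chosen to keep Monte Carlo error well
below the margins being asserted: 1000 fuzzed traces for segmentation
oracle equivalence; 100 sessions of ~20 motion bouts for power checks
and 1000 sessions for null calibration of the Q4 > Q1 comparison (the
rejection count is compared against the exact binomial 95% interval
around 5%); ≥ 500 bout pairs for gain recovery; 100 trials/group and
100–200 replicates for the optogenetic comparisons. All suite and
script seeds are fixed via `numpy.random.SeedSequence` so results are
reproducible; note that a nominal-level calibration check against a 95%
interval would, by construction, fail about 5% of fresh seed draws — the
fixed canonical seeds make the suite deterministic instead.

## Known limitations

* The lethargus detector is a threshold convention; recordings with
  gradual quiescence onset may need tuned thresholds.
* The motion-active margin (0.20 ΔR/R₀ units) inherits the ambiguity of
  the additive-vs-multiplicative reading discussed above.
* Binned homeostasis tests use ANOVA-family statistics on durations,
  which are right-skewed; with the default median split and ≥ 50 pairs
  per bin this is well-calibrated (verified by simulation), but tiny
  samples may prefer rank-based alternatives.
* Censored optogenetic latencies are excluded from the group comparison
  rather than handled by survival methods.
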