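# Methods

This note records the models, conventions and numerical choices behind
each vigilkit stage, what the synthetic-data generators do and do not
emulate, and the known limitations. All defaults named here are the
package's shipped configuration; every threshold is overridable through
the corresponding parameter object.

## Time, clock and coordinate conventions

Time is in seconds. Clock-of-day arithmetic is modulo 86 400 s so the
active (lights-off) window 19:00→07:00 wraps midnight; the inactive
window is its complement and the two tile the 24-h day. Recordings are
assumed to start at a known clock time (default 18:00) and the first
`discard_initial_s` (default 3 600 s) of every architecture computation
is discarded to avoid handling-stress artifacts. Hypnogram epochs are
half-open 10-s intervals [t, t+10), so every sample or frame belongs to
exactly one epoch. Arena coordinates are top-down centimetres with the
origin at the shelter-end wall corner and x along the 36-cm axis; the
zone extents are shelter [0, 12.7), intermediate [12.7, 26.0), trigger
[26.0, 36.0] cm (the printed zone lengths sum to 35.9 cm, 0.1 cm short
of the total; the trigger zone absorbs the remainder).

## Sleep architecture

EEG preprocessing is a zero-phase (forward–backward) 4th-order
Butterworth low-pass at 625 Hz followed by integer-factor decimation to
1 250 Hz. Zero-phase filtering is chosen so spindle event timing is not
shifted by filter group delay. When the input is already at the target
rate the cutoff is clipped just below Nyquist and the signal is filtered
only.

Per-epoch spectra use Welch's method with 1-s Hamming segments, zero
overlap and a one-sided spectrum, giving 1-Hz bins. Band power is the
sum of PSD bins whose center lies inside the band (bounds inclusive),
normalized by the 1–80 Hz total — the union of the five defined bands —
so fractions are comparable across sampling rates. A trailing partial
epoch is dropped and logged. Note the Hamming main lobe spreads a pure
tone over ±1 bin; band fractions, not single bins, are the meaningful
unit.

State percentages and bout metrics are computed in 1-h clock bins and
averaged over each 12-h phase; bins without epochs are excluded, so the
three state percentages sum to 100 per phase by construction. A bout is
a maximal run of identical epoch labels, *truncated where the circadian
phase changes* (and at the discard boundary); each (sub)bout is assigned
to the 1-h bin of its first epoch. Truncation is what makes per-phase
bout durations sum exactly to per-phase state time; the alternative
(assigning whole boundary-spanning bouts to one phase) breaks that
conservation. Phases with no bouts report a missing mean duration, never
zero.

Spindle detection follows the cubed-RMS-envelope rule: each maximal
contiguous NREM segment is band-passed to 10–15 Hz (4th-order
Butterworth, zero phase), a centered 700-ms moving RMS envelope is
computed (the window shrinks at segment edges) and cubed, and events are
the excursions above twice the mean cubed envelope over *all* NREM
samples. Events shorter than 0.5 s or longer than 5 s are discarded —
never split or merged — and event boundaries are the threshold
crossings. The threshold average includes every NREM sample regardless
of segment length; segments shorter than the RMS window contribute no
envelope samples. Peak values are reported in cubed-RMS envelope units.
A known property of this rule: the RMS window smears a burst's envelope
by up to the window length, so a very large-amplitude burst slightly
shorter than 0.5 s can still produce a supra-threshold excursion longer
than the gate. Spindle density divides event count (by event midpoint)
by NREM minutes per phase.

## Looming assay

Stimulus timing is: 3-s slow ramp (0.5→3 cm), fast expansion #1
(3→21 cm in 0.5 s), reset to 3 cm, fast expansion #2, then the full disc
held until t = 6 s. The stated segments sum to only 4 s; holding the
full disc to the stated 6-s total is this package's resolution of that
gap. The geometry helpers are exact closed forms: area expansion rate
(π r₁² − π r₀²)/Δt, full visual angle 2·atan(d/2h), Michelson contrast
(I_max − I_min)/(I_max + I_min)×100. With the 30-cm screen height the
0.5-cm onset disc subtends 0.95°; the conventionally quoted "≈0.9°" is a
rounding of the same formula, which this package does not force.

Velocity is the central-difference speed of the body centroid, smoothed
with a centered 0.25-s moving average before any thresholding (without
smoothing, frame-rate jitter dominates the 35 cm/s crossings). Frames
flagged invalid by pose QC (confidence < 0.9, gaps > 0.5 s) cannot
trigger thresholds.

Escape requires all three criteria inside the 7-s response window:
(1) smoothed speed > 35 cm/s; (2) during the first supra-threshold run,
the angle between the head-direction vector (tail_base→head, falling
back to the centroid motion vector) and the bearing to the shelter-zone
center stays below 60° for at least half the run's frames — a
majority-of-run rule robust to single-frame jitter; (3) the centroid
enters the shelter zone no later than 7 s after cue onset ("within at
most 7 s", the reading consistent with the 7-s immobility window). When
no run exceeds 35 cm/s the heading criterion is still evaluated — on the
first run above the 20 cm/s vigor threshold, else above the 1 cm/s
movement floor — so the three criteria remain independently defined for
every trial. Tracks not covering the full window yield a not-performed
trial, excluded from the escape-probability denominator. Escape vigor is
the peak speed of the *first* run above 20 cm/s that is shelter-directed
and followed by shelter entry within the window; with no such run the
value is missing. Immobility is any maximal run below 1 cm/s lasting
≥ 1 s; per-trial immobility is clipped to the response window before
summing across trials. Latency is reported whenever the shelter is
reached, escaped or not.

## Photometry

The isosbestic fit is a single OLS regression of the whole-recording
405 nm channel onto the 470 nm channel (a per-event refit is available
via refitting on sliced sessions but is not the default, matching the
whole-recording convention). ΔF/F is computed at the acquisition rate
and then downsampled 20→5 Hz by non-overlapping 4-sample block means —
adequate anti-aliasing for calcium kinetics well below 2.5 Hz.
Event alignment snaps each event to the nearest 5-Hz sample (no
interpolation, for determinism); trials lacking full [−10, +10] s
coverage are dropped and logged, and trials with zero baseline standard
deviation are dropped with a warning. z-scores use the per-trial
[−10, −3] s baseline with the sample (n−1) sd, so every retained trial's
baseline has mean 0 and sd 1 exactly.

Window AUC implements "total positive peak area, 10 % minimum peak
height": within the window, contiguous z > 0 excursions are found, the
tallest peak defines the reference, excursions whose peak is below 10 %
of it are ignored, and the rest contribute their trapezoidal area above
zero, including the bounding zero-crossing samples. All-negative windows
score 0. AUCs from windows of different lengths are not directly
comparable (area grows with duration); null comparisons should use
equal-length windows. AUC is computed per trial (and can be taken on
the trial-mean trace by passing a one-row matrix).

## Behavioral composites

z = (X − μ_ctrl)/σ_ctrl with the sample (n−1) sd, applied to every
animal including controls, so control z has mean 0 and sd 1 exactly.
Variables with fewer than two control values or zero control sd are
excluded with a warning. A dimension composite is the mean of
direction × z over the dimension's variables; the direction map encodes
whether larger raw values mean more of the construct (e.g. escape
probability +1 and escape latency −1 for defensive behavior; open-arm
time −1 for anxiety) and ships as explicit configuration precisely so
sign conventions are never silent. Missing values are pairwise-deleted
within a dimension and the count of contributing variables is reported;
an animal with no values gets a missing composite. Averaging (not
summing) keeps composites comparable across dimensions with different
variable counts. Group comparison offers unpaired t and Mann–Whitney
with Cohen's d; choosing between them (e.g. by normality checks) is left
to the caller, and no multiple-testing correction is applied across
dimensions.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure the analyses
assume*, not biophysics.

* **Hypnograms** are semi-Markov chains with exponential dwell times
  quantized to whole epochs (defaults: AWAKE/NREM/REM means 600/120/60 s
  in the active phase, 180/240/80 s in the inactive phase; AWAKE→NREM
  always, NREM→REM with p = 0.25, REM→AWAKE with p = 0.6). Real
  hypnograms have heavier-tailed bout distributions and time-of-day
  drift within phases.
* **EEG** is 1/f broadband noise plus per-state components: a delta-band
  hump and a steady 12.5-Hz sigma rhythm in NREM, a 7-Hz theta
  oscillation in REM; EMG is white noise with state-dependent amplitude
  (AWAKE 1.0, NREM 0.3, REM 0.05). The sigma rhythm's RMS is 5× the
  in-band 1/f-noise RMS; modelling the ongoing background sigma activity
  as a near-constant-envelope rhythm is a deliberate choice — with a
  purely Gaussian background the relative cubed-RMS threshold crosses
  envelope fluctuations hundreds of times per hour, so a zero
  false-positive detector would be impossible on principle, whereas a
  stable background isolates the detector's behavior on injected events.
  Real NREM sigma background fluctuates more; passing tests therefore
  demonstrate correct detector mechanics, not field performance on real
  EEG. Spindles are Hann-windowed 12-Hz bursts placed only inside
  contiguous NREM with ≥ 0.5 s edge clearance and ≥ 1 s separation,
  durations U(0.8, 2) s, envelope amplitude `ratio` × the background
  sigma envelope (default 4).
* **Looming sessions** program round(p × n_trials) escapes exactly
  (shuffled order), realized as shelter-directed dashes with sin²-speed
  profiles peaking at U(45, 70) cm/s after a U(0.3, 0.8) s reaction
  latency — satisfying all three criteria by construction — while
  non-escapes freeze (immobile, default 60 % of them) or wander slowly
  (6 cm/s) without entering the shelter. Head and tail points lie along
  the motion direction. Trials occupy fixed 40-s slots (cue at 5 s),
  which stands in for the trigger-zone/30-s-refractory acquisition
  logic.
* **Photometry** channels follow F = B(t)(1 + artifact + transients) +
  noise with exponential-plus-plateau bleaching (default τ = 800 s,
  plateau 0.7, both channels; equal time-constants make the channels
  exactly proportional, the regime the single linear fit assumes), a
  shared low-pass (< 0.5 Hz) multiplicative motion artifact of 10 % RMS,
  additive sensor noise (sd 0.05 counts on baselines of 200/150 counts),
  and double-exponential transients (rise 0.5 s, decay 1.5 s, peak ΔF/F
  0.05) only in the 470 channel, locked 3.5 s after each event. Because
  transients are multiplicative alongside the artifact, recovered peak
  amplitude is modulated by ±(artifact) on single events; recovery is
  assessed on the across-event mean. Unequal bleach time-constants (a
  supported setting) leave a residual the single linear fit cannot
  remove.
* **Variable tables** draw control values from per-variable Normal
  distributions (fixed arbitrary scales) and shift treated animals by
  `effect × σ` per variable. Effects are exact in generator-population
  σ units; sample-σ z-scores therefore recover them up to sampling error
  in the control sd.

Every generator is a pure function of (params, seed) and emits ground
truth sufficient to score its consumer without re-deriving labels.

## Problem sizes and numerical notes

The shipped verification workloads use 2-h all-NREM recordings at
1 250 Hz for spindle recovery (5 seeds, with and without injected
spindles), 1 000 random hypnograms of up to 1 000 epochs for the bout
oracle, 10-min photometry sessions at 20 Hz, 200-trial looming sessions
per programmed probability, and 200 replicates of n = 16-per-group
tables for composite power — sizes chosen so the full suite completes in
a few minutes while keeping every statistical check well-powered.
Spindle-event matching uses a 0.25-s midpoint tolerance. Detection
monotonicity in burst amplitude holds on fixed noise seeds. Degenerate
inputs fail loudly: non-finite samples, unknown state labels, constant
405 nm control, zero-crossing fitted control, phases or groups with no
data all raise typed errors rather than propagating NaN.

## Known limitations

No automatic sleep staging, artifact rejection beyond non-finite checks,
REM phasic analysis, pose estimation, stimulus rendering, hardware
demodulation or hemodynamic correction. The spindle detector's duration
gate operates on RMS-smeared envelope excursions (see above). The
heading criterion needs either head and tail_base points or a clean
centroid trajectory; with noisy single-point tracks the motion-vector
fallback inherits that noise. EDF input depends on the optional `mne`
package and reports values in the reader's SI units (volts).
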