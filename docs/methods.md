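# Methods

This note documents the models and procedures implemented by `tablet_vfhp`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## System overview

The package is the computational stack of an fMRI-compatible writing
tablet that gives the user live **visual feedback of hand position
(VFHP)**: a video camera films the hand and stylus over the tablet, a
per-pixel color rule segments hand/stylus from background, and the
segmented pixels are superimposed in real time onto the stimulus/response
graphics to form an augmented-reality display. Writing behavior is
measured through a force sensor in the stylus tip, and the behavioral
comparisons (writing with vs. without VFHP) use paired nonparametric and
repeated-measures parametric statistics.

## Skin/stylus segmentation

A pixel (R, G, B), 8-bit per channel, is classified as skin/stylus iff

```
R > 55  ∧  G > 20  ∧  B > 20
∧  max(R,G,B) − min(R,G,B) > 15
∧  |R − G| > 15  ∧  R > G  ∧  R > B
```

This is the classical uniform-daylight skin-color locus in RGB space; the
stylus wears a red sleeve so it falls inside the same locus. Decisions:

* **Strict inequalities** everywhere; threshold-valued pixels are
  non-skin. The rule as published uses strict comparisons, and keeping
  them strict makes the monotone-threshold property exact.
* Thresholds are **configurable** (`SkinRule`) because real rigs need
  slight R/G retuning for lab vs. scanner illumination; the defaults are
  the daylight values.
* **Integer frames only.** Consumer video is 8-bit; floating-point frames
  are rejected rather than rounded so no silent quantization can shift a
  pixel across a strict threshold.
* **No morphological post-processing** (no erosion/dilation or hole
  filling): the segmentation is used per frame in a real-time loop, and
  the mask contract (`mask[i,j] == rule(pixel[i,j])` exactly) is what the
  tests verify against a per-pixel oracle.

## Augmented-reality compositing

The composited frame is `S = C·M + T·(¬M)` with camera frame `C`, stimulus
frame `T` and binary mask `M`, applied element-wise per channel. For a
binary mask this arithmetic is exactly per-pixel *selection*, and it is
implemented as selection, which cannot overflow 8-bit intensities. The
invariant is provenance: every output pixel is bit-identical to the
corresponding pixel of exactly one input; no blended values exist.

Camera and display rasters differ in practice (640×480 NTSC camera,
1024×768 projector). Reconciliation is a separate, explicit
nearest-neighbor `resample_to` step (`src = (dst·n_src)//n_dst` per axis);
`compose` refuses mismatched shapes. No geometric calibration is modeled —
the physical system itself did not scale the video into world
coordinates, so any calibration here would be invented.

## Feedback-latency model

The stimulus/response computer and the video-processing computer run
asynchronously. The camera is the slower stream, so each camera frame is
paired with the **most recently acquired** stimulus frame — the latest
stimulus frame with timestamp ≤ the camera frame's; a simultaneous frame
pairs with lag 0, and camera frames before the first stimulus frame are
flagged unpaired.

Two worst-case bounds follow, and both are *computed* by discrete-event
simulation rather than quoted:

* **Pairing lag** < one display refresh period. `worst_case_pairing_lag`
  sweeps the inter-stream phase offset densely over one display period
  (default 4001 phases over 1 s of frames), takes the supremum of the
  simulated lags, and rounds to 0.1 ms. At 30 Hz camera / 60 Hz display
  this yields 16.7 ms; the sweep converges to the analytic bound
  (1000/display rate) within one sweep step.
* **Interaction-to-display lag** = one camera frame period, provided all
  per-frame processing fits inside that period (a precondition that is
  enforced, not assumed): an interaction just after an exposure waits one
  full period to be captured and shown. At 30 Hz this is 33 ms, reported
  to the nearest ms.

Both bounds sit below the ≈50 ms conduction time from peripheral
receptors to primary sensory cortex, the criterion for calling the
feedback delay perceptually negligible. The display rate defaults to
60 Hz (the projector's refresh and the rate consistent with the 16.7 ms
bound); the desktop monitor's 75 Hz is obtainable by setting
`display_rate_hz=75`. Rounding conventions (0.1 ms / 1 ms) are fixed to
the precision at which these figures are conventionally reported.

## Stylus-force kinematics

The stylus tip carries a force-sensing resistor sampled every 25 ms; its
units are the raw uncalibrated readout and are treated as arbitrary
non-negative units. A zero ("null") reading means the stylus is off the
surface. Definitions:

* **Contact episode**: maximal run of consecutive samples with
  `force > threshold`; a run of n samples starting at t spans
  `[t, t + n·Δt)`, so episode durations are exact multiples of Δt.
* **Contact time** = Σ episode durations = (# above-threshold
  samples)·Δt.
* **Total writing time** = first contact → last lift-off. The span from
  trial onset instead is available via `detect_trial_end`; anchoring to
  first contact isolates writing behavior from pre-trial idling.
* **Mean stylus force** is averaged over contact samples only. Whether
  the original analysis averaged over contact samples or all samples is
  not determinable; the all-samples view stays expressible through
  `force_histogram`, which deliberately counts null values, since
  null-value frequency is the feature that distinguishes the feedback
  conditions.
* The **contact threshold defaults to 0** (contact = strictly positive
  reading), matching the null/contact dichotomy of the sensor; it is
  configurable for noisy sensors.
* **Trial completion** is the start of the first terminal null-force run
  lasting ≥ 1 s (participants lift the stylus when done); shorter interior
  lifts are ignored, and a trace without a long terminal lift falls back
  to its last sample time.
* For the three-task experiment, per-participant, per-condition totals
  are **sums across the three tasks** — including the mean-force
  parameter, which follows the original aggregation even though summing
  means is unusual; the per-task summaries remain available if a pooled
  mean is preferred.

## Behavioral statistics

* **Wilcoxon signed-rank** (paired conditions, two-sided): zero
  differences are discarded (classic convention; the Pratt variant is
  deliberately not offered, to keep one auditable path), ties among
  |differences| get average ranks. For ≤ 15 nonzero differences — every
  nine-participant analysis — the p-value is **exact**: the null
  distribution of the positive-rank sum is built by convolution over the
  (doubled, integer) ranks, equivalent to enumerating all 2ⁿ sign
  assignments, and the two-sided p is the null mass at least as far from
  the center as observed. Beyond 15, a normal approximation with
  tie-corrected variance (no continuity correction) is used. Tests verify
  the exact path against a literal 2ⁿ enumeration oracle and against
  scipy's exact method on tie-free data.
* **Bonferroni**: p·m capped at 1, with m ≥ the number of comparisons
  (three, for the three kinematic parameters).
* **"Three-way mixed-effects ANOVA"** with condition and trial fixed and
  participants random is implemented as the classical **balanced two-way
  repeated-measures decomposition**: each fixed effect is tested against
  its interaction with the participant factor
  (F = MS_effect / MS_effect×participant), the expected-mean-squares
  denominators for this design. Unbalanced or incomplete tables are
  refused with an explicit error — a general unbalanced mixed model is
  out of scope. The implementation agrees with `pingouin.rm_anova` to
  machine precision on random cohorts, and its condition-effect type-I
  error on 10,000 simulated null cohorts (9 participants, 2×4 cells) lies
  within the binomial band around α = 0.05.
* All tests are two-sided; only significance categories (p < 0.05,
  corrected) were ever reported for the original cohorts, so validation
  is by oracle and simulation, not by reproducing printed statistics.

## Synthetic data: what it emulates, and what it does not

No camera, force, or participant data exists to ship, so the generators
define the test conditions:

* **Scenes** (`render_scene`): hand = rotated ellipse, stylus = thick
  line segment, drawn over a background palette (grays, blue graphics,
  black text — all failing the rule); skin/stylus colors are
  reject-sampled from a warm red-dominant color box verified against the
  active rule at generation time. Ground truth is therefore *exact*, and
  the core contract — segmentation recovers the drawn mask pixel-exactly
  under a separating palette — is a theorem of the construction, which
  the tests exercise. An adversarial palette inside the skin locus
  demonstrates false positives. The generator does **not** emulate
  shading, motion blur, demosaicing noise, or real skin-tone diversity;
  passing tests certify the rule's implementation, not its detection
  efficiency on real video.
* **Force traces** (`synthesize_trace`): episodes placed on the uniform
  25 ms grid; force is above zero exactly within episodes. Optional
  additive noise is clipped at zero and off by default, since the
  null/contact dichotomy is the analyzed feature; heavy noise can split
  episodes, which is a property of real sensors too.
* **Cohorts** (`synthesize_cohort`): balanced 9 participants × 2
  conditions × 4 trials of contact time (s), value = grand mean (60 s) +
  participant effect (σ_p = 10 s) + condition effect (δ = 15 s added to
  without-VFHP, matching the observed ≈15 s plateau of the median
  difference) + trial effect + residual (σ = 5 s). The default trial
  profile (3, 1.5, 0.5, 0 s) mimics mild, monotonically fading learning,
  consistent with learning effects being minor. Values are clipped at 0
  (contact times are durations); with the default location/spread this
  clip is never active.

All generators are seed-deterministic.

## Numerical choices and degenerate inputs

* Phase sweeps use 4001 grid points by default (20001 in the acceptance
  script); the supremum error is one sweep step, far below the 0.1 ms
  reporting precision. Simulated durations of 1 s (30 camera frames)
  suffice because the 30/60 Hz lattice repeats every camera period.
* The exact Wilcoxon path doubles average ranks to integers so the
  convolution is exact in integer arithmetic; the two-sided tail uses a
  1e-9 tolerance when comparing deviations, protecting ties at the
  center.
* ANOVA with zero error mean square (e.g. all values identical) raises a
  degenerate-data error instead of returning infinite F.
* All-zero force traces produce an explicit `no_contact` summary, never
  silent zeros; empty traces are rejected outright.
* The null-simulation and power checks use 10,000 and single-cohort runs
  respectively at the default cohort size (9 participants), the size the
  design targets.

## Known limitations

* The segmentation rule is a fixed color box; no learned or per-ethnicity
  models (explicitly out of scope), so real-world detection efficiency is
  not certified by these tests.
* The latency model ignores capture-card/DAC delays, dropped frames and
  clock drift; it bounds only the frame-pairing and frame-period terms.
* The ANOVA path requires a complete balanced design; missing cells need
  a general mixed model, which this package does not provide.
* Force units are arbitrary; cross-device force comparisons are not
  meaningful without calibration.
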