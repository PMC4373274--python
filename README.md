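# tablet-vfhp

Computational stack of an fMRI-compatible writing tablet with live
**visual feedback of hand position (VFHP)**. Performing pen-and-paper
neuropsychological tests inside an MRI scanner requires a tablet the
participant cannot see directly; without sight of the hand, writing
relies on proprioception and degrades. This package implements, as
tested software, everything between the cameras and the behavioral
conclusions of such a system:

* **Segmentation** — per-pixel skin/stylus classification in RGB space:
  a pixel is skin iff `R>55 ∧ G>20 ∧ B>20 ∧ max−min>15 ∧ |R−G|>15 ∧ R>G ∧ R>B`
  (thresholds configurable), producing a binary mask **M** per camera frame.
* **Compositing** — the augmented-reality frame `S = C·M + T·(¬M)`:
  camera pixels where the mask is 1, stimulus/response graphics
  elsewhere, with strict per-pixel provenance (no blending).
* **Stream synchronization** — a discrete-event model of the
  asynchronous 30 Hz camera / 60 Hz stimulus pairing ("most recently
  acquired frame" rule) that computes the worst-case pairing lag
  (16.7 ms) and interaction-to-display lag (33 ms) by phase-sweep
  simulation and compares them to the ≈50 ms sensory conduction time.
* **Kinematics** — the three per-trial handwriting parameters from the
  25 ms-sampled stylus force trace: total writing time, stylus contact
  time, and mean contact force; plus lift-off-based trial-completion
  detection and force histograms.
* **Statistics** — exact-small-sample Wilcoxon signed-rank with
  Bonferroni correction for the paired-condition comparisons, and the
  balanced repeated-measures ANOVA (condition × trial fixed,
  participants random) for the learning design.
* **Synthetic data** — seed-deterministic generators for camera scenes
  with exact ground-truth masks, force traces built from known contact
  episodes, and behavioral cohorts with injected condition effects, so
  the whole pipeline is testable without hardware.

See `docs/methods.md` for models, assumptions, and design choices.

## Worked example

The `demo` subcommand chains every stage on synthetic inputs:

```sh
tablet-vfhp demo --seed 7 --out demo_out
```

prints (abridged):

```json
{
  "segmentation": {"skin_pixels": 1801, "mask_matches_ground_truth": true},
  "latency_ms": {"worst_case_pairing": 16.7, "worst_case_feedback": 33,
                 "sensory_conduction": 50.0},
  "kinematics": {"total_writing_time_s": 1.0, "contact_time_s": 1.0,
                 "mean_contact_force": 10.0, "trial_end_ms": 1500.0},
  "stats": {
    "anova_condition_p": 6.77e-07,
    "per_trial_median_difference_s": [13.45, 12.40, 16.69, 14.29],
    "wilcoxon_total_time": {"statistic": 0.0, "p_value": 0.00390625,
                            "p_corrected": 0.01171875}
  }
}
```

Reading it: the rendered hand/stylus scene is segmented pixel-exactly
(1801 skin pixels recovered); the 30/60 Hz timing model bounds feedback
latency at 16.7 ms (frame pairing) and 33 ms (interaction to display),
both under the 50 ms sensory threshold; a synthetic trace with one 1 s
contact episode at force 10 yields exactly (1.0 s, 1.0 s, 10.0) with the
trial ending at the 1500 ms lift; and a nine-participant cohort with a
15 s injected condition effect shows per-trial median contact-time
differences near 15 s, a highly significant condition main effect, and a
significant paired Wilcoxon test after threefold Bonferroni correction.

The same stages are available individually (`segment`, `compose`,
`simulate-latency`, `kinematics`, `stats wilcoxon|anova|differences`,
`synth scene|trace|cohort`) and, equivalently, as library functions:

```python
from tablet_vfhp import (HandScene, render_scene, segment_frame,
                         TimingModel, worst_case_pairing_lag)

scene = render_scene(HandScene(seed=7))
mask = segment_frame(scene.frame)          # == scene.mask, pixel-exact
worst_case_pairing_lag(TimingModel())      # 16.7
```

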