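# fearcortex

Analysis pipeline and circuit model for longitudinal two-photon imaging
studies of **differential auditory fear conditioning** (DFC): a mouse hears
two nearby pure tones, one paired with a foot-shock (CS+, 15 kHz) and one
safe (CS−, 11.4 kHz, 0.40 octaves away), and its fear memory is read out as
freezing. The package is for systems neuroscientists who want to relate
cortical frequency coding to behavioral learning specificity with the full
statistical chain in one tested place.

It provides:

- **Behavior** — freezing scored from a video motion index via a
  session-wide 12.5th-percentile threshold, and learning specificity
  `LS = mean fr_CS+ − mean fr_CS−`, with per-mouse learner classification
  (two-way ANOVA on stimulus × period).
- **Single-neuron statistics** — ΔF/F_std trial responses, responsiveness
  (t-tests with Holm correction), frequency response functions, best
  frequency, sparseness `S = (1 − a)/(1 − 1/N)` with
  `a = (Σr_i/N)²/(Σr_i²/N)`, and the discriminability score
  `Z_diff = |mean r_CS+ − mean r_CS−| / √(sd(r_CS+)·sd(r_CS−))`
  with a 250-shuffle permutation null.
- **Population decoding** — linear-kernel SVM, stratified 10-fold CV,
  min-neuron resampling across mice, cross-session decoder transfer and
  Z_diff similarity as drift measures.
- **Bootstrap inference** — Spearman correlations with 1000-resample
  percentile CIs and a paired bootstrap correlation-difference test.
- **Cell tracking** — landmark-based affine registration and
  nearest-centroid ROI matching with review flags.
- **Circuit model** — a rate-based MGB → AC → BLA network with Delta-rule
  plasticity of the amygdala projections and slow drift of cortical tuning
  width, reproducing how cortical discriminability before learning shapes
  fear specificity.
- **Synthetic cohorts** — a generator programming a ground-truth link
  between neuronal discriminability and learning specificity, used by the
  tests and reproduction script.

## Worked example

```python
import numpy as np
from fearcortex import CohortConfig, generate_cohort, zdiff_significance, spearman
from fearcortex.pipeline import mean_zdiff_per_mouse
from fearcortex.circuit import CircuitParams, run_experiment

# a 14-mouse conditioned cohort with a programmed discriminability gradient
cfg = CohortConfig(seed=1, n_pseudo=0, n_sessions=4, n_pre_sessions=4,
                   include_motion=False)
cohort = generate_cohort(cfg)

# single-neuron discriminability of the two conditioned tones
mouse = cohort.mice[-1]
r_plus, r_minus = cohort.cs_repeats(mouse, session=1)
res = zdiff_significance(r_plus[0], r_minus[0], seed=0)
print(f"neuron 0: Z_diff = {res.zdiff:.2f}, null 95th = {res.null_95th:.2f}, "
      f"significant = {res.significant}")

# does pre-learning discriminability predict learning specificity?
table = mean_zdiff_per_mouse(cohort, sessions=(1, 2, 3, 4))
r = spearman(table["mean_zdiff"], table["ls_true"])
print(f"pre-DFC mean Z_diff vs ground-truth LS: Spearman r = {r:.2f} (n = {len(table)})")

# circuit model: narrow vs broad cortical tuning
narrow = run_experiment(CircuitParams(sigma_ctx_init=3.0), "control", seed=0)
broad  = run_experiment(CircuitParams(sigma_ctx_init=10.0), "control", seed=0)
print(f"model LS: narrow tuning {narrow.ls_at_conditioning:.3f}, "
      f"broad tuning {broad.ls_at_conditioning:.3f}")
```

prints

```
neuron 0: Z_diff = 0.37, null 95th = 0.58, significant = False
pre-DFC mean Z_diff vs ground-truth LS: Spearman r = 0.87 (n = 14)
model LS: narrow tuning 0.594, broad tuning 0.409
```

The first line shows one neuron whose CS+/CS− response difference does not
exceed its label-shuffled null. The Spearman r of 0.87 recovers the
programmed cohort-level link: mice whose cortical populations separate the
two tones before conditioning go on to specialize their fear. The model
lines show that sharper cortical tuning during conditioning yields more
specific fear memory.

A command-line interface wraps the same functions
(`fearcortex simulate | behavior | respond | decode | correlate | model | run`),
e.g.

```sh
fearcortex simulate --seed 1 --out cohort.h5
fearcortex respond --in cohort.h5 --session 1 --out stats.csv
fearcortex model --tuning both --seeds 50 --out fig_model.csv
```

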