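# gazestate

Analysis pipeline for VR eye-tracking studies of learner cognitive states.
It targets researchers who record head-mounted-display gaze data while
inducing **cognitive overload**, **immersion**, or **distraction** in VR
learning environments, and who want a reproducible desk-scale
implementation of the full analysis chain:

1. **I-VT gaze-event detection** — angular velocity between consecutive
   unit gaze vectors, `v = Δθ/Δt`; fixations at `v < 30°/s` lasting
   100–500 ms, saccades at `v > 60°/s` lasting 30–80 ms.
2. **AOI metrics** — analytic ray/collider intersection (spheres, boxes)
   replacing the engine raycast, with cumulative fixation/saccade
   duration and count time series per area of interest, saved as CSV.
3. **Statistical battery** — repeated-measures ANOVA with Mauchly
   sphericity test and Greenhouse–Geisser correction, partial η²,
   Bonferroni-corrected paired post hocs with Cohen's
   d = |m₁−m₂| / √((s₁²+s₂²)/2), and Pearson metric↔scale correlations.
4. **Subject-independent classification** — sliding-window sequences
   (T = 10 steps, label = final step), train-only standardization,
   leave-one-subject-out cross-validation of an LSTM (50 hidden units →
   dropout 0.2 → batch norm → softmax; NumPy implementation with BPTT and
   Adam), plus random-forest and XGBoost baselines on identical folds.
5. **Synthetic data** — a seeded generator that emulates the study's
   statistical structure (26 participants × 3 states, 120 Hz gaze streams
   with planted ground-truth events, 100-step metric series and
   questionnaire scores calibrated to the published per-state means/SDs),
   so every stage is testable without the unreleased participant dataset.

See `docs/methods.md` for the model details, parameter choices, and
limitations.

## Worked example

```python
from gazestate.synthetic import (SimulationSpec, default_profiles,
                                 simulate_gaze_stream, simulate_dataset,
                                 sessions_to_long)
from gazestate.gaze_events import detect_events
from gazestate.stats_analysis import rm_anova, posthoc_bonferroni

# detect planted events from a simulated 10 s, 120 Hz gaze stream
profiles = default_profiles()
stream, truth = simulate_gaze_stream(profiles[1], duration_s=10.0, seed=7)
events = detect_events(stream)
print("planted:", truth.counts())
print("detected fixations:", sum(e.kind == "fixation" for e in events))

# repeated-measures analysis of a full synthetic study (26 x 3 sessions)
long = sessions_to_long(simulate_dataset(SimulationSpec(seed=7)))
res = rm_anova(long, "fixation_count")
print(f"F({res.df1}, {res.df2}) = {res.F:.2f}, p_GG = {res.p_gg:.2e}, "
      f"eps = {res.eps_gg:.3f}, eta_p2 = {res.eta_p2:.3f}")
for ph in posthoc_bonferroni(long, "fixation_count"):
    print(f"  {ph.pair}: t({ph.df}) = {ph.t:.2f}, "
          f"p_bonf = {ph.p_bonf:.4f}, d = {ph.d:.2f}")
```

prints

```
planted: {'fixation': 30, 'saccade': 30}
detected fixations: 30
F(2, 50) = 18.59, p_GG = 1.67e-05, eps = 0.734, eta_p2 = 0.427
  (0, 1): t(25) = 8.59, p_bonf = 0.0000, d = 2.20
  (0, 2): t(25) = 2.52, p_bonf = 0.0553, d = 0.81
  (1, 2): t(25) = -3.04, p_bonf = 0.0165, d = 0.93
```

Every planted event is recovered exactly (zero-noise recovery is exact to
one sample interval), and the simulated study reproduces the expected
repeated-measures structure: a strong state effect on fixation count with
GG-corrected degrees of freedom `(2·ε, 50·ε)`, the overload–immersion
contrast largest (d = 2.20), and the overload–distraction contrast weakest
— the same ordering as the published analysis.

The same stages are available from the shell:

```sh
gazestate simulate --seed 7 --out-dir data/
gazestate detect --gaze data/gaze_P01_0.csv --out events.csv
gazestate metrics --gaze data/gaze_P01_0.csv --aoi data/aoi.json --out metrics.csv
gazestate stats --in sessions_long.csv --out report/
gazestate classify --manifest manifest.csv --model lstm --window 10 --seed 7 --out results/
gazestate run --seed 7 --out-dir runs/full   # all stages + manifest
```

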