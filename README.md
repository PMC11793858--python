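# physioscreen

Nonparametric screening of wearable-friendly biosignal features for stress
and mental-workload (MWL) studies.

Psychophysiological protocols of this kind record photoplethysmography
(PPG), electrodermal activity (EDA) and skin temperature while subjects
perform stress- and workload-inducing tasks (Stroop, visual / auditory /
dual N-Back), then rate each task phase on a coarse subjective scale.
The analysis question is: *which physiological features separate the
relaxed baseline from the self-rated altered states?*  Because class
populations are small, unbalanced and non-normal, the screening is fully
rank-based.

`physioscreen` implements that analysis end to end, plus a simulator that
generates cohorts with *known* class effects so every stage can be
validated against ground truth:

1. **Simulation** — per subject, test and phase: PPG pulses placed at
   inter-beat intervals with planted low-frequency (0.10 Hz) and
   high-frequency (0.25 Hz) modulation; EDA as a tonic level/drift plus
   Poisson skin-conductance responses (SCRs) shaped by a Bateman kernel;
   temperature as a linear drift with AR(1) noise.  A latent class in
   {0..4} (0 = rest baseline) modulates all of it.
2. **Preprocessing** — the acquisition filter chain (50 Hz notch, 30 Hz
   low-pass, 0.1 Hz high-pass on PPG), applied zero-phase; phase
   segmentation and 10 s windowing.
3. **Feature extraction** — a fixed 43-entry catalogue: 9 pulse-shape
   features, 3 heart-rate and 9 heart-rate-variability features (pNN50,
   band powers P_LF [0.04–0.15 Hz] and P_HF [0.15–0.4 Hz] of the BPM
   trend and their ratio, RMSSD, SDNN), 3 skin-conductance-level and
   5 SCR features from a convex tonic/phasic deconvolution, and 7 + 7
   temperature features on the raw signal and its first derivative.
4. **Dataset assembly** — per-subject max–min normalization and labelled
   long tables whose row count obeys
   `n_data = n_participants x n_phases x n_features`
   (4816 for the default 28 x 4 x 43 design).
5. **Screening** — per feature: Kruskal–Wallis across the class
   populations (α = 0.05), then pairwise Mann–Whitney U tests — *Binary
   Analysis* (BA: class 0 vs each altered class, 4 pairs) or *Overall
   Analysis* (OA: all 10 class pairs) — with Benjamini–Hochberg FDR
   correction (q = 0.05) within each feature's family of pairwise
   p-values.  Summaries count features by Kruskal–Wallis significance and
   by the number of surviving pairwise comparisons, and a bullet matrix
   marks features significant in *all* baseline comparisons of every
   test.

## Worked example

```python
import physioscreen as ps

cfg = ps.CohortConfig(n_participants=4, tests=("stroop",), phase_duration_s=120.0,
                      label_distribution=(0.25, 0.25, 0.25, 0.25), seed=5)
cohort = ps.simulate_cohort(cfg)                       # signals + ground truth
features = ps.extract_cohort_features(cohort)          # 43 features per phase
table = ps.build_feature_tables(features, cohort.labels)["stroop"]
report = ps.run_screening(table, ps.ScreeningConfig(mode="BA"))
print(ps.significance_counts(report).to_string(index=False))
s = report.features["scl_mean"]
print(f"SCL mean: KW p = {s.kw.p_value:.4f}, "
      f"significant baseline pairs = {s.n_significant_pairs}/4")
```

prints

```
                     row  count
       test_significance     25
feature_significance_gt1     24
feature_significance_gt2      0
feature_significance_gt3      0
SCL mean: KW p = 0.0102, significant baseline pairs = 2/4
```

The simulator plants class-dependent effects in most channels, so even
this 4-subject toy cohort shows many Kruskal–Wallis-significant features
(`test_significance`), and 24 of 43 survive Benjamini–Hochberg correction
in more than one baseline-vs-altered Mann–Whitney comparison.  The
tonic skin-conductance level rises with class, so its mean is flagged
(KW p ≈ 0.01); with only 4 subjects per class the pairwise tests retain
2 of the 4 baseline comparisons.

The same stages are scriptable from the shell:

```sh
physioscreen simulate --subjects 4 --out cohort/
physioscreen extract --cohort-dir cohort/ --out tables
physioscreen screen --input tables_stroop.csv --mode BA --out report.json
```

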