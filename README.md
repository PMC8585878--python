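# gazeforge

Analysis pipeline for perceptuomotor learning during action observation:
how gaze variability during expert demonstrations relates to motor-skill
acquisition in stone-tool knapping.

Participants learning to knap a handaxe watch the same demonstration video
before, midway through, and after ~100 h of training, while an eye tracker
records gaze and button presses mark moments they judge meaningful.
`gazeforge` turns those recordings into the study's chain of statistics:

1. **Salience** — press latencies become a binary subject × second matrix;
   a 10-s/5-s sliding window yields a probability series of meaningful
   events, and windows at/above the 90th percentile dominated by *core
   move* actions become the shared analysis set.
2. **Temporal dispersion** — per window, x-gaze from all subjects forms a
   time × subject matrix; gaze coefficient of variation (CV = SD/mean) and
   Ward/Euclidean agglomerative time-clusters summarise how gaze varies,
   with within-/between-class variance and per-cluster central objects.
3. **Spatial dispersion** — the core's working edge is tracked per frame by
   RANSAC template registration; distances from each subject's central
   objects to the edge give a mean offset and an edge-referenced
   variability (SD across cluster time centroids).
4. **Shift functions** — session-to-session change per variable is
   quantified decile-by-decile with the Harrell-Davis estimator
   (q̂ = Σᵢ wᵢ x₍ᵢ₎, wᵢ from the regularised incomplete beta function),
   percentile-bootstrap CIs, and Hochberg-adjusted significance.
5. **Canonical correlation** — per session, the performance variate
   (learning slope, handaxe score, percussion error) and gaze variate
   (gaze CV, mean distance from core, gaze variability from core) are
   z-scored, whitened via Cholesky factors, and related through the SVD of
   La⁻¹Σ_ab Lb⁻ᵀ; singular values are the canonical correlations.

A synthetic-experiment generator (`gazeforge.synth`) emulates the whole
data layout — salience-locked presses, fixation/saccade gaze streams with
session-dependent variability, a drifting working edge with
outlier-contaminated feature points, and power-curve performance scores
latently coupled to gaze — so every stage is testable against planted
ground truth without the original recordings.  See `docs/methods.md` for
the models, parameters, and design choices.

## Worked example

Run the full default experiment (11 subjects, three sessions, 1024-s video)
end to end:

```bash
python analysis/02_salience_windows.py
python analysis/03_temporal_dispersion.py
python analysis/04_edge_dispersion.py
```

which prints:

```
203 windows scanned per session; threshold (90th pct, pooled) = 1.000
retained 40 core-move windows; probability range 1.00-1.00
mean analysed core-move run: 6.1 s

cluster count distribution: {2: 76, 3: 35, 4: 7, 5: 2}
mean within-class variance: 61.2% (between: 38.8%)
session mean gaze CV: {'Post1': 0.1066, 'Post2': 0.1005, 'Pre': 0.1542}
-> CV is highest before training, the planted quiet-eye pattern

tracked 10200 frames; 0.0% flagged low-quality
session mean edge-referenced variability: {'Post1': 0.031, 'Post2': 0.0482, 'Pre': 0.0353}
-> variability relative to the edge peaks at Post2, the planted late-training pattern
```

Reading the numbers: every subject presses at every core-move onset in the
default scenario, so onset windows saturate at probability 1 and the
90th-percentile rule keeps 40 of 203 windows.  Gaze CV over the selected
core-move runs falls from 0.154 before training to ~0.10 after — the
"quiet eye" transition from scene exploration to focused observation —
while the dispersion of gaze *relative to the moving working edge* rises at
Post2 (0.048 vs 0.031–0.035), the planted late-training decoupling of gaze
from the edge.  Both match the session profiles configured in the
generator.  The remaining drivers (`05_shift_functions.py`,
`06_canonical_correlation.py`) print the decile shifts across training
transitions and the per-session canonical modes.

The same run is available as a library call or CLI:

```python
from gazeforge.pipeline import RunConfig, run_pipeline
bundle = run_pipeline(RunConfig(seed=1))
bundle.tables["gaze_params"]   # 1,320 rows: 40 windows x 11 subjects x 3 sessions
```

```bash
gazeforge run --seed 1 --out results/run1
```

## Layout

```
src/gazeforge/     library: synth, salience, clustering, edge, shifts, cca,
                   pipeline, cli
analysis/          numbered drivers narrating each stage, writing results/
tests/             unit, property and end-to-end suites (+ brute-force oracles)
scripts/           acceptance.py
docs/methods.md    models, parameters, design choices, limitations
```
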