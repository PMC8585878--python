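# Methods

This note documents the models and procedures implemented in `gazeforge`,
the design choices behind them, and what the synthetic experiments do and do
not establish.

## Study design being emulated

Novice participants learn to knap a stone handaxe over ~100 h of practice.
At three assessments — Pre (0 h), Post1 (50 h), Post2 (100 h) — each
participant watches the same 1024-s demonstration video of an expert while a
60 Hz eye tracker records gaze in normalised screen coordinates, and presses
a button whenever the demonstrator completes a meaningful unit of action.
Each second of the video carries one of six action-phase labels
(core reposition, core move, light percussion, percussion, grinding, tool
change).  Motor skill is scored at each assessment by a handaxe quality
score (higher is better) and a percussion error (lower is better).

## Pipeline

1. **Press salience.** Press latencies are rounded to the nearest second
   (half-up) into a binary subject x second matrix.  A 10-s window sliding
   by 5 s gives, per window, the fraction of subjects with at least one
   press — a probability series of "meaningful events" (203 windows for a
   1024-s video; the final partial window is dropped).
2. **Window selection.** The per-session probability series are pooled by
   window-wise averaging (one shared window set for all sessions) and
   thresholded at their 90th percentile (type-7 linear interpolation).
   Windows at/above threshold whose dominant phase (strict majority of
   seconds; ties to the earliest-occurring phase) is a core move are
   retained; when more than `top_k` (default 40) qualify, the 40 highest-
   probability windows are kept.  Because windows are onset-aligned, each
   retained window is trimmed to the longest continuous core-move run it
   contains before any gaze is analysed.
3. **Temporal dispersion.** Per window and session, x-gaze from all
   subjects is linearly resampled onto a shared 60 Hz grid (invalid samples
   interpolated; subjects >50% invalid excluded) to form a time x subject
   matrix.  Gaze CV per subject is SD/mean of x over the run.  The time
   rows are clustered agglomeratively (Ward's minimum-variance criterion on
   Euclidean distances); when k is not fixed it is chosen by the largest
   merge-height gap with k in [2, 5], ties resolved toward 3.  Cluster
   output: within-/between-class variance as percentages of total sum of
   squares, a dissimilarity summary (mean pairwise distance between cluster
   centroids), and central objects.
4. **Central objects.** Two notions are computed.  The *row* central object
   (the time row closest to the cluster mean, ties to the earliest
   timestamp) summarises the cluster.  The *per-subject* central object —
   for each subject, their own sample closest to their coordinate of the
   cluster centroid, with its own timestamp — feeds the spatial analysis.
   The per-subject form is what makes the edge-referenced statistics robust:
   a subject briefly glancing away is never represented by the glance, so
   transient excursions do not contaminate the dispersion measure.
5. **Edge tracking.** The working edge (rightmost edge of the core) is the
   x-maximum of a bounding box fitted by registering a template feature
   cloud onto each frame's candidate points with RANSAC (translation model;
   one sampled correspondence per hypothesis; consensus inliers within
   0.005 normalised units; least-squares refit; 500 iterations standalone,
   with the previous frame's translation accepted as a warm start when it
   already explains >=80% of the template).  Frames below a 0.3 inlier
   fraction are flagged and interpolated.  Gaze at 60 Hz is matched to
   frames at 30 fps by nearest-frame lookup (discrepancy <= 16.7 ms).
6. **Spatial dispersion.** Signed distance = gaze_x(central object) −
   edge_x(its timestamp); positive = gaze right of the edge.  Per subject
   and window, the mean distance and the sample SD of the distances across
   the window's cluster centroids ("edge variability") are reported.
7. **Session summaries.** Subject identity is permuted within each session
   (a within-condition shuffle that preserves every session-level
   distribution), then per-window values are averaged into one row per
   subject and session.
8. **Shift functions.** For each variable, Shift1 compares Pre to Post1 and
   Shift2 compares Post1 to Post2 as independent groups.  Both samples are
   summarised by nine deciles via the Harrell-Davis estimator (beta-weighted
   average of all order statistics, w_i = I(i/n; a, b) − I((i−1)/n; a, b)
   with a = (n+1)q, b = (n+1)(1−q)).  Decile differences get percentile-
   bootstrap CIs (default 2000 resamples per group) and two-sided bootstrap
   p-values 2·min{P(δ* < 0), P(δ* > 0)} (half-mass at zero), adjusted
   across the nine deciles by Hochberg's step-up method at α = 0.05.
9. **Effect sizes and learning slopes.** Hedges g = J·(mean(a) −
   mean(b))/s_pooled with J = 1 − 3/(4·df − 1); η² = SS_between/SS_total;
   rank-based ε² = H·(n+1)/(n²−1) from the Kruskal–Wallis H.  The learning
   slope is the per-subject OLS slope of handaxe score on √(practice
   hours) — performance follows a power curve, so score is roughly linear
   in √hours and high initial aptitude yields a flatter slope.
10. **Canonical correlation.** Per session, the performance variate
    (learning slope, handaxe score, percussion error) and gaze variate
    (gaze CV, mean distance from core, gaze variability from core) are
    z-scored (ddof = 1 throughout); covariance blocks are whitened by
    Cholesky factors and the SVD of La⁻¹ Σab Lb⁻ᵀ gives the canonical
    correlations (singular values) and weights Wa = La⁻ᵀU, Wb = Lb⁻ᵀV.
    All min(p, q) = 3 modes are reported.  Weights are sign-indeterminate;
    the first nonzero element of each performance-weight column is made
    positive (flipping the paired gaze column so corr(Za, Zb) stays +S).
    The module verifies corr(Za_m, Zb_m) = S_m to 1e-8 and warns when
    n < 5·p, where the estimates are strongly upward-biased.

## Synthetic-data generator

The generator emulates the full data layout with planted ground truth so
every stage is testable without the original recordings.

* **Phase track.** Segments are sampled by phase weight (no immediate
  repeats) with 1 + Poisson(mean − 1) second lengths.  Core moves dominate
  (weight 0.45, mean 7 s), as they do in the demonstration video; with
  saturated press probabilities this leaves at least the canonical 40
  core-move windows at/above the 90th-percentile threshold, which `top_k`
  then fixes at 40.
* **Presses.** Every subject responds to each core-move onset
  (press_response_prob 1.0) with lag ~ N(1.0 s, 0.4 s) clipped at 0, plus
  Poisson background false alarms at 0.003 Hz.
* **Working edge and frames.** The true edge drifts sinusoidally
  (amplitude 0.04, period 90 s) and, within each core-move segment, steps
  through 3 pose plateaus with N(0, 0.04) offsets — the shared structure
  that produces a small number of time clusters.  Frames at 30 fps carry
  the translated 20-point template jittered by N(0, 0.002) plus 40%
  uniform outliers.
* **Gaze.** A two-state renewal process: fixation durations ~
  Gamma(2, 0.15 s) (mean 300 ms), saccades instantaneous, with forced
  saccades at phase transitions (observers re-orient when the action
  changes).  During core moves the anchor tracks the true edge plus a
  Gaussian offset whose SD follows `edge_offset_sd_by_session`
  (default 0.02, 0.02, 0.05) and which is redrawn at each pose — the
  observer re-anchors when the demonstrator resettles the core.  Fixations
  open with a brief exploratory glance (120 ms, uniform locus over the
  scene) with a session probability calibrated so the within-run gaze
  variance meets the session CV target (default 0.30, 0.12, 0.12), capped
  at an exploring time fraction of 0.12.  Outside core moves the anchor
  scans around screen centre.  Sample jitter is N(0, 0.01); coordinates
  are clipped to the unit square.
* **Why the cap.** Within a run, any per-fixation gaze variance feeds both
  the CV and the SD of centroid distances; only brief glances that the
  central-object selection avoids can raise CV without destroying the
  planted edge-offset ordering.  Bounded loci limit how much variance
  glances can add, so large CV targets saturate: the Pre target 0.30 is
  realised at ~0.15 while post-training targets of 0.12 are met exactly.
  Session CV profiles are therefore contracts about *ordering* first and
  magnitude second; post-training targets of 0.15 would be realised at
  ~0.14, indistinguishable from the capped Pre level, which is why the
  default profile uses 0.12.
* **Performance.** Handaxe score rises along a saturating curve in
  √hours toward an asymptote (initial 2, asymptote 10, rate 0.35, noise SD
  0.4); percussion error decays stepwise (30, 15, 8) with noise SD 2.
  A latent aptitude z ~ N(0,1) raises the initial score (gain 1.2, slightly
  lowering the asymptote), lowers percussion error multiplicatively, and is
  correlated (default 0.6) with a gaze parameter that scales the subject's
  edge-offset SD — the planted gaze-performance coupling the CCA should
  find.

### What the generator does not model

No pixel-level video, pupil or blink dynamics, saccadic flight samples,
smooth-pursuit dynamics, calibration drift, or missing-data structure
beyond an optional uniform missingness flag.  Passing tests therefore show
that the *analysis* recovers planted structure of this idealised form; they
do not validate the pipeline against real eye-tracking artefacts.

## Numerical choices

* Percentile threshold and bootstrap CIs use linear interpolation between
  order statistics; sample SDs use ddof = 1.
* Round-half-up latency binning; latencies rounding to the video end are
  clamped into the final second.
* Ward clustering delegates to `scipy.cluster.hierarchy.linkage`
  (method="ward"); tests verify it against a brute-force Lance–Williams
  recomputation.  Cluster labels are renumbered in order of first
  appearance so results are deterministic.
* Degenerate guards: all-identical rows in the variance decomposition
  report (0, 0) flagged; dissimilarity for k = 1 is NaN; constant samples
  collapse shift-function CIs to a point, flagged; all-equal groups give
  zero effect sizes, flagged; constant columns are an error in CCA.
* All randomness flows from one root seed split per stage
  (`numpy.random.SeedSequence`); two runs with the same configuration are
  byte-identical.

## Problem sizes

The default experiment (11 subjects, 3 sessions, 1024 s video, 60 Hz gaze,
30 fps frames) runs end to end in a few seconds.  Repeated-run checks use
10–20 seeded replicates; bootstrap calibration uses 500 simulations of
n = 50 groups at 2000 resamples — sizes chosen so the whole suite completes
in minutes while keeping Monte-Carlo error well below the margins being
asserted.

## Known limitations

* With n = 11 subjects and p = q = 3 the canonical correlations are
  strongly upward-biased; the module warns but computes, since that is the
  design being emulated.  Mode-level r² values fluctuate widely across
  seeds at this n.
* The dissimilarity statistic (mean pairwise centroid distance) is one
  reading of an under-specified summary; it is flagged as an
  interpretation in its docstring.
* The exploration cap couples large CV targets to partial realisation (see
  above); configurations demanding CV targets far above what bounded
  glances can produce will realise the ordering, not the magnitude.
* Edge tracking assumes the core is rigid and moves slowly between frames;
  the optional translation+scale model is provided but untuned.
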