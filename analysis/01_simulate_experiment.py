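#!/usr/bin/env python
"""Generate the default synthetic observation-learning experiment.

Eleven subjects watch a 1024-s knapping demonstration at three assessments
(Pre, Post1, Post2); the generator plants session profiles -- gaze CV
highest before training, edge-referenced offset SD elevated at Post2, and a
latent aptitude coupling performance to gaze.  Writes the small per-study
tables (presses, phases, performance, true edge, latents); the per-sample
gaze and feature-point tables are regenerated on demand by the pipeline
rather than stored.
"""

import numpy as np

from gazeforge.synth import SynthConfig, generate_dataset, write_dataset_csvs

from _common import SEED, outdir


def main():
    cfg = SynthConfig(seed=SEED)
    ds = generate_dataset(cfg)
    out = outdir("01_synthetic")
    paths = write_dataset_csvs(
        ds, out,
        include={"press.csv", "phase.csv", "performance.csv", "edge.csv",
                 "template.csv", "latent_truth.csv"},
    )
    n_moves = len(ds.phase_track.onsets("core_move"))
    presses = np.mean([len(l.latencies) for l in ds.press_logs])
    print(f"wrote {len(paths)} tables to {out}")
    print(f"video: {ds.phase_track.duration_s} s with {n_moves} core-move "
          f"segments; mean presses per viewing: {presses:.1f}")
    print(f"gaze: {len(ds.gaze_streams)} subject-session streams at "
          f"{cfg.sample_rate_hz:.0f} Hz; frames: {ds.frame_points.shape[0]} "
          f"at {cfg.frame_rate_hz:.0f} fps "
          f"({ds.frame_points.shape[1]} candidate points each)")
    print(f"planted aptitude-gaze coupling: {cfg.latent_coupling}")


if __name__ == "__main__":
    main()
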