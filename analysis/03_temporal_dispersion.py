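#!/usr/bin/env python
"""Temporal dispersion of gaze: CV and Ward time-clusters per window.

Each selected window's core-move run is resampled into a time x subject
x-gaze matrix, clustered with Ward/Euclidean agglomeration, and summarised
by within-/between-class variance and cluster count; gaze CV is computed per
subject over the same continuous segment.
"""

from _common import default_bundle, outdir


def main():
    _, bundle = default_bundle()
    out = outdir("03_temporal")
    bundle.tables["cluster_summary"].to_csv(out / "cluster_summary.csv",
                                            index=False)
    bundle.tables["central_objects"].to_csv(out / "central_objects.csv",
                                            index=False)
    cs = bundle.tables["cluster_summary"]
    print("cluster count distribution:",
          cs["k"].value_counts().sort_index().to_dict())
    print(f"mean within-class variance: {cs['within_pct'].mean():.1f}% "
          f"(between: {cs['between_pct'].mean():.1f}%)")
    cv = bundle.tables["gaze_params"].groupby("session")["gaze_cv"].mean()
    print("session mean gaze CV:",
          {k: round(v, 4) for k, v in cv.items()})
    print("-> CV is highest before training, the planted quiet-eye pattern"
          if cv["Pre"] > max(cv["Post1"], cv["Post2"])
          else "-> warning: CV ordering not recovered in this run")


if __name__ == "__main__":
    main()
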