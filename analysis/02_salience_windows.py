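#!/usr/bin/env python
"""Button-press salience and selection of the analysis windows.

Presses are pooled into a subject x second matrix per session, a 10-s/5-s
sliding window turns them into a probability series, and windows at or above
the 90th percentile whose dominant phase is a core move become the shared
analysis set (trimmed to the canonical 40).
"""

from _common import default_bundle, outdir


def main():
    _, bundle = default_bundle()
    out = outdir("02_salience")
    bundle.tables["salience_series"].to_csv(out / "salience_series.csv",
                                            index=False)
    bundle.tables["selected_windows"].to_csv(out / "selected_windows.csv",
                                             index=False)
    sel = bundle.manifest["selection"]
    wins = bundle.tables["selected_windows"]
    print(f"{len(bundle.tables['salience_series'])//3} windows scanned per "
          f"session; threshold (90th pct, pooled) = {sel['threshold']:.3f}")
    print(f"retained {sel['n_windows']} core-move windows; probability range "
          f"{wins['probability'].min():.2f}-{wins['probability'].max():.2f}")
    print(f"mean analysed core-move run: "
          f"{(wins['run_end_s'] - wins['run_start_s']).mean():.1f} s")


if __name__ == "__main__":
    main()
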