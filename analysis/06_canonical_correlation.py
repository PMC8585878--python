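#!/usr/bin/env python
"""Canonical correlation between the performance and gaze variates.

Per session, the 3-variable performance variate (learning slope, handaxe
score, percussion error) and the 3-variable gaze variate (gaze CV, mean
distance from core, gaze variability from core) are z-scored, whitened by
Cholesky factors, and related by SVD; the singular values are the canonical
correlations and the weights give each variable's contribution.
"""

from _common import default_bundle, outdir


def main():
    _, bundle = default_bundle()
    out = outdir("06_cca")
    bundle.tables["cca_modes"].to_csv(out / "cca_modes.csv", index=False)
    bundle.tables["cca_weights"].to_csv(out / "cca_weights.csv", index=False)
    weights = bundle.tables["cca_weights"]
    for sess in ("Pre", "Post1", "Post2"):
        sub = weights[(weights["session"] == sess) & (weights["mode"] == 1)]
        r2 = sub["r_squared"].iloc[0]
        top = sub.reindex(sub["weight"].abs().sort_values(ascending=False).index)
        names = ", ".join(
            f"{r['variable']} ({r['weight']:+.2f})" for _, r in top.head(2).iterrows()
        )
        print(f"{sess}: mode-1 r^2 = {r2:.3f}; dominant weights: {names}")


if __name__ == "__main__":
    main()
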