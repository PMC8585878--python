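#!/usr/bin/env python
"""Shift functions and effect sizes across training transitions.

Subject-level session means (after the within-condition permutation) are
compared decile-by-decile with Harrell-Davis shift functions: Shift1 is
Post1 vs Pre, Shift2 is Post2 vs Post1, each decile with a percentile-
bootstrap CI and Hochberg-adjusted significance.
"""

from _common import default_bundle, outdir


def main():
    _, bundle = default_bundle()
    out = outdir("05_shifts")
    bundle.tables["shift_functions"].to_csv(out / "shift_functions.csv",
                                            index=False)
    bundle.tables["effect_sizes"].to_csv(out / "effect_sizes.csv", index=False)
    sf = bundle.tables["shift_functions"]
    for comp in ("Shift1", "Shift2"):
        sub = sf[sf["comparison"] == comp]
        strongest = (
            sub.groupby("variable")["difference"]
            .apply(lambda d: d.abs().mean())
            .idxmax()
        )
        sel = sub[sub["variable"] == strongest]
        print(f"{comp}: strongest shift in {strongest} "
              f"(mean decile difference {sel['difference'].mean():+.3f}, "
              f"{int(sel['significant'].sum())}/9 deciles significant)")
    es = bundle.tables["effect_sizes"]
    print("largest |Hedges g|:")
    top = es.reindex(es["hedges_g"].abs().sort_values(ascending=False).index)
    for _, r in top.head(3).iterrows():
        print(f"  {r['variable']} {r['comparison']}: g = {r['hedges_g']:+.2f}")


if __name__ == "__main__":
    main()
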