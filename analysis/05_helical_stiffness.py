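#!/usr/bin/env python
"""Conditional twist statistics and harmonic stiffness per case.

For every generated case/condition: the BI/BII-conditional twist widths
(the BI distribution is broader, so raising the BII population narrows
the cumulative twist distribution), the segment-level
(twist, stretch, bend) covariance and stiffness K = kB*T*C^-1, and the
reference-vs-masked relative stiffness changes.  Writes
results/mechanics/.
"""

from pathlib import Path

import pandas as pd

from methylflex.mechanics import (conditional_twist_stats, gaussianity_check,
                                  relative_change, segment_aggregate,
                                  stiffness)

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "mechanics"
SEGMENT = [1, 2, 3, 4]


def load(case, cond):
    d = BASE / "ensembles" / case / cond
    return (pd.read_csv(d / "step_parameters.csv"),
            pd.read_csv(d / "substates.csv"))


def main():
    manifest = pd.read_csv(BASE / "ensembles" / "manifest.csv")
    OUT.mkdir(parents=True, exist_ok=True)
    twist_rows, stiff = [], {}
    for _, m in manifest.iterrows():
        steps, track = load(m["case"], m["condition"])
        tw = conditional_twist_stats(steps, track, n_blocks=5)
        twist_rows.append({"case": m["case"], "condition": m["condition"],
                           **{k: v for k, v in tw.items()}})
        seg = segment_aggregate(steps, SEGMENT)
        res = stiffness(seg[["twist", "stretch", "bend"]],
                        temperature=300.0)
        stiff[(m["case"], m["condition"])] = res
        cov_df, k_df = res.to_frames()
        k_df.to_csv(OUT / f"stiffness_{m['case']}_{m['condition']}.csv")
        gauss = gaussianity_check(seg[["frame", "twist", "stretch", "bend"]])
        gauss.to_csv(OUT / f"gaussianity_{m['case']}_{m['condition']}.csv",
                     index=False)

    twist = pd.DataFrame(twist_rows)
    twist.to_csv(OUT / "conditional_twist.csv", index=False)

    rel_rows = []
    for case in manifest["case"].unique():
        rel = relative_change(stiff[(case, "reference")],
                              stiff[(case, "masked")])
        rel.insert(0, "case", case)
        rel_rows.append(rel)
    rel_table = pd.concat(rel_rows, ignore_index=True)
    rel_table.to_csv(OUT / "relative_stiffness_changes.csv", index=False)

    cols = ["case", "condition", "sigma_BI", "sigma_BII", "sigma_total"]
    print("Conditional twist widths (deg; BI broader than BII):")
    print(twist[cols].round(3).to_string(index=False))
    print("\nRelative stiffness changes, masked vs reference (percent):")
    pivot = rel_table.pivot(index="case", columns="variable",
                            values="stiffness_change_percent")
    print(pivot.round(1).to_string())
    print("\n-> raising the BII population stiffens the twist mode "
          "(narrower cumulative distribution), the mechanism linking "
          "methyl-sugar clashes to DNA flexibility.")


if __name__ == "__main__":
    main()
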