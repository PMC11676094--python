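#!/usr/bin/env python
"""Biochemical calculations on the published summary tables.

Runs the pooled two-tailed Student's t-test on every serum analyte row
(mean, SD, n per group), derives XDH activity from the XOR/XO group means,
and shows a worked 2^-ddCt example.  Writes results/biochemistry.json and
a per-analyte t-test table.
"""

import json
from pathlib import Path

import pandas as pd

from stressnmr.biochem import (
    CtQuartet,
    GroupSummary,
    ddct_fold_change,
    pooled_t_test,
    xdh_from_xor_xo,
)
from stressnmr.datasets import (
    N_CONTROL,
    N_STRESSED,
    load_enzyme_activities,
    load_serum_biochemistry,
)

panel = load_serum_biochemistry()
rows = []
for _, row in panel.iterrows():
    res = pooled_t_test(
        GroupSummary(row["control_mean"], row["control_sd"], N_CONTROL),
        GroupSummary(row["stressed_mean"], row["stressed_sd"], N_STRESSED),
    )
    rows.append({"analyte": row["analyte"], "unit": row["unit"],
                 "t": round(res.t, 3), "df": int(res.df), "p": round(res.p, 4)})
ttests = pd.DataFrame(rows)
ttests.to_csv("results/serum_ttests.tsv", sep="\t", index=False)

sig = ttests[ttests["p"] < 0.05]
print(f"serum panel: {len(ttests)} analytes tested (pooled t, df = "
      f"{N_CONTROL + N_STRESSED - 2}); significant at p < 0.05: "
      f"{', '.join(sig['analyte'])}")
ua = ttests.set_index("analyte").loc["UA"]
print(f"uric acid: t = {ua['t']}, p = {ua['p']} (below-threshold trend)")

acts = load_enzyme_activities().set_index("group")
xdh = {
    g: xdh_from_xor_xo(float(acts.loc[g, "xor_mean"]), float(acts.loc[g, "xo_mean"]))
    for g in acts.index
}
for g, v in xdh.items():
    print(f"XDH activity ({g}) = XOR - XO = {v:.3f} U/mL")

ddct_example = ddct_fold_change(CtQuartet(24.2, 17.8, 23.4, 17.9))
print(f"2^-ddCt example (target shifted +0.9 cycles relative to control): "
      f"fold change = {ddct_example:.3f}")

Path("results/biochemistry.json").write_text(json.dumps({
    "xdh_u_per_ml": xdh,
    "uric_acid_p": float(ua["p"]),
    "glucose_p": float(ttests.set_index("analyte").loc["Glc", "p"]),
    "ddct_example_fold_change": ddct_example,
}, indent=2) + "\n")
print("wrote results/serum_ttests.tsv and results/biochemistry.json")
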