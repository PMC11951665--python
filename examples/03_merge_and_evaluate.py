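"""Merge the two imputation strategies and tabulate PPV and recall.

"Logical" merging keeps, per SV, whichever strategy produced the higher
posterior support; "non-logical" always prefers the GL-supplemented call.
Both append the SVs that only the LD-only run covers, so merging restores
the recall the GL-supplemented run loses to evidence dropout while
keeping most of its accuracy gain.
"""

import pandas as pd

from svimpute import (
    RunSpec, SimulationConfig, evaluate, merge_strategies,
    run_strategy, simulate_panel, simulate_target,
)

config = SimulationConfig(seed=7)
panel, variants = simulate_panel(config)
truth = simulate_target(panel, config, sample="S0004")

base = {
    s: run_strategy(RunSpec("S0004", 1.0, s, seed=11), panel, truth, config)
    for s in ("ld_only", "gl_supplemented")
}
merged = merge_strategies(base["ld_only"], base["gl_supplemented"], "logical")

rows = []
for name, recs in {**base, "merged_logical": merged}.items():
    t = evaluate(recs, truth, variants, pp_cutoffs=(0.9,), strategy=name)
    rows.append(t[(t.var_class == "DEL") & (t.length_bin == "all")])
table = pd.concat(rows)[["strategy", "n_correct", "n_incorrect",
                         "n_missing", "n_total_panel", "ppv", "recall"]]
print("deletions at 1x, PP >= 0.9:")
print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print("\nrecall counts calls against ALL panel deletions, so the merged",
      "strategy recovers the recall gl_supplemented loses to dropout.")

bins = evaluate(merged, truth, variants, pp_cutoffs=(0.9,))
bins = bins[(bins.var_class == "DEL") & (bins.length_bin != "all")]
print("\nmerged deletion PPV by length bin (bp):")
print(bins[["length_bin", "n_total_panel", "ppv", "recall"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3f}"))
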