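"""Punctate vs uniform cohort: per-group index distributions and a rank test.

Generates matched jittered nuclei for both groups, runs the batch pipeline,
and summarizes the per-nucleus fluctuation indices.  A small cohort is used
here to keep the example fast; increase n_per_group for a real comparison.
"""

import laminafluct as lf
from laminafluct.pipeline import RunConfig, run_analysis, summarize_groups

members = lf.generate_cohort(lf.punctate_spec(), lf.uniform_spec(), n_per_group=8, seed=0)
inputs = [(m.stack, f"{m.label}_{m.index_in_group}", m.label) for m in members]
report = run_analysis(RunConfig(log_level="WARNING"), inputs)

summary, p = summarize_groups(report, alternative="greater")
print(summary.to_string(index=False))
if p is not None:
    print(f"one-sided Mann-Whitney U p (punctate > uniform): {p:.3f}")
print("with camera noise the group separation is modest and a cohort this small\n"
      "can even reverse the medians (see docs/methods.md on noise sensitivity);\n"
      "noise-free runs separate cleanly, as in example 02")
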