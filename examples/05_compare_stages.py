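"""Compare AUC across estrous stages in a simulated cohort.

Runs the full pipeline on 6 animals x 4 stages (each animal's proestrous
trace serving as its prominence reference), then applies the test-policy
layer: normality and variance checks pick the parametric (RM-ANOVA +
Tukey) or non-parametric (Friedman + Dunn) branch.
"""

import pandas as pd

import photosurge as ps

rows = []
for i in range(6):
    ref = None
    for j, stage in enumerate(["proestrus", "metestrus", "diestrus", "estrus"]):
        raw, _ = ps.generate_recording(stage, seed=100 * i + j)
        raw.animal_id = f"m{i}"
        res = ps.run_pipeline(raw, reference_trace=ref)
        if stage == "proestrus":
            ref = res.trace
        rows.append(res.summary.to_frame())
summaries = pd.concat(rows, ignore_index=True)

print(summaries.pivot(index="animal_id", columns="stage", values="auc").round(0))
comp = ps.compare_groups(summaries, value="auc")
print(f"\n{comp.test} ({comp.branch}): statistic={comp.statistic:.2f}, p={comp.p:.4g}")
for a, b, stat, p_adj in comp.posthoc:
    print(f"  {a} vs {b}: adjusted p = {p_adj:.4g}")
# Proestrous AUC exceeding every other stage, with a significant omnibus
# test, mirrors the stage dependence of surge-generator output.
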