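"""Pain-scale descriptives and inter-observer reliability.

Summarizes generated total pain scores per scale and phase (the floor effect
is visible in the medians), then computes the absolute-agreement ICC(2, A1)
per scale with its 95% CI and reliability label.
"""
from equipain import (StudyConfig, builtin_scales, generate_study,
                      icc_by_scale, percent_of_max, summarize_scores)

study = generate_study(StudyConfig(seed=1))

print("score summaries (median / Q1-Q3 / max):")
summary = summarize_scores(study.assessments, by="phase")
for _, r in summary.iterrows():
    print(f"  {r['scale']:10s} {r['phase']:15s} median {r['median']:.1f}  "
          f"IQ {r['q1']:.2f}-{r['q3']:.2f}  max {r['max']:.0f}")

print("\nhighest total as % of scale maximum:")
for s in builtin_scales():
    top = study.assessments.loc[study.assessments["scale"] == s.name, "total"].max()
    print(f"  {s.name:10s} {percent_of_max(top, s):5.1f}% (total {top}/{s.total_max})")

print("\ninter-observer reliability:")
icc = icc_by_scale(study.assessments, [s.name for s in builtin_scales()])
for _, r in icc.iterrows():
    print(f"  {r['scale']:10s} ICC {r['icc']:.3f} ({r['ci_low']:.3f}-{r['ci_high']:.3f})"
          f"  {r['label']}")
# Most totals sit near zero (floor effect); ICC labels follow the
# poor (<0.5) / moderate / good / excellent (>=0.9) convention.
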