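"""ROC/AUC of model predictions against TAS-defined pain status.

Pain status is TAS > 10 mm (a mild-lameness analogue).  Model-predicted
scores serve as the diagnostic test; AUC is the probability a 'pain'
observation outranks a 'no pain' one.
"""
from equipain import (StudyConfig, add_timeline_columns, compute_roc,
                      fit_association_model, generate_study, predict_scores)
from equipain.pipeline import compute_study_asymmetry

study = generate_study(StudyConfig(seed=1), out_dir="scratch/example_study")
asym = add_timeline_columns(compute_study_asymmetry(study.occasions, study.trace_dir))
merged = study.assessments.merge(
    asym[["horse", "occasion", "tas_mm", "prop_time_pct", "pain_status"]],
    on=["horse", "occasion"])

for scale in ("CPS", "HGS"):
    cell = merged[(merged["observer"].astype(str) == "1")
                  & (merged["scale"] == scale)]
    fit = fit_association_model(cell)
    curve = compute_roc(predict_scores(fit, cell),
                        cell["pain_status"].to_numpy(bool))
    print(f"observer 1 x {scale}: AUC {curve.auc:.3f} "
          f"(95% CI {curve.ci_low:.3f}-{curve.ci_high:.3f})  {curve.label}  "
          f"[{curve.n_pos} pain / {curve.n_neg} no-pain]")
# AUC > 0.72 counts as good diagnostic accuracy; <= 0.5 means the scale
# cannot distinguish pain from no pain for that observer.
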