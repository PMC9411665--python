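"""Generate a synthetic LPS-synovitis study and look at its structure.

Builds the default 8-horse study: per-horse asymmetry pulses, gait-analysis
occasions, and before/after pain assessments by three observers on four
scales.  Prints the design counts a real study report would state.
"""
import numpy as np

from equipain import StudyConfig, generate_study

cfg = StudyConfig(seed=1)
study = generate_study(cfg)

occ = study.occasions
events = study.assessments.drop_duplicates(subset=["horse", "occasion", "timing"])
peaks = [t.peak for t in study.trajectories.values()]

print(f"horses:                  {occ['horse'].nunique()}")
print(f"gait occasions/horse:    {len(occ) / occ['horse'].nunique():.2f}")
print(f"pain assessments/horse:  {len(events) / occ['horse'].nunique():.2f}")
print(f"peak TAS per horse (mm): {np.round(sorted(peaks), 1)}")
print(f"max true TAS sampled:    {occ['true_tas_mm'].max():.1f} mm")
# Each horse gets one baseline occasion (TAS 0) and serial post-induction
# occasions; peak TAS varies strongly between horses, as in a real induction.
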