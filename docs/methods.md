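# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Gait metrics

A trotting horse's head and pelvis move down twice per stride, once per
diagonal stance phase; orthopedic pain reduces loading of the painful limb
and makes the two minima unequal. The pipeline ingests per-trial vertical
traces (tab-separated `time_s, head_z_mm, pelvis_z_mm`, nominally 200 Hz)
and computes:

* **Stride segmentation.** The dominant spectral peak of the pelvis trace is
  located in 2.0–5.0 Hz (the double-frequency oscillation) and halved to an
  estimated stride rate, which must fall in the physiologic 1.0–2.5 Hz trot
  band; the peak must exceed 20× the broadband median power, otherwise a
  segmentation-failure error is raised. Both traces are low-pass filtered
  with a zero-phase 4th-order Butterworth at 4× the stride rate. Local
  minima are detected with a minimum separation of 0.3 stride periods and a
  prominence of at least 20% of the median minimum prominence; edge minima
  whose half-stride window leaves the trace are discarded, and fewer than 5
  complete strides is an error. Minimum *values* are refined by parabolic
  interpolation of the three samples around each minimum, which removes the
  sampling-grid discretization error (important at 200 Hz, where the raw
  sample minimum can be off by ~0.05 mm).
* **HDmin / PDmin.** Per stride, side-1 minus side-2 stance minima of the
  filtered head (pelvis) trace; minima alternate, with parity fixed by the
  first detected minimum. Trial means are converted once to positive
  magnitudes (the conventional "right-positive" reporting); the signed
  means are retained alongside. When an occasion has several trials their
  trial means are averaged.
* **TAS.** `|ΔHDmin|/2 + |ΔPDmin|` relative to the horse's single baseline
  occasion (clock time ≤ 0). The halving of the head term reflects the
  head's larger compensatory excursion; applying it to the differenced
  value is algebraically identical to halving before differencing.

Because side-1/side-2 labels are parity labels, not true left/right limb
identities (no limb markers are ingested), cross-trial comparability rests
on the magnitude-based TAS formula.

## Proportional time and pain status

Each horse responds on its own clock, so occasions are mapped horse-by-horse
onto a proportional scale: baseline → 0%, the peak-TAS occasion → 50%, the
last occasion → 100%, other occasions linearly interpolated in clock time
within their segment. Ties in the peak resolve to the earliest occasion. If
the peak *is* the last occasion, that occasion maps to 100% and the 50%
anchor is placed one inter-occasion segment earlier (logged); a peak at
baseline is a degenerate-anchor error. Whether intermediate occasions should
interpolate in clock time or rank is genuinely open; clock time was chosen
as the less information-destroying option.

Binary pain status uses the strict rule TAS > 10 mm (a mild-lameness
analogue); the cut-off is configurable (`--pain-cutoff-mm`).

## Pain scales and summaries

The four scales are represented by total range and observation time only —
HGS 0–12 (2 min), EQUUS-FAP 0–18 (2 min), EPS 0–30 (2 min), CPS 0–39
(5 min); item-level wording belongs to the original scale publications, and
the analysis consumes totals exclusively. Optional user-supplied item lists
are validated (item maxima must sum to the total maximum; totals recomputed
from items). Score summaries report median, Q1–Q3, min and max per scale ×
phase with quartiles by linear interpolation between order statistics
(R type-7, numpy's default) — the rule is fixed and documented because
quartiles of small integer samples depend visibly on it. A Shapiro–Wilk
p-value per scale flags non-normality; constant or tiny samples are flagged
`n/a` rather than tested.

## Reliability

ICC(2, A1): two-way random-effects, absolute-agreement, single-rater, from
the subjects × raters ANOVA mean squares (subjects = assessment events).
The 95% CI is the McGraw–Wong F construction with a Satterthwaite
denominator df. Missing ratings are handled by complete-case deletion after
pooling all non-fixed observers into a single "third rater" column,
mirroring a rotating-third-observer design; per-observer columns are
available (`pool_third=False`). At least 5 complete subjects are required;
zero-variance grids raise a degenerate-variance error. Labels: < 0.5 poor,
0.5–0.75 moderate, 0.75–0.9 good, ≥ 0.9 excellent (configurable).

## Association model

Per observer × scale:

```
score_ij = β0 + f(TAS_ij) + β1·1[before gait] + b_i + ε_ij
b_i ~ N(0, σ²_horse),  corr(ε_ij, ε_ij') = φ^|j−j'|  within horse
```

* **Smooth.** Cubic B-splines, basis dimension k = 10 on quantile-spaced
  knots. The penalty is the second-order *divided* difference on the
  Greville abscissae, so its null space is exactly {1, x} even with unequal
  knots; the smooth therefore decomposes exactly into a fixed centred
  linear column plus a wiggle block `Z = B D⁺` treated as i.i.d. random
  coefficients (the standard mixed-model representation of a penalized
  spline). This exactness is what makes the infinite-smoothing limit
  coincide with ordinary least squares to machine precision, which the
  tests exploit as an oracle.
* **Estimation.** The variance parameters (smoothing parameter as a
  variance ratio, horse-to-residual ratio, AR(1) φ) are estimated by
  numerically maximized profiled REML (L-BFGS-B on log/atanh scales, with a
  Nelder-Mead polish on flat profiles); β and the wiggle BLUPs follow by
  penalized GLS. |φ| > 0.97 triggers a warning and a profile refit at
  ±0.95. The AR(1) index is the within-horse *rank* of proportional time
  (equal-step assumption); the true observation spacing is not used, which
  is itself an open modelling choice.
* **EDF.** Trace of the smooth's block of the influence matrix
  `(CᵀV⁻¹C + P)⁻¹ CᵀV⁻¹C`, clipped to [1, k−1]. EDF ≈ 1 means effectively
  linear. Note the REML EDF has a fat right tail under exactly linear
  truth (a sizeable minority of fits land above 1.5 with a near-flat REML
  profile); properties about EDF are therefore asserted on replicate
  medians, and an independent mixed-model spline implementation shows the
  same behaviour on identical data.
* **Inference.** Association: maximum-likelihood likelihood-ratio test of
  the full model against the smooth-dropped model (intercept + timing +
  random structure), referred to χ² with the smooth's EDF — approximate,
  but empirically calibrated in the suite's null simulation (measured
  rejection ≈ 5% at nominal 5%). Timing: Wald test on β1 with the
  penalized-GLS covariance. `r2_adj = 1 − [RSS/(n − edf_total)]/[TSS/(n−1)]`
  from population-level fitted values; it can be negative on null data, and
  the suite asserts that this occurs.
* **Prediction / partial effects.** Population-level by default (random
  effects at zero), horse-conditional on request. TAS beyond the training
  range extrapolates the smooth linearly with a warning. Partial-effect
  curves are centred to mean zero over the training TAS values with
  pointwise ±1.96·SE bands from the penalized-GLS (Bayesian) covariance.

Models require ≥ 20 rows and ≥ 2 horses; observer × scale cells below that
are skipped with a logged warning, mirroring sparse rotating observers.

## Diagnostic accuracy

Empirical ROC over all distinct prediction thresholds; AUC as the
Mann–Whitney probability with ties counted ½ (identical to the trapezoid
area, which a property test verifies against brute-force pair counting).
95% CI by DeLong structural components with a normal approximation, clipped
to [0, 1]; degenerate variance collapses the CI to the point with a
warning. Labels: ≤ 0.5 no discrimination, (0.5, 0.72) poor, [0.72, 0.8)
good, [0.8, 0.9) excellent, ≥ 0.9 outstanding — the good/poor boundary at
0.72 follows the convention that AUC > 0.72 marks good accuracy; bands are
configurable.

## Synthetic-data generator

The generator emulates an 8-horse LPS-induction study and is the package's
test bed; its defaults are the study conditions, not tuning knobs.

* **Trial waveform.** With stride phase θ = 2πft (f ≈ 1.25–1.55 Hz,
  per-horse), vertical displacement is
  `A·sin(2θ) + (d/2)·cos(θ − 3π/4) + noise`. The phase offset −3π/4 makes
  the slow (once-per-stride) component have zero slope exactly at the fast
  component's minima, so alternate minima differ by exactly `d` without
  shifting position — the injected HDmin/PDmin is exact by construction,
  which the recovery tests rely on. Defaults: head amplitude 60 mm, pelvis
  45 mm, 1 mm Gaussian marker noise, 15 s at 200 Hz (~21 strides; real
  straight-line trials are of this order).
* **Asymmetry pulse.** True TAS follows `P·(t/τ)·exp(1 − t/τ)`: zero at
  induction, peak P at t = τ, smooth decay. P is log-normal with population
  mean 27 mm and SD 26 mm (right-skewed, SD ≈ mean, matching the strong
  between-horse variation of induced lameness), truncated at 110 mm — the
  analogue of a rescue-analgesia severity cap, which also keeps injected
  asymmetries inside the waveform's two-minima regime; the truncation moves
  the population mean by under 2%. τ ~ N(8 h, 2 h) clipped so the pulse is
  below 10% of its peak at the 52 h horizon.
* **Design.** One baseline occasion (t = −24 h, TAS 0) plus post-induction
  occasions (count ~ N(6.6, 1.2) total, minimum 4 post-induction) at times
  drawn via a u² mapping of uniform draws over (1.5 h, 52 h) — denser
  during pain progression, ≥ 1 h apart. Occasion spacing is unreported in
  such studies and is a free design choice here. TAS splits into injected
  metrics as ΔPDmin = 0.6·TAS and ΔHDmin = 0.8·TAS (so |ΔHD|/2 + |ΔPD|
  reproduces TAS exactly) on top of per-horse baseline asymmetries.
* **Pain scores.** Each kept (occasion, before/after) slot is one
  assessment event scored by observers 1, 2 and a rotating third (3/4/5,
  weights 0.6/0.2/0.2, fixed per occasion). Slots are subsampled so events
  per horse match N(12.1, 2.4). A score is
  `clip(round(scale_max · (gain·g(TAS) + bias + before_effect·1[before] + noise)), 0, max)`
  with `g(t) = t/(t + 60 mm)` (monotone, saturating: meaningful score
  increases only at substantial asymmetry) and per-observer zero-inflation.
  Observer defaults (gain 0.20–0.40, noise SD 0.02–0.05, zero-inflation
  0.10–0.25) were chosen once to land in the moderate-reliability,
  strong-floor-effect regime typical of untrained observers; the
  heterogeneity is per-observer configurable so reliability experiments can
  span poor to excellent. The before-gait elevation (0.03 of scale maximum)
  emulates higher scores before movement.
* **Determinism.** One root seed; per-horse/per-purpose substreams derived
  via `SeedSequence` key paths. Identical config ⇒ byte-identical study
  files, and the pipeline manifest (config snapshot, seed, SHA-256 of every
  input and output, no timestamps) makes whole runs byte-reproducible.

**What the generator does not emulate:** real stride-to-stride variability
(stride frequency is constant within a trial), non-stationary baselines,
limb-specific compensation patterns, observer drift or learning, missing
trace segments, and ordinal item-level scoring (totals are generated
directly). Passing tests therefore demonstrate correctness of the analysis
chain under the assumed signal and scoring models, not robustness to every
artefact of field data.

## Problem sizes in the suite

The acceptance tests use: 16-point injected-asymmetry grids at 0 and 1 mm
noise; 1000 simulated horses for pulse calibration; n = 400-row model fits
(21 replicates for EDF/slope medians, 9 for φ); and a 1000-replicate null
simulation at n = 150 rows for the association test's type-I error — sizes
chosen to give stable medians and ~0.7 pp Monte-Carlo error on the
rejection rate.

## Known limitations

* ICC missing-data handling is complete-case after third-rater pooling;
  algorithms that exploit partially observed rows would differ on sparse
  designs.
* The association LRT p-value is approximate (boundary/adaptive-df issues);
  its calibration was verified by simulation at the suite's design points
  only.
* The AR(1) structure ignores irregular occasion spacing (rank-based index).
* ROC treats model predictions as fixed; no uncertainty from the model fit
  propagates into the AUC CI.
* True limb identity (left/right) is not recovered — only asymmetry
  magnitudes.
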