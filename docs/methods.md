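# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would need to know.

## Plate calibration and quality control

Each PCR array carries a synthetic inter-plate calibrator (IPC) template in
six no-template-control wells. The plate offset is defined as the plate's
mean calibrator Ct minus the grand mean of per-plate calibrator means, and is
subtracted from every well on the plate; after correction all plates share
the same calibrator mean by construction. The calibrator is assumed to be
pipetted at a fixed amount, so offsets capture instrument/plate effects only.

A hard ceiling of **35.00 cycles** is then applied: undetected wells, wells
above the ceiling, and wells whose amplification curve was rejected are all
set to exactly 35.00 and flagged. Ceiling cells count as non-detections; the
value itself acts as a conservative floor on abundance when fold-changes are
computed. The curve flag defaults to "good" when the export has no curve
column, because curve review is a manual step the pipeline can only record.

Three filters follow, each computed **once on the full input set** before any
exclusion (so the pass/fail partition is independent of processing order and
of other exclusions; the alternative — iterative re-filtering — is not
uniquely defined and was rejected for that reason):

* spike-in filter: both the isolation spike-in and the RT spike-in of a
  sample must lie within mean ± 2 SD of that spike-in over all samples;
  a missing spike-in fails the sample ("missing_spike").
* sample detection filter: the number of detected assays (Ct strictly below
  the ceiling) must be at least mean − 2 SD of the per-sample counts.
* assay prevalence filter: an assay detected in fewer samples than
  mean − 2 SD of the per-assay counts is removed.

Degenerate inputs pass: with one sample, or zero spread, there is no evidence
of deviation and nothing is excluded. Thresholds are met with ≥, not >.

## Hemolysis screening

Free hemoglobin absorbs at 414 nm; lipemia also raises 414 nm and is
corrected by the 414/375 nm ratio. A sample is admitted when A414 < 1.5 **or**
the ratio is < 1.4 (high absorbance explained by lipid). Admitted samples are
classed `non_hemolyzed` (A414 ≤ 0.2), `hemolyzed` (A414 > 0.2 and
ratio ≥ 1.4) or `lipemic_non_hemolyzed` (A414 > 0.2, ratio < 1.4).

Each assay receives two pieces of evidence, computed on the pooled
case+control set: the R² of an OLS fit of Ct on A414 with lipemic samples
excluded (their A414 does not track hemoglobin), and a two-sided rank-sum
test of Ct between the hemolyzed group and everyone else (lipemic samples
count as non-hemolyzed). The verdict is `affected` (R² > 0.3 and p < 0.01),
`unaffected` (R² < 0.2 and p > 0.05) or `indeterminate`; boundary values are
indeterminate (strict inequalities). The rank test is exact for tie-free
groups of ≤ 8, otherwise a normal approximation with tie correction.

Verdicts gate downstream use: `affected` assays are barred from control
candidacy and from prognostic models; `indeterminate` assays are barred from
control candidacy unless explicitly whitelisted; prognostic tree features are
restricted to `unaffected` assays.

## Endogenous-control selection

Stability is scored by a model-based variance decomposition on the Ct (log)
scale. Within each group the two-way model `Ct = gene + sample + noise` is
fitted by means; per-gene residual mean squares `s²` are bias-corrected into
within-group variances via `σ̂² = (s² − Σs²/(k(k−1))) · k/(k−2)` (clipped at
0; with k = 2 candidates the correction is undefined and `s²` is used
directly). Between-group biases are the doubly-centered gene-by-group means,
shrunken toward zero by `γ̂²/(γ̂² + σ̂²/n_g)`, where `γ̂²` estimates the
variance of true biases across genes. The **stability value** is the
group-averaged `|shrunken bias| + SE(bias estimate)`; the SE uses the
unshrunken sampling variance so that under a null bias structure the ranking
reduces to a variance ranking (using the shrunken SE instead collapses every
gene to zero stability when γ̂² = 0, which destroys the ranking). Combination
stability of a set averages the shrunken biases and sums the sampling
variances of the mean, so compensating biases are rewarded as in the original
method.

Candidates must be expressed (below the ceiling) in **every** sample and
carry an `unaffected` verdict (or be whitelisted while `indeterminate`). The
candidate list is capped at the **10 least-variable** eligible assays (pooled
SD pre-screen, blind to group labels): the stability model is intended for
short candidate lists, and with long lists a single strongly group-shifted
assay inflates γ̂² and weakens the shrinkage of noisy candidates.

Selection takes the best stable pair, adds the candidate minimizing the
trio's combined stability, and considers a 4th control (the next candidate in
the ranking) only when the trio's normalization factor is itself unstable:
with `V(a, b)` the SD over samples of the difference between two control
sets' normalization factors (mean Ct of each set — Ct is already log-scale),
the 4th is added iff `V(pair, trio) ≥ 0.15` and `V(trio, quad) < 0.15`. A 4th
that leaves the variability where it was is unnecessary. The full decision
(candidates, rejections with reasons, stability values, V statistics) is
recorded in a replayable audit.

## Normalization and effect sizes

`ΔCt*(s, a) = geometric mean of the control Cts of sample s − Ct(s, a)`,
computed in one pass over the combined sample set; larger = more abundant.
The geometric mean is taken of the Ct values themselves (for typical control
Cts it differs from the arithmetic mean by < 0.05 cycles but is less
outlier-sensitive). Control assays self-normalize to ≈ 0 and are excluded
from DE and prognostic modelling rather than reported.

Fold-changes per case sample are `FC = 2^(ΔCt*_case − median control ΔCt*)`;
the reported effect is the median FC over case samples, expressed as a
symmetric fold-difference (`FD = FC` if ≥ 1 else `−1/FC`, so |FD| ≥ 1 and
upregulated ⇒ FD > 1). This orientation is fixed by the convention that
upregulated markers must carry positive fold-differences.

## Differential expression

Each retained miRNA is tested per case-cohort against the single control
group with a two-sided Wilcoxon rank-sum on ΔCt* (exact for small tie-free
groups). Benjamini–Hochberg adjustment is applied within each
cohort-vs-control comparison (the family mirrors per-cohort reporting), with
significance at adjusted p < 0.05. A Shapiro–Wilk gate (every group p > 0.05)
is computed and recorded per miRNA, but the pipeline always uses the
non-parametric test — group sizes are too small to certify normality, and
roughly half the miRNAs fail the gate, so a single global choice avoids
mixing test types across the panel.

## Survival analysis

Kaplan–Meier product-limit curves; the median is the smallest time with
S(t) ≤ 0.5 (undefined if never reached). The log-rank test is the standard
(O−E)²/V chi-square with 1 df; pairwise comparisons multiply raw p by the
number of pairs (Bonferroni), capped at 1.

Expression markers are dichotomized at the **maximally selected log-rank
cutpoint**: candidate cutpoints are midpoints between consecutive distinct
values whose split leaves at least `floor(minprop·n)` samples on each side
(minprop 0.2; floor-with-≥ so that small cohorts retain admissible splits);
the selected cutpoint maximizes the absolute standardized statistic, ties
resolved toward the smallest cutpoint, and "high" refers to abundance. The
downstream p is the ordinary log-rank of the dichotomized groups and inherits
the optimism of data-driven cutpoints; no Lausen–Schumacher small-sample
correction is applied (flagged as an extension).

Cox proportional-hazards fits maximize the Efron-tied partial likelihood by
damped Newton iterations (step-halving, gradient tolerance 1e-9); the 95% CI
is `exp(β̂ ± 1.96·SE)` from the observed information. Monotone likelihoods
(perfect separation, |β̂| > 15) are flagged and reported with an unbounded
CI. Categorical covariates are dummy-coded against each level in turn as
reference, one joint fit per reference; single-sample categories are
inestimable and reported as such. Fixed-horizon endpoints (183/365/730 days)
censor events past the horizon at the horizon, so an early event remains an
event at every longer horizon.

## Tree models

Classification trees split on Gini impurity; survival trees fit an
exponential (constant event-rate) model per node, `λ̂ = events/exposure`, and
split to maximize the deviance reduction `2(ll_left + ll_right − ll_parent)`
with `ll = d(log(d/T) − 1)`. Growth defaults follow the rpart conventions:
min 20 samples to split, min 7 per leaf, complexity threshold 0.01 on the
root-risk-normalized scale, 10-fold CV. Tie-breaks are deterministic (first
feature in column order at equal gain; prediction ties go to the positive
class). Missing feature values route down the larger child with a warning
(no surrogate splits).

Pruning computes the weakest-link cost-complexity path (for survival trees
the node risk is −2×profile log-likelihood, whose collapse-minus-subtree
differences are exact deviance differences), evaluates each candidate
complexity by the geometric-mean rule on re-grown fold trees (stratified by
class or event status), and returns the subtree at minimum CV error, ties to
the smaller tree. Held-out deviance for survival uses lightly shrunken leaf
rates `(d + 0.5)/(T + 0.5/λ_root)` so event-free leaves cannot produce
infinite deviance. Leaf "hazard ratios" are event-rate ratios against the
root node; a Cox fit on pairwise group indicators is available as an
alternative (`compare_groups(..., use_cox=True)`) since rate ratios and Cox
HRs answer slightly different questions.

The diagnostic split protocol is configuration: the first cohorts plus 80%
of controls train; the last cohort plus the held-out 20% of controls test
(seeded permutation of control ids, `round(holdout·n)` withheld).

## Synthetic cohorts

The generator emulates the study's structure: three case cohorts (35/13/13)
and 21 controls on a 56-assay panel spread round-robin over 6 plates with
Gaussian plate offsets (SD 0.5 Ct) removed later by the IPC; per-well Ct =
assay baseline + planted case shift + hemolysis coupling·A414 + per-sample
shift (SD 0.5) + Gaussian noise. Noise SD is 0.8 Ct for regular assays
(the standard qPCR assumption at these input amounts), 0.3 for the three
designated control assays, 0.45 for two semi-stable padding assays. Baselines
place named markers at 22–30 Ct, filler assays up to 34.5 (so, as in real
plasma panels, only a minority of assays is expressed in every sample), and
six assays at 36–38 Ct — near the detection limit, exercising the prevalence
filter; wells past 40 cycles read as undetected. Hemolysis latents draw A414
from a short-tailed mixture (75% below 0.2, tail to 1.2) with a 10% lipemic
subgroup (ratio ≈ 1.25); coupled assays default to −3 Ct per absorbance
unit. Spike-ins are drawn uniform with ±1.73 SD bounds — emulating cohorts
whose isolation/RT efficiency is in control, so the ±2 SD filter excludes
nobody; filter behavior itself is tested on constructed toys.

Survival is exponential proportional hazards with baseline median 300 days
(overall survival) and 250 days (disease-free interval): each linked miRNA
contributes `β·I[expression above the case median]` to the log hazard, where
the indicator uses the normalization-recoverable part of the signal
(baseline + effect + noise, excluding the per-sample shift that the controls
remove). The binary link makes the event-rate ratio between the planted
groups exactly `exp(β)` — the quantity the cutpoint + Cox analysis targets.
Censoring is independent exponential, calibrated so the configured fraction
(default 20%) is censored. Survival times are rounded up to whole days.

What the generator does **not** emulate: cohort-specific effect sizes (a
planted shift applies to all case cohorts equally, whereas real confirmatory
cohorts showed attenuated or reversed effects, e.g. from sample-storage
degradation), assay-specific amplification chemistry, correlated miRNA
co-regulation, batch-varying hemolysis, or administrative censoring patterns.
Passing recovery tests therefore demonstrates that the pipeline finds the
structure it assumes — not that real plasma data satisfy those assumptions.

## Known limitations and measured behavior

* **Optimal-cutpoint optimism**: the maximally selected cutpoint's rank error
  at n = 60 and HR 3 has median ≈ 3 order statistics (80th percentile ≈ 7);
  downstream log-rank p-values on the selected split are optimistic.
* **Weak-signal survival trees**: at the default study conditions (≈ 61
  cases, ≈ 49 events, HR 2.9 on one marker among ≈ 36 noise assays),
  min-CV-error pruning collapses the survival tree to its root in roughly
  half the cohorts, and the maximally selected deviance of a noise assay
  exceeds the true marker's in a further fraction; single-cohort tree
  structure is therefore unstable at this effect size, which is a property
  of the method, not of this implementation.
* **Null pruning rate**: under pure noise the survival tree prunes back to
  its root in ≈ 85–90% of runs with the min-CV rule; the test suite
  cross-checks this against R's rpart (method "exp", identical growth
  controls, min-xerror pruning) on shared datasets, which shows the same
  order of null pruning. The 1-SE rule would push the rate near 100% but is
  deliberately not used, as the pipeline pins the minimum-CV-error
  convention.
* BH adjustment is monotone, dominating and capped, but not idempotent under
  re-application (no step-up procedure is).
* No multivariable Cox, competing risks, or surrogate splits.
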