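# Methods

## Problem setting

During a 33-fraction course of head-and-neck (chemo)radiotherapy, tumour
shrinkage and weight loss degrade the spatial accuracy of the original plan:
doses to organs at risk (OAR) such as the parotid glands, brainstem and
spinal cord can drift above their planning objectives, and patients can lose
clinically significant weight. Adaptive radiotherapy (ART) — replanning in
response to these changes — helps, but replanning everyone is prohibitively
expensive and only a minority of patients benefit. The practical question is
*which* patients to refer for a replan assessment, stated as rules simple
enough to pin to a wall.

`artselect` implements that analysis end to end: label each patient
normal/violation per ART objective, screen random-forest regressors over
predictor-category subsets to find which objectives are predictable and from
what data, and distill the winning forest into a conjunctive threshold
guideline ("If planned brainstem D0.03cc >= 16 Gy AND ... then violation
likely"), validated on a held-out chronological cohort.

## Violation labeling

For an objective with planned value $p$, estimated delivered value $d$, and
planning criterion $c$ (where one exists), the signed violation magnitude is

- **ALARA paradigm**: $m = d - p$ — any adverse drift from plan counts;
- **planning-criteria paradigm**: $m = d - \max(c, p)$ — the reference is
  the criterion when the plan met it, and the planned value when the plan
  already exceeded it. The single $\max$ formula reproduces both branches.

Decrease-type objectives (weight loss, target coverage) are sign-flipped
first so the adverse direction is always positive; magnitudes are left
signed and unclipped because the forests regress on them and ordering
information below tolerance is useful.

A patient is labeled **violation** when $m \ge$ tolerance (inclusive
comparison). Two tolerance modes:

- **deviation tolerance** — calibrated from weekly trend data: fit ordinary
  least squares to each trend patient's weekly objective values, take the
  difference between the actual and linearly projected final value, and set
  the tolerance to twice the cross-patient sample SD (n−1 denominator) of
  those differences. This separates random inter-fraction variation from
  systematic drift. Note the final point participates in the fit, so the
  difference is the OLS residual at the last fraction, whose SD is
  $\sigma\sqrt{1-h_{\text{last}}}$ for trend noise $\sigma$ and leverage
  $h_{\text{last}}$; the calibration inherits this, which is fine because
  the same quantity defines the tolerance and the screening statistic.
- **worst quartile** — flag the $\lceil n/4\rceil$ patients with the largest
  magnitudes, ties broken by ascending patient id. Quartiles are cut within
  each dataset (training and validation separately) so validation labels
  never depend on training data.

The four combinations (paradigm × tolerance mode) are the label formats the
screening grid searches over. Objectives without a planning criterion
(weight loss, volume changes) use only the ALARA formats, since the two
paradigms coincide when no criterion exists.

**Feasibility screen.** An objective is dropped before modelling when
(a) fewer than `min_violations` training patients violate (default 10% of
the training cohort — a prevalence like 6/250 cannot anchor a classifier),
or (b) the mean absolute linearly-projected systematic change across trend
patients is below the deviation tolerance, i.e. random inter-fraction
changes dominate systematic effects.

## Forest screening and model selection

For each feasible objective and every non-empty subset of the predictor
categories {EMR, pCT, RTx, Obs} × label format, a random-forest *regressor*
is fit on the violation magnitude with five-fold cross-validation under five
random initializations (each initialization seeds both the shuffled fold
split and the forest). Forest settings: 500 trees by default, one-third of
features per split (the classic regression-forest convention), no depth
limit. Sweeping the threshold that converts the out-of-fold magnitude
estimate into a violation call traces an ROC curve; thresholds are midpoints
between consecutive sorted unique predictions plus ±∞ sentinels. The
maximum Youden index $J = \text{sens} + \text{spec} - 1$ is the primary
metric (ties toward higher sensitivity, then lower threshold — screening
intent); AUC, computed as the Mann–Whitney concordance with ties counted ½,
is secondary.

**Greedy stepwise selection.** The cell meta-parameters are the four
category-inclusion flags, the paradigm, and the tolerance mode. Each round
groups the per-initialization Youden indices of the surviving cells by the
levels of each unfixed parameter and computes a Kruskal–Wallis rank-sum
test; the parameter with the smallest p-value is fixed at the level with the
highest median J and the grid is filtered. Rounds stop when all parameters
are fixed or min p > α (default 0.05). Survivors within ΔJ = 0.02 of the
best mean J form a shortlist; the most complete and most parsimonious
members (by feature count) are compared on mean achievable specificity over
a 21-point sensitivity grid spanning [0.60, 0.80], and the larger mean wins.
The per-initialization J (5 values per cell) is the replication unit of the
rank test; α, ΔJ and the grid resolution are package choices where only the
qualitative procedure is prescribed.

The BMI/weight-loss objective excludes the Obs category from its grid: the
on-unit measurements already contain ΔBMI, which would leak the outcome.

**Learning curve.** The winning cell is refit on chronological prefixes of
the training cohort (default 100, 125, 150, 175, 200 patients), reporting
the mean and SD of AUC over the five initializations per size.

## Heuristic distillation

1. **Importance.** Predictors are ranked by out-of-bag permutation
   importance: for each tree, the increase in MSE on its out-of-bag samples
   after permuting the predictor, averaged over trees. Predictors no tree
   splits on score exactly zero; ties break by name.
2. **Boundary probing.** With the violation-call threshold fixed at the
   screening stage's Youden optimum, the other predictors are held at the
   medians of patients predicted violation (falling back to a band of ±1
   cross-validated residual SD around the threshold, widened geometrically,
   when nobody is predicted violation). Each of the `top_k` (default 8)
   high-importance predictors is swept across its observed range; the value
   where the forest's output crosses the threshold seeds a `>=`/`<=` term.
   Predictors whose sweep never crosses are dropped — the forest does not
   use them near the boundary.
3. **Joint refinement.** All cutoffs are refined by coordinate ascent on the
   training-set Youden index of the conjunction: predictors cycle in
   importance order, 101 candidate cutoffs per sweep over the observed
   range, stopping when a full cycle improves J by < 10⁻⁶ or after 20
   cycles; ties go to the more permissive cutoff. Terms refined to a
   predictor's permissive range edge are vacuous and pruned.
4. **Simplification.** Terms implied on the training data by the remaining
   conjunction are removed (to a fixpoint; the flagged set is invariant).
   Whole measurement categories can then be dropped: remove the category's
   terms, re-refine the survivors, and keep the reduced rule iff the
   training Youden loss is at most `max_J_loss` (default 0.10 — accepting a
   small specificity cost for a large workflow gain, since on-unit
   measurements cost minutes of staff time per patient). The pipeline
   attempts to drop Obs and then EMR terms by default.

Rule cards round cutoffs to clinical precision (integers) for display only;
evaluation always uses unrounded values. An empty rule flags nobody.

## Synthetic cohort generator

No institutional cohort of this kind is shareable, so the generator emulates
the schema: ~20 predictors across the four categories with truncated-normal
or integer-coded categorical marginals centred on typical head-and-neck
values (age 58.7 ± 10.1 y, BMI 27.6 ± 5.8 kg/m², planned OAR doses placed
below their planning objectives: brainstem D0.03cc ≤ 54 Gy, cord ≤ 48 Gy,
parotid Dmean ≤ 26 Gy, constrictor Dmean ≤ 50 Gy). Delivered values follow

    delivered = planned ± (baseline + (effect − baseline)·[rule holds] + N(0, σ))

with a planted conjunctive rule per objective — the ground-truth analogue of
the guideline format — floored at zero. Default mechanisms conjoin two
predictors at roughly their marginal medians (~25% conjunction prevalence)
with 5–6 Gy effects against 1.2–1.5 Gy noise; weight loss is a single-term
mechanism on initial BMI with a decrease being adverse. Weekly trend series
are linear from planned to delivered value plus N(0, 0.7–0.9 Gy) noise,
giving calibrated deviation tolerances of roughly 1–2.5 Gy, the clinically
reported range. The 200/50 chronological train/validation split mirrors
routine consecutive-cohort practice.

What the generator does *not* emulate: correlations between predictors
(marginals are independent), non-Gaussian or heteroscedastic dose errors,
informative missingness, and violation mechanisms more complex than a single
conjunction. Passing recovery tests therefore show the pipeline recovers
conjunctive structure under realistic noise — not that real anatomies
behave this way.

## Numerical and design choices

- All randomness derives from one global seed through
  `stage_seed(seed, stage_index)` (SeedSequence-based, values < 2³¹);
  identical configs give bit-identical artifacts and the manifest hash
  covers the semantic config plus artifact digests.
- Missing predictor values are imputed with training-set medians plus a
  missingness-indicator column (relevant for, e.g., contralateral doses of
  unilaterally treated patients in real data).
- Undefined metrics (empty denominators) are reported as nulls, never 0.
- Degenerate inputs raise typed errors: identical trend fractions,
  single-class labels for ROC/AUC, fewer than two trend series for the
  tolerance, empty selection grids.
- Problem sizes in the test suite and acceptance script are scaled to the
  package's simulation study: cohorts of 100–250 patients and forests of
  15–200 trees for structure-recovery checks (recovery there is already
  decisive), with the 500-tree default reserved for production use.

## Known limitations

- The boundary-probing realization (violation-side base point, single sweep
  per predictor) is one faithful implementation of the ensemble-to-rule
  idea; other probing schemes could yield different but similarly performing
  cutoffs when predictors interact strongly.
- A single conjunction cannot represent disjunctive risk groups; objectives
  whose risk structure is a union of patterns will lose sensitivity in the
  simplified rule even when the forest captures them.
- Coordinate ascent is a local optimizer; with strongly correlated
  predictors the refined cutoffs are one of several near-equivalent optima
  (the determinism guarantees reproducibility, not global optimality).
- OOB membership is recovered through scikit-learn's internal bootstrap
  helpers, which are not public API; the calls are guarded against both
  current signatures.
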