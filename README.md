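# artselect

Patient-selection guideline development for head-and-neck **adaptive
radiotherapy (ART)**: which patients should be referred for a replan
assessment, and can that decision be written down as a rule simple enough to
pin to a wall?

During a 33-fraction (chemo)radiotherapy course, tumour shrinkage and weight
loss can push delivered doses to organs at risk (brainstem, spinal cord,
parotid glands, pharyngeal constrictor) above their planning objectives.
Replanning fixes this but is expensive, and only a minority of patients
benefit. `artselect` implements a complete analysis pipeline for deriving
explicit selection guidelines from tabular per-patient data:

1. **Labeling** — each patient × objective becomes a signed *violation
   magnitude* and a normal/violation label. Under the planning-criteria
   paradigm a violation is `delivered ≥ max(criterion, planned) + tolerance`;
   under ALARA it is `delivered ≥ planned + tolerance`. The deviation
   tolerance is calibrated as 2× the cross-patient SD of (actual − linearly
   projected) final values from weekly trend data, separating random from
   systematic change; a worst-quartile format is the alternative.
2. **Screening** — random-forest regressors on the magnitude, five-fold
   cross-validated under five initializations, over every subset of the
   predictor categories {EMR, pCT, RTx, Obs} × label format. Performance is
   the maximum Youden index J = sensitivity + specificity − 1 of the ROC
   obtained by thresholding the out-of-fold regression estimate; AUC is
   secondary.
3. **Selection** — a greedy stepwise procedure fixes one meta-parameter per
   round (category inclusion, paradigm, tolerance mode) by Kruskal–Wallis
   separation of per-initialization Youden indices; ties within ΔJ are
   resolved by specificity over the 0.60–0.80 sensitivity band.
4. **Distillation** — the winning forest is converted into a conjunctive
   rule ("If … AND … then violation likely") by out-of-bag permutation
   importance, decision-boundary probing, coordinate-ascent cutoff
   refinement, redundant-term removal, and optional dropping of costly
   measurement categories (e.g. on-unit observations).
5. **Validation** — forest and rule are scored on a held-out chronological
   validation cohort (sensitivity, specificity, J, replan fraction).

Because institutional ART cohorts are rarely shareable, the package includes
a first-class synthetic cohort generator with the same schema and *planted*
conjunctive violation mechanisms, so every stage can be tested for recovery
of known ground truth. See `docs/methods.md` for the model details and the
generator's scope.

## Worked example

```python
from artselect.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, n_patients=120, n_trees=25,
                     objectives=("brainstem_spinal_cord",),
                     output_dir="demo_run")
out = run_pipeline(cfg)
print((out / "rule_brainstem_spinal_cord.txt").read_text())
```

prints the distilled guideline card:

```
[brainstem_spinal_cord]
If planned_brainstem_d0_03cc >= 28
AND planned_spinal_cord_d0_03cc >= 40
then violation likely.
```

which exactly recovers the mechanism planted by the generator (brainstem
D0.03cc ≥ 28 Gy AND spinal cord D0.03cc ≥ 40 Gy). The run directory also
contains the calibrated deviation tolerance (`deviation_tolerances.json`:
1.32 Gy here), the screening grid and selection report, and
`evaluation.json` with held-out performance — in this run the full forest
scores sensitivity 1.00 / specificity 0.78 on the 24-patient validation
split, and the two-term simplified rule sensitivity 1.00 / specificity 0.89
with a replan fraction of 0.33, i.e. one patient in three would be referred
for replan assessment.

The same pipeline runs from the shell:

```bash
artselect run-all --seed 1 --n-patients 250 --out my_run
artselect simulate --seed 1 --out sim            # cohort + trends only
artselect calibrate-tolerance sim/trends.csv      # tolerances per objective
```

Runs are deterministic: a single `--seed` drives every stage through a
documented counter scheme, and `manifest.json` records the configuration
hash plus a digest of every artifact — two runs with the same configuration
are bit-identical.

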