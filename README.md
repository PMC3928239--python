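# subtypebench

Benchmarking **subtype-specific** versus **generic** predictors of
chemotherapy response in breast cancer.

## The problem

Breast cancer splits into clinically distinct subtypes by receptor status:
HER2-positive (any ER), Luminal (HER2−, ER+) and Triple Negative (HER2−,
ER−), with the HER2+ group refined into HER2+/ER− and HER2+/ER+.  After
neoadjuvant chemotherapy, some tumours show a *pathological complete
response* (pCR: no residual invasive cancer in breast and axillary nodes) —
a binary endpoint worth predicting before treatment.  An obvious question
for anyone building such predictors from pooled multi-institute expression
cohorts: should you train one predictor per subtype, or a single generic
predictor on all subtypes and just *evaluate* it per subtype?

Neither answer is universally right, and this package exists to measure the
trade-off.  Two mechanisms pull in opposite directions:

* a feature can be strongly predictive pooled yet **constant inside a
  subgroup** (ER status is, by definition, fixed within HER2+/ER−).  A
  generic predictor built on such features produces one identical score for
  every subgroup sample; with tied pairs counted half, its AUC is exactly
  0.5 there, while a subtype-specific predictor is free to use features that
  actually vary within the subgroup;
* when responders are **rare within a subtype** (Luminal pCR ≈ 7 %), the
  subtype-specific training set contains too few positive events to learn
  from, and the generic predictor — trained with every subtype's responders
  — wins on sheer minority-class sample size.

## What the package does

* `subtypebench.cohort` — domain model: expression matrix + clinical table,
  receptor-based subtype assignment, composition tables, TSV I/O.
* `subtypebench.harmonize` — cross-dataset normalization: per-gene median
  centering to a reference dataset computed on composition-balanced subsets,
  and probe→gene collapsing by highest pooled standard deviation.
* `subtypebench.ranking` — six feature rankers: Wilcoxon–Mann–Whitney
  (WMW), WMW with correlated features removed (|Pearson r| > 0.75), the
  between/within-group sum-of-squares ratio (BWR) for expression; information
  gain, correlation-based feature selection (CFS) and ReliefF for clinical
  features.
* `subtypebench.classifiers` — six scorers: naive Bayes, nearest mean,
  3-nearest-neighbour, logistic regression, linear SVM and a decision tree
  (embedded feature selection), each emitting a continuous pCR score.
* `subtypebench.cv` — the double-loop cross-validation: 15 outer stratified
  2/3–1/3 splits; an inner stratified 3-fold loop choosing the feature count
  per (ranker, classifier); subtype-specific and generic training scopes
  validated on identical subtype-restricted validation samples.  3 rankers ×
  5 classifiers + the tree = 16 predictor configurations per modality.
* `subtypebench.evaluation` — Mann–Whitney AUC with half-credit ties,
  best-predictor selection, Welch two-sided t-tests with Bonferroni
  correction, and report generation.
* `subtypebench.simulate` — a synthetic multi-dataset cohort generator with
  named presets (`null`, `shared_signal`, `subtype_private_signal`,
  `confounded_marker`, `rare_minority`) reproducing the phenomena above.
* `subtypebench.cli` — `subtypebench simulate | run | compare | report`.

## Worked example

Train one clinical predictor (naive Bayes with information-gain ranking) in
both scopes on the confounded-marker scenario and compare the AUC
distributions in the HER2+/ER− subgroup:

```python
from subtypebench import (concat_cohorts, generate, preset, run_double_loop,
                          default_scopes, compare_table)
from subtypebench.cohort import Subtype
from subtypebench.cv import PredictorConfig
from subtypebench.harmonize import median_center

cohorts = {c.clinical["dataset_id"].iloc[0]: c
           for c in generate(preset("confounded_marker", seed=1))}
pooled = concat_cohorts(
    [median_center(cohorts, "D1", seed=1)[d] for d in sorted(cohorts)])

table = run_double_loop(
    pooled,
    configs=[PredictorConfig("clinical", "infogain", "NB")],
    scopes=default_scopes([Subtype.HER2_POS_ER_NEG]),
    n_repetitions=15,
    seed=11,
)
outcome = compare_table(table, family_size=1)[0]
print(f"specific mean AUC: {outcome.specific_mean_auc:.3f}")
print(f"generic  mean AUC: {outcome.generic_mean_auc:.3f}")
print(f"t = {outcome.t_statistic:.2f}, adjusted p = {outcome.p_adjusted:.2e}, "
      f"significant: {outcome.significant}")
```

Output:

```
specific mean AUC: 0.837
generic  mean AUC: 0.616
t = 4.60, adjusted p = 2.14e-04, significant: True
```

The subtype-specific predictor selects the age/grade/stage features that
carry signal inside the HER2+ subgroups; the generic predictor's inner loop
is dominated by the pooled receptor-status signal, which is flat within the
subgroup, so it averages barely above chance there.  The same pipeline from
the shell:

```sh
subtypebench simulate --preset confounded_marker --seed 1 --out data/
subtypebench run --data data/ --out results/ --seed 11 \
    --modalities clinical --subtypes HER2_POS_ER_NEG
subtypebench compare --auc-table results/auc_table.tsv
```

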