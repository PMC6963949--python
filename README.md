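# rerx — continuous Re-RX rule extraction for diabetes/prediabetes cohorts

`rerx` is a Python toolkit for extracting interpretable if–then diagnostic
rules from tabular patient cohorts with a neural-network-guided decision-tree
pipeline, built around the problem of discriminating **prediabetes from
diabetes** in NHANES-style survey data and of reading clinically meaningful
cut-offs — notably lower-albuminuria thresholds on the urinary
albumin-to-creatinine ratio (UACR, mg/g Cr) — directly off the rules.

It is aimed at biostatisticians and clinical-ML researchers who want an
auditable "white box" alternative to a raw classifier: every prediction is
a conjunction of threshold and category tests on familiar clinical
variables (HbA1c, fasting plasma glucose, LDL, UACR, race/ethnicity, ...).

## The method

The package implements **recursive-rule eXtraction with continuous
attributes (continuous Re-RX)**:

1. **Network.** Train a single-hidden-layer backpropagation classifier on
   all 19 predictor attributes (continuous inputs standardized, categorical
   inputs one-hot encoded; cross-entropy loss with an L2 weight penalty).
2. **Attribute pruning.** Iteratively remove the attribute with the
   smallest aggregate input-weight magnitude and retrain, keeping each
   removal while training accuracy stays within a tolerance of the
   unpruned network.
3. **Tree.** Induce a C4.5 decision tree — gain-ratio splits in bits,
   midpoint thresholds for continuous attributes, multi-way splits for
   categorical ones, pessimistic-error pruning — on the samples the network
   classifies correctly, over the surviving attributes. The *continuous*
   variant admits both discrete and continuous attributes into the tree.
4. **Rules.** Convert root-to-leaf paths to if–then rules ("C4.5 rules"
   simplification optional).
5. **Recursion.** For each rule with support ≥ δ₁ (cover rate) whose error
   exceeds δ₂ (error rate), re-run the whole stack on just the records that
   rule covers, replacing it by parent-conjoined child rules.

Because the published cut-offs came from survey data that cannot be
redistributed, the package ships a **synthetic cohort generator** that
reproduces the published per-class summary statistics (normal draws for
near-symmetric variables, median-anchored log-normal draws for skewed ones
such as UACR and fasting glucose, renormalized categorical frequencies,
class sizes 942 diabetes / 524 prediabetes), plus the published
**15-rule reference model** as a machine-readable fixture, and an
**evaluation harness** (10 × 5 stratified cross-validation with accuracy,
rule counts and Mann–Whitney AUC-ROC; Welch/rank-sum/chi-square group
comparisons).

## Worked example

```python
from rerx import (RerxConfig, RuleSet, canonical_ruleset, default_cohort_spec,
                  extract_rules, extract_thresholds, generate_cohort,
                  serialize_rules)

cohort = generate_cohort(default_cohort_spec(), seed=1)
print(f"cohort: {len(cohort)} records, {cohort.class_counts()}")

result = extract_rules(cohort, RerxConfig(), seed=1)
print(f"extracted {len(result.rules)} rules, "
      f"training accuracy {100 * result.training_accuracy:.2f}%")
print(serialize_rules(RuleSet(result.rules.rules[:3], schema=cohort.schema)))

canonical = canonical_ruleset()
print("canonical UACR cut-offs:", extract_thresholds(canonical, "UACR"))
```

prints

```
cohort: 1466 records, {'diabetes': 942, 'prediabetes': 524}
extracted 74 rules, training accuracy 86.83%
IF HbA1c > 7.157107890555856 AND FPG > 104.0159447909553 AND UACR > 4.787125259940179 THEN diabetes
IF HbA1c > 7.157107890555856 AND LDL <= 145.22210671740345 AND HDL > 25.10651938287046 AND UACR > 6.984100429068247 THEN diabetes
IF HbA1c > 7.157107890555856 AND total_cholesterol <= 269.1904768008035 AND FPG > 104.0159447909553 AND BMI <= 44.915553113452674 AND SBP > 97.96894562549382 THEN diabetes

canonical UACR cut-offs: [6.1, 71.0]
```

The first lines are rules extracted from the synthetic cohort: thresholds
are in raw clinical units, and glycohemoglobin and fasting glucose — the
two largest configured between-class effects — dominate the antecedents.
The last line queries the shipped 15-rule reference model for its UACR
cut-offs, 6.1 and 71.0 mg/g Cr, the lower-albuminuria boundaries of
interest. Rules evaluate first-match, so the rule set as a whole is a
complete classifier (`predict`, `predict_cohort`), and `cross_validate`
scores it with repeated stratified CV.

The same workflow is available from the shell:

```bash
rerx generate --seed 1 --out runs/cohort
rerx extract runs/cohort/cohort.csv --seed 1 --out runs/model
rerx thresholds runs/model/rules.json UACR
rerx evaluate runs/cohort/cohort.csv -k 5 --runs 10 --seed 1 --out runs/cv
```

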