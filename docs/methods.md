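# Methods

## Problem and data model

The package targets two-class tabular diagnosis: discriminating diabetes
from prediabetes in adults using 19 predictor variables — 15 continuous
(age, blood pressures, waist, BMI, lipids, UACR, HbA1c, alcohol,
triglycerides, fasting plasma glucose, insulin, bilirubin), two binary
(sex, exercise to lose weight), one 5-level nominal (race/ethnicity) and
one ordered 3-level tobacco-use variable. A `Schema` carries names, kinds,
units, category levels and catalogued value ranges; a `Cohort` couples a
schema with an ordered `pandas.DataFrame`, and row order is preserved
everywhere so a seed fully determines downstream behaviour. Tobacco use is
catalogued inconsistently in survey documentation (nominal vs ordinal); it
is implemented as an ordered categorical (every day > some days > not at
all), which only affects bookkeeping since trees split it multi-way either
way.

## Synthetic cohort generator

The generator emulates the class-conditional *marginals* of the study
population:

- **Near-symmetric continuous variables** are drawn normal with the
  published per-class mean and SD, then clipped to the catalogued range.
  Clipping (rather than resampling) is used so the published moments shift
  only negligibly; the age clip at 80 doubles as the survey's top-coding.
- **Right-skewed variables** (UACR, FPG, insulin, alcohol, triglycerides)
  are published as medians (triglycerides as mean/SD, used here as the
  location), and are drawn log-normal with `mu = log(median)` — the median
  of a log-normal is `exp(mu)`, so the published medians are preserved
  exactly. Log-scale SDs default to 0.8 (UACR), 0.25 (FPG, insulin) and
  0.5 (triglycerides, alcohol): heavy right tail for albuminuria, tight
  physiological spread for glucose and insulin, intermediate for lipids
  and drinking.
- **Categorical variables** are drawn from the published per-class
  percentages, renormalized to sum to one. The published prediabetes
  race/ethnicity row contains a stray duplicate entry; the five entries
  matching the schema levels sum to ~100% and are used as listed.
- **Class labels** are assigned by construction with exact counts
  (942 diabetes / 524 prediabetes by default), *not* by re-applying the
  ADA glycaemic definitions: the diabetes class includes diagnosed,
  treated patients whose HbA1c can be below 6.5%, which is exactly what
  the published class-conditional HbA1c distribution (mean 7.38, SD 1.81)
  implies. `ada_label` (diabetes: FPG ≥ 126 mg/dL or HbA1c ≥ 6.5%;
  prediabetes: FPG 100–125 or HbA1c 5.7–6.4%) is provided separately for
  validation studies.

**What the generator does not emulate.** Attributes are independent within
class — the published tables carry no correlation structure — so joint
patterns (e.g. BMI–waist correlation) are absent; there are no missing
values, no survey weights, and no intra-individual UACR variability. A
passing pipeline on synthetic cohorts therefore demonstrates correctness
of the machinery and direction-of-effect behaviour, not clinical
performance on real survey data.

Four attributes place more than 1% of their parametric mass outside the
catalogued range, so a ">=99% in range before clipping" sanity check holds
for all continuous attributes *except*: age (class mean 60 with SD 13.5
against the 80+ top-code), diabetes-class HbA1c (mean 7.38 is ~2.1 SD above
the 3.5% floor), total bilirubin (mean 0.72, ~2.2 SD above 0.1), and
alcohol (published median 1 sits on the range minimum, so about half the
log-normal mass clips to 1, which still preserves the median).

## C4.5

Splits are scored by gain ratio in bits. Within a continuous attribute the
cut point is the information-gain-maximizing midpoint between consecutive
distinct sorted values (choosing the cut by *ratio* favours extreme
low-split-info cuts); attributes then compete on gain ratio among
candidates whose gain reaches the mean gain of all positive candidates
(toggleable guard). Categorical attributes split one branch per level and
are consumed once per path; continuous attributes may recur. Ties break on
schema order, then smaller threshold, making induction deterministic.
Stopping: purity, fewer than `2 * min_leaf_size` records (default
`min_leaf_size=2`), optional depth bound, or no admissible split.

Pruning replaces a subtree by a leaf when the leaf's pessimistic error —
`N` times the Clopper–Pearson upper bound `BetaInv(1 - CF; E+1, N-E)`,
`CF = 0.25` by default, which reduces to the classic `1 - CF^(1/N)` at
`E = 0` — does not exceed the sum over the subtree's leaves. Lower CF
prunes harder. Two boundary behaviours are worth knowing: on pure-noise
labels pessimistic pruning contracts the tree substantially but does not
collapse it to a single leaf (a known weakness of the method), and as
CF → 1 pruning is *mostly* disabled but a split that fails to reduce raw
training errors can still be removed.

Path-to-rule conversion merges per-attribute bounds (`> a` and `<= b`
become the half-open interval `(a, b]`; repeated bounds keep the
tightest). With simplification, conditions are greedily dropped while the
rule's pessimistic training error does not increase, rules are reordered
most-accurate-first, and a majority default rule restores full coverage.

## Continuous Re-RX

Defaults: δ₁ = 0.10 (cover rate) and δ₂ = 0.10 (error rate) — the
conventional choice in the recursive-extraction literature, exposed as
mandatory CLI flags; one hidden layer of 4 sigmoid units, learning rate
0.5 with momentum 0.9, 300 full-batch epochs, weight penalty 1e-4, pruning
tolerance 0.01 (retraining at half the epochs during pruning);
`max_recursion_depth=3`. The tree stage fits the true labels restricted to
the network-correctly-classified subset (falling back to the full cohort
when that subset is degenerate); an alternative mode fits
network-predicted labels for all records (pedagogical extraction). Rule
simplification runs per recursion level by default; both global-only and
per-level behaviour are available via `simplify_rules`.

Subdivision replaces a rule in place by its parent-conjoined children, so
first-match semantics and coverage are preserved; a subdivision is kept
only if it does not lower training accuracy on the covered subset,
otherwise the parent rule is retained and the trace records why. Each
recursion level operates on a strictly smaller record set and draws its
seeds from the parent's generator in rule order, so the whole pipeline is
reproducible from one integer seed. Standardization statistics are
recomputed per recursion subset and never leak into rules: tree thresholds
are always in raw measurement units.

Because a rule classifier emits hard labels, ROC analysis uses
Laplace-corrected rule purity as the per-record score: a record scores
`(n_class2 + 1) / (n + 2)` of its first-matching rule's training coverage.
This is the standard device for decision-rule ROC curves and makes AUC the
Mann–Whitney probability computed by `auc_roc`.

## Evaluation harness

`cross_validate` runs repeated stratified k-fold CV (default 10 runs ×
5 folds) and reports per-cell training/test accuracy (%), rule count and
AUC (%), aggregated as mean ± SD over all 50 cells (sample SD, ddof = 1);
a pooled AUC over all held-out scores is reported alongside the per-cell
mean since summary conventions differ. Group comparisons use Welch's
two-sample t-test for near-symmetric continuous attributes (a paired
option exists, but independent diagnostic groups cannot be paired),
Wilcoxon rank-sum for the skewed ones, and chi-square for categorical
frequencies; no multiplicity correction by default, Bonferroni by flag.

## Numerical and design choices

- Interval conditions are half-open `(low, high]`, and `<= t` includes the
  boundary while `> t` excludes it — the only gap- and overlap-free
  reading of the reference model's published intervals, applied uniformly.
- The published reference model's interval conditions are transcribed with
  this convention; the model is a *reference*, not the regeneration target
  of any particular seed, since the original training hyperparameters are
  not published.
- Indicator conditions on race levels ("Mexican-American = no") are
  evaluated against the nominal race attribute, so published one-hot rule
  tables and tree-native `race_ethnicity = level` conditions coexist.
- Degenerate inputs: empty cohorts, single-class cohorts (single default
  rule), constant attributes (no split / flagged in comparisons) and
  empty categorical branches (majority leaf with n = 0) are all defined.
- CSV round-trips use `repr` floats (exact to 1e-9 and beyond); readers
  reject missing predictor cells by default (`drop_incomplete=True` drops
  rows) and warn — rather than fail — on out-of-range continuous values.

## Problem sizes used in the checks

The test suite works at deliberately modest scales chosen to exercise the
statistics rather than to benchmark: planted-model recovery uses 50
replicates of n = 2000 with 0–10% label noise (recovery tolerance: one
`span * n^(-1/3)` unit, the cube-root convergence rate of empirical
split-point estimators; exact midpoint recovery is only meaningful at zero
noise); the direction-of-effect study is a full 10 × 5 CV of the pipeline
on the 1466-record synthetic cohort; oracle equivalence enumerates all
two-class count tables exhaustively up to 12 records for 2–3 branches and
8 records for 4 branches, plus seeded fuzz for wider tables; generator
fidelity uses 10,000 draws per class (100,000 for median-convergence
checks).

## Known limitations

- Within-class attribute independence makes synthetic cohorts easier than
  real ones in some respects (no redundant-attribute structure for the
  network pruner to disentangle) and harder in others (no correlated
  backup signal when an attribute is pruned).
- Extracted rule sets on the synthetic cohort are larger than published
  real-data rule counts; rule-set size is sensitive to δ₂, the pruning
  confidence factor, and the absence of attribute correlations, and no
  attempt is made to match a published rule count.
- C4.5 here omits windowing, fractional (missing-value) splits,
  cost-sensitive trees and the MDL-based global rule selection of the
  full C4.5rules program; simplification is the greedy
  pessimistic-error condition-dropping stage only.
- The backpropagation network is intentionally small; it is a filter for
  the tree stage, not a state-of-the-art classifier.
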