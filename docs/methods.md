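# Methods

This note documents the models, algorithms, parameters and design choices of
`harmonizer`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## 1. Metadata profiling

Every column of an incoming cohort CSV is reduced to a feature profile
(`metadata.VariableMetadata`): name, optional label (from a `name,label`
sidecar CSV — bare CSV carries no label channel), inferred type, scale
level, number of distinct non-missing values, proportion of the most
frequent value, and, for numeric columns, median and interquartile range.
Rules see only this profile; participant-level values never propagate
further, which keeps the method usable on confidential data.

Parsing choices (all configurable via `ProfileConfig`):

* **Missing markers** default to `{"", "NA", "NaN", ".", "NULL"}`, compared
  case-insensitively after stripping. Missing cells are excluded from all
  statistics. In a column typed numeric, cells that fail to parse as numbers
  carry no usable value and are likewise treated as missing, so the modal
  proportion times the non-missing count is always an integer count.
* **Type inference**: a column is `number` if ≥ 95% of non-missing cells
  parse as numerals, else `date` if ≥ 95% parse under the configured pattern
  list (ISO first), else `string`. Number takes precedence, so a column of
  four-digit years is numeric, never date.
* **Scale levels**: ≤ 2 distinct values ⇒ dichotomous; numeric with more
  than `k_scale` (default 10) distinct values ⇒ ratio; numeric,
  integer-coded, 3–10 levels ⇒ ordinal; numeric non-integer with few
  observed levels stays ratio (a measured quantity does not become
  categorical by being coarsely observed); otherwise nominal. Real exports
  rarely carry usable scale metadata, so inference from values is the
  default; the decision rule is deliberately simple and documented rather
  than clever.
* **Quantiles** use linear interpolation between order statistics (the
  common "type 7" convention, numpy's default), chosen so that any
  mainstream numeric stack reproduces the same medians and IQRs.

## 2. Rules and cutoff calibration

A rule (`rules.Rule`) is one of five total predicates on a profile:
`name_contains`, `label_contains` (case- and accent-insensitive substring
after Unicode NFKD normalization — cohort exports mix cases and diacritics
freely), `dtype_is`, `scale_is`, and `threshold` (strict `>`/`<` on median,
IQR, distinct-value count or modal proportion). Totality is a contract: a
predicate whose feature is absent (no label, no median on a string column)
evaluates false, never missing, because the tree engine needs complete
binary inputs.

Threshold cutoffs can be calibrated on labelled training profiles by an ROC
scan maximizing sensitivity + specificity. Candidate cutoffs are the
midpoints between consecutive sorted distinct feature values plus ±∞
sentinels; observed values themselves are not candidates (a strict
comparison at an observed value is reproduced by the adjacent midpoint, and
midpoints are robust to ties). The objective is compared in exact integer
arithmetic (tp·n_neg + tn·n_pos over the common denominator), so ties break
deterministically on the smallest cutoff; floating-point summation of the
two rates would otherwise order genuinely tied candidates arbitrarily.

The packaged registry (`data/registry.yaml`, YAML with a schema version;
JSON is accepted) defines the 41 targets of the uniform dataset with 4–6
rules each. These rule sets are **reconstructed defaults** authored from
each target's name, unit and plausible value range; the original curated
rule table is not public, and no fidelity to it is claimed. Users supply
their own registry file for production use.

## 3. Logic regression by simulated annealing

A model for one target is a single Boolean tree over its rule outputs:
leaves carry a rule index and an optional complement (NOT is permitted, as
is standard for logic-regression trees), internal nodes are binary AND/OR.

**Scoring.** Two methods are implemented. *Classification* scores a tree by
the weighted misclassification count Σ wᵢ(yᵢ − ŷᵢ)²: each false negative
costs w₊, each false positive w₋, with w₊ + w₋ = 1 (operating default
0.9995/0.0005, an error-cost ratio of 1999). *Logistic* scores the tree
output x ∈ {0,1} by the weighted deviance of P(y=1) = expit(a + b·x). With
a binary covariate the weighted MLE is closed-form — the fitted probability
in each covariate group is the group's weighted outcome mean — and fitted
logits are capped at ±15, so perfect separation yields a small positive
deviance rather than a numerical failure; a constant covariate degrades to
the intercept-only fit. The closed form is exact, not an approximation; the
test suite checks it against a general-purpose numeric optimizer.

**Moves.** Proposals draw uniformly from the applicable subset of six move
types, then a site uniformly within the type: alternate leaf (swap the rule
or toggle the complement), alternate operator (AND↔OR), grow branch and
split leaf (both expand a leaf into a two-leaf branch, attaching the fresh
leaf on the right resp. left — the two names describe the same structural
operation at mirrored attachment points, kept distinct for fidelity to the
six-move vocabulary), prune branch (replace an internal node by one child)
and delete leaf (promote the sibling). On a single leaf only the three
non-shrinking moves apply.

**Schedule.** The acceptance probability for score-worsening proposals
decays geometrically (log-linearly) from `p_start` = 0.1 to `p_end` =
0.0001 over `n_iterations` (default 50,000). This "falling transition
probability" reading — a fixed, schedule-driven acceptance probability
rather than a Metropolis score-difference criterion — is a deliberate
design choice; the classical description of annealing admits both, and the
fixed-probability variant needs no score-scale tuning, which matters here
because classification scores and logistic deviances live on different
scales. Improving or equal-scoring proposals are always accepted.

**Constraints.** Candidate trees violating `treesize` (max leaves, default
5) or `minmass` (the tree must predict positive on at least this many
training instances, default 4) are rejected outright rather than penalized
— a hard feasibility region keeps the score interpretable. The best
feasible tree seen anywhere in the run is returned; ties go to the first
tree encountered. The search starts from a uniformly random single
uncomplemented leaf and stops early once a score of exactly 0 is reached,
since no move can improve on it. A single seeded generator drives every
stochastic draw, so runs are bit-reproducible.

One tree per target: multi-tree logic-regression models exist in the
literature, but single expressions are what this allocation problem uses,
and they stay human-reviewable.

## 4. Tuning study

The operating configuration is chosen over a full factorial grid — by
default 2 scoring methods × 4 negative weights (5·10⁻⁴ … 5·10⁻¹) × 2 tree
sizes (5, 10) × 2 minmass values (4, 8) = 32 design points — evaluated by
k-fold cross-validation (default k = 10) and selected by maximizing
sensitivity subject to floors of 99% on sensitivity and 75% on specificity.
If no point meets both floors the sensitivity floor is dropped first, then
the specificity floor, and the relaxation level is reported: sensitivity is
the quantity the application cannot afford to lose.

Two choices the procedure leaves open are fixed as follows and exposed as
flags. *Fold grouping*: folds are grouped by source dataset — all variables
of one cohort share a fold — because logic trees latch onto dataset-specific
naming conventions, and ungrouped folds would leak them from training into
test (`grouped=False` restores plain folds). *Aggregation*: a design point's
headline sensitivity/specificity pool confusion counts over folds
(micro-average) rather than averaging per-fold rates, because with ~0–1
positives per target per dataset many folds have degenerate denominators.
Per-fold metrics are retained, and a fold without positives reports missing
sensitivity, excluded from fold means with a warning.

The factor-analysis layer is reduced to the 32-run result table plus
main-effect summaries; response-surface modelling and profiler graphics are
out of scope.

## 5. Allocation pipeline

Training instances are per (dataset, variable) pair: a variable mapped to
target A by the gold standard is a positive instance of A and a negative
instance of every other target. Identically named variables in different
datasets are distinct instances — names are evidence, not identity. Targets
with no positive instance are reported as unfitted, never silently dropped.

Applied to a new dataset, a fitted tree yields a 0/1 prediction per
variable. Because a bare prediction is a poor interface for a reviewer, the
candidates are ranked by the fraction of satisfied leaves (complement
respected), ties broken by variable name; all predicted positives are
returned, padded with the best-ranked negatives up to `top_k` so that even
an empty prediction yields a reviewable list (the escape hatch for a tree
that missed the true variable). The rank key is an extension of the
original true/false output and can be disabled (`ranked=False`).

Reported metrics per target: sensitivity (matching source variables
correctly identified), specificity (non-matching ones identified as such),
PPV (flagged variables that are correct), NPV (cleared variables that are
correct); a rate with a zero denominator is missing, and missing cells are
excluded from the report's unweighted Average row. The packaged
`table2.csv` fixture carries the published 41-target performance values and
their Average row: the suite verifies the aggregation reproduces the
printed row, and `table1.csv` carries the 34-dataset manifest with its
construction/validation split (a `resplit` helper reproduces the random 1:1
assignment procedure under a seed). The published per-target values
themselves are fixture content — they were computed on undeposited cohort
data and are not reproducible as computations here.

## 6. Synthetic cohorts

The generator (`synth`) emulates the study's data regime: suites of
heterogeneous cohort datasets (defaults: 500 participants, ~140 variables
per dataset — within the 50–1500 variables / 100–15,000 participants range
the method targets; sizes jittered ±40% per dataset), each target present
in a dataset with probability 0.9 so every target has ~0–1 true match per
dataset, with a gold-mapping table and a manifest split ~1:1.

Each target has an authored distribution template keyed to its unit
(systolic blood pressure ~ Normal(130, 17) so its median clears the classic
94 cutoff; sex 0/1 Bernoulli(0.5); cholesterol Normal(210, 40) mg/dl vs
Normal(5.4, 1.0) mmol/l, so unit variants share a name token and are
separable only by scale) and a name per dialect: verbose, abbreviated, or
coded (opaque `v017`, identifiable only via labels and distributions).
Noise variables draw realistic non-target names from a pool verified (by
test) to contain no target's name token, and assorted distributions.
Missingness is uniform at random; there is no informative missingness, no
inter-variable correlation and no longitudinal structure — the generator
reproduces exactly the features the metadata rules test, nothing more, so
green tests certify the pipeline mechanics and the method's qualitative
behaviour, not performance on real cohorts.

Two presets bracket the difficulty range. **easy** (no decoys, no
missingness, informative names everywhere) is the end-to-end correctness
gate: the default rules identify every planted variable exactly, so the
pipeline must reach pooled sensitivity 1.0 and near-perfect specificity.
**hard** (coded names in a third of datasets, 5% missingness, and with
probability 0.9 per target a decoy column sharing the target's name token
*and* distribution) makes some false positives information-theoretically
unavoidable: no metadata rule separates the decoy from the true variable,
so PPV collapses while the heavy positive weighting keeps sensitivity and
NPV high — the method's central qualitative finding, asserted as a pattern
(PPV well below sensitivity, NPV high), never as specific published values.

## 7. Problem sizes and numerical choices

* Tests and the acceptance script run the pipeline at desk scale: 6
  datasets, ~150 participants, ~40 noise variables, 3,000 annealing
  iterations, `minmass` 1. At this scale each target has only 2–3 positive
  training instances, so the grid values 4/8 for `minmass` — appropriate
  for a 17-dataset construction sample — would forbid the correct trees;
  `minmass` must be chosen relative to the expected positive count.
* Planted-model recovery is checked over 20 seeds (200 instances, 8 rules,
  planted trees ≤ 3 leaves) at the default 50,000 iterations; early exit at
  score 0 keeps this cheap.
* Oracle equivalence of tree evaluation is exhaustive for all trees with
  ≤ 3 leaves over 3 rules (every tree × every assignment against a
  truth-table oracle built on Python's own boolean operators) and densely
  sampled (seeded) for 4–5-leaf trees over 5 rules; full enumeration at 5
  leaves (~22 million trees) is not informative enough to justify its cost.
  The ROC scan is checked exhaustively over small value/label grids and by
  derandomized property tests up to 12 points against a plain-loop oracle.
* Logistic deviance uses a logit cap of ±15 (deviance contribution ≈ 6·10⁻⁷
  per unit weight at the cap), making separation finite while leaving
  interior fits untouched.
* ScoreWeights enforces w₊ + w₋ = 1 to 10⁻¹², keeping the error-cost ratio
  w₊/w₋ well-defined; `w_pos` is always derived as 1 − `w_neg` in configs.

## 8. Known limitations

* The packaged rule sets are reconstructions; real deployments must author
  or calibrate their own registry, and reported synthetic performance says
  nothing quantitative about real cohorts.
* Substring rules are exact (after normalization): no fuzzy distance,
  embeddings or dictionaries, by design — interpretability of the fitted
  trees is the point.
* Value-level harmonization (unit conversion, recoding) is out of scope;
  the tool identifies variables, it does not transform them.
* The annealing schedule's fixed-probability acceptance is one defensible
  reading of a loosely specified procedure; a Metropolis variant would need
  per-method score scaling and is not implemented.
* `generate_design` is typed to the four factors of this study (method,
  w_neg, treesize, minmass) rather than arbitrary factor mappings.
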