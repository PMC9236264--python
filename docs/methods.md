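# Methods

## The prediction problem

The package models a two-class prediction task: given one modality's
baseline feature table for a cohort of fatigued rheumatoid-arthritis
patients, predict who will show clinically relevant fatigue improvement —
a decrease of at least 2 points on the Chalder Fatigue Scale (CFS) between
baseline and a 6-month follow-up. ΔCFS is defined as baseline − follow-up
(lower CFS = less fatigue, so positive ΔCFS is improvement);
`label_improvement` applies the ΔCFS ≥ 2 rule and the instrument's 0–11
bimodal score range. The reference cohort is 54 subjects, 22 improvers and
32 non-improvers; this imbalance is why balanced accuracy
(= (sensitivity + specificity)/2) is the headline metric everywhere.

## Feature schemas

Three modalities with fixed, deterministic schemas:

* **sMRI** (596): 52 subcortical segmentation volumes plus 8 morphometric
  statistics (surface area, gray-matter volume, mean/SD thickness,
  mean/gaussian curvature, folding and curvature indices) for each of 68
  Desikan–Killiany parcellations (34 per hemisphere). The parcellation is
  each cortical feature's *group tag*.
* **DTI** (304): 4 tensor measures (FA, mean/longitudinal/radial
  diffusivity) × 76 tracts; the tract is the group tag. Tract and
  subcortical naming is deterministic but synthetic in detail (the
  original segmentation inventories live in supplementary material not
  distributed here); counts and tag structure are exact.
* **clinical**: user-configurable; the default 8 variables are age, sex,
  disease duration, weight, baseline CFS, pain VAS, and HADS depression
  and anxiety.

Tables are CSV/TSV with a `subject_id` column; floats are serialized with
shortest-round-trip `repr` and parsed with round-trip precision, so
write→read is bit-exact. Missing schema columns are fatal, extra columns
are ignored with a warning, and missing values are fatal unless
complete-case dropping is requested.

## Classifiers

**LSLD.** The least-squares linear discriminant fits y = Σ wₙxₙ + b to ±1
targets by minimizing mean squared error. Features are standardized with
the *training rows'* mean and population SD (ddof = 0; this keeps the
model's coordinates equal to the raw ones for already-standardized
designs); zero-variance training columns are zeroed and logged. The
normal equations are solved by `numpy.linalg.lstsq`, so in the singular
regime (L ≥ n or collinear columns) the minimum-norm solution is
returned; tests verify agreement with an independent `scipy.linalg.pinv`
solve to < 1e-8. Ties at score exactly 0 predict the negative
(non-improver) class.

**SVMs.** Soft-margin linear and RBF SVMs delegate the quadratic program
to scikit-learn's `SVC`; the contract here is the objective, not the
solver. `tune_svm` grid-searches C (and γ for RBF) over the nine integer
powers of two in 2⁻⁴…2⁴ (9 linear / 81 RBF candidates) by stratified
5-fold inner CV on the training partition, scoring with balanced accuracy
and breaking ties toward smaller C then smaller γ. If the minority class
is smaller than the inner k, the number of inner splits is reduced to the
minority class size (leave-one-out within that class at the limit) with a
warning.

## GA feature selection

A chromosome is a set of L distinct feature indices (gene order is never
meaningful; fitness is cached by sorted gene tuple). Defaults: L = 8,
population 10 × L, parent fraction 10% (rank selection, stable-order
ties), uniform random crossover (each position from either parent with
probability ½, duplicates repaired from the parents' gene union and then
from the remaining pool), mutation of round(1% × gene slots of the
offspring) slots chosen without replacement (each replaced by a uniform
feature absent from its chromosome), 100 generations, 1 elite copied
unchanged and never mutated — elitism is what makes the recorded
best-per-generation fitness non-increasing, and it can be disabled.

Two numerical choices worth noting:

* *Mutation floor.* With small desk-scale populations the exact count
  round(rate × slots) truncates to zero (e.g. 1% of 40 slots), which
  freezes the gene pool and leaves the search stuck in its initial
  subsets; when the rate is positive the count is floored at one slot per
  generation. At the full-scale defaults (80 × 8 slots) the arithmetic is
  unchanged (6 slots per generation).
* *Refill scheme.* Offspring are produced by crossover of parent pairs
  drawn uniformly with replacement from the parent pool until the
  population is refilled — the simplest scheme consistent with
  rank-based parent selection.

All GA randomness flows through a single `numpy` Generator handed down
from the CV layer, so runs are bitwise reproducible.

## Nested cross-validation

Outer loop: stratified 5-fold CV (class proportions preserved; fold sizes
differ by ≤ 1) with fresh, re-randomized folds in each of the (default
100) repeats. Stratification is not strictly required by the design but a
22/32 split makes unstratified folds occasionally degenerate. Within each
outer training fold the GA selects a chromosome and the classifier is
fitted on those columns only; SVM hyperparameters are tuned by the inner
CV on the same training fold. Test rows contribute nothing before
prediction — a property the test suite enforces by perturbing test rows
and asserting the selected chromosome and fitted model are unchanged.

Per repeat, every subject is predicted exactly once out-of-fold;
sensitivity/specificity/balanced accuracy/PPV/NPV and a ROC curve are
computed from the repeat's pooled 54 predictions, and the overall summary
averages across repeats with a 95% normal-approximation CI from the
across-repeat distribution. ROC curves are aggregated by vertical
averaging on a fixed 101-point FPR grid; the band is mean ± 1.96 SE
(percentile band by flag), and the averaged curve is anchored at (0,0)
and (1,1) — note this anchoring overrides a curve's own value at exactly
FPR = 0 when it has a vertical rise there.

Selection frequency counts, for each feature, the fold-fits whose
selected chromosome contains it; the denominator is repeats × k (500 at
full scale) and counts always sum to L × repeats × k. Trend annotations
are per-feature two-sample t-tests (pooled variance by default, Welch by
flag), signed '+' when the non-improver mean exceeds the improver mean;
no multiple-testing correction, as they are descriptive labels for the
frequency ranking, not inference.

Randomness: one master seed expands through `numpy.random.SeedSequence`
spawning (per repeat → per fold → GA / inner-CV streams), so reports are
bitwise reproducible and repeats are independent streams.

## Synthetic cohorts

`generate_cohort` draws features multivariate-normal per class with equal
covariance: unit-variance noise with exchangeable correlation
`block_correlation` (default 0.3) among features sharing a group tag —
mimicking how one parcellation's statistics or one tract's measures
co-vary — scaled by `noise_sd`. Planted features receive a between-class
mean shift of `effect_size` marginal SDs (half up, half down around the
grand mean; sign random per feature, '+' meaning higher in
non-improvers). CFS baselines are uniform on 4–11 (the eligibility floor
is a score above 3); improvers' follow-ups drop by 2–4 points,
non-improvers change by −2…+1, so `label_improvement` reproduces the
intended classes exactly for every seed. A `sex` column in a clinical
schema is emitted as 0/1.

What the generator does **not** emulate: realistic marginal distributions
of morphometrics (units, skew), site/scanner effects, feature–feature
correlation across tags, label noise, or any relation between the
features and the CFS scores beyond the class labels. Passing tests
therefore demonstrate that the machinery is correct and leakage-free
under a known generative model — not that the original clinical findings
replicate.

## Study-condition and test-scale choices

* Null-calibration checks run all three classifiers on null 22/32 DTI
  cohorts (D = 304) at scaled-down settings — repeats 5, generations 20,
  population 40, 20 runs — and require the mean out-of-fold balanced
  accuracy to sit in [45%, 55%].
* The planted-recovery experiment plants 3 features at standardized
  effect 1.5 in a 20-feature table and uses chromosome length 3 (matched
  to the planted support: with L much larger than the support, the forced
  extra gene slots dilute the frequency ranking), generations 20, repeats
  10, aggregated over 5 cohort replicates. The replication matters: in a
  single 54-subject draw the training-MSE optimum can genuinely include a
  lucky noise feature (exact top-3 recovery holds in only ~80–85% of
  single cohorts at this effect size), whereas noise features do not
  persist across replicate cohorts and the aggregated ranking is stable.
  These sizes were fixed by a power analysis before freezing the test
  conditions.
* GA/exhaustive agreement is checked at D = 10, L = 2 against brute force
  over all 45 subsets, at the selector's full defaults.

## Known limitations

* The chromosome length is fixed per run, not learned inside training;
  `sweep_chromosome_length` explores it descriptively.
* PPV/NPV are undefined (NaN, flagged) when a repeat predicts only one
  class; across-repeat means are NaN-aware.
* The GA's crossover/refill policy is one reasonable instantiation of
  "random crossover" rank-based reproduction; alternatives (tournament,
  roulette, variable-length chromosomes) are out of scope.
* Full-scale runs (596 features × 100 repeats × 100 generations) are
  compute-heavy; the defaults in the examples and tests use the scaled
  settings listed above, with full scale available through configuration.
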