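# Methods

## The model

`clusterfis` builds Mamdani-type fuzzy classifiers entirely from data. A
classifier is determined by three fitted objects:

- **Fuzzy variables.** For each selected feature, the observed values are
  clustered in one dimension and the sorted centers c₁ < … < c_k become
  membership-function apexes. MF 1 is a left shoulder (degree 1 on
  [domain-min, c₁], descending linearly to 0 at c₂), MF j (1 < j < k) a
  triangle with apex c_j and feet at c_{j−1}, c_{j+1}, and MF k a right
  shoulder. Consequences used throughout: every domain point has positive
  degree in at least one MF, and between consecutive apexes the two active
  degrees sum to exactly 1 (partition of unity), which makes the argmax
  cluster label of a value well defined up to the midpoint tie.
- **Rule base.** Each training record is mapped to the tuple of its argmax
  MF indices over the selected features plus the output; identical tuples
  merge into one rule with a support count. Antecedents observed with more
  than one consequent are resolved to the majority consequent; ties break by
  the summed firing strength of the matching records, then by the lower
  class index. Every resolution is logged. Rule weights are uniformly 1.
- **Inference settings.** min-AND, min-implication, max-aggregation,
  centroid defuzzification on a uniform grid over the output domain.

For binary classification the output variable lives on [1, 2] with a
left shoulder at 1 (benign) and right shoulder at 2 (malignant); the crisp
output Z is thresholded at the apex midpoint 1.5 (exact ties go to class 2
and are logged). Because labels were remapped from {2, 4} to {1, 2}, no
defuzzified value can sit ambiguously between the raw codes.

## Clustering parameters

| parameter | default | notes |
|---|---|---|
| cluster count per input variable | #distinct observed values, capped at 10 | the "optimal" count; minimum 2 |
| output clusters | 2 | one MF per class |
| k-means | Euclidean, 10 seeded restarts | deterministic given seed |
| Ward | Euclidean linkage, tree cut at k | fully deterministic |
| FCM fuzzifier m | 50 | framework default; far above the conventional 2, logged with a warning |
| FCM iterations / tolerance | 100 / 1e−5 | best iterate returned with a flag on non-convergence |

FCM is fit by standard alternating optimization of
Σᵢⱼ u.. ᵐ ‖xᵢ − cⱼ‖². With m = 50 the memberships approach 1/k (the
analytic m→∞ limit), while the uᵐ center weights behave like inverse-square
distances, so hard argmax assignment remains informative; the soft partition
is used only during fitting and the argmax (ties toward the lower index)
drives rule induction.

Clustering is performed on the **full** value column before partitioning —
the protocol fits variables once, then resamples train/validation splits.
This is a mild information leak from validation feature values (never
labels) into MF placement, and is flagged here as a caveat.

## Evaluation protocol

- Random sampling: validation and test sizes are round(n·fraction) (half
  rounds up), the remainder trains; 699 records at 70/30/0 give 489/210.
  Default 3000 iterations; each iteration re-randomizes the partition from a
  seed derived from the plan seed.
- k-fold: seeded permutation split into k near-equal folds (sizes within 1).
- Metrics treat benign (class 1) as positive: sensitivity = benign recall,
  specificity = malignant recall, AUC = (sensitivity + specificity)/2 —
  the balanced accuracy of a hard classifier — and Cohen's kappa from the
  marginal-product expected agreement. Zero-denominator ratios are reported
  as nan with a flag, never raised.
- McNemar's test uses discordant counts b, c; the continuity-corrected
  statistic max(|b−c|−1, 0)²/(b+c) by default (uncorrected available),
  significance above the χ²₀.₀₅,₁ value 3.84. Under cross-validation,
  predictions are pooled across folds before the test.

Candidate selection in `run_search` ranks by validation accuracy pooled
across iterations/folds, then fewer rules, then enumeration order. The
winning system is refit with rules induced on the full table, which is
deterministic and uses every record's label exactly once.

## Numerical choices

- Centroid by plain grid summation with 1001 points. Exact piecewise-linear
  integration was rejected for simplicity; refinement to 10001 points moves
  Z by < 1e−3 on random systems (tested), and the closed-form shoulder
  centroid on [1, 2] (4/3) is matched to ~3e−6 at 1e5 points.
- "No rule fired" (possible when a validation record's label combination
  never occurred in training and its values sit exactly on neighbouring
  apexes, where adjacent-MF degrees vanish): Z is reported as the domain
  midpoint with a flag and the prediction falls back to the training
  majority class.
- Cluster centers within 1e−9 of the domain edge are clipped onto it to
  absorb floating-point jitter from the fitters; genuinely out-of-domain
  centers raise.
- Monotonicity of Z in a rule's firing strength holds for the binary
  complementary-shoulder output (Z moves toward the rule's class apex) and
  is tested in that form; it is **not** true for arbitrary shoulder
  consequents under max-aggregation, because the incremental mass of a
  clipped shoulder lies off-apex.

## Synthetic data

`make_ground_truth` builds per-class value distributions on the 0–10 integer
scale: informative features put geometrically decaying mass on scores 1–4
for benign and 7–10 for malignant (decay ratio drawn once from [0.2, 0.4]
per feature), matching the strong skew of ordinal cytology scores;
non-informative features are uniform on 1–10 in both classes. The generating
FIS (two-MF variables at the class-conditional means, one all-low→benign and
one all-high→malignant rule) classifies noiseless samples perfectly because
the class supports do not overlap. `sample_records` draws the class from a
Bernoulli(benign-fraction) — default 458/699 ≈ 0.655 — samples features
independently within the class, and flips labels with the configured noise
rate.

What the generator does **not** emulate: feature–feature correlation within
a class (features are sampled independently) and the real data's exact
marginal frequencies. Consequence: label-combination diversity is higher
than in the real, strongly correlated cytology data, so pooled validation
accuracies on the 699-record replica land around 90–95% — the unseen-
combination fallback costs specificity — rather than the ~99% attainable on
the real dataset. Passing tests therefore certify the mechanics and the
metric arithmetic, not a clinical performance level.

## Problem sizes used in the checks

The reproduction script runs 30 random-sampling iterations (the protocol's
reference count is 3000) and one 10-fold pass on 699 synthetic records with
a five-feature subset; the search-recovery test uses 1000 records, four
features and five iterations. These sizes give stable pooled matrices while
keeping the full rebuild in seconds.

## Known limitations

- Integer/ordinal feature domains only; continuous features would need a
  different "optimal cluster count" rule than distinct-value counting.
- No rule pruning beyond deduplication and conflict resolution, and no rule
  weighting.
- AUC is the hard-classifier definition; ROC-curve AUC from the continuous
  Z is not implemented.
- Full-data clustering before partitioning (see above) follows the protocol
  but leaks feature distributions across splits.
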