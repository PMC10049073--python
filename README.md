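# clusterfis

Data-driven construction of Mamdani fuzzy inference systems (FIS) for
classifying tabular records with ordinal integer features — the setting of
clinical decision support on cytology scores such as the Wisconsin Breast
Cancer Dataset (WBCD: 699 records, nine features scored 1–10, benign /
malignant outcome).

Instead of hand-designing membership functions and rules, everything is
derived from the data:

1. **Fuzzification by clustering.** Each variable's observed values are
   clustered in one dimension (k-means, Ward agglomerative, or fuzzy
   c-means; the cluster count defaults to the number of distinct observed
   values, capped at 10). The sorted cluster centers become the apexes of an
   ordered membership-function family — a left shoulder, interior triangles
   with feet at the neighbouring apexes, and a right shoulder — which covers
   the domain and forms a partition of unity between consecutive apexes.
2. **Rule induction by deduplication.** Every training record is labelled
   with its argmax-membership cluster index per variable; identical
   (antecedent, consequent) label tuples collapse into one rule with a
   support count, and conflicting antecedents are resolved by majority
   support. This is the pivot-table / `unique` style of rule building.
3. **Mamdani inference.** Canonical operator set — min (AND), min
   (implication clipping), max (aggregation) — followed by center-of-gravity
   defuzzification on a 1001-point grid:

   Z = Σᵢ µ_c(zᵢ) · zᵢ / Σᵢ µ_c(zᵢ)

   (`som`/`mom`/`lom` — smallest/mean/largest of maximum — are also
   available). For the binary problem the output domain is [1, 2] with one
   membership function per class; Z < 1.5 predicts benign (class 1),
   otherwise malignant (class 2).
4. **Evaluation.** Random sampling (70/30 train/validation, repeated) or
   k-fold cross-validation (k = 10); confusion matrix with benign as the
   positive class; accuracy, sensitivity, specificity, F-measure, AUC
   (= balanced accuracy for a hard classifier) and Cohen's kappa; McNemar's
   paired test (χ², continuity-corrected, significant above 3.84).
5. **Model search.** Exhaustive enumeration of feature subsets × clustering
   methods, each scored on pooled validation predictions; the winner is
   refit on the full table.

A synthetic-data module generates WBCD-shaped datasets (skewed ordinal
scores, ~2:1 class imbalance, optional label noise and `?` missing cells)
from a known generating FIS, so the whole pipeline is testable end to end
with ground truth in hand.

## Worked example

```bash
clusterfis simulate --n 699 --features 9 --noise 0.02 --missing 0.02 \
    --seed 11 --out data.csv
# wrote 699 records to data.csv (432 benign, 267 malign)

clusterfis train --input data.csv --features 2,4,5,6,8 --method ward \
    --scheme rs --iterations 30 --seed 11 --out model.json
# best: ward on ['Uniformity of Cell Size', 'Marginal Adhesion',
#   'Single Epithelial Cell Size', 'Bare Nuclei', 'Normal Nucleoli']
#   (224 rules, validation accuracy 0.8749); model written to model.json

clusterfis evaluate --model model.json --input data.csv --json metrics.json
# Num of Rules: 224
# Accuracy (%): 98.86%
# Sensitivity: 1.0000
# Specificity: 0.9700
# F-Measure: 0.9908
# Area under curve: 0.9850
# Kappa statistics: 0.9756
```

`simulate` writes a synthetic dataset in the WBCD CSV dialect (`id`, nine
feature columns with `?` for missing cells, class codes 2/4). `train` cleans
it (`?`→0, 2→1 / 4→2), builds one membership-function family per selected
feature from Ward clustering, induces the rule base on each of 30 random
70/30 splits, and reports the pooled validation accuracy (0.8749 here —
held-out combinations of labels that never occurred in training fall back to
the majority class). `evaluate` then scores the refit system on the full
table: 224 rules classify 98.86% of the records correctly, with perfect
benign recall (sensitivity 1.0000) and specificity 0.9700 on the malignant
class; kappa 0.9756 says the agreement is far beyond chance. `predict`
emits per-record crisp outputs (id, Z, class) and `compare` runs McNemar's
test between two prediction files.

The same workflow applies to the real WBCD file
(`breast-cancer-wisconsin.data` from the UCI repository) — it is read by the
identical `--input` path.

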