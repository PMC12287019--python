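"""Published benchmark metrics for KNN and linear SVM on the clinical lumbar
VCF dataset (63 patients, 315 vertebral bodies), indexed by train:test split.

These per-split numbers are inputs to the statistical model-comparison
machinery: the Average rows, paired t statistics and exact Wilcoxon results
are always recomputed from the per-split columns, never read from a table.
"""

from __future__ import annotations

import pandas as pd

SPLITS = ["30-70", "40-60", "50-50", "60-40", "70-30", "80-20"]

#: KNN accuracy per train:test split, by k.
KNN_ACCURACY: dict[int, list[float]] = {
    3:  [74.55, 77.89, 80.97, 85.20, 93.16, 96.92],
    5:  [73.41, 75.79, 78.71, 76.00, 80.53, 81.54],
    7:  [73.18, 76.32, 78.39, 80.40, 82.11, 86.15],
    9:  [75.23, 75.00, 78.71, 82.40, 84.21, 91.54],
    11: [74.77, 75.26, 77.74, 80.40, 81.58, 87.69],
}

#: Linear-SVM metrics per train:test split.
SVM_ACCURACY = [95.72, 96.19, 97.42, 98.00, 96.58, 98.15]
SVM_PRECISION = [96.36, 96.24, 98.10, 98.16, 97.27, 98.89]
SVM_RECALL = [97.10, 97.60, 98.04, 98.86, 95.53, 95.53]
SVM_F_MEASURE = [96.54, 96.89, 98.02, 98.46, 96.69, 97.11]


def knn_table() -> pd.DataFrame:
    rows = [
        {"k": k, "split": s, "accuracy": a}
        for k, accs in KNN_ACCURACY.items()
        for s, a in zip(SPLITS, accs)
    ]
    return pd.DataFrame(rows)


def svm_table() -> pd.DataFrame:
    return pd.DataFrame({
        "split": SPLITS,
        "accuracy": SVM_ACCURACY,
        "precision": SVM_PRECISION,
        "recall": SVM_RECALL,
        "f_measure": SVM_F_MEASURE,
    })
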