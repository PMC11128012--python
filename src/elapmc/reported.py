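"""Published reference results for EL-APMC and 21 comparison classifiers.

These are the performance figures reported for the BRATS2015 glioma-grading
benchmark (binary low- vs high-grade, ~275 subjects, the 8 segmentation
descriptor features, fivefold cross-validation), ranked by accuracy. They
serve as a regression fixture for the metric formulas — in particular, each
row's F1 must equal the harmonic mean of its printed recall and precision —
and as inputs for summary statistics. All values are percentages.
"""

from __future__ import annotations

#: (model name, accuracy %, recall %, precision %, F1 %), accuracy-ranked.
REPORTED_RESULTS: tuple[tuple[str, float, float, float, float], ...] = (
    ("EL-APMC", 88.73, 97.59, 89.05, 93.12),
    ("Logistic regression", 87.59, 95.00, 90.09, 92.48),
    ("Linear SVM", 87.59, 97.27, 88.43, 92.64),
    ("Ensemble bagged trees", 87.59, 94.09, 90.79, 92.41),
    ("Ensemble subspace discriminant", 87.59, 96.82, 88.75, 92.61),
    ("Linear discriminant", 86.86, 96.36, 88.33, 92.17),
    ("Medium Gaussian SVM", 86.86, 97.27, 87.70, 92.24),
    ("Quadratic SVM", 86.50, 96.36, 87.97, 91.97),
    ("Coarse Gaussian SVM", 86.50, 98.64, 86.45, 92.14),
    ("Weighted KNN", 86.50, 96.36, 87.97, 91.97),
    ("Gaussian naive Bayes", 86.13, 92.73, 90.27, 91.48),
    ("Ensemble subspace KNN", 86.13, 97.27, 86.99, 91.85),
    ("Medium KNN", 85.40, 96.36, 86.89, 91.38),
    ("Cubic KNN", 85.04, 97.27, 85.94, 91.26),
    ("Decision tree", 84.67, 88.64, 91.98, 90.28),
    ("Kernel naive Bayes", 84.67, 89.55, 91.20, 90.37),
    ("Cubic SVM", 84.31, 90.91, 89.69, 90.29),
    ("Ensemble RUS boosted trees", 84.31, 85.91, 94.03, 89.79),
    ("Fine KNN", 83.94, 91.82, 88.60, 90.18),
    ("Ensemble boosted trees", 83.21, 93.64, 86.55, 89.96),
    ("Cosine KNN", 82.12, 91.82, 86.70, 89.18),
    ("Fine Gaussian SVM", 80.29, 99.09, 80.74, 88.98),
)

#: Column means quoted alongside the benchmark (percent).
REPORTED_METRIC_MEANS: dict[str, float] = {
    "accuracy": 85.57,
    "recall": 94.58,
    "precision": 88.38,
    "f1": 91.31,
}
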