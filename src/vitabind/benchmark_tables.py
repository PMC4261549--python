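"""Reference confusion tables for metric replay.

Thirty-two whole-dataset confusion tables from five-fold cross-validation
and independent validation of sequence-based vitamin-binding residue
predictors on the four benchmark collections (DVI: all vitamins, DVAI:
vitamin A, DVBI: vitamin B, DPLPI: pyridoxal-5'-phosphate), spanning the
~1:20 class imbalance and both threshold strategies (balanced and
MCC-maximizing).  Each entry pairs the raw TP/TN/FP/FN counts with the
Sn/Sp/Acc (percent, 2 d.p.) and MCC (2 d.p.) values they imply; the
metric values were derived from the counts with independent decimal
arithmetic, so they exercise the metric implementations end to end,
including half-up rounding at the printed precision.
"""

from typing import NamedTuple, Tuple


class ReferenceRow(NamedTuple):
    table: str       # source grouping: cv_balanced, feature_balanced, iv_balanced, iv_maxmcc
    dataset: str     # DVI | DVAI | DVBI | DPLPI
    method: str
    sn: float
    sp: float
    acc: float
    mcc: float
    tp: int
    tn: int
    fp: int
    fn: int


REFERENCE_ROWS: Tuple[ReferenceRow, ...] = (
    # residue- vs sequence-level five-fold CV, balanced threshold
    ReferenceRow("cv_balanced", "DVI", "svm_residue", 77.88, 81.34, 81.18, 0.30, 2349, 50530, 11592, 667),
    ReferenceRow("cv_balanced", "DVI", "svm_sequence", 77.65, 80.16, 80.04, 0.29, 2342, 49797, 12325, 674),
    ReferenceRow("cv_balanced", "DVAI", "svm_residue", 73.98, 77.94, 77.67, 0.30, 398, 5749, 1627, 140),
    ReferenceRow("cv_balanced", "DVAI", "svm_sequence", 72.12, 76.34, 76.06, 0.27, 388, 5631, 1745, 150),
    ReferenceRow("cv_balanced", "DVBI", "svm_residue", 80.44, 83.83, 83.68, 0.33, 1785, 42063, 8116, 434),
    ReferenceRow("cv_balanced", "DVBI", "svm_sequence", 79.86, 82.90, 82.77, 0.32, 1772, 41598, 8581, 447),
    ReferenceRow("cv_balanced", "DPLPI", "svm_residue", 91.48, 93.38, 93.30, 0.55, 999, 24874, 1764, 93),
    ReferenceRow("cv_balanced", "DPLPI", "svm_sequence", 90.38, 92.62, 92.53, 0.52, 987, 24672, 1966, 105),
    # profile-only vs combined feature blocks, sequence-level CV, balanced
    ReferenceRow("feature_balanced", "DVI", "pssm_only", 77.65, 80.16, 80.04, 0.29, 2342, 49797, 12325, 674),
    ReferenceRow("feature_balanced", "DVI", "pssm_ss_vbp", 78.55, 82.02, 81.86, 0.31, 2369, 50951, 11171, 647),
    ReferenceRow("feature_balanced", "DVAI", "pssm_only", 72.12, 76.34, 76.06, 0.27, 388, 5631, 1745, 150),
    ReferenceRow("feature_balanced", "DVAI", "pssm_ss_vbp", 72.12, 78.28, 77.86, 0.29, 388, 5774, 1602, 150),
    ReferenceRow("feature_balanced", "DVBI", "pssm_only", 79.86, 82.90, 82.77, 0.32, 1772, 41598, 8581, 447),
    ReferenceRow("feature_balanced", "DVBI", "pssm_ss_vbp", 80.71, 85.14, 84.96, 0.35, 1791, 42724, 7455, 428),
    ReferenceRow("feature_balanced", "DPLPI", "pssm_only", 90.38, 92.62, 92.53, 0.52, 987, 24672, 1966, 105),
    ReferenceRow("feature_balanced", "DPLPI", "pssm_ss_vbp", 91.48, 93.09, 93.03, 0.54, 999, 24798, 1840, 93),
    # independent validation, balanced threshold
    ReferenceRow("iv_balanced", "DVI", "svm_sequence", 75.38, 78.51, 78.35, 0.28, 493, 9167, 2509, 161),
    ReferenceRow("iv_balanced", "DVI", "ensemble", 80.73, 81.05, 81.03, 0.33, 528, 9463, 2213, 126),
    ReferenceRow("iv_balanced", "DVAI", "svm_sequence", 73.48, 79.25, 78.61, 0.38, 133, 1142, 299, 48),
    ReferenceRow("iv_balanced", "DVAI", "ensemble", 79.01, 79.18, 79.16, 0.41, 143, 1141, 300, 38),
    ReferenceRow("iv_balanced", "DVBI", "svm_sequence", 78.28, 81.49, 81.35, 0.30, 328, 7291, 1656, 91),
    ReferenceRow("iv_balanced", "DVBI", "ensemble", 81.38, 81.69, 81.68, 0.32, 341, 7309, 1638, 78),
    ReferenceRow("iv_balanced", "DPLPI", "svm_sequence", 85.77, 90.18, 90.00, 0.44, 211, 5352, 583, 35),
    ReferenceRow("iv_balanced", "DPLPI", "ensemble", 89.02, 89.30, 89.29, 0.44, 219, 5300, 635, 27),
    # independent validation, MCC-maximizing threshold
    ReferenceRow("iv_maxmcc", "DVI", "svm_sequence", 47.09, 98.40, 95.68, 0.52, 308, 11489, 187, 346),
    ReferenceRow("iv_maxmcc", "DVI", "ensemble", 47.09, 98.42, 95.69, 0.52, 308, 11491, 185, 346),
    ReferenceRow("iv_maxmcc", "DVAI", "svm_sequence", 32.04, 97.09, 89.83, 0.38, 58, 1399, 42, 123),
    ReferenceRow("iv_maxmcc", "DVAI", "ensemble", 38.12, 96.81, 90.26, 0.43, 69, 1395, 46, 112),
    ReferenceRow("iv_maxmcc", "DVBI", "svm_sequence", 52.03, 98.25, 96.18, 0.53, 218, 8790, 157, 201),
    ReferenceRow("iv_maxmcc", "DVBI", "ensemble", 51.07, 98.69, 96.56, 0.56, 214, 8830, 117, 205),
    ReferenceRow("iv_maxmcc", "DPLPI", "svm_sequence", 72.76, 99.11, 98.06, 0.74, 179, 5882, 53, 67),
    ReferenceRow("iv_maxmcc", "DPLPI", "ensemble", 74.39, 99.07, 98.09, 0.75, 183, 5880, 55, 63),
)
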