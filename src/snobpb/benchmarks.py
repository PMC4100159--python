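"""Published benchmark rows for S-nitrosylation site predictors.

These are the jackknife results reported on the Li training dataset
(784 S-nitrosylated / 1568 non-S-nitrosylated 21-mers) and the independent
Li test dataset (43 / 121) for several published predictors, including the
ANBPB + composition model this package implements. They are inputs to the
audit machinery in :mod:`snobpb.evaluation`: each row's integer confusion
matrix is reconstructed from printed Sn/Sp and the class sizes, and all
four metrics are recomputed from it, so the printed Acc/MCC can be checked
to printed precision without access to the underlying (external,
supplementary) peptide data.

Xu-dataset rows are omitted: they are means over 50 runs of 10-fold CV and
do not correspond to a single integer confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluation import AuditResult, audit_printed_row

LI_TRAIN_N_POS = 784
LI_TRAIN_N_NEG = 1568
LI_TEST_N_POS = 43
LI_TEST_N_NEG = 121


@dataclass(frozen=True)
class BenchmarkRow:
    dataset: str
    predictor: str
    sn: float  # %
    sp: float  # %
    acc: float  # %
    mcc: float
    n_pos: int
    n_neg: int

    def audit(self) -> AuditResult:
        return audit_printed_row(
            sn=self.sn, sp=self.sp, acc=self.acc, mcc=self.mcc,
            n_pos=self.n_pos, n_neg=self.n_neg,
        )


#: Jackknife results of four encoding schemes (each + the two composition
#: features) on the Li training set, at each scheme's best class weight W1.
ENCODING_ROWS = (
    BenchmarkRow("li_train", "BPB", 65.31, 65.63, 65.52, 0.2933,
                 LI_TRAIN_N_POS, LI_TRAIN_N_NEG),
    BenchmarkRow("li_train", "BRABSB", 73.09, 58.16, 63.14, 0.2949,
                 LI_TRAIN_N_POS, LI_TRAIN_N_NEG),
    BenchmarkRow("li_train", "ANBPB", 67.60, 64.29, 65.39, 0.3014,
                 LI_TRAIN_N_POS, LI_TRAIN_N_NEG),
    BenchmarkRow("li_train", "RANS", 63.90, 61.42, 62.24, 0.2391,
                 LI_TRAIN_N_POS, LI_TRAIN_N_NEG),
)

#: Cross-predictor comparison on the Li training set (jackknife) and the
#: independent Li test set. The iSNO-ANBPB test-set Sn is printed as 74.12%
#: although the other three printed metrics imply TP = 32, i.e. Sn = 74.42%;
#: the audit flags exactly this row.
COMPARISON_ROWS = (
    BenchmarkRow("li_train", "Li et al.", 42.86, 70.98, 61.61, 0.1381,
                 LI_TRAIN_N_POS, LI_TRAIN_N_NEG),
    BenchmarkRow("li_train", "iSNO-ANBPB", 67.60, 64.29, 65.39, 0.3014,
                 LI_TRAIN_N_POS, LI_TRAIN_N_NEG),
    BenchmarkRow("li_test", "SNOSite", 74.42, 28.10, 40.24, 0.0248,
                 LI_TEST_N_POS, LI_TEST_N_NEG),
    BenchmarkRow("li_test", "iSNO-AAPair", 27.91, 80.17, 66.46, 0.0858,
                 LI_TEST_N_POS, LI_TEST_N_NEG),
    BenchmarkRow("li_test", "Li et al.", 51.16, 69.42, 64.63, 0.1886,
                 LI_TEST_N_POS, LI_TEST_N_NEG),
    BenchmarkRow("li_test", "iSNO-PseAAC", 58.14, 63.64, 62.20, 0.1940,
                 LI_TEST_N_POS, LI_TEST_N_NEG),
    BenchmarkRow("li_test", "iSNO-ANBPB", 74.12, 59.50, 63.41, 0.2984,
                 LI_TEST_N_POS, LI_TEST_N_NEG),
)

ALL_ROWS = ENCODING_ROWS + COMPARISON_ROWS


def get_row(dataset: str, predictor: str) -> BenchmarkRow:
    for row in ALL_ROWS:
        if row.dataset == dataset and row.predictor == predictor:
            return row
    raise KeyError(f"no benchmark row for ({dataset!r}, {predictor!r})")
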