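"""Metrics arithmetic, printed-table audits, and the CV protocols."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from snobpb import benchmarks
from snobpb.classifier import ModelConfig
from snobpb.evaluation import (
    ConfusionCounts,
    audit_printed_row,
    counts_from_rates,
    jackknife,
    metrics_from_counts,
    repeated_kfold,
    round_half_up,
)
from snobpb.io import PeptideWindow, SnobpbError


class TestMetricsFromCounts:
    def test_published_jackknife_row(self):
        rep = metrics_from_counts(ConfusionCounts(tp=530, fp=560, tn=1008, fn=254))
        assert (rep.sn, rep.sp, rep.acc, rep.mcc) == (67.60, 64.29, 65.39, 0.3014)

    def test_perfect_prediction(self):
        rep = metrics_from_counts(ConfusionCounts(tp=5, fp=0, tn=9, fn=0))
        assert (rep.sn, rep.sp, rep.acc, rep.mcc) == (100.0, 100.0, 100.0, 1.0)

    def test_symmetric_counts_give_chance_metrics(self):
        rep = metrics_from_counts(ConfusionCounts(tp=3, fp=3, tn=3, fn=3))
        assert (rep.acc, rep.mcc) == (50.0, 0.0)

    def test_zero_denominator_mcc_is_zero(self):
        rep = metrics_from_counts(ConfusionCounts(tp=0, fp=0, tn=4, fn=2))
        assert rep.mcc == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(SnobpbError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    @given(
        st.integers(0, 300), st.integers(0, 300),
        st.integers(0, 300), st.integers(0, 300),
    )
    def test_matches_sklearn_and_manual_tally(self, tp, fp, tn, fn):
        from sklearn.metrics import matthews_corrcoef

        if tp + fp + tn + fn == 0:
            return
        rep = metrics_from_counts(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        true = [1] * tp + [-1] * fp + [-1] * tn + [1] * fn
        pred = [1] * tp + [1] * fp + [-1] * tn + [-1] * fn
        if tp + fn:
            assert rep.sn == pytest.approx(
                100 * sum(t == p == 1 for t, p in zip(true, pred)) / (tp + fn),
                abs=0.005,
            )
        assert rep.acc == pytest.approx(
            100 * np.mean(np.array(true) == np.array(pred)), abs=0.005
        )
        assert rep.mcc == pytest.approx(
            matthews_corrcoef(true, pred), abs=5.1e-5
        )


class TestRounding:
    @pytest.mark.parametrize(
        "value,digits,expected",
        [(0.125, 2, 0.13), (2.675, 2, 2.68), (0.30145, 4, 0.3015), (-0.125, 2, -0.13)],
    )
    def test_half_up_at_exact_ties(self, value, digits, expected):
        from fractions import Fraction

        assert round_half_up(Fraction(str(value)), digits) == expected


class TestCountsFromRates:
    def test_published_test_set_row(self):
        counts = counts_from_rates(sp=28.10, n_pos=43, n_neg=121, sn=74.42)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (32, 11, 34, 87)
        assert metrics_from_counts(counts).acc == 40.24

    def test_accuracy_form(self):
        counts = counts_from_rates(sp=64.29, n_pos=784, n_neg=1568, acc=65.39)
        assert (counts.tp, counts.tn) == (530, 1008)

    def test_perfect_rates(self):
        counts = counts_from_rates(sp=100, n_pos=10, n_neg=10, sn=100)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (10, 0, 10, 0)

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(SnobpbError, match="out of"):
            counts_from_rates(sp=200, n_pos=4, n_neg=4, sn=50)

    def test_inconsistent_reconstruction_names_cell(self):
        with pytest.raises(SnobpbError, match="TP"):
            counts_from_rates(sp=0.0, n_pos=10, n_neg=10, acc=90.0)

    @given(
        st.integers(1, 400), st.integers(0, 400),
        st.integers(1, 400), st.integers(0, 400),
    )
    def test_round_trip_identity_on_integer_matrices(self, p, tp, n, tn):
        counts = ConfusionCounts(tp=min(tp, p), fp=n - min(tn, n),
                                 tn=min(tn, n), fn=p - min(tp, p))
        rep = metrics_from_counts(counts)
        back = counts_from_rates(
            sp=rep.sp, n_pos=counts.n_pos, n_neg=counts.n_neg, sn=rep.sn
        )
        assert back == counts


class TestPublishedTableAudits:
    @pytest.mark.parametrize("row", benchmarks.ALL_ROWS,
                             ids=lambda r: f"{r.dataset}-{r.predictor}")
    def test_acc_and_mcc_reproduce_to_printed_precision(self, row):
        audit = row.audit()
        assert audit.recomputed.acc == row.acc
        assert audit.recomputed.mcc == row.mcc

    def test_known_sensitivity_typo_is_flagged_not_resolved(self):
        row = benchmarks.get_row("li_test", "iSNO-ANBPB")
        audit = row.audit()
        assert not audit.consistent
        assert audit.inconsistencies == (
            "Sn: printed 74.12 but counts imply 74.42",
        )
        # all other rows are fully self-consistent
        others = [r for r in benchmarks.ALL_ROWS if r is not row]
        assert all(r.audit().consistent for r in others)


def tiny_windows(n_pos, n_neg, seed, L=9):
    from snobpb.synthetic import SyntheticSpec, generate_dataset

    return generate_dataset(SyntheticSpec(n_pos=n_pos, n_neg=n_neg, L=L, seed=seed))


class TestJackknife:
    def test_separable_motif_data_is_classified_perfectly(self, separable_windows):
        rep = jackknife(separable_windows)
        assert rep.acc == 100.0 and rep.mcc == 1.0

    def test_two_windows_lose_a_class(self):
        w = tiny_windows(1, 1, seed=4)
        with pytest.raises(SnobpbError, match="class"):
            jackknife(w)

    def test_global_profile_scope_is_optimistic_on_shuffled_labels(
        self, null_windows
    ):
        # the documented leak diagnostic: global-scope profiles let the
        # held-out window see itself, inflating apparent correlation
        leaky = jackknife(null_windows, profile_scope="global")
        honest = jackknife(null_windows, profile_scope="fold")
        assert leaky.mcc > honest.mcc
        assert leaky.mcc > 0.2

    def test_deterministic(self):
        w = tiny_windows(8, 8, seed=9)
        assert jackknife(w) == jackknife(w)


class TestRepeatedKfold:
    def test_leave_one_out_equals_jackknife(self):
        w = tiny_windows(10, 10, seed=2)
        loo = repeated_kfold(w, k=len(w), repeats=1, seed=0)
        jk = jackknife(w)
        assert loo.repeats[0].counts == jk.counts

    def test_same_seed_reproducible(self):
        w = tiny_windows(15, 15, seed=3)
        a = repeated_kfold(w, k=5, repeats=3, seed=11)
        b = repeated_kfold(w, k=5, repeats=3, seed=11)
        assert a.mean == b.mean and a.sd == b.sd

    def test_separable_data_has_high_mean_mcc(self, separable_windows):
        rep = repeated_kfold(separable_windows, k=10, repeats=3, seed=5)
        assert rep.mean["MCC"] >= 0.8

    def test_k_larger_than_minority_class_rejected(self):
        w = tiny_windows(4, 30, seed=6)
        with pytest.raises(SnobpbError, match="k="):
            repeated_kfold(w, k=10, repeats=1, seed=0)
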