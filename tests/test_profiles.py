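"""Count matrices, propensity ratios, and the BPB/ANBPB posterior profiles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from snobpb.io import PeptideWindow, SnobpbError
from snobpb.profiles import (
    AA_INDEX,
    BiProfile,
    PositionCountMatrix,
    anbpb_posterior,
    bpb_posterior,
    build_biprofile,
    count_positions,
    normal_cdf,
    relative_propensity,
)
from snobpb.synthetic import Motif, SyntheticSpec, generate_dataset


def brute_force_counts(windows, L):
    counts = np.zeros((20, L), dtype=int)
    for w in windows:
        for j, ch in enumerate(w.residues):
            if ch != "X":
                counts[AA_INDEX[ch], j] += 1
    return counts


def make_counts(columns):
    """Build a PositionCountMatrix from explicit per-position count columns."""
    counts = np.array(columns, dtype=np.int64).T
    eff = counts.sum(axis=0)
    return PositionCountMatrix(counts=counts, n=int(eff.max()), effective_n=eff)


class TestCountPositions:
    def test_hand_tally(self):
        windows = [PeptideWindow("ACA", 1), PeptideWindow("CCC", 1)]
        pcm = count_positions(windows, 3)
        A, C = AA_INDEX["A"], AA_INDEX["C"]
        assert pcm.counts[A, 0] == 1 and pcm.counts[C, 0] == 1
        assert pcm.counts[C, 1] == 2
        assert pcm.counts[A, 2] == 1 and pcm.counts[C, 2] == 1
        assert pcm.counts.sum() == 6

    def test_pad_contributes_to_no_row(self):
        pcm = count_positions([PeptideWindow("XCA", 1)], 3)
        assert pcm.counts[:, 0].sum() == 0
        assert pcm.effective_n.tolist() == [0, 1, 1]

    def test_empty_or_mixed_length_rejected(self):
        with pytest.raises(SnobpbError):
            count_positions([], 3)
        with pytest.raises(SnobpbError, match="length"):
            count_positions([PeptideWindow("ACA", 1)], 5)

    def test_matches_brute_force_on_random_windows(self, padded_windows):
        pcm = count_positions(padded_windows, 21)
        assert np.array_equal(pcm.counts, brute_force_counts(padded_windows, 21))
        assert np.array_equal(pcm.effective_n, pcm.counts.sum(axis=0))
        assert pcm.n == len(padded_windows)


class TestRelativePropensity:
    def test_ratio_by_definition(self):
        # K in 2 of 4 positives vs 1 of 4 negatives at position 0 -> r = 2
        K, A = AA_INDEX["K"], AA_INDEX["A"]
        pos = np.zeros((20, 3), dtype=np.int64)
        neg = np.zeros((20, 3), dtype=np.int64)
        pos[K, 0], pos[A, 0] = 2, 2
        neg[K, 0], neg[A, 0] = 1, 3
        pos[AA_INDEX["C"], 1] = neg[AA_INDEX["C"], 1] = 4
        pos[A, 2] = neg[A, 2] = 4
        pm = relative_propensity(
            PositionCountMatrix(pos, 4, pos.sum(0)),
            PositionCountMatrix(neg, 4, neg.sum(0)),
        )
        assert pm.r[K, 0] == pytest.approx(2.0)

    def test_identical_classes_give_unit_ratio(self, null_windows):
        pcm = count_positions(null_windows, 21)
        pm = relative_propensity(pcm, pcm)
        finite = np.isfinite(pm.r)
        assert np.allclose(pm.r[finite], 1.0)

    def test_zero_negative_frequency_undefined_and_excluded(self):
        K = AA_INDEX["K"]
        pos = np.zeros((20, 3), dtype=np.int64)
        neg = np.zeros((20, 3), dtype=np.int64)
        pos[K] = [2, 2, 2]
        neg[AA_INDEX["A"]] = [2, 2, 2]
        pm = relative_propensity(
            PositionCountMatrix(pos, 2, pos.sum(0)),
            PositionCountMatrix(neg, 2, neg.sum(0)),
        )
        assert np.isnan(pm.r[K, 0])
        assert np.isnan(pm.averages[K])  # every entry undefined -> excluded

    def test_pseudocount_regularizes(self):
        K = AA_INDEX["K"]
        pos = np.zeros((20, 1), dtype=np.int64)
        neg = np.zeros((20, 1), dtype=np.int64)
        pos[K, 0] = 4
        neg[AA_INDEX["A"], 0] = 4
        pm = relative_propensity(
            PositionCountMatrix(pos, 4, pos.sum(0)),
            PositionCountMatrix(neg, 4, neg.sum(0)),
            pseudocount=1.0,
        )
        # (4+1)/(4+20) over (0+1)/(4+20) = 5
        assert pm.r[K, 0] == pytest.approx(5.0)


class TestBpbPosterior:
    def test_frequencies_and_zero_column(self):
        cols = [[0] * 20 for _ in range(2)]
        cols[0][AA_INDEX["A"]] = 2
        cols[0][AA_INDEX["C"]] = 2
        pcm = make_counts(cols)
        post = bpb_posterior(pcm)
        assert post[AA_INDEX["A"], 0] == pytest.approx(0.5)
        assert post[AA_INDEX["C"], 0] == pytest.approx(0.5)
        assert np.all(post[:, 1] == 0)  # all-pad column

    def test_columns_sum_to_one(self, weak_motif_windows):
        pcm = count_positions(weak_motif_windows, 21)
        post = bpb_posterior(pcm)
        assert np.allclose(post.sum(axis=0), 1.0, atol=1e-12)

    def test_single_window_column(self):
        pcm = count_positions([PeptideWindow("KCK", 1)], 3)
        post = bpb_posterior(pcm)
        assert post[AA_INDEX["K"], 0] == 1.0


class TestNormalCdf:
    def test_symmetry(self):
        assert normal_cdf(0.0) == pytest.approx(0.5)
        for x in np.linspace(-6, 6, 25):
            assert normal_cdf(x) + normal_cdf(-x) == pytest.approx(1.0, abs=1e-12)

    def test_against_adaptive_quadrature(self):
        def oracle(x):
            val, _ = quad(
                lambda t: math.exp(-t * t / 2) / math.sqrt(2 * math.pi), 0, x
            )
            return 0.5 + val

        for x in (-4.0, -1.0, 0.3, 1.0, 2.5):
            assert normal_cdf(x) == pytest.approx(oracle(x), abs=1e-10)
        assert normal_cdf(1.0) == pytest.approx(0.8413447, abs=1e-7)

    def test_non_finite_rejected(self):
        with pytest.raises(SnobpbError):
            normal_cdf(float("nan"))


class TestAnbpbPosterior:
    def test_uniform_column_degenerates_to_half(self):
        cols = [[1] * 20]
        post = anbpb_posterior(make_counts(cols))
        assert np.all(post == 0.5)

    def test_hand_standardized_column(self):
        # n=20: one count of 8, twelve of 1, seven of 0; mean=1=n*p,
        # V = sqrt(56/20) ~ 1.6733
        col = [8] + [1] * 12 + [0] * 7
        pcm = make_counts([col])
        post = anbpb_posterior(pcm)
        V = math.sqrt(56 / 20)
        assert V == pytest.approx(1.6733, abs=1e-4)
        assert post[0, 0] == pytest.approx(1.0, abs=5e-5)  # count 8: z = 7/V
        assert post[19, 0] == pytest.approx(0.2751, abs=1e-4)  # count 0

    def test_monotone_in_counts_within_column(self, weak_motif_windows):
        pcm = count_positions(weak_motif_windows, 21)
        post = anbpb_posterior(pcm)
        for j in range(21):
            order = np.argsort(pcm.counts[:, j], kind="stable")
            assert np.all(np.diff(post[order, j]) >= -1e-15)

    def test_needs_two_windows(self):
        pcm = count_positions([PeptideWindow("ACA", 1)], 3)
        with pytest.raises(SnobpbError):
            anbpb_posterior(pcm)

    def test_invariant_to_window_order(self, null_windows):
        rev = list(reversed(null_windows))
        a = anbpb_posterior(count_positions(null_windows, 21))
        b = anbpb_posterior(count_positions(rev, 21))
        assert np.array_equal(a, b)


class TestBuildBiprofile:
    def test_identical_classes_identical_profiles(self, null_windows):
        pos = [w for w in null_windows if w.label == 1]
        bp = build_biprofile(pos, pos, "bpb", 21)
        assert np.array_equal(bp.pos, bp.neg)

    def test_enriched_residue_scores_higher_in_positive_profile(
        self, weak_motif_windows
    ):
        pos = [w for w in weak_motif_windows if w.label == 1]
        neg = [w for w in weak_motif_windows if w.label == -1]
        bp = build_biprofile(pos, neg, "anbpb", 21)
        K = AA_INDEX["K"]
        assert bp.pos[K, 2] > bp.neg[K, 2]
        assert bp.n_pos == 2000 and bp.n_neg == 2000 and bp.p == 1 / 20

    def test_empty_class_rejected(self, null_windows):
        with pytest.raises(SnobpbError):
            build_biprofile([], null_windows, "anbpb", 21)

    def test_json_round_trip(self, weak_motif_windows):
        pos = [w for w in weak_motif_windows if w.label == 1]
        neg = [w for w in weak_motif_windows if w.label == -1]
        bp = build_biprofile(pos, neg, "anbpb", 21)
        again = BiProfile.from_json(bp.to_json())
        assert again.method == bp.method
        assert np.array_equal(again.pos, bp.pos)
        assert np.array_equal(again.neg, bp.neg)


class TestEnrichmentRecovery:
    def test_planted_ratio_recovered_at_large_n(self):
        # sd(r_hat) ~ 0.033 at this size, so +/-0.1 is a ~3 sigma band
        spec = SyntheticSpec(
            n_pos=200_000, n_neg=200_000, L=9,
            motif=(Motif(position=3, residue="K", rho=3.0),), seed=20140610,
        )
        windows = generate_dataset(spec)
        pos = [w for w in windows if w.label == 1]
        neg = [w for w in windows if w.label == -1]
        pm = relative_propensity(
            count_positions(pos, 9), count_positions(neg, 9)
        )
        assert abs(pm.r[AA_INDEX["K"], 2] - 3.0) <= 0.1
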