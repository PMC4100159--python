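# Methods

## Windows and datasets

The unit of analysis is a fixed-length peptide window centered on a
candidate cysteine. The default length is L = 21 (10 flanking residues per
side); L must be odd. Sites are 1-based positions into a protein sequence
and must index a cysteine (a hard error otherwise; `extract_window` offers
an explicit escape hatch for non-canonical centers). Windows that overrun a
protein terminus are padded with `X`, which is treated everywhere as
"no residue": it contributes to no positional count, maps to the neutral
posterior when encoding, and is excluded from composition denominators.

Redundancy reduction is exact-duplicate removal only: the first occurrence
of each (residues, label) pair is kept, and identical peptides carrying
opposite labels are both kept with a logged warning (such conflicts are a
data-curation question, not one the extractor should resolve silently).
Similarity-based clustering of near-duplicates is out of scope; users with
redundant data should pre-cluster with a dedicated tool.

## Profiles

For a class of n windows, X_ij counts amino acid i at position j
(effective_n[j] = Σ_i X_ij ≤ n at padded positions).

* **BPB** posteriors are the per-column relative frequencies
  X_ij / effective_n[j] (an all-pad column is all zeros).
* **ANBPB** posteriors are Φ((X_ij − n·p)/V_j) with p = 1/20.
  Two readings of "the spread V_j" are defensible; this package uses the
  **population standard deviation of the 20 counts at position j**
  (divisor 20). A standard deviation — not a variance — is required for the
  standardized score to be dimensionless; using the variance would make the
  Φ argument scale with n. The standardization mean is n·p with the nominal
  n even at padded positions, because the binomial null is defined by the
  class size, not by the post-padding coverage. A degenerate column
  (V_j = 0, e.g. the uniform column or the constant center column) gets the
  neutral value Φ(0) = 0.5, which also removes the division by zero at the
  center.
* **Propensities** r_xj are positive-class over negative-class frequencies
  with an optional symmetric pseudocount a: (X⁺+a)/(eff⁺+20a) over the
  negative analogue. The default a = 0 reproduces the plain ratio;
  zero-denominator entries are then undefined (NaN) and excluded from the
  per-residue averages, as is the center column (constitutively C, no
  signal).

Profiles serialize to JSON (method, class sizes, row/column labels,
matrices) so trained profiles are portable and diffable.

## Feature vector

A window is encoded as 2·(L−1)+2 features (42 at L = 21): the
positive-profile posterior of the observed residue at each of the 20
flanking positions, the same from the negative profile, then the fractions
of non-pad residues in the charge class A = {A,C,D,E,H,L,P,Q,S,V,W} and the
helix class H = {C,D,G,N,P,S,T,W,Y} (the complementary classes are linearly
dependent and omitted). The center position is dropped from the profile
features because it is constitutively cysteine in both classes; the feature
layout is recorded with each trained model so a model can refuse
mismatching inputs. `X` looks up the neutral posterior (0.5 for ANBPB,
1/20 for BPB) — padding must not masquerade as class evidence.

## Classifier

A soft-margin SVM with RBF kernel exp(−γ‖x−y‖²); the penalty for the
positive class is C·W₊₁ and for the negative class C·W₋₁. Defaults
C = 22.6274 (= 2^4.5), γ = 0.03125 (= 2^−5), W₊₁ = 2, W₋₁ = 1 — the
operating point established for this encoding on the reference training
data; the 1:2 class imbalance there is why the positive class gets double
weight. Fitting uses scikit-learn's libsvm binding (optimizer tolerance
fixed at 1e-6 and recorded in the model payload), but the fitted machine is
stored as plain arrays (support vectors, dual coefficients, intercept) and
prediction evaluates the kernel expansion directly, so a model JSON
round-trips to bit-identical decision values. A decision value of exactly 0
is called negative — conservative for site calling.

Two searches mirror common practice: W₊₁ over {1, 1.5, 2, 2.5} maximizing
cross-validated MCC (ties to the smaller weight), and an exhaustive
(C, γ) grid over log₂C ∈ {−5, −4.5, …, 15} × log₂γ ∈ {−15, …, 3} by
15-fold stratified CV accuracy (ties to smaller C, then smaller γ). The
defaults bypass the search; the default grid contains the default optimum.

## Evaluation

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/N as percentages, and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), computed in exact
rational arithmetic and rounded half-up to 2 d.p. (percentages) and 4 d.p.
(MCC), the usual table precision. A zero factor in the MCC denominator
gives MCC = 0 by convention.

The inverse map (`counts_from_rates`) reconstructs integer confusion
matrices from printed rates: TP = round(Sn·n₊/100) (or via Acc when Sn is
not printed), TN = round(Sp·n₋/100), remaining cells by complement,
rounding half-up, with hard errors on infeasible cells. This makes
published result tables auditable without the underlying data;
`snobpb.benchmarks` applies it to the shipped comparison rows. One shipped
row is knowingly inconsistent (a printed sensitivity of 74.12% whose own
Sp/Acc/MCC imply 32/43 = 74.42%); the audit reports the discrepancy rather
than resolving it.

Protocols:

* **Jackknife** (leave-one-out). With `profile_scope="fold"` (default) the
  bi-profile is rebuilt without the held-out window on every fold and the
  SVM refit, so no held-out information reaches the encoding. With
  `"global"` the profile is built once on all windows — a deliberately
  leaky mode kept as a diagnostic: on label-shuffled data it produces
  strongly positive MCC (≈ +0.5 on the 400-window null fixture) where the
  fold-scoped protocol stays near zero.
* **Repeated k-fold**: stratified folds, fresh seeded shuffle per repeat,
  per-repeat metrics pooled from fold counts, across-repeat mean ± sd
  reported. k = n is supported as an explicit leave-one-out special case
  (stratification is moot at fold size 1), which makes the protocol
  identity `repeated_kfold(k=n, repeats=1) == jackknife` hold exactly.

A subtlety of the fold-scoped jackknife worth knowing: each *training*
window still contributes to its own class profile, while the held-out
window does not. ANBPB deliberately amplifies single-count differences, so
the SVM can partially fit this self-inclusion signature, and the held-out
MCC on null data consequently fluctuates more than the binomial ~n^{-1/2}
(empirically sd ≈ 0.1 rather than 0.05 at n = 400, centered on zero, i.e.
noisier but not biased). This is a property of the protocol definition, not
an implementation artifact; the BPB encoding, whose per-window
self-contribution is O(1/n), does not show it.

## Synthetic data

The generator draws residues i.i.d. per position from a background
distribution (uniform 1/20 by default, matching the ANBPB null; a
SwissProt-like vector is provided), fixes the center to C, and plants
enrichments: residue R at position q with ratio ρ gets probability
ρ·background(R) in positives, the other 19 residues rescaled to the
leftover mass, so the planted value of r_{R,q} is exactly ρ. ρ = ∞ plants R
deterministically and an `exclusive` motif bans R at q in negatives,
yielding a perfectly separable dataset. A `pad_fraction` of windows
receives a random-length terminal `X` run to exercise the padding paths.
Everything derives from the spec's seed; the canonical fixture seed is
20140610.

Four canonical fixtures ship as code (`make_fixture_suite` writes them as
window TSV + FASTA + site TSV with a manifest): `null` (200+200, no
motif), `weak_motif` (2000+2000, K enriched threefold at position 3),
`separable` (150+150, exclusive W at position 5), `padded` (150+150,
30% truncated). What the generator does *not* emulate: positional
dependence along the peptide, homology-induced redundancy, realistic
protein domain context, and class-conditional composition differences
beyond the planted motif — so green synthetic tests demonstrate
correctness of the machinery, not field performance on real proteomes.

## Problem sizes in the tests and acceptance script

Statistical checks are run at sizes chosen from the analytic sampling
variance of the quantity under test so that the asserted band is roughly a
3σ statement rather than a seed lottery: the [2.7, 3.3] recovery band for a
planted ρ = 3 is checked at 20000+20000 windows (sd of r̂ ≈ 0.1), and the
tighter ±0.1 convergence check at 200000+200000 (sd ≈ 0.033). The
end-to-end jackknife checks use 150+150 (separable) and 400 (null)
windows, sizes at which a full leave-one-out refit of profile + SVM runs in
seconds. As noted above, at n = 400 the null jackknife MCC has an empirical
sd of ≈ 0.1, so individual seeds can land outside ±0.05 without indicating
bias.

## Known limitations

* The ANBPB "spread" is interpreted as a standard deviation (see above);
  results under the variance reading would differ.
* Negative annotations are accepted from any protein; the package does not
  enforce that negatives come from proteins with at least one positive
  site.
* Exact-duplicate removal only; no similarity clustering.
* No probability calibration; decision values are margins, not
  probabilities.
* The composition features use only the two printed residue classes; the
  full 20-component amino-acid composition and other PseAAC modes are not
  implemented.
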