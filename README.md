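# snobpb — protein S-nitrosylation site prediction

Protein *S*-nitrosylation — the covalent attachment of a nitric-oxide moiety
to a cysteine thiol — is a redox-dependent post-translational modification
that is hard to map experimentally because the S–NO bond is chemically
unstable and endogenously nitrosylated proteins are scarce. Sequence-based
predictors are therefore a standard auxiliary tool: given a cysteine and its
flanking residues, score whether the site is likely to be modified.

`snobpb` implements such a predictor for bioinformaticians working on
cysteine PTMs. Its core is the **adapted normal-distribution bi-profile
Bayes (ANBPB)** encoding combined with two pseudo amino-acid composition
terms and a class-weighted RBF-kernel SVM.

## The model

Each candidate site is a 21-mer peptide centered on the cysteine, padded
with `X` at protein termini. Let X<sub>ij</sub> be the count of amino acid
*i* (of 20) at position *j* (of 21) over a class of training windows of
size *n*. Under a null model the X<sub>ij</sub> are Binomial(*n*, *p*) with
*p* = 1/20. ANBPB standardizes each count against the binomial mean using
the observed spread of the 20 counts at that position,

&nbsp;&nbsp;&nbsp;&nbsp;X′<sub>ij</sub> = (X<sub>ij</sub> − *np*) / V<sub>j</sub>,&nbsp;&nbsp;
p<sub>ij</sub> = Φ(X′<sub>ij</sub>),

where V<sub>j</sub> is the population standard deviation of the 20 counts
at position *j* and Φ is the standard normal CDF. Computing these
posteriors separately on the positive (*S*-nitrosylated) and negative
window sets gives a *bi-profile*; a window is encoded as

&nbsp;&nbsp;&nbsp;&nbsp;P = [ψ₁, …, ψ₄₂],

with ψ₁…ψ₂₀ the positive-profile posteriors of the window's residues at the
20 flanking positions, ψ₂₁…ψ₄₀ the same from the negative profile, and
ψ₄₁, ψ₄₂ the fractions of window residues in an electrostatic-charge class
A = {A,C,D,E,H,L,P,Q,S,V,W} and an α-helix-propensity class
H = {C,D,G,N,P,S,T,W,Y}. A soft-margin SVM with kernel
k(x, y) = exp(−γ‖x−y‖²) and class-specific penalties C·W₊₁, C·W₋₁
(defaults C = 22.6274, γ = 0.03125, W₊₁ = 2, W₋₁ = 1) does the
classification. Performance is reported as Sn, Sp, Acc and Matthews
correlation (MCC) from jackknife or repeated stratified 10-fold
cross-validation, with the bi-profile rebuilt inside every fold by default
so no held-out information leaks into the encoding.

A plain bi-profile Bayes encoding (`method="bpb"`, relative frequencies
instead of Φ-scores) is available for comparison, as are the r<sub>xj</sub>
positional propensity statistics used for exploratory sequence analysis.

## Worked example

Generate the bundled synthetic fixtures (labeled 21-mers with planted
positional enrichments), fit the predictor, and cross-validate it:

```python
from snobpb import SnoSiteModel
from snobpb.io import read_windows_tsv

windows = read_windows_tsv("fx/separable.windows.tsv")  # snobpb make-fixtures fx
res = SnoSiteModel(windows, method="anbpb").fit()
print(res.summary())
print(res.jackknife())
```

```
S-nitrosylation site predictor (bi-profile Bayes + RBF SVM)
============================================================
encoding:            anbpb  (L=21, 42 features)
windows:             150 positive / 150 negative
C, gamma:            22.6274, 0.03125
class weights:       W+1=2.0, W-1=1.0
support vectors:     80
------------------------------------------------------------
resubstitution fit (optimistic; use jackknife()/repeated_kfold()
for generalization):
  Sn=100.00%  Sp=100.00%  Acc=100.00%  MCC=1.0000
============================================================
Sn=100.00% Sp=100.00% Acc=100.00% MCC=1.0000 [jackknife(profile_scope=fold)]
```

This fixture plants a tryptophan at flank position 5 of every positive
window and bans it from negatives, so a correct pipeline must reach 100%
leave-one-out accuracy — which it does. The same workflow is available from
the shell (`snobpb extract / train / predict / eval`); positions are
1-based and must index a cysteine.

Published benchmark rows can be audited without the original peptide data
by reconstructing their integer confusion matrices from the printed rates
and class sizes:

```
$ snobpb audit-table --sn 67.60 --sp 64.29 --n-pos 784 --n-neg 1568
TP=530 FP=560 TN=1008 FN=254
Sn=67.60% Sp=64.29% Acc=65.39% MCC=0.3014 [audit]
```

i.e. the reported jackknife performance of the ANBPB predictor on its
2352-window training set is exactly self-consistent under the Sn/Sp/Acc/MCC
definitions. `snobpb.benchmarks` ships the published comparison rows and
flags the one row whose printed sensitivity disagrees with its own
confusion matrix.

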