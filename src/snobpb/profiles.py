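"""Position-specific profiles: counts, propensities, BPB and ANBPB posteriors.

The bi-profile Bayes (BPB) family encodes a peptide by per-position
posterior probabilities estimated separately on the positive (modified) and
negative (unmodified) window sets. The adapted normal-distribution variant
(ANBPB) treats each positional count X_ij as a draw from Binomial(n, p) with
p = 1/20, standardizes it against the binomial mean n*p using the observed
spread of the 20 counts at that position, and maps the standardized score
through the standard normal CDF. The relative propensity r_xj (positive
frequency over negative frequency of residue x at position j) is the
exploratory statistic that motivates the encoding: r > 1 means enrichment
around modified cysteines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import ndtr

from .io import AMINO_ACIDS, PAD, PeptideWindow, SnobpbError

#: Residue -> row index (0..19); the pad "X" maps to no row.
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
#: Integer code used for the pad in encoded windows.
PAD_CODE = 20

#: Background probability of any single amino acid under the binomial model.
UNIFORM_P = 1.0 / 20.0


def windows_to_codes(windows: Sequence[PeptideWindow], L: int) -> np.ndarray:
    """Encode windows as an (n, L) int8 matrix of residue codes (X -> 20)."""
    if not windows:
        raise SnobpbError("empty window list")
    codes = np.empty((len(windows), L), dtype=np.int8)
    for k, w in enumerate(windows):
        if len(w.residues) != L:
            raise SnobpbError(
                f"window {k} has length {len(w.residues)}, expected {L}"
            )
        codes[k] = [AA_INDEX.get(ch, PAD_CODE) for ch in w.residues]
    return codes


@dataclass(frozen=True)
class PositionCountMatrix:
    """Counts of each amino acid at each window position.

    ``counts[i, j]`` is the number of windows carrying amino acid i at
    position j; the pad ``X`` contributes to no row, so column sums give
    ``effective_n`` (the number of non-pad residues seen at each position),
    which is <= ``n``, the number of windows.
    """

    counts: np.ndarray  # (20, L) int64
    n: int
    effective_n: np.ndarray  # (L,) int64

    @property
    def L(self) -> int:
        return self.counts.shape[1]


def count_positions(windows: Sequence[PeptideWindow], L: int) -> PositionCountMatrix:
    """Tally residues per position over a window set (pads excluded)."""
    codes = windows_to_codes(windows, L)
    counts = np.zeros((20, L), dtype=np.int64)
    for j in range(L):
        col = np.bincount(codes[:, j], minlength=21)
        counts[:, j] = col[:20]
    return PositionCountMatrix(
        counts=counts, n=len(windows), effective_n=counts.sum(axis=0)
    )


def counts_from_codes(codes: np.ndarray) -> PositionCountMatrix:
    """Like :func:`count_positions` but from a pre-encoded code matrix."""
    n, L = codes.shape
    counts = np.zeros((20, L), dtype=np.int64)
    for j in range(L):
        col = np.bincount(codes[:, j], minlength=21)
        counts[:, j] = col[:20]
    return PositionCountMatrix(counts=counts, n=n, effective_n=counts.sum(axis=0))


@dataclass(frozen=True)
class PropensityMatrix:
    """Relative position-specific propensities r_xj and per-residue averages.

    Undefined entries (zero negative frequency with zero pseudocount) are
    NaN and excluded from the averages, as is the invariant center column.
    """

    r: np.ndarray  # (20, L), NaN where undefined
    averages: np.ndarray  # (20,)
    center: int


def relative_propensity(
    pos_counts: PositionCountMatrix,
    neg_counts: PositionCountMatrix,
    pseudocount: float = 0.0,
) -> PropensityMatrix:
    """r_xj = positive frequency / negative frequency of residue x at j.

    Frequencies use a symmetric additive pseudocount:
    (X_ij + a) / (eff_n_j + 20 a). With a = 0, entries with a zero
    denominator are NaN and excluded from the per-residue averages.
    """
    if pos_counts.L != neg_counts.L:
        raise SnobpbError("count matrices have different window lengths")
    if pseudocount < 0:
        raise SnobpbError("pseudocount must be >= 0")
    a = float(pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        fpos = (pos_counts.counts + a) / (pos_counts.effective_n + 20 * a)
        fneg = (neg_counts.counts + a) / (neg_counts.effective_n + 20 * a)
        r = fpos / fneg
    r = np.where(np.isfinite(r), r, np.nan)
    center = pos_counts.L // 2
    masked = r.copy()
    masked[:, center] = np.nan  # constitutively C; carries no signal
    defined = np.isfinite(masked)
    with np.errstate(invalid="ignore", divide="ignore"):
        averages = np.where(
            defined.any(axis=1),
            np.nansum(masked, axis=1) / defined.sum(axis=1),
            np.nan,
        )
    return PropensityMatrix(r=r, averages=averages, center=center)


def bpb_posterior(counts: PositionCountMatrix) -> np.ndarray:
    """Plain BPB posteriors: per-column relative frequencies.

    Columns with no non-pad residues are all zeros.
    """
    if counts.n < 1:
        raise SnobpbError("need at least one window")
    eff = counts.effective_n.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        post = counts.counts / eff
    post[:, eff == 0] = 0.0
    return post


def normal_cdf(x):
    """Standard normal distribution function Phi(x)."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise SnobpbError("normal_cdf requires finite input")
    return ndtr(x)


def anbpb_posterior(counts: PositionCountMatrix, p: float = UNIFORM_P) -> np.ndarray:
    """Adapted normal-distribution posteriors Phi((X_ij - n p) / V_j).

    V_j is the population standard deviation of the 20 counts at position j;
    a degenerate column (V_j = 0, e.g. a perfectly uniform column) gets the
    neutral value Phi(0) = 0.5 everywhere.
    """
    if counts.n < 2:
        raise SnobpbError("ANBPB standardization needs at least 2 windows")
    X = counts.counts.astype(float)
    V = X.std(axis=0, ddof=0)  # spread of the 20 counts at each position
    mean = counts.n * p
    post = np.full_like(X, 0.5)
    ok = V > 0
    post[:, ok] = ndtr((X[:, ok] - mean) / V[ok])
    return post


@dataclass(frozen=True)
class BiProfile:
    """Paired positive/negative posterior matrices plus their parameters."""

    method: Literal["bpb", "anbpb"]
    pos: np.ndarray  # (20, L)
    neg: np.ndarray  # (20, L)
    n_pos: int
    n_neg: int
    p: float = UNIFORM_P

    @property
    def L(self) -> int:
        return self.pos.shape[1]

    @property
    def neutral(self) -> float:
        """Posterior assigned to the pad 'X': evidence-free lookup value."""
        return 0.5 if self.method == "anbpb" else self.p

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "n_pos": self.n_pos,
                "n_neg": self.n_neg,
                "p": self.p,
                "rows": list(AMINO_ACIDS),
                "columns": list(range(1, self.L + 1)),
                "pos": self.pos.tolist(),
                "neg": self.neg.tolist(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "BiProfile":
        d = json.loads(text)
        return cls(
            method=d["method"],
            pos=np.asarray(d["pos"], dtype=float),
            neg=np.asarray(d["neg"], dtype=float),
            n_pos=int(d["n_pos"]),
            n_neg=int(d["n_neg"]),
            p=float(d["p"]),
        )


def build_biprofile(
    pos_windows: Sequence[PeptideWindow],
    neg_windows: Sequence[PeptideWindow],
    method: Literal["bpb", "anbpb"] = "anbpb",
    L: int = 21,
    p: float = UNIFORM_P,
) -> BiProfile:
    """Build the paired positive/negative profile from labeled window sets."""
    if not pos_windows or not neg_windows:
        raise SnobpbError("both classes must be non-empty to build a bi-profile")
    if method not in ("bpb", "anbpb"):
        raise SnobpbError(f"unknown profile method {method!r}")
    pc = count_positions(pos_windows, L)
    nc = count_positions(neg_windows, L)
    return biprofile_from_counts(pc, nc, method, p)


def biprofile_from_counts(
    pos_counts: PositionCountMatrix,
    neg_counts: PositionCountMatrix,
    method: Literal["bpb", "anbpb"] = "anbpb",
    p: float = UNIFORM_P,
) -> BiProfile:
    if method == "bpb":
        pos, neg = bpb_posterior(pos_counts), bpb_posterior(neg_counts)
    elif method == "anbpb":
        pos, neg = anbpb_posterior(pos_counts, p), anbpb_posterior(neg_counts, p)
    else:
        raise SnobpbError(f"unknown profile method {method!r}")
    return BiProfile(
        method=method, pos=pos, neg=neg,
        n_pos=pos_counts.n, n_neg=neg_counts.n, p=p,
    )
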