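"""The 42-dimensional feature encoding of one cysteine window.

A window of length L = 21 becomes psi_1..psi_42: the positive-profile
posterior of the observed residue at each of the 20 flanking positions
(center excluded — it is constitutively cysteine in both classes and carries
no signal), the same 20 from the negative profile, then two pseudo
amino-acid composition terms: the fraction of residues in the
electrostatic-charge class A and in the alpha-helix-propensity class H. The
complementary classes are linearly dependent on these and are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import PAD, PeptideWindow, SnobpbError
from .profiles import AA_INDEX, PAD_CODE, BiProfile, windows_to_codes

#: Electrostatic-charge class "A" (the remaining 9 residues form its complement).
CLASS_A = frozenset("ACDEHLPQSVW")
#: Alpha-helix-propensity class "H" (complement: the other 11 residues).
CLASS_H = frozenset("CDGNPSTWY")


@dataclass(frozen=True)
class FeatureLayout:
    """Records how a feature vector was laid out, for safe model reuse."""

    method: str
    L: int
    flanks: tuple[int, ...]  # 0-based window positions used per profile

    @property
    def n_features(self) -> int:
        return 2 * len(self.flanks) + 2

    def to_dict(self) -> dict:
        return {"method": self.method, "L": self.L, "flanks": list(self.flanks)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureLayout":
        return cls(method=d["method"], L=int(d["L"]), flanks=tuple(d["flanks"]))

    @classmethod
    def default(cls, method: str, L: int) -> "FeatureLayout":
        center = L // 2
        flanks = tuple(j for j in range(L) if j != center)
        return cls(method=method, L=L, flanks=flanks)


def composition_features(window: PeptideWindow) -> tuple[float, float]:
    """(fA, fH): class-A and class-H fractions among non-pad residues."""
    residues = [ch for ch in window.residues if ch != PAD]
    if not residues:
        raise SnobpbError("all-pad window: composition undefined")
    n = len(residues)
    fA = sum(ch in CLASS_A for ch in residues) / n
    fH = sum(ch in CLASS_H for ch in residues) / n
    return fA, fH


def encode_window(window: PeptideWindow, profile: BiProfile) -> np.ndarray:
    """Encode one window against a bi-profile as the psi_1..psi_42 vector."""
    if len(window.residues) != profile.L:
        raise SnobpbError(
            f"window length {len(window.residues)} does not match "
            f"profile length {profile.L}"
        )
    layout = FeatureLayout.default(profile.method, profile.L)
    vec = np.empty(layout.n_features)
    k = 0
    for matrix in (profile.pos, profile.neg):
        for j in layout.flanks:
            ch = window.residues[j]
            vec[k] = profile.neutral if ch == PAD else matrix[AA_INDEX[ch], j]
            k += 1
    vec[k], vec[k + 1] = composition_features(window)
    return vec


def encode_dataset(
    windows: Sequence[PeptideWindow], profile: BiProfile
) -> tuple[np.ndarray, np.ndarray]:
    """Encode windows into an (n, 42) feature matrix and a +/-1 label vector."""
    layout = FeatureLayout.default(profile.method, profile.L)
    if not windows:
        return np.empty((0, layout.n_features)), np.empty((0,), dtype=int)
    codes = windows_to_codes(windows, profile.L)
    labels = np.array([w.label for w in windows], dtype=int)
    X = encode_codes(codes, profile)
    # composition features need the original residues (pad-aware denominators)
    for k, w in enumerate(windows):
        try:
            X[k, -2], X[k, -1] = composition_features(w)
        except SnobpbError as exc:
            raise SnobpbError(f"window {k}: {exc}") from exc
    return X, labels


def encode_codes(codes: np.ndarray, profile: BiProfile) -> np.ndarray:
    """Vectorized profile lookup for pre-encoded windows (codes 0..19, 20=pad).

    Composition columns are computed from the codes as well; callers holding
    the original windows may overwrite them (identical values).
    """
    layout = FeatureLayout.default(profile.method, profile.L)
    n = codes.shape[0]
    flanks = np.asarray(layout.flanks)
    X = np.empty((n, layout.n_features))
    for half, matrix in enumerate((profile.pos, profile.neg)):
        # append a neutral row so PAD_CODE indexes cleanly
        lut = np.vstack([matrix, np.full(profile.L, profile.neutral)])
        X[:, half * len(flanks) : (half + 1) * len(flanks)] = lut[
            codes[:, flanks], flanks
        ]
    in_a = np.array([aa in CLASS_A for aa in "ACDEFGHIKLMNPQRSTVWY"] + [False])
    in_h = np.array([aa in CLASS_H for aa in "ACDEFGHIKLMNPQRSTVWY"] + [False])
    non_pad = (codes != PAD_CODE).sum(axis=1)
    if np.any(non_pad == 0):
        raise SnobpbError("all-pad window: composition undefined")
    X[:, -2] = in_a[codes].sum(axis=1) / non_pad
    X[:, -1] = in_h[codes].sum(axis=1) / non_pad
    return X
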