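"""Performance assessment: Sn/Sp/Acc/MCC, table audits, and CV protocols.

Metrics are computed in exact rational arithmetic from integer confusion
counts and rounded half-up to the conventional display precision
(percentages to 2 d.p., MCC to 4 d.p.). The inverse direction —
reconstructing integer confusion matrices from printed rates and class
sizes — makes published benchmark rows auditable: a row is self-consistent
iff the metrics recomputed from its reconstructed counts reproduce the
printed values at printed precision.

Two cross-validation protocols are provided. The jackknife (leave-one-out)
can rebuild the bi-profile for every fold (``profile_scope="fold"``, the
default, leakage-free) or build it once on all data
(``profile_scope="global"``, a deliberately leaky mode kept as a diagnostic
for how much optimism profile leakage buys). Repeated stratified k-fold
pools fold counts per repeat and reports the across-repeat mean and sd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Optional, Sequence

import numpy as np

from .classifier import ModelConfig, train
from .features import composition_features, encode_codes
from .io import PeptideWindow, SnobpbError
from .profiles import (
    PAD_CODE,
    PositionCountMatrix,
    biprofile_from_counts,
    counts_from_codes,
    windows_to_codes,
)


def round_half_up(x: Fraction | float, digits: int) -> float:
    """Round to ``digits`` decimals with ties going away from zero-ward up.

    Exact for Fraction input; floats are converted via their repr so that
    printed values like 74.42 behave as written.
    """
    fr = x if isinstance(x, Fraction) else Fraction(repr(float(x)))
    scale = Fraction(10) ** digits
    sign = 1 if fr >= 0 else -1
    return float(sign * math.floor(abs(fr) * scale + Fraction(1, 2)) / scale)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise SnobpbError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class MetricsReport:
    """Sn/Sp/Acc as percentages (2 d.p.), MCC (4 d.p.), plus raw counts."""

    sn: float
    sp: float
    acc: float
    mcc: float
    counts: ConfusionCounts
    protocol: str = "counts"

    def as_dict(self) -> dict:
        return {
            "Sn": self.sn, "Sp": self.sp, "Acc": self.acc, "MCC": self.mcc,
            "TP": self.counts.tp, "FP": self.counts.fp,
            "TN": self.counts.tn, "FN": self.counts.fn,
            "protocol": self.protocol,
        }

    def __str__(self) -> str:
        return (
            f"Sn={self.sn:.2f}% Sp={self.sp:.2f}% Acc={self.acc:.2f}% "
            f"MCC={self.mcc:.4f} [{self.protocol}]"
        )


def metrics_from_counts(counts: ConfusionCounts, protocol: str = "counts") -> MetricsReport:
    """Sn/Sp/Acc/MCC from a confusion matrix, exactly then rounded half-up.

    Any zero factor in the MCC denominator makes MCC 0 by convention.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise SnobpbError("empty confusion matrix")
    sn = round_half_up(Fraction(100 * tp, tp + fn), 2) if tp + fn else 0.0
    sp = round_half_up(Fraction(100 * tn, tn + fp), 2) if tn + fp else 0.0
    acc = round_half_up(Fraction(100 * (tp + tn), counts.total), 2)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        mcc = 0.0
    else:
        mcc = round_half_up((tp * tn - fp * fn) / math.sqrt(den), 4)
    return MetricsReport(sn=sn, sp=sp, acc=acc, mcc=mcc, counts=counts, protocol=protocol)


def counts_from_rates(
    sp: float,
    n_pos: int,
    n_neg: int,
    sn: Optional[float] = None,
    acc: Optional[float] = None,
) -> ConfusionCounts:
    """Reconstruct integer confusion counts from printed rates.

    Requires Sp plus either Sn or Acc (all in percent). Cells are obtained
    by half-up rounding of rate * size / 100; remaining cells by complement.
    Inconsistent inputs (a cell negative or exceeding its class size) raise.
    """
    if n_pos < 1 or n_neg < 1:
        raise SnobpbError("class sizes must be >= 1")
    for name, rate in (("Sn", sn), ("Sp", sp), ("Acc", acc)):
        if rate is not None and not 0 <= rate <= 100:
            raise SnobpbError(f"{name}={rate} out of [0, 100]")
    if (sn is None) == (acc is None):
        raise SnobpbError("provide exactly one of Sn or Acc alongside Sp")
    tn = int(round_half_up(Fraction(repr(float(sp))) * n_neg / 100, 0))
    if sn is not None:
        tp = int(round_half_up(Fraction(repr(float(sn))) * n_pos / 100, 0))
    else:
        total_correct = int(
            round_half_up(Fraction(repr(float(acc))) * (n_pos + n_neg) / 100, 0)
        )
        tp = total_correct - tn
    cells = {"TP": (tp, n_pos), "TN": (tn, n_neg)}
    for name, (value, bound) in cells.items():
        if not 0 <= value <= bound:
            raise SnobpbError(
                f"reconstructed {name}={value} outside [0, {bound}]: "
                "printed rates inconsistent with class sizes"
            )
    return ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


@dataclass(frozen=True)
class AuditResult:
    """Outcome of auditing one printed benchmark row."""

    counts: ConfusionCounts
    recomputed: MetricsReport
    printed: dict
    inconsistencies: tuple[str, ...]

    @property
    def consistent(self) -> bool:
        return not self.inconsistencies


def audit_printed_row(
    sn: float, sp: float, acc: float, mcc: float, n_pos: int, n_neg: int
) -> AuditResult:
    """Reconstruct counts from printed (Sn, Sp) and recompute all metrics.

    Every printed value is compared against the recomputed one at its
    printed precision; mismatches are reported, not resolved.
    """
    counts = counts_from_rates(sp=sp, sn=sn, n_pos=n_pos, n_neg=n_neg)
    rec = metrics_from_counts(counts, protocol="audit")
    printed = {"Sn": sn, "Sp": sp, "Acc": acc, "MCC": mcc}
    bad = tuple(
        f"{k}: printed {printed[k]} but counts imply {got}"
        for k, got in (("Sn", rec.sn), ("Sp", rec.sp), ("Acc", rec.acc), ("MCC", rec.mcc))
        if not math.isclose(printed[k], got, abs_tol=1e-9)
    )
    return AuditResult(counts=counts, recomputed=rec, printed=printed, inconsistencies=bad)


# ---------------------------------------------------------------------------
# Cross-validation protocols
# ---------------------------------------------------------------------------

ProfileScope = Literal["fold", "global"]


def _counts_minus_rows(
    counts: PositionCountMatrix, codes_rows: np.ndarray
) -> PositionCountMatrix:
    """Subtract one or more encoded windows from a count matrix."""
    c = counts.counts.copy()
    rows = np.atleast_2d(codes_rows)
    L = counts.L
    for row in rows:
        for j in range(L):
            if row[j] != PAD_CODE:
                c[row[j], j] -= 1
    return PositionCountMatrix(
        counts=c, n=counts.n - rows.shape[0], effective_n=c.sum(axis=0)
    )


def _tally(true: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(np.sum((true == 1) & (pred == 1))),
        fp=int(np.sum((true == -1) & (pred == 1))),
        tn=int(np.sum((true == -1) & (pred == -1))),
        fn=int(np.sum((true == 1) & (pred == -1))),
    )


def _encode_all(codes, windows, profile):
    X = encode_codes(codes, profile)
    for k, w in enumerate(windows):
        X[k, -2], X[k, -1] = composition_features(w)
    return X


def jackknife(
    windows: Sequence[PeptideWindow],
    method: Literal["bpb", "anbpb"] = "anbpb",
    config: ModelConfig = ModelConfig(),
    profile_scope: ProfileScope = "fold",
) -> MetricsReport:
    """Leave-one-out evaluation of the full encode+train pipeline.

    With ``profile_scope="fold"`` the bi-profile is rebuilt without the
    held-out window on every fold (no information leakage); with
    ``"global"`` it is built once on all windows, which leaks the held-out
    window's residues into its own encoding and is provided only as a
    diagnostic for that optimism.
    """
    labels = np.array([w.label for w in windows], dtype=int)
    L = len(windows[0].residues) if windows else 0
    if np.sum(labels == 1) < 2 or np.sum(labels == -1) < 2:
        raise SnobpbError(
            "jackknife needs >= 2 windows per class: some fold would lose "
            "an entire class"
        )
    codes = windows_to_codes(windows, L)
    pos_counts = counts_from_codes(codes[labels == 1])
    neg_counts = counts_from_codes(codes[labels == -1])
    n = len(windows)
    predictions = np.empty(n, dtype=int)
    if profile_scope == "global":
        profile = biprofile_from_counts(pos_counts, neg_counts, method)
        X = _encode_all(codes, windows, profile)
        for i in range(n):
            keep = np.arange(n) != i
            model = train(X[keep], labels[keep], config)
            predictions[i] = model.predict(X[i : i + 1])[0][0]
    elif profile_scope == "fold":
        for i in range(n):
            if labels[i] == 1:
                pc = _counts_minus_rows(pos_counts, codes[i])
                nc = neg_counts
            else:
                pc = pos_counts
                nc = _counts_minus_rows(neg_counts, codes[i])
            profile = biprofile_from_counts(pc, nc, method)
            X = _encode_all(codes, windows, profile)
            keep = np.arange(n) != i
            model = train(X[keep], labels[keep], config)
            predictions[i] = model.predict(X[i : i + 1])[0][0]
    else:
        raise SnobpbError(f"unknown profile_scope {profile_scope!r}")
    return metrics_from_counts(
        _tally(labels, predictions),
        protocol=f"jackknife(profile_scope={profile_scope})",
    )


@dataclass(frozen=True)
class RepeatedKFoldReport:
    """Across-repeat mean and sd of each metric, plus per-repeat reports."""

    mean: dict
    sd: dict
    repeats: tuple[MetricsReport, ...]
    protocol: str

    def __str__(self) -> str:
        m, s = self.mean, self.sd
        return (
            f"Sn={m['Sn']:.2f}±{s['Sn']:.2f}% Sp={m['Sp']:.2f}±{s['Sp']:.2f}% "
            f"Acc={m['Acc']:.2f}±{s['Acc']:.2f}% MCC={m['MCC']:.4f}±{s['MCC']:.4f} "
            f"[{self.protocol}]"
        )


def repeated_kfold(
    windows: Sequence[PeptideWindow],
    k: int = 10,
    repeats: int = 50,
    seed: int = 0,
    method: Literal["bpb", "anbpb"] = "anbpb",
    config: ModelConfig = ModelConfig(),
    profile_scope: ProfileScope = "fold",
) -> RepeatedKFoldReport:
    """Repeated stratified k-fold CV with a fresh shuffle per repeat.

    Per-repeat metrics are computed from the confusion counts pooled over
    the k folds; the report carries their across-repeat mean and sd.
    """
    from sklearn.model_selection import StratifiedKFold

    labels = np.array([w.label for w in windows], dtype=int)
    n = len(windows)
    n_min = min(np.sum(labels == 1), np.sum(labels == -1))
    if k < 2 or (k > n_min and k != n):
        raise SnobpbError(f"k={k} incompatible with minority class size {n_min}")
    L = len(windows[0].residues)
    codes = windows_to_codes(windows, L)
    rng = np.random.default_rng(seed)
    per_repeat: list[MetricsReport] = []
    for rep in range(repeats):
        if k == n:  # leave-one-out: stratification is moot, order immaterial
            splits = [
                (np.delete(np.arange(n), i), np.array([i])) for i in range(n)
            ]
        else:
            skf = StratifiedKFold(
                n_splits=k, shuffle=True, random_state=int(rng.integers(2**31))
            )
            splits = list(skf.split(codes, labels))
        true_all: list[np.ndarray] = []
        pred_all: list[np.ndarray] = []
        for tr, te in splits:
            if profile_scope == "fold":
                pc = counts_from_codes(codes[tr][labels[tr] == 1])
                nc = counts_from_codes(codes[tr][labels[tr] == -1])
            else:
                pc = counts_from_codes(codes[labels == 1])
                nc = counts_from_codes(codes[labels == -1])
            profile = biprofile_from_counts(pc, nc, method)
            X = _encode_all(codes, windows, profile)
            model = train(X[tr], labels[tr], config)
            pred, _ = model.predict(X[te])
            true_all.append(labels[te])
            pred_all.append(pred)
        counts = _tally(np.concatenate(true_all), np.concatenate(pred_all))
        per_repeat.append(
            metrics_from_counts(counts, protocol=f"kfold(k={k}, repeat={rep})")
        )
    keys = ("Sn", "Sp", "Acc", "MCC")
    values = {key: np.array([r.as_dict()[key] for r in per_repeat]) for key in keys}
    return RepeatedKFoldReport(
        mean={key: float(values[key].mean()) for key in keys},
        sd={key: float(values[key].std(ddof=1)) if repeats > 1 else 0.0 for key in keys},
        repeats=tuple(per_repeat),
        protocol=f"kfold(k={k}, repeats={repeats}, seed={seed}, "
        f"profile_scope={profile_scope})",
    )
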