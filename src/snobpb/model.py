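"""High-level modelling interface: build from data, fit, inspect, evaluate.

:class:`SnoSiteModel` bundles the whole pipeline — bi-profile construction,
42-feature encoding, class-weighted RBF-SVM training — behind a
fit()/Results pair. ``fit()`` returns a :class:`SnoSiteResults` carrying the
fitted profile and decision function, resubstitution diagnostics and a
``summary()`` table; honest generalization estimates come from
``results.jackknife()`` / ``results.repeated_kfold()`` (equivalently the
functions in :mod:`snobpb.evaluation`), which refit per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from . import evaluation
from .classifier import ModelConfig, TrainedModel, train
from .features import FeatureLayout, encode_dataset
from .io import PeptideWindow, SnobpbError, extract_dataset, read_fasta, read_site_table
from .profiles import BiProfile, build_biprofile


class SnoSiteModel:
    """An S-nitrosylation site predictor specification bound to data.

    Parameters
    ----------
    windows
        Labeled cysteine-centered peptide windows (both classes present).
    method
        Profile encoding: ``"anbpb"`` (default) or plain ``"bpb"``.
    config
        SVM hyper-parameters; defaults are the published operating point
        (C = 22.6274, gamma = 0.03125, W_pos = 2, W_neg = 1).
    """

    def __init__(
        self,
        windows: Sequence[PeptideWindow],
        method: Literal["bpb", "anbpb"] = "anbpb",
        config: ModelConfig = ModelConfig(),
    ):
        if not windows:
            raise SnobpbError("no windows supplied")
        lengths = {len(w.residues) for w in windows}
        if len(lengths) != 1:
            raise SnobpbError(f"mixed window lengths {sorted(lengths)}")
        self.windows = list(windows)
        self.L = lengths.pop()
        self.method = method
        self.config = config

    @classmethod
    def from_files(
        cls,
        fasta_path,
        sites_path,
        L: int = 21,
        method: Literal["bpb", "anbpb"] = "anbpb",
        config: ModelConfig = ModelConfig(),
    ) -> "SnoSiteModel":
        proteins = read_fasta(fasta_path)
        annotations = read_site_table(sites_path)
        return cls(extract_dataset(proteins, annotations, L), method, config)

    def fit(self) -> "SnoSiteResults":
        pos = [w for w in self.windows if w.label == 1]
        neg = [w for w in self.windows if w.label == -1]
        profile = build_biprofile(pos, neg, self.method, self.L)
        X, y = encode_dataset(self.windows, profile)
        layout = FeatureLayout.default(self.method, self.L)
        trained = train(X, y, self.config, layout=layout, biprofile=profile)
        labels, scores = trained.predict(X)
        resub = evaluation.metrics_from_counts(
            evaluation._tally(y, labels), protocol="resubstitution"
        )
        return SnoSiteResults(
            model=self, trained=trained, profile=profile,
            resubstitution=resub, n_support=len(trained.dual_coef),
        )


@dataclass
class SnoSiteResults:
    """Fitted predictor: decision function, profile and diagnostics."""

    model: SnoSiteModel
    trained: TrainedModel
    profile: BiProfile
    resubstitution: evaluation.MetricsReport
    n_support: int

    def predict_windows(
        self, windows: Sequence[PeptideWindow]
    ) -> tuple[np.ndarray, np.ndarray]:
        """(labels, decision values) for new windows, encoded against the
        training bi-profile."""
        X, _ = encode_dataset(windows, self.profile)
        return self.trained.predict(X)

    def jackknife(self, profile_scope: str = "fold") -> evaluation.MetricsReport:
        return evaluation.jackknife(
            self.model.windows, self.model.method, self.model.config,
            profile_scope=profile_scope,
        )

    def repeated_kfold(
        self, k: int = 10, repeats: int = 50, seed: int = 0
    ) -> evaluation.RepeatedKFoldReport:
        return evaluation.repeated_kfold(
            self.model.windows, k=k, repeats=repeats, seed=seed,
            method=self.model.method, config=self.model.config,
        )

    def save(self, path) -> None:
        self.trained.save(path)

    def summary(self) -> str:
        cfg = self.model.config
        n_pos = self.profile.n_pos
        n_neg = self.profile.n_neg
        r = self.resubstitution
        lines = [
            "S-nitrosylation site predictor (bi-profile Bayes + RBF SVM)",
            "=" * 60,
            f"encoding:            {self.model.method}  (L={self.model.L}, "
            f"{2 * (self.model.L - 1) + 2} features)",
            f"windows:             {n_pos} positive / {n_neg} negative",
            f"C, gamma:            {cfg.C}, {cfg.gamma}",
            f"class weights:       W+1={cfg.W_pos}, W-1={cfg.W_neg}",
            f"support vectors:     {self.n_support}",
            "-" * 60,
            "resubstitution fit (optimistic; use jackknife()/repeated_kfold()",
            "for generalization):",
            f"  Sn={r.sn:.2f}%  Sp={r.sp:.2f}%  Acc={r.acc:.2f}%  MCC={r.mcc:.4f}",
            "=" * 60,
        ]
        return "\n".join(lines)
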