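"""Synthetic labeled window datasets with planted positional enrichments.

The generator emulates the statistical structure the profile machinery is
built to detect: residues drawn i.i.d. per position from a background
distribution, with the positive class enriched for chosen residues at
chosen flank positions. An enrichment of ratio ``rho`` for residue R at
position q sets P(R at q | positive) = rho * background(R), rescaling the
other 19 residues to the leftover mass, so the planted value of the
relative propensity r_{R,q} is exactly ``rho``. ``rho = inf`` plants R
deterministically, and an ``exclusive`` motif additionally bans R at q in
the negative class — together they yield a perfectly separable dataset.

Everything is reproducible from the spec's seed. The canonical fixture
seed used across the test fixtures is 20140610.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io import (
    AMINO_ACIDS,
    PAD,
    PeptideWindow,
    SiteAnnotation,
    SnobpbError,
    write_windows_tsv,
)

#: Canonical seed used for the shipped fixture suite.
FIXTURE_SEED = 20140610

#: SwissProt-like background frequencies (order ACDEFGHIKLMNPQRSTVWY),
#: an alternative to the uniform default for less idealized data.
SWISSPROT_BACKGROUND = np.array([
    0.0826, 0.0138, 0.0546, 0.0672, 0.0386, 0.0708, 0.0227, 0.0591, 0.0580,
    0.0965, 0.0241, 0.0406, 0.0475, 0.0393, 0.0553, 0.0665, 0.0536, 0.0686,
    0.0110, 0.0292,
])
SWISSPROT_BACKGROUND = SWISSPROT_BACKGROUND / SWISSPROT_BACKGROUND.sum()


@dataclass(frozen=True)
class Motif:
    """One planted enrichment: residue ``residue`` at 1-based window
    ``position`` is ``rho`` times more frequent in positives than the
    background; ``exclusive`` bans it from negatives at that position."""

    position: int
    residue: str
    rho: float
    exclusive: bool = False


@dataclass(frozen=True)
class SyntheticSpec:
    n_pos: int
    n_neg: int
    L: int = 21
    background: Optional[np.ndarray] = None  # (20,), default uniform
    motif: tuple[Motif, ...] = ()
    pad_fraction: float = 0.0
    seed: int = FIXTURE_SEED

    def validate(self) -> np.ndarray:
        """Check the spec and return the background vector."""
        if self.n_pos < 1 or self.n_neg < 1:
            raise SnobpbError("class sizes must be >= 1")
        if self.L % 2 == 0 or self.L < 3:
            raise SnobpbError("L must be an odd integer >= 3")
        if not 0 <= self.pad_fraction <= 1:
            raise SnobpbError("pad_fraction must be in [0, 1]")
        bg = (
            np.full(20, 1 / 20)
            if self.background is None
            else np.asarray(self.background, dtype=float)
        )
        if bg.shape != (20,) or np.any(bg < 0) or not math.isclose(bg.sum(), 1.0):
            raise SnobpbError("background must be a length-20 probability vector")
        center = self.L // 2 + 1
        for m in self.motif:
            if m.residue not in AMINO_ACIDS:
                raise SnobpbError(f"unknown motif residue {m.residue!r}")
            if not 1 <= m.position <= self.L or m.position == center:
                raise SnobpbError(
                    f"motif position {m.position} invalid (center {center} "
                    "is constitutively C)"
                )
            if not m.rho > 0:
                raise SnobpbError("motif rho must be > 0")
            i = AMINO_ACIDS.index(m.residue)
            if math.isfinite(m.rho) and m.rho * bg[i] > 1:
                raise SnobpbError(
                    f"rho={m.rho} puts probability > 1 on {m.residue} "
                    f"at position {m.position}"
                )
        return bg


def _enriched(bg: np.ndarray, residue: str, rho: float) -> np.ndarray:
    """Positive-class distribution at a motif position (ratio exactly rho)."""
    i = AMINO_ACIDS.index(residue)
    out = np.empty_like(bg)
    if math.isinf(rho):
        out[:] = 0.0
        out[i] = 1.0
        return out
    target = rho * bg[i]
    out[:] = bg * (1 - target) / (1 - bg[i])
    out[i] = target
    return out


def _excluded(bg: np.ndarray, residue: str) -> np.ndarray:
    """Negative-class distribution with ``residue`` banned."""
    i = AMINO_ACIDS.index(residue)
    out = bg.copy()
    out[i] = 0.0
    return out / out.sum()


def generate_dataset(spec: SyntheticSpec) -> list[PeptideWindow]:
    """Draw the labeled window set described by ``spec`` (positives first)."""
    bg = spec.validate()
    rng = np.random.default_rng(spec.seed)
    center = spec.L // 2
    aa = np.array(list(AMINO_ACIDS))

    def draw(n: int, dists: dict[int, np.ndarray], label: int, offset: int):
        cols = []
        for j in range(spec.L):
            if j == center:
                cols.append(np.full(n, "C"))
            else:
                pj = dists.get(j, bg)
                cols.append(rng.choice(aa, size=n, p=pj))
        grid = np.stack(cols, axis=1)
        if spec.pad_fraction > 0:
            flank = (spec.L - 1) // 2
            padded = rng.random(n) < spec.pad_fraction
            sides = rng.integers(0, 2, size=n)
            lengths = rng.integers(1, flank + 1, size=n)
            for k in np.nonzero(padded)[0]:
                if sides[k] == 0:
                    grid[k, : lengths[k]] = PAD
                else:
                    grid[k, spec.L - lengths[k] :] = PAD
        return [
            PeptideWindow(
                "".join(grid[k]), label, origin=(f"syn{label:+d}_{offset + k}", 0)
            )
            for k in range(n)
        ]

    pos_dists = {
        m.position - 1: _enriched(bg, m.residue, m.rho) for m in spec.motif
    }
    neg_dists = {
        m.position - 1: _excluded(bg, m.residue)
        for m in spec.motif
        if m.exclusive
    }
    windows = draw(spec.n_pos, pos_dists, 1, 0)
    windows += draw(spec.n_neg, neg_dists, -1, spec.n_pos)
    return windows


def shuffle_labels(
    windows: Sequence[PeptideWindow], seed: int
) -> list[PeptideWindow]:
    """Randomly permute labels across windows (a permutation-null dataset)."""
    rng = np.random.default_rng(seed)
    labels = np.array([w.label for w in windows])
    rng.shuffle(labels)
    return [replace(w, label=int(lab)) for w, lab in zip(windows, labels)]


# ---------------------------------------------------------------------------
# Canonical fixture suite
# ---------------------------------------------------------------------------

def canonical_specs(seed: int = FIXTURE_SEED) -> dict[str, SyntheticSpec]:
    """The four canonical fixture datasets used across the test suite."""
    return {
        "null": SyntheticSpec(n_pos=200, n_neg=200, seed=seed),
        "weak_motif": SyntheticSpec(
            n_pos=2000, n_neg=2000,
            motif=(Motif(position=3, residue="K", rho=3.0),), seed=seed + 1,
        ),
        "separable": SyntheticSpec(
            n_pos=150, n_neg=150,
            motif=(Motif(position=5, residue="W", rho=math.inf, exclusive=True),),
            seed=seed + 2,
        ),
        "padded": SyntheticSpec(
            n_pos=150, n_neg=150, pad_fraction=0.3, seed=seed + 3,
        ),
    }


def _window_to_protein(w: PeptideWindow, idx: int):
    """Embed a window in a synthetic protein record (pads stripped)."""
    core = w.residues.strip(PAD)
    left_pad = len(w.residues) - len(w.residues.lstrip(PAD))
    center = len(w.residues) // 2
    pid = f"synprot{idx}"
    return pid, core, center - left_pad + 1  # 1-based site position in core


def make_fixture_suite(out_dir, seed: int = FIXTURE_SEED) -> dict:
    """Write the canonical fixtures as window TSV + FASTA + site TSV triples.

    Returns (and writes as ``manifest.json``) the seeds and summary
    statistics of each fixture; reruns are byte-identical.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"seed": seed, "fixtures": {}}
    for name, spec in canonical_specs(seed).items():
        windows = generate_dataset(spec)
        win_path = os.path.join(out_dir, f"{name}.windows.tsv")
        write_windows_tsv(windows, win_path)
        fasta_path = os.path.join(out_dir, f"{name}.fasta")
        sites_path = os.path.join(out_dir, f"{name}.sites.tsv")
        with open(fasta_path, "w") as fa, open(sites_path, "w") as st:
            st.write("protein_id\tposition\tlabel\n")
            for k, w in enumerate(windows):
                pid, core, site = _window_to_protein(w, k)
                fa.write(f">{pid}\n{core}\n")
                st.write(f"{pid}\t{site}\t{w.label}\n")
        with open(win_path, "rb") as fh:
            digest = hashlib.sha256(fh.read()).hexdigest()
        manifest["fixtures"][name] = {
            "seed": spec.seed,
            "n_pos": spec.n_pos,
            "n_neg": spec.n_neg,
            "L": spec.L,
            "pad_fraction": spec.pad_fraction,
            "motif": [
                {"position": m.position, "residue": m.residue,
                 "rho": "inf" if math.isinf(m.rho) else m.rho,
                 "exclusive": m.exclusive}
                for m in spec.motif
            ],
            "n_windows": len(windows),
            "windows_sha256": digest,
        }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
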