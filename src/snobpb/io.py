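"""Sequence input/output and cysteine-window extraction.

Proteins come in as FASTA, candidate sites as a TSV of
``(protein_id, position, label)`` rows with 1-based positions, and the unit
of analysis everywhere downstream is the :class:`PeptideWindow`: a
fixed-length (default 21) peptide centered on a cysteine, padded with ``X``
where the window runs off a protein terminus.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Padding character used at protein termini.
PAD = "X"
#: Full residue alphabet accepted in windows.
ALPHABET = frozenset(AMINO_ACIDS) | {PAD}

#: Default tokens accepted in the label column of a site table.
DEFAULT_LABEL_ALIASES: Mapping[str, int] = {
    "1": 1, "+1": 1, "pos": 1, "positive": 1,
    "-1": -1, "neg": -1, "negative": -1,
}

WINDOW_TSV_COLUMNS = ("residues", "label", "protein_id", "position")


class SnobpbError(Exception):
    """Base class for data/usage errors raised by this package."""


class ParseError(SnobpbError):
    """A file could not be parsed."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SnobpbError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise SnobpbError(
                f"protein {self.id!r}: letters outside the amino-acid "
                f"alphabet: {sorted(bad)}"
            )


@dataclass(frozen=True)
class SiteAnnotation:
    """A candidate S-nitrosylation site: 1-based cysteine position + label."""

    protein_id: str
    position: int
    label: int

    def __post_init__(self) -> None:
        if self.label not in (1, -1):
            raise SnobpbError(f"label must be +1 or -1, got {self.label!r}")
        if self.position < 1:
            raise SnobpbError(
                f"site positions are 1-based; got {self.position} "
                f"for protein {self.protein_id!r}"
            )


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length peptide centered on a candidate cysteine.

    ``residues`` is a string of odd length over the 21-letter alphabet
    (20 amino acids plus the terminal pad ``X``); ``X`` may occur only as a
    contiguous prefix and/or suffix. ``origin`` optionally records the
    (protein_id, position) the window was cut from.
    """

    residues: str
    label: int
    origin: Optional[tuple[str, int]] = None

    def __post_init__(self) -> None:
        L = len(self.residues)
        if L % 2 == 0 or L == 0:
            raise SnobpbError(f"window length must be odd, got {L}")
        if self.label not in (1, -1):
            raise SnobpbError(f"label must be +1 or -1, got {self.label!r}")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise SnobpbError(f"window contains invalid letters: {sorted(bad)}")
        core = self.residues.strip(PAD)
        if PAD in core:
            raise SnobpbError(
                "pad 'X' must form a contiguous prefix/suffix, got "
                f"{self.residues!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def center(self) -> str:
        return self.residues[len(self.residues) // 2]


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and whitespace-stripped. Letters outside the
    20-amino-acid + ``X`` alphabet, duplicate ids and content before the
    first header line are all hard errors.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header '>', "
                    f"got {line.strip()!r}"
                )
            break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ParseError(f"{path}: duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper().replace(" ", "").replace("\t", "")
        try:
            records.append(ProteinRecord(id=entry.id, sequence=seq))
        except SnobpbError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return records


def read_site_table(
    path,
    label_aliases: Mapping[str, int] = DEFAULT_LABEL_ALIASES,
) -> list[SiteAnnotation]:
    """Read a site-annotation TSV with columns protein_id, position, label.

    A header row equal to the column names is permitted and skipped.
    ``label_aliases`` maps label tokens (case-insensitive) to +1/-1.
    """
    annotations: list[SiteAnnotation] = []
    with open(path, newline="") as handle:
        for rowno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if rowno == 1 and [c.strip().lower() for c in row[:3]] == [
                "protein_id", "position", "label",
            ]:
                continue
            if len(row) < 3:
                raise ParseError(f"{path}: row {rowno}: expected 3 columns")
            pid, pos_token, label_token = (c.strip() for c in row[:3])
            try:
                position = int(pos_token)
            except ValueError:
                raise ParseError(
                    f"{path}: row {rowno}: non-integer position {pos_token!r}"
                ) from None
            key = label_token.lower()
            if key not in label_aliases:
                raise ParseError(
                    f"{path}: row {rowno}: unknown label token {label_token!r}"
                )
            try:
                annotations.append(
                    SiteAnnotation(pid, position, label_aliases[key])
                )
            except SnobpbError as exc:
                raise ParseError(f"{path}: row {rowno}: {exc}") from exc
    return annotations


def extract_window(
    protein: ProteinRecord,
    position: int,
    L: int = 21,
    *,
    allow_any_center: bool = False,
) -> str:
    """Cut the length-``L`` peptide centered on ``position`` (1-based).

    Positions falling before the first or after the last residue are filled
    with ``X``. The central residue must be a cysteine unless
    ``allow_any_center`` is set.
    """
    if L % 2 == 0 or L < 1:
        raise SnobpbError(f"window length must be a positive odd integer, got {L}")
    n = len(protein.sequence)
    if not 1 <= position <= n:
        raise SnobpbError(
            f"position {position} outside protein {protein.id!r} (length {n})"
        )
    center = protein.sequence[position - 1]
    if center != "C" and not allow_any_center:
        raise SnobpbError(
            f"protein {protein.id!r} position {position}: central residue is "
            f"{center!r}, not 'C' (use allow_any_center to override)"
        )
    flank = (L - 1) // 2
    lo = position - 1 - flank
    hi = position - 1 + flank
    left_pad = max(0, -lo)
    right_pad = max(0, hi - (n - 1))
    return (
        PAD * left_pad
        + protein.sequence[max(lo, 0) : min(hi, n - 1) + 1]
        + PAD * right_pad
    )


def extract_dataset(
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    L: int = 21,
    *,
    allow_any_center: bool = False,
) -> list[PeptideWindow]:
    """One window per annotation, labels and input order preserved."""
    by_id = {p.id: p for p in proteins}
    if len(by_id) != len(proteins):
        raise SnobpbError("duplicate protein ids in input")
    windows: list[PeptideWindow] = []
    for ann in annotations:
        protein = by_id.get(ann.protein_id)
        if protein is None:
            raise SnobpbError(f"annotation references unknown protein {ann.protein_id!r}")
        residues = extract_window(
            protein, ann.position, L, allow_any_center=allow_any_center
        )
        windows.append(
            PeptideWindow(residues, ann.label, origin=(ann.protein_id, ann.position))
        )
    return windows


def dedup_exact(windows: Iterable[PeptideWindow]) -> list[PeptideWindow]:
    """Drop exact duplicates, keeping the first of each (residues, label) pair.

    Identical residues carrying opposite labels both survive (with a logged
    warning): resolving such conflicts is the caller's call. The number of
    removals is logged.
    """
    seen: set[tuple[str, int]] = set()
    sequences_by_label: dict[str, set[int]] = {}
    kept: list[PeptideWindow] = []
    removed = 0
    for w in windows:
        key = (w.residues, w.label)
        if key in seen:
            removed += 1
            continue
        seen.add(key)
        labels = sequences_by_label.setdefault(w.residues, set())
        if labels and w.label not in labels:
            logger.warning(
                "window %r occurs with both labels; keeping both", w.residues
            )
        labels.add(w.label)
        kept.append(w)
    if removed:
        logger.info("dedup_exact removed %d duplicate windows", removed)
    return kept


def write_windows_tsv(windows: Sequence[PeptideWindow], path, header_lines=()) -> None:
    """Serialize windows to TSV (columns residues/label/protein_id/position)."""
    with open(path, "w", newline="") as handle:
        for line in header_lines:
            handle.write(f"# {line}\n")
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(WINDOW_TSV_COLUMNS)
        for w in windows:
            pid, pos = w.origin if w.origin is not None else ("", "")
            writer.writerow([w.residues, w.label, pid, pos])


def read_windows_tsv(path) -> list[PeptideWindow]:
    """Read a window TSV produced by :func:`write_windows_tsv`."""
    windows: list[PeptideWindow] = []
    with open(path, newline="") as handle:
        rows = (
            row for row in csv.reader(handle, delimiter="\t")
            if row and not row[0].startswith("#")
        )
        try:
            header = next(rows)
        except StopIteration:
            raise ParseError(f"{path}: empty window TSV (header required)") from None
        if tuple(c.strip() for c in header) != WINDOW_TSV_COLUMNS:
            raise ParseError(
                f"{path}: bad header {header!r}, expected {list(WINDOW_TSV_COLUMNS)}"
            )
        for rowno, row in enumerate(rows, start=2):
            if len(row) < 2:
                raise ParseError(f"{path}: row {rowno}: expected >= 2 columns")
            residues, label = row[0], row[1]
            origin = None
            if len(row) >= 4 and row[2] != "" and row[3] != "":
                origin = (row[2], int(row[3]))
            try:
                windows.append(PeptideWindow(residues, int(label), origin=origin))
            except (ValueError, SnobpbError) as exc:
                raise ParseError(f"{path}: row {rowno}: {exc}") from exc
    return windows
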