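"""Sequence input, cleaning, sub-region extraction and fixed-size blocking.

Pipeline front end: FASTA records are read as-is, cleaned down to the DNA
alphabet ``{A, C, G, T}``, optionally restricted to a 1-based inclusive
coordinate range (GenBank convention), and finally partitioned into
non-overlapping fixed-length blocks.  Any trailing partial block is
discarded, so a sequence of length ``L`` with block size ``B`` yields
exactly ``floor(L / B)`` blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

log = logging.getLogger(__name__)

#: The DNA alphabet; every cleaned sequence is a string over this set.
ALPHABET = ("A", "C", "G", "T")
_ALPHABET_SET = frozenset(ALPHABET)


class EmptySequenceError(ValueError):
    """Raised when cleaning leaves no bases at all."""


class FastaError(ValueError):
    """Raised for unreadable or empty FASTA input."""


@dataclass(frozen=True)
class RawSequenceRecord:
    """A FASTA entry exactly as read, before any cleaning."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")


@dataclass(frozen=True)
class CleanSequence:
    """A validated DNA sequence: uppercase bases over {A, C, G, T} only."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not _ALPHABET_SET.issuperset(self.bases):
            bad = sorted(set(self.bases) - _ALPHABET_SET)
            raise ValueError(f"non-ACGT characters in cleaned sequence: {bad}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Block:
    """One fixed-length window of a sequence.

    ``start`` is the 1-based position of the block's first base in the
    parent sequence; ``index`` is the 0-based block ordinal, so
    ``start == index * l_block + 1``.
    """

    seq_id: str
    index: int
    start: int
    bases: str

    @property
    def l_block(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class BlockingConfig:
    """Blocking parameter: the window length in bases (l_block)."""

    block_size: int = 200

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError(f"block_size must be >= 1, got {self.block_size}")


def read_fasta(path: str | Path) -> list[RawSequenceRecord]:
    """Read all records from a FASTA file, order preserved, bodies uncleaned.

    Multi-line sequence bodies are concatenated.  Lowercase letters,
    ambiguity codes and gap characters pass through untouched; cleaning
    is a separate stage (:func:`preprocess`).
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"FASTA file not found: {path}")
    records = [
        RawSequenceRecord(id=rec.id, description=rec.description, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FastaError(f"no records in FASTA file: {path}")
    return records


def preprocess(raw: RawSequenceRecord) -> CleanSequence:
    """Clean a raw record: uppercase, drop every non-ACGT character.

    Line breaks never survive FASTA parsing, and any other character that
    is not a canonical base after uppercasing (N, IUPAC ambiguity codes,
    gaps, digits, whitespace) is silently removed; the relative order of
    the retained bases is preserved.

    Raises
    ------
    EmptySequenceError
        If nothing is left after cleaning.
    """
    upper = raw.residues.upper()
    bases = "".join(c for c in upper if c in _ALPHABET_SET)
    dropped = len(upper) - len(bases)
    if dropped:
        log.debug("sequence %s: dropped %d non-base characters", raw.id, dropped)
    if not bases:
        raise EmptySequenceError(f"sequence {raw.id!r} is empty after cleaning")
    return CleanSequence(id=raw.id, bases=bases)


def extract_region(seq: CleanSequence, start: int, end: int) -> CleanSequence:
    """Return the sub-sequence at 1-based inclusive positions ``start..end``.

    Follows the GenBank coordinate convention, so the result has length
    ``end - start + 1``.
    """
    if not (1 <= start <= end <= seq.length):
        raise ValueError(
            f"region {start}..{end} out of range for sequence {seq.id!r} "
            f"of length {seq.length}"
        )
    return CleanSequence(id=seq.id, bases=seq.bases[start - 1 : end])


def blockize(seq: CleanSequence, cfg: BlockingConfig) -> list[Block]:
    """Split a cleaned sequence into consecutive fixed-size blocks.

    Returns ``floor(len / block_size)`` blocks; a trailing partial window
    is discarded.  A sequence shorter than one block yields an empty list
    (with a warning) — downstream stages decide how to treat that.
    """
    B = cfg.block_size
    n_blocks = seq.length // B
    if n_blocks == 0:
        log.warning(
            "sequence %s (length %d) shorter than block size %d: zero blocks",
            seq.id, seq.length, B,
        )
    return [
        Block(seq_id=seq.id, index=i, start=i * B + 1, bases=seq.bases[i * B : (i + 1) * B])
        for i in range(n_blocks)
    ]


def load_clean_sequences(
    path: str | Path, region: tuple[int, int] | None = None
) -> list[CleanSequence]:
    """Read, clean, and optionally region-restrict every record of a FASTA file."""
    seqs = [preprocess(rec) for rec in read_fasta(path)]
    if region is not None:
        seqs = [extract_region(s, *region) for s in seqs]
    return seqs
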