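"""Deterministic fixtures: the worked-example block and seeded random data.

Everything any test needs is generated here at run time; no downloads,
no binary files.  The single most important fixture is
:func:`reconstruct_example_block`, which rebuilds the 20-base
worked-example block uniquely from its four single-base projected
databases.  That block pins the projected-database indexing convention
(1-based occurrence END positions): if the reconstruction or its mining
result ever disagrees with the recorded pattern set, the convention is
wrong everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_prep import ALPHABET, Block, CleanSequence

#: Single-base projected databases (1-based positions) of the worked-example
#: block; the four sets partition 1..20 and determine the block uniquely.
EXAMPLE_BLOCK_SINGLES: dict[str, tuple[int, ...]] = {
    "A": (1, 8, 13, 20),
    "C": (7, 10, 14, 16, 17),
    "G": (3, 4, 6, 12, 19),
    "T": (2, 5, 9, 11, 15, 18),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a deterministic fixture sequence.

    ``edits`` is a list of ``(position, operation, base)`` triples with
    1-based positions; operation is ``"sub"`` or ``"ins"`` (insert before
    the given position; position length+1 appends).
    """

    kind: str = "random"
    length: int = 0
    seed: int = 0
    edits: tuple[tuple[int, str, str], ...] = field(default_factory=tuple)


def reconstruct_example_block() -> Block:
    """Rebuild the 20-base worked-example block from its single-base DBs.

    Asserts that the four position sets partition 1..20 before returning;
    a violation would indicate a transcription error in the fixture.
    """
    positions: dict[int, str] = {}
    for base, pdb in EXAMPLE_BLOCK_SINGLES.items():
        for pos in pdb:
            if pos in positions:
                raise AssertionError(f"position {pos} assigned twice")
            positions[pos] = base
    if sorted(positions) != list(range(1, 21)):
        raise AssertionError("single-base databases do not partition 1..20")
    bases = "".join(positions[i] for i in range(1, 21))
    return Block(seq_id="example1", index=0, start=1, bases=bases)


def random_sequence(length: int, seed: int) -> CleanSequence:
    """I.i.d. uniform ACGT sequence, fully determined by (length, seed)."""
    if length < 0:
        raise ValueError("length must be >= 0")
    rng = np.random.default_rng(seed)
    bases = "".join(rng.choice(list(ALPHABET), size=length)) if length else ""
    return CleanSequence(id=f"random-{length}-{seed}", bases=bases)


def random_block(length: int, seed: int) -> Block:
    """Random block of the given length (convenience for miner tests)."""
    return Block(
        seq_id=f"random-{length}-{seed}", index=0, start=1,
        bases=random_sequence(length, seed).bases,
    )


def perturb(seq: CleanSequence, spec: FixtureSpec) -> CleanSequence:
    """Apply the spec's substitutions/insertions deterministically, in order."""
    bases = list(seq.bases)
    for pos, op, base in spec.edits:
        if op == "sub":
            if not (1 <= pos <= len(bases)):
                raise ValueError(f"substitution position {pos} out of range")
            bases[pos - 1] = base
        elif op == "ins":
            if not (1 <= pos <= len(bases) + 1):
                raise ValueError(f"insertion position {pos} out of range")
            bases.insert(pos - 1, base)
        else:
            raise ValueError(f"unknown edit operation {op!r}")
    return CleanSequence(id=f"{seq.id}|edited", bases="".join(bases))


def write_fixture_fasta(path, seqs: list[CleanSequence], width: int = 70) -> None:
    """Write sequences as a plain multi-record FASTA file."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")
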