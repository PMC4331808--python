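"""Maximal frequent pattern mining within one sequence block.

A depth-first prefix-growth miner (a PrefixSpan variant specialised to a
single ungapped sequence) enumerates contiguous patterns over {A, C, G, T}.
Occurrences may overlap: the support of a pattern is the number of its
(possibly overlapping) occurrences in the block.  Pseudo-projection is
used throughout — a pattern's *projected database* is the sorted list of
1-based END positions of its occurrences, standing in for the set of
suffixes that follow each occurrence.

A pattern is emitted as *maximal* when it

* is frequent (support >= s_min),
* is closed in the left-extension sense (no single base precedes every
  one of its occurrences — the subset test against the single-base
  projected databases),
* has no frequent single-base right-extension, and
* is at least l_min bases long.

Non-closed patterns are pruned from the search: left non-closedness is
inherited by every right-extension, so the pruning loses nothing.

:func:`brute_force_maximal` re-derives the same set by exhaustive
substring enumeration and is kept deliberately independent of the miner;
it also offers a *strict* maximality variant (no frequent super-sequence
of any kind) behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

from .io_prep import ALPHABET, Block

ProjectedDB = tuple[int, ...]
"""Sorted 1-based end positions of a pattern's occurrences within a block."""


@dataclass(frozen=True)
class MiningParams:
    """Thresholds of the miner: minimum support and minimum pattern length."""

    s_min: int = 3
    l_min: int = 2

    def __post_init__(self) -> None:
        if self.s_min < 1:
            raise ValueError(f"s_min must be >= 1, got {self.s_min}")
        if self.l_min < 1:
            raise ValueError(f"l_min must be >= 1, got {self.l_min}")


@dataclass(frozen=True)
class MaximalPatternSet:
    """Result of mining one block: pattern -> projected database.

    ``entries`` maps each maximal frequent pattern (a string over ACGT) to
    the sorted end positions of its occurrences.  Iteration order is
    lexicographic for reproducible serialization.
    """

    entries: Mapping[str, ProjectedDB]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "entries", dict(sorted(dict(self.entries).items()))
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __contains__(self, pattern: str) -> bool:
        return pattern in self.entries

    def __getitem__(self, pattern: str) -> ProjectedDB:
        return self.entries[pattern]

    def supports(self) -> dict[str, int]:
        return {p: len(db) for p, db in self.entries.items()}


def block_from_bases(bases: str, seq_id: str = "block", index: int = 0) -> Block:
    """Convenience wrapper turning a bare base string into a one-off block."""
    return Block(seq_id=seq_id, index=index, start=index * len(bases) + 1, bases=bases)


def project_single(block: Block) -> dict[str, ProjectedDB]:
    """Projected databases of the four single-base patterns.

    For a length-1 pattern the end position of an occurrence is the
    occurrence position itself, so the four lists partition
    ``1..l_block``.
    """
    if len(block) == 0:
        raise ValueError("cannot project an empty block")
    singles: dict[str, list[int]] = {b: [] for b in ALPHABET}
    for pos, base in enumerate(block.bases, start=1):
        singles[base].append(pos)
    return {b: tuple(v) for b, v in singles.items()}


def extend(block: Block, pdb: ProjectedDB, base: str) -> ProjectedDB:
    """Projected database of ``pattern + base`` from that of ``pattern``.

    Each end position ``c`` of the parent pattern contributes ``c + 1``
    when the next base of the block matches; an empty result is valid.
    """
    bases = block.bases
    n = len(bases)
    return tuple(c + 1 for c in pdb if c + 1 <= n and bases[c] == base)


def support(pdb: ProjectedDB) -> int:
    """Number of (possibly overlapping) occurrences: the projected-DB size."""
    return len(pdb)


def is_closed(pattern: str, pdb: ProjectedDB, singles: Mapping[str, ProjectedDB]) -> bool:
    """Left-extension closedness test via the single-base projected DBs.

    ``P = {c - |pattern| : c in pdb}`` is the set of positions immediately
    preceding each occurrence.  If P is a subset of one base's projected
    database, that base precedes *every* occurrence, so prepending it
    yields a longer pattern with identical support: not closed.  An
    occurrence starting at position 1 contributes 0 to P, which belongs to
    no single-base database, so the test correctly reports closed.
    """
    preceding = {c - len(pattern) for c in pdb}
    return not any(preceding.issubset(singles[b]) for b in ALPHABET)


def mine_maximal(block: Block, params: MiningParams) -> MaximalPatternSet:
    """Mine all maximal frequent patterns of one block.

    Depth-first prefix growth: starting from the frequent single bases,
    each pattern is extended one base at a time; recursion descends only
    into extensions that are both frequent and closed.  A pattern is
    emitted when no single-base right-extension is frequent and its
    length reaches ``l_min``.
    """
    if len(block) == 0:
        raise ValueError("cannot mine an empty block")
    singles = project_single(block)
    result: dict[str, ProjectedDB] = {}

    def grow(pattern: str, pdb: ProjectedDB) -> None:
        is_maximal = True
        for base in ALPHABET:
            child = extend(block, pdb, base)
            if len(child) >= params.s_min:
                is_maximal = False
                if is_closed(pattern + base, child, singles):
                    grow(pattern + base, child)
        if is_maximal and len(pattern) >= params.l_min:
            result[pattern] = pdb

    for base in ALPHABET:
        pdb = singles[base]
        if len(pdb) >= params.s_min and is_closed(base, pdb, singles):
            grow(base, pdb)
    return MaximalPatternSet(result)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def _occurrence_ends(bases: str, pattern: str) -> ProjectedDB:
    """End positions of every (overlapping) occurrence, by direct scan."""
    ends: list[int] = []
    i = bases.find(pattern)
    while i != -1:
        ends.append(i + len(pattern))
        i = bases.find(pattern, i + 1)
    return tuple(ends)


def brute_force_maximal(
    block: Block, params: MiningParams, strict: bool = False
) -> MaximalPatternSet:
    """Exhaustive re-derivation of the maximal frequent pattern set.

    Enumerates every distinct substring of the block, counts overlapping
    occurrences by direct scan, keeps the frequent ones, then applies the
    emission rule.  With ``strict=False`` (default) the rule mirrors the
    prefix-growth miner: frequent, left-closed, no frequent single-base
    right-extension, length >= l_min.  With ``strict=True`` a pattern is
    kept only if *no* frequent pattern strictly contains it (maximality in
    the literal no-frequent-super-sequence sense); the strict set is
    always a subset of the default one.

    Intended for test-scale blocks (up to a few hundred bases).
    """
    bases = block.bases
    n = len(bases)
    if n == 0:
        raise ValueError("cannot mine an empty block")

    frequent: dict[str, ProjectedDB] = {}
    seen: set[str] = set()
    for i in range(n):
        for j in range(i + 1, n + 1):
            sub = bases[i:j]
            if sub in seen:
                continue
            seen.add(sub)
            ends = _occurrence_ends(bases, sub)
            if len(ends) >= params.s_min:
                frequent[sub] = ends

    def left_closed(pattern: str, ends: ProjectedDB) -> bool:
        # a left-extension with equal support is itself frequent, hence recorded
        sup = len(ends)
        return not any(len(frequent.get(b + pattern, ())) == sup for b in ALPHABET)

    result: dict[str, ProjectedDB] = {}
    for pattern, ends in frequent.items():
        if len(pattern) < params.l_min:
            continue
        if any(pattern + b in frequent for b in ALPHABET):
            continue
        if strict:
            if any(p != pattern and pattern in p for p in frequent):
                continue
        elif not left_closed(pattern, ends):
            continue
        result[pattern] = ends
    return MaximalPatternSet(result)
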