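"""Entropy vectorization of a blocked sequence.

Each block is summarised by a single weighted entropy computed from its
maximal frequent pattern set R.  A pattern of length ``l_pat`` with
support ``s_pat`` in a block of length ``l_block`` has probability

    p_pat = s_pat / (l_block - l_pat + 1)

(the support over the number of windows that could host the pattern),
and the block entropy, in nats, is the support-weighted average of the
surprisal terms:

    H = -(1 / sum_R s_pat) * sum_R s_pat * p_pat * ln(p_pat)

Because the weights sum to one and each term p*ln(1/p) is at most 1/e,
H always lies in [0, 1/e].  The ordered per-block entropies form the
sequence's representative vector; sequences of different lengths thus
get vectors of different dimensions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .io_prep import Block, BlockingConfig, CleanSequence, blockize
from .mining import MaximalPatternSet, MiningParams, mine_maximal

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatternStats:
    """One mined pattern with its support, length and probability."""

    pattern: str
    s_pat: int
    l_pat: int
    p_pat: float


@dataclass(frozen=True)
class BlockEntropy:
    seq_id: str
    block_index: int
    H: float


@dataclass(frozen=True)
class SequenceVector:
    """Ordered per-block entropies representing one sequence."""

    seq_id: str
    components: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.components)

    @property
    def dimension(self) -> int:
        return len(self.components)


class EmptyVectorError(ValueError):
    """Sequence shorter than one block: no vector can be formed."""


def pattern_probability(s_pat: int, l_pat: int, l_block: int) -> float:
    """Probability of a pattern in a block: s_pat / (l_block - l_pat + 1)."""
    if l_pat > l_block:
        raise ValueError(f"pattern length {l_pat} exceeds block length {l_block}")
    if l_pat < 1 or s_pat < 0:
        raise ValueError("need l_pat >= 1 and s_pat >= 0")
    return s_pat / (l_block - l_pat + 1)


def pattern_stats(patterns: MaximalPatternSet, l_block: int) -> list[PatternStats]:
    """Attach supports, lengths and probabilities to a mined pattern set."""
    return [
        PatternStats(
            pattern=p,
            s_pat=len(db),
            l_pat=len(p),
            p_pat=pattern_probability(len(db), len(p), l_block),
        )
        for p, db in patterns.entries.items()
    ]


def block_entropy(
    stats: list[PatternStats], seq_id: str = "", block_index: int = 0
) -> BlockEntropy:
    """Support-weighted entropy of one block from its pattern statistics.

    An empty pattern set (possible when thresholds are aggressive for the
    block) is defined to have H = 0, with a warning, so that vectors stay
    well-formed.
    """
    total = sum(st.s_pat for st in stats)
    if total == 0:
        log.warning(
            "block %s[%d]: no maximal frequent patterns; entropy set to 0",
            seq_id, block_index,
        )
        return BlockEntropy(seq_id=seq_id, block_index=block_index, H=0.0)
    H = -sum(st.s_pat * st.p_pat * math.log(st.p_pat) for st in stats) / total
    return BlockEntropy(seq_id=seq_id, block_index=block_index, H=H)


def entropy_of_block(block: Block, params: MiningParams) -> BlockEntropy:
    """Mine one block and compute its entropy."""
    patterns = mine_maximal(block, params)
    stats = pattern_stats(patterns, len(block))
    return block_entropy(stats, seq_id=block.seq_id, block_index=block.index)


def sequence_vector(
    seq: CleanSequence, cfg: BlockingConfig, params: MiningParams
) -> SequenceVector:
    """Entropy vector of a whole sequence: one component per retained block."""
    blocks = blockize(seq, cfg)
    if not blocks:
        raise EmptyVectorError(
            f"sequence {seq.id!r} (length {seq.length}) yields no block of "
            f"size {cfg.block_size}"
        )
    return SequenceVector(
        seq_id=seq.id,
        components=tuple(entropy_of_block(b, params).H for b in blocks),
    )
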