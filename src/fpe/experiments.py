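"""Robustness experiments and tree building.

Drivers for the standard characterisation of the entropy-vector
representation:

* segment-shuffle tolerance — how far does a random within-segment
  permutation move the representation?
* insertion-noise tolerance — how does the distance to the original
  sequence grow as random bases are inserted?
* block-size sweep — finer blocks expose finer-granularity differences
  between two sequences;
* hierarchical clustering of a pairwise distance matrix into a rooted
  Newick tree (average linkage / UPGMA by default).

All stochastic drivers take an explicit integer seed and are
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .distance import DistanceMatrix, vector_distance
from .entropy import SequenceVector, entropy_of_block, sequence_vector
from .io_prep import ALPHABET, Block, BlockingConfig, CleanSequence
from .mining import MiningParams


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of the stochastic robustness experiments.

    ``segment_fraction`` is the length of the shuffled segment relative to
    the whole sequence; ``noise_ratio`` is inserted bases per original
    base.  Defaults follow the standard protocol: 100 trials, block size
    200 for the shuffle test, mining thresholds s_min=3 / l_min=2.
    """

    block_size: int = 200
    s_min: int = 3
    l_min: int = 2
    n_trials: int = 100
    seed: int = 0
    segment_fraction: float = 0.1
    noise_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0 < self.segment_fraction <= 1):
            raise ValueError("segment_fraction must be in (0, 1]")
        if self.noise_ratio < 0:
            raise ValueError("noise_ratio must be >= 0")

    @property
    def blocking(self) -> BlockingConfig:
        return BlockingConfig(block_size=self.block_size)

    @property
    def mining(self) -> MiningParams:
        return MiningParams(s_min=self.s_min, l_min=self.l_min)


@dataclass(frozen=True)
class TrialSummary:
    """Per-trial distances with their mean and population std (ddof=0)."""

    mean: float
    std: float
    per_trial: tuple[float, ...]

    @classmethod
    def from_trials(cls, per_trial: list[float]) -> "TrialSummary":
        arr = np.asarray(per_trial, dtype=float)
        return cls(mean=float(arr.mean()), std=float(arr.std(ddof=0)), per_trial=tuple(per_trial))


def _distance_between(a: CleanSequence, b: CleanSequence, cfg: ExperimentConfig) -> float:
    va = sequence_vector(a, cfg.blocking, cfg.mining)
    vb = sequence_vector(b, cfg.blocking, cfg.mining)
    return vector_distance(va, vb).dist


def shuffle_robustness(seq: CleanSequence, cfg: ExperimentConfig) -> TrialSummary:
    """Distance between a random segment and its base-shuffled copy.

    Per trial: a uniformly placed consecutive segment of length
    ``floor(segment_fraction * len)`` is cut out, its bases permuted
    uniformly at random, and the entropy-vector distance between original
    and shuffled segment is recorded.
    """
    rng = np.random.default_rng(cfg.seed)
    seg_len = int(cfg.segment_fraction * seq.length)
    if seg_len < cfg.block_size:
        raise ValueError(
            f"segment length {seg_len} smaller than block size {cfg.block_size}: "
            "the segment would yield zero blocks"
        )
    trials: list[float] = []
    for t in range(cfg.n_trials):
        start = int(rng.integers(0, seq.length - seg_len + 1))
        segment = seq.bases[start : start + seg_len]
        shuffled = "".join(rng.permutation(list(segment)))
        orig = CleanSequence(id=f"{seq.id}|seg{t}", bases=segment)
        perm = CleanSequence(id=f"{seq.id}|seg{t}|shuf", bases=shuffled)
        trials.append(_distance_between(orig, perm, cfg))
    return TrialSummary.from_trials(trials)


def insert_noise(seq: CleanSequence, n_insert: int, rng: np.random.Generator) -> CleanSequence:
    """Insert ``n_insert`` uniform random bases at uniform random slots.

    Slots are the ``len + 1`` gaps of the original sequence, drawn with
    replacement; letters are i.i.d. uniform over ACGT.
    """
    slots = np.sort(rng.integers(0, seq.length + 1, size=n_insert))
    letters = rng.choice(list(ALPHABET), size=n_insert)
    out: list[str] = []
    prev = 0
    for slot, letter in zip(slots, letters):
        out.append(seq.bases[prev:slot])
        out.append(str(letter))
        prev = slot
    out.append(seq.bases[prev:])
    return CleanSequence(id=f"{seq.id}|noisy", bases="".join(out))


def _vector_whole_if_short(
    seq: CleanSequence, block_size: int, params: MiningParams
) -> SequenceVector:
    """Entropy vector, degrading to a single whole-sequence block.

    The robustness protocols deliberately allow a block size larger than
    the sequence to switch blocking off; in that case the whole sequence
    is mined as one block instead of yielding an empty vector.
    """
    if seq.length < block_size:
        block = Block(seq_id=seq.id, index=0, start=1, bases=seq.bases)
        return SequenceVector(seq_id=seq.id, components=(entropy_of_block(block, params).H,))
    return sequence_vector(seq, BlockingConfig(block_size=block_size), params)


def noise_robustness(seq: CleanSequence, cfg: ExperimentConfig) -> TrialSummary:
    """Distance between a sequence and randomly base-inserted copies of it.

    ``floor(noise_ratio * len)`` bases are inserted per trial.  A block
    size exceeding the sequence length means no blocking: original and
    contaminated sequences are each mined as a single block.
    """
    rng = np.random.default_rng(cfg.seed)
    n_insert = int(cfg.noise_ratio * seq.length)
    trials: list[float] = []
    for _ in range(cfg.n_trials):
        noisy = insert_noise(seq, n_insert, rng)
        va = _vector_whole_if_short(seq, cfg.block_size, cfg.mining)
        vb = _vector_whole_if_short(noisy, cfg.block_size, cfg.mining)
        trials.append(vector_distance(va, vb).dist)
    return TrialSummary.from_trials(trials)


def block_size_sweep(
    seq_a: CleanSequence,
    seq_b: CleanSequence,
    sizes: list[int],
    params: MiningParams,
) -> list[tuple[int, float]]:
    """Distance between two sequences at each block size, same mining params."""
    out: list[tuple[int, float]] = []
    for size in sizes:
        cfg = BlockingConfig(block_size=size)
        if seq_a.length < size or seq_b.length < size:
            raise ValueError(f"block size {size} too large for the input sequences")
        va = sequence_vector(seq_a, cfg, params)
        vb = sequence_vector(seq_b, cfg, params)
        out.append((size, vector_distance(va, vb).dist))
    return out


def build_tree(matrix: DistanceMatrix, method: str = "average") -> str:
    """Agglomerative clustering of a distance matrix into rooted Newick.

    ``method`` is any scipy linkage name; the default, average linkage,
    is UPGMA.  Branch lengths derive from merge heights (each node sits at
    half its merge height, the ultrametric convention), so an ultrametric
    input is reproduced exactly.
    """
    v = matrix.values
    if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    condensed = squareform(v, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    root = hierarchy.to_tree(Z)
    children = ",".join(
        _newick_node(child, root.dist, matrix.labels)
        for child in (root.left, root.right)
    )
    return f"({children});"


def _newick_node(node, parent_height: float, labels: tuple[str, ...]) -> str:
    """Serialize one clustering subtree; heights are halved merge distances."""
    if node.is_leaf():
        return f"{labels[node.id]}:{parent_height / 2:.6f}"
    length = (parent_height - node.dist) / 2
    inner = ",".join(
        _newick_node(child, node.dist, labels) for child in (node.left, node.right)
    )
    return f"({inner}):{length:.6f}"
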