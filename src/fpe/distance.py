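"""Distance between entropy vectors, pairwise matrices, and correlation scoring.

Two sequences generally produce vectors of different dimensions
(m-dimensional V1 and n-dimensional V2, m <= n after swapping).  The
comparison first *anchors* the shorter vector inside the longer one: the
start offset k minimises the gap between V2's component and V1's first
component,

    |V2[k] - V1[1]| = min over i in 1..n-m+1 of |V2[i] - V1[1]|,

ties going to the smallest k.  The distance is then the Euclidean norm of
the aligned window difference, scaled up by the dimension ratio:

    dist(V1, V2) = (n / m) * sqrt( sum_{i=1..m} (V2[k+i-1] - V1[i])^2 )

For equal dimensions this degenerates to the plain Euclidean distance.
The measure is symmetric by construction (the shorter vector always plays
the V1 role) but is not a proven metric: the triangle inequality is not
asserted anywhere in this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from .entropy import SequenceVector


@dataclass(frozen=True)
class AnchorResult:
    """Anchor offset k (1-based, into the longer vector) and the dimensions."""

    k: int
    m: int
    n: int


@dataclass(frozen=True)
class DistanceResult:
    dist: float
    anchor: AnchorResult


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric pairwise distance matrix with ordered labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        object.__setattr__(self, "values", v)


def find_anchor(v1: SequenceVector, v2: SequenceVector) -> AnchorResult:
    """Best start offset of the shorter vector v1 within the longer v2.

    Expects ``len(v1) <= len(v2)`` (callers swap first); ties are broken
    toward the smallest k for determinism.
    """
    m, n = len(v1), len(v2)
    if m == 0 or n == 0:
        raise ValueError("cannot anchor empty vectors")
    if m > n:
        raise ValueError(f"v1 (dim {m}) must not be longer than v2 (dim {n})")
    gaps = [abs(v2.components[i] - v1.components[0]) for i in range(n - m + 1)]
    k = int(np.argmin(gaps)) + 1  # argmin returns the first minimum
    return AnchorResult(k=k, m=m, n=n)


def vector_distance(v1: SequenceVector, v2: SequenceVector) -> DistanceResult:
    """Anchor-aligned, dimension-scaled Euclidean distance between two vectors.

    Inputs may come in either order; the shorter one is assigned the V1
    role, which makes the result symmetric.
    """
    if len(v1) == 0 or len(v2) == 0:
        empty = [v.seq_id for v in (v1, v2) if len(v) == 0]
        raise ValueError(f"cannot compute distance with empty vector(s): {empty}")
    if len(v1) > len(v2):
        v1, v2 = v2, v1
    anchor = find_anchor(v1, v2)
    k, m, n = anchor.k, anchor.m, anchor.n
    window = v2.components[k - 1 : k - 1 + m]
    sq = sum((w - x) ** 2 for w, x in zip(window, v1.components))
    return DistanceResult(dist=(n / m) * math.sqrt(sq), anchor=anchor)


def pairwise_matrix(vectors: list[SequenceVector]) -> DistanceMatrix:
    """All-against-all distances; zero diagonal, symmetric."""
    if len(vectors) < 2:
        raise ValueError("need at least two vectors for a pairwise matrix")
    empty = [v.seq_id for v in vectors if len(v) == 0]
    if empty:
        raise ValueError(f"empty vectors for: {empty}")
    N = len(vectors)
    values = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            d = vector_distance(vectors[i], vectors[j]).dist
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=tuple(v.seq_id for v in vectors), values=values)


def pearson(x: list[float], y: list[float]) -> float:
    """Sample Pearson product-moment correlation of two equal-length lists."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise ValueError("need at least two points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(_scipy_stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def matrix_to_tsv(matrix: DistanceMatrix, precision: int = 4) -> str:
    """TSV with a header row and a label column; values rounded."""
    lines = ["\t".join(("",) + matrix.labels)]
    for label, row in zip(matrix.labels, matrix.values):
        lines.append(label + "\t" + "\t".join(f"{v:.{precision}f}" for v in row))
    return "\n".join(lines) + "\n"


def matrix_to_phylip(matrix: DistanceMatrix, precision: int = 6) -> str:
    """PHYLIP square distance matrix (relaxed names, tab-separated)."""
    lines = [f"{len(matrix.labels)}"]
    for label, row in zip(matrix.labels, matrix.values):
        lines.append(label + "\t" + "\t".join(f"{v:.{precision}f}" for v in row))
    return "\n".join(lines) + "\n"


def matrix_from_tsv(text: str) -> DistanceMatrix:
    """Parse the TSV format written by :func:`matrix_to_tsv`."""
    rows = [line.split("\t") for line in text.splitlines() if line]
    labels = tuple(rows[0][1:])  # header starts with an empty corner cell
    values = np.array([[float(x) for x in row[1:]] for row in rows[1:]])
    return DistanceMatrix(labels=labels, values=values)
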