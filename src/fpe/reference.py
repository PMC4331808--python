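"""Published benchmark values for the 11-species β-globin similarity test.

The β-globin gene set below is the classical benchmark for alignment-free
similarity methods.  The tables in this module are printed reference
outputs of other tools on that benchmark — MEGA 5.2 (alignment-based,
used as ground truth), BLASTN 2.2.29+, a 2D graphical-representation
method (Yu & Huang, 2013) and a weighted pseudo-entropy method (Li et
al., 2011) — plus the entropy-vector pairwise distance matrix obtained
with block size 200, s_min 2, l_min 8.  They serve as *inputs* to the
correlation and tree utilities (e.g. scoring a new distance row against
MEGA), not as anything this package recomputes from them.
"""

from __future__ import annotations

import numpy as np

from .distance import DistanceMatrix

#: Accession and 1-based inclusive sub-region of each benchmark gene.
BETA_GLOBIN_REGIONS: dict[str, tuple[str, int, int]] = {
    "bovine": ("X00376", 278, 1741),
    "chimpanzee": ("X02345", 4189, 5532),
    "gallus": ("V00409", 465, 1810),
    "goat": ("M15387", 279, 1749),
    "gorilla": ("X61109", 4538, 5881),
    "human": ("U01317", 62187, 63610),
    "lemur": ("M15734", 154, 1595),
    "mouse": ("V00722", 275, 1462),
    "opossum": ("J03643", 467, 2488),
    "rabbit": ("V00882", 277, 1419),
    "rat": ("X06701", 310, 1505),
}

#: Order of the ten non-human species in the human-vs-others rows below.
HUMAN_COMPARISON_SPECIES: tuple[str, ...] = (
    "bovine", "chimpanzee", "gallus", "goat", "gorilla",
    "lemur", "mouse", "opossum", "rabbit", "rat",
)

#: Human-vs-others distances reported by each method on the benchmark.
HUMAN_DISTANCE_ROWS: dict[str, tuple[float, ...]] = {
    "mega": (0.4485, 0.0095, 0.8456, 0.4696, 0.0117,
             0.2423, 0.4815, 0.8337, 0.4083, 0.4935),
    "blastn": (0.8600, 0.0896, 0.9880, 0.8765, 0.0896,
               0.6643, 0.9026, 1.0000, 0.8423, 0.9182),
    "yu_huang_2013": (22.4257, 5.3704, 23.5869, 26.8209, 5.3704,
                      25.2515, 25.8007, 25.9952, 20.5706, 27.0102),
    "li_2011": (0.1000, 0.0100, 0.2150, 0.1050, 0.0110,
                0.0550, 0.0830, 0.0890, 0.0700, 0.0620),
    "fpe": (0.0670, 0.0000, 0.0792, 0.0820, 0.0000,
            0.0478, 0.0663, 0.1537, 0.0664, 0.0664),
}

_MATRIX_LABELS: tuple[str, ...] = (
    "bovine", "chimpanzee", "gallus", "goat", "gorilla", "human",
    "lemur", "mouse", "opossum", "rabbit", "rat",
)

_MATRIX_ROWS = [
    [0.0000, 0.0782, 0.1112, 0.0474, 0.0782, 0.0670, 0.0824, 0.0666, 0.1202, 0.0666, 0.0663],
    [0.0782, 0.0000, 0.0679, 0.0957, 0.0000, 0.0000, 0.0558, 0.0568, 0.1579, 0.0569, 0.0569],
    [0.1112, 0.0679, 0.0000, 0.1239, 0.0679, 0.0792, 0.0962, 0.0806, 0.1935, 0.0805, 0.0805],
    [0.0474, 0.0957, 0.1239, 0.0000, 0.0957, 0.0820, 0.0675, 0.0939, 0.0994, 0.0939, 0.0938],
    [0.0782, 0.0000, 0.0679, 0.0957, 0.0000, 0.0000, 0.0558, 0.0568, 0.1579, 0.0569, 0.0569],
    [0.0670, 0.0000, 0.0792, 0.0820, 0.0000, 0.0000, 0.0478, 0.0663, 0.1537, 0.0664, 0.0664],
    [0.0824, 0.0558, 0.0962, 0.0675, 0.0558, 0.0478, 0.0000, 0.0942, 0.1428, 0.0945, 0.0944],
    [0.0666, 0.0568, 0.0806, 0.0939, 0.0568, 0.0663, 0.0942, 0.0000, 0.1643, 0.0672, 0.0671],
    [0.1202, 0.1579, 0.1935, 0.0994, 0.1579, 0.1537, 0.1428, 0.1643, 0.0000, 0.1643, 0.1643],
    [0.0666, 0.0569, 0.0805, 0.0939, 0.0569, 0.0664, 0.0945, 0.0672, 0.1643, 0.0000, 0.0003],
    [0.0663, 0.0569, 0.0805, 0.0938, 0.0569, 0.0664, 0.0944, 0.0671, 0.1643, 0.0003, 0.0000],
]


def beta_globin_reference_matrix() -> DistanceMatrix:
    """Published entropy-vector distance matrix (block 200, s_min 2, l_min 8)."""
    return DistanceMatrix(labels=_MATRIX_LABELS, values=np.array(_MATRIX_ROWS))
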