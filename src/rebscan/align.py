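"""Pairwise protein alignment and similarity scoring.

The package's homology predicate works on deterministic global (end-to-end)
alignments with a BLOSUM62-style matrix and affine gaps; searching scores with
local alignments of the same parameterisation.  "Percent similarity" is the
BLAST "Positives" notion: the percentage of alignment columns (gap columns
included in the denominator, as BLAST reports it) whose residue pair has a
positive substitution score.  Percent identity is reported alongside.

``X`` (unknown residue) scores 0 against everything, including itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import AMINO_ACIDS, validate_sequence

#: Alphabet used for matrix lookups (20 residues + X).
MATRIX_ALPHABET = AMINO_ACIDS + "X"


@dataclass(frozen=True)
class AlignParams:
    """Alignment scoring parameters (BLOSUM62 conventions by default)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = -11.0     # score of the first residue of a gap
    gap_extend: float = -1.0    # score of each further gap residue


DEFAULT_PARAMS = AlignParams()


@lru_cache(maxsize=8)
def substitution_matrix(matrix_name: str = "BLOSUM62") -> np.ndarray:
    """Dense (21, 21) substitution matrix over :data:`MATRIX_ALPHABET`.

    The X row/column is forced to zero.
    """
    src = substitution_matrices.load(matrix_name)
    n = len(MATRIX_ALPHABET)
    mat = np.zeros((n, n), dtype=float)
    for i, a in enumerate(MATRIX_ALPHABET):
        for j, b in enumerate(MATRIX_ALPHABET):
            if a == "X" or b == "X":
                mat[i, j] = 0.0
            else:
                mat[i, j] = float(src[a][b])
    mat.setflags(write=False)
    return mat


_AA_INDEX: Dict[str, int] = {aa: i for i, aa in enumerate(MATRIX_ALPHABET)}


def encode(sequence: str) -> np.ndarray:
    """Integer-encode a validated sequence over :data:`MATRIX_ALPHABET`."""
    return np.fromiter((_AA_INDEX[a] for a in sequence), dtype=np.int64,
                       count=len(sequence))


@lru_cache(maxsize=16)
def _make_aligner(params: AlignParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    mat = substitution_matrix(params.matrix_name)
    aligner.substitution_matrix = substitution_matrices.Array(
        alphabet=MATRIX_ALPHABET, dims=2, data=mat
    )
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one deterministic global alignment of a protein pair.

    Percentages follow BLAST's Identities/Positives convention: the
    denominator is the total number of alignment columns *including* gap
    columns (``total_columns``).  For gapless alignments this coincides with
    the residue-residue column count (``aligned_columns``).
    """

    aligned_pair: Tuple[str, str]
    raw_score: float
    percent_identity: float
    percent_similarity: float
    aligned_columns: int
    total_columns: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= self.percent_similarity <= 100.0):
            raise ValueError(
                "0 <= percent_identity <= percent_similarity <= 100 violated: "
                f"{self.percent_identity} / {self.percent_similarity}"
            )


def _column_stats(alignment, x: str, y: str,
                  matrix: np.ndarray) -> Tuple[int, int, int]:
    """(aligned_columns, identities, positives) from residue-residue blocks."""
    ex, ey = encode(x), encode(y)
    columns = identities = positives = 0
    blocks_x, blocks_y = alignment.aligned
    for (xs, xe), (ys, ye) in zip(blocks_x, blocks_y):
        seg_x, seg_y = ex[xs:xe], ey[ys:ye]
        columns += xe - xs
        identities += int(np.count_nonzero(seg_x == seg_y))
        positives += int(np.count_nonzero(matrix[seg_x, seg_y] > 0))
    return columns, identities, positives


def align_sequences(x: str, y: str,
                    params: AlignParams = DEFAULT_PARAMS,
                    ids: Tuple[str, str] = ("a", "b")) -> AlignmentResult:
    """Global-align two sequences and report score, identity and similarity.

    Symmetric by construction: the pair is canonically ordered before the DP
    runs, so co-optimal alignment ambiguity cannot make the reported column
    statistics depend on argument order.
    """
    validate_sequence(x, ids[0])
    validate_sequence(y, ids[1])
    # canonical order: by sequence string (ids may coincide for raw strings)
    if (y, ids[1]) < (x, ids[0]):
        x, y = y, x
    aligner = _make_aligner(params, "global")
    alignments = aligner.align(x, y)
    best = alignments[0]
    matrix = substitution_matrix(params.matrix_name)
    columns, identities, positives = _column_stats(best, x, y, matrix)
    total = int(best.length)
    pct_id = 100.0 * identities / total if total else 0.0
    pct_sim = 100.0 * positives / total if total else 0.0
    # identity counts X==X columns which score 0; fold them into similarity
    # so the identity <= similarity invariant holds with X scoring 0
    pct_sim = max(pct_sim, pct_id)
    return AlignmentResult(
        aligned_pair=(min(ids), max(ids)),
        raw_score=float(best.score),
        percent_identity=float(pct_id),
        percent_similarity=float(pct_sim),
        aligned_columns=int(columns),
        total_columns=total,
    )


def align_pair(a, b, params: AlignParams = DEFAULT_PARAMS) -> AlignmentResult:
    """:func:`align_sequences` over two :class:`~rebscan.records.ProteinRecord`."""
    return align_sequences(a.sequence, b.sequence, params=params,
                           ids=(a.protein_id, b.protein_id))


def local_score(query: str, subject: str,
                params: AlignParams = DEFAULT_PARAMS) -> float:
    """Smith–Waterman score (no traceback) used inside seed searches."""
    aligner = _make_aligner(params, "local")
    return float(aligner.score(query, subject))


def global_score(x: str, y: str,
                 params: AlignParams = DEFAULT_PARAMS) -> float:
    """End-to-end alignment score only (several-fold faster than traceback)."""
    aligner = _make_aligner(params, "global")
    return float(aligner.score(x, y))
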