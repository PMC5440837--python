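"""Global pairwise protein alignment with affine gap penalties and
identity / similarity percentages (EMBOSS Stretcher conventions).

Defaults mirror the classic protein settings: BLOSUM62, gap open 12, gap
extend 2 (a gap of length L costs 12 + 2*(L-1)), end gaps penalized.  Both
percentages share the full alignment length (including gap columns) as the
denominator; a column is "similar" when its substitution score is positive,
which includes every identical column.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentResult",
    "global_align",
    "identity_similarity",
    "load_matrix",
    "STANDARD_AA",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    gaps: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    def as_dict(self) -> dict:
        return {
            "score": self.score,
            "length": self.length,
            "identity_pct": self.identity_pct,
            "similarity_pct": self.similarity_pct,
            "gaps": self.gaps,
        }

    def __str__(self) -> str:
        marks = []
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            marks.append("|" if (ca == cb and ca != GAP) else " ")
        return (
            f"{self.aligned_a}\n{''.join(marks)}\n{self.aligned_b}\n"
            f"score {self.score:.1f}  identity {self.identity_pct:.1f}%  "
            f"similarity {self.similarity_pct:.1f}%  gaps {self.gaps}"
        )


def load_matrix(name: str = "BLOSUM62"):
    """Substitution matrix with 'X' scoring 0 against everything."""
    base = substitution_matrices.load(name)
    alphabet = STANDARD_AA + "X"
    out = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == "X" or b == "X":
                out[a, b] = 0.0
            else:
                out[a, b] = base[a, b]
    return out


def _validate(seq: str, which: str) -> str:
    if not seq:
        raise ValueError(f"sequence {which} is empty")
    seq = seq.upper()
    allowed = set(STANDARD_AA + "X")
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise ValueError(
                f"sequence {which}: invalid residue {ch!r} at position {pos}"
            )
    return seq


def global_align(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 12.0,
    gap_extend: float = 2.0,
) -> AlignmentResult:
    """Optimal global alignment under affine gaps, end gaps penalized.

    Tie-breaking among co-optimal alignments follows the aligner's
    deterministic first-traceback order, so identical inputs always return
    the identical alignment.
    """
    a = _validate(a, "a")
    b = _validate(b, "b")
    if matrix is None:
        matrix = load_matrix()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    alignment = aligner.align(a, b)[0]
    aligned_a, aligned_b = alignment[0], alignment[1]
    identity, similarity = identity_similarity(aligned_a, aligned_b, matrix)
    gaps = sum(1 for ca, cb in zip(aligned_a, aligned_b) if ca == GAP or cb == GAP)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        identity_pct=identity,
        similarity_pct=similarity,
        gaps=gaps,
    )


def identity_similarity(aligned_a: str, aligned_b: str, matrix=None) -> tuple[float, float]:
    """Percent identical and percent positively-scoring columns.

    Both use the full alignment length (gap columns included) as denominator;
    gap columns themselves are neither identical nor similar.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    if not aligned_a:
        raise ValueError("empty alignment")
    if matrix is None:
        matrix = load_matrix()
    length = len(aligned_a)
    n_ident = 0
    n_similar = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == GAP or cb == GAP:
            continue
        if ca == cb:
            n_ident += 1
        if matrix[ca, cb] > 0:
            n_similar += 1
    return 100.0 * n_ident / length, 100.0 * n_similar / length
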