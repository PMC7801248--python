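"""Shared global protein aligner (Needleman-Wunsch, BLOSUM62, affine gaps)."""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=1)
def protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def align_protein_pair(a: str, b: str) -> tuple[float, str, str]:
    """Globally align two protein sequences.

    Returns (score, gapped_a, gapped_b). Deterministic: the first optimal
    alignment reported by the aligner is used.
    """
    if not a or not b:
        raise ValueError("cannot align an empty protein sequence")
    aln = protein_aligner().align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return float(aln.score), ga, gb


def alignment_identity(gapped_a: str, gapped_b: str) -> tuple[float, int]:
    """Percent identity over columns where both sequences have a residue.

    Returns (identity_percent, n_aligned_columns).
    """
    matches = 0
    cols = 0
    for x, y in zip(gapped_a, gapped_b):
        if x == "-" or y == "-":
            continue
        cols += 1
        if x == y:
            matches += 1
    if cols == 0:
        return 0.0, 0
    return 100.0 * matches / cols, cols
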