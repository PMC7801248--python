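"""Genetic-code tables shared by the Ka/Ks estimator and the sequence simulator.

Everything here is derived once from the universal genetic code: per-codon
amino acids, stop codons, and for every (codon, position) the three possible
single-base changes with their class (synonymous / nonsynonymous / to-stop).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

AA = {c: str(Seq(c).translate()) for c in CODONS}
STOP_CODONS = frozenset(c for c, aa in AA.items() if aa == "*")
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]
SENSE_INDEX = np.array([CODON_INDEX[c] for c in SENSE_CODONS], dtype=np.int64)

# change classes
SYN, NONSYN, TO_STOP = 0, 1, 2


def change_class(codon: str, pos: int, new_base: str) -> int:
    """Class of the single-base change codon[pos] -> new_base."""
    mutant = codon[:pos] + new_base + codon[pos + 1 :]
    if mutant in STOP_CODONS:
        return TO_STOP
    return SYN if AA[mutant] == AA[codon] else NONSYN


@lru_cache(maxsize=1)
def mutation_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised lookup tables over (codon index, position, alternative).

    Returns
    -------
    alt_codon : (64, 3, 3) int  index of the codon after the change
    cls       : (64, 3, 3) int  SYN / NONSYN / TO_STOP
    tau       : (64, 3)    int  number of to-stop changes at the position
    is_stop   : (64,)      bool codon is itself a stop
    """
    alt_codon = np.zeros((64, 3, 3), dtype=np.int64)
    cls = np.zeros((64, 3, 3), dtype=np.int64)
    tau = np.zeros((64, 3), dtype=np.int64)
    is_stop = np.zeros(64, dtype=bool)
    for ci, codon in enumerate(CODONS):
        is_stop[ci] = codon in STOP_CODONS
        for pos in range(3):
            alts = [b for b in BASES if b != codon[pos]]
            for ai, b in enumerate(alts):
                mutant = codon[:pos] + b + codon[pos + 1 :]
                alt_codon[ci, pos, ai] = CODON_INDEX[mutant]
                if codon in STOP_CODONS:
                    cls[ci, pos, ai] = NONSYN  # never used for sense input
                else:
                    cls[ci, pos, ai] = change_class(codon, pos, b)
            tau[ci, pos] = int(np.sum(cls[ci, pos] == TO_STOP))
    return alt_codon, cls, tau, is_stop


def codons_of(seq: str) -> list[str]:
    """Split a CDS into codons; length must be divisible by 3."""
    if len(seq) % 3:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def encode_codons(seq: str) -> np.ndarray:
    """CDS string -> int64 array of codon indices (uppercased)."""
    s = seq.upper()
    if len(s) % 3:
        raise ValueError(f"CDS length {len(s)} not divisible by 3")
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    idx = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        idx[arr == ord(b)] = i
    if (idx < 0).any():
        raise ValueError("CDS contains non-ACGT characters")
    trip = idx.reshape(-1, 3)
    return trip[:, 0] * 16 + trip[:, 1] * 4 + trip[:, 2]


def decode_codons(idx: np.ndarray) -> str:
    return "".join(CODONS[i] for i in idx)
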