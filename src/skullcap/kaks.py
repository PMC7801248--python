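"""Pairwise Ka/Ks estimation by the Nei-Gojobori (1986) counting method.

The estimator works on a protein-guided codon alignment of two coding
sequences:

* per-codon synonymous site fractions: at each codon position the fraction of
  the three possible single-base changes that preserve the amino acid, with
  changes to stop codons excluded from both numerator and denominator;
* per-column difference counts: codon pairs differing at 2 or 3 positions are
  resolved by averaging synonymous/nonsynonymous step counts over all
  mutational pathways that avoid stop codons;
* multiple-hit correction: Jukes-Cantor, d = -3/4 ln(1 - 4p/3), applied to
  pS = Sd/S and pN = Nd/N.

Ka/Ks < 1 indicates purifying selection on the protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from math import isclose, log

from . import _codons
from ._align import align_protein_pair
from ._codons import AA, STOP_CODONS

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "SaturationError",
    "TooShortError",
    "align_codons",
    "compute_kaks",
    "jc_correct",
    "ng86_differences",
    "ng86_sites",
]

AMBIGUOUS = set("NRYSWKMBDHV")
MIN_CODONS = 30


class SaturationError(ValueError):
    """Raised when an observed proportion is outside the Jukes-Cantor domain."""


class TooShortError(ValueError):
    """Raised when fewer than MIN_CODONS aligned codons survive filtering."""


@dataclass
class CodonAlignment:
    """Gap-free, stop-free, ambiguity-free codon columns of an aligned pair."""

    codons_a: list[str]
    codons_b: list[str]
    dropped_codons: int = 0

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon lists differ in length")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ka: float | None
    Ks: float | None
    ratio: float | None
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return "ks_saturated" not in self.flags and "ka_saturated" not in self.flags


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -3/4 ln(1 - 4p/3).

    Monotone on [0, 0.75); raises SaturationError at or beyond p = 0.75.
    """
    if p < 0:
        raise ValueError(f"proportion must be nonnegative, got {p}")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 0.75: JC correction undefined")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes syn/(3 - to_stop) synonymous sites, where syn
    counts the amino-acid-preserving changes and to_stop the changes producing
    a stop codon; the three positions sum to s + n = 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no NG86 site decomposition")
    if codon not in AA:
        raise ValueError(f"invalid codon {codon!r}")
    s = 0.0
    for pos in range(3):
        syn = stops = 0
        for base in _codons.BASES:
            if base == codon[pos]:
                continue
            cls = _codons.change_class(codon, pos, base)
            if cls == _codons.TO_STOP:
                stops += 1
            elif cls == _codons.SYN:
                syn += 1
        if stops < 3:
            s += syn / (3 - stops)
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    For codons differing at k positions, every ordering of the k single-base
    steps is enumerated; orderings passing through a stop codon are excluded.
    If every ordering hits a stop, all orderings are averaged anyway (steps
    into/out of stops count as nonsynonymous) -- callers may flag such columns.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if c in STOP_CODONS or c not in AA:
            raise ValueError(f"invalid or stop codon {c!r}")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in permutations(diff_pos):
        current = a
        sd = nd = 0.0
        hit_stop = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                hit_stop = True
                nd += 1.0
            elif current in STOP_CODONS:
                hit_stop = True
                nd += 1.0
            elif AA[nxt] == AA[current]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        (fallback if hit_stop else valid).append((sd, nd))
    paths = valid if valid else fallback
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def align_codons(cds_a: str, cds_b: str) -> CodonAlignment:
    """Protein-guided codon alignment of two CDS.

    The translated proteins are globally aligned (BLOSUM62, affine gaps) and
    the alignment is back-translated to codons. Columns with a gap, an
    ambiguity code, or a stop codon in either sequence are dropped and
    counted. Raises TooShortError below 30 surviving codons.
    """
    from .io import translate  # local import to avoid a cycle

    ca, cb = _codons.codons_of(cds_a.upper()), _codons.codons_of(cds_b.upper())
    pa, pb = translate(cds_a), translate(cds_b)
    _, ga, gb = align_protein_pair(pa, pb)
    ia = ib = 0
    keep_a: list[str] = []
    keep_b: list[str] = []
    dropped = 0
    for x, y in zip(ga, gb):
        codon_a = ca[ia] if x != "-" else None
        codon_b = cb[ib] if y != "-" else None
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
        if codon_a is None or codon_b is None:
            dropped += 1
            continue
        if _has_ambiguity(codon_a) or _has_ambiguity(codon_b):
            dropped += 1
            continue
        if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
            dropped += 1
            continue
        keep_a.append(codon_a)
        keep_b.append(codon_b)
    if len(keep_a) < MIN_CODONS:
        raise TooShortError(
            f"only {len(keep_a)} aligned codons survive filtering (< {MIN_CODONS})"
        )
    return CodonAlignment(keep_a, keep_b, dropped)


def _has_ambiguity(codon: str) -> bool:
    return any(b not in "ACGT" for b in codon)


def compute_kaks(alignment: CodonAlignment) -> KaKsResult:
    """NG86 Ka, Ks and Ka/Ks for one codon alignment.

    Site counts are averaged over the two sequences; differences are summed
    over columns; Jukes-Cantor correction is applied to each proportion.
    Saturation and zero-synonymous-difference cases are flagged, not raised.
    """
    s_a = s_b = 0.0
    sd = nd = 0.0
    flags: list[str] = []
    for codon_a, codon_b in zip(alignment.codons_a, alignment.codons_b):
        s_a += ng86_sites(codon_a)[0]
        s_b += ng86_sites(codon_b)[0]
        d = ng86_differences(codon_a, codon_b)
        sd += d[0]
        nd += d[1]
    n_cod = alignment.n_codons
    S = 0.5 * (s_a + s_b)
    N = 3.0 * n_cod - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    ks = ka = None
    if sd == 0:
        flags.append("ks_zero")
    try:
        ks = jc_correct(pS)
    except SaturationError:
        flags.append("ks_saturated")
    try:
        ka = jc_correct(pN)
    except SaturationError:
        flags.append("ka_saturated")
    ratio = None
    if ks is not None and ka is not None and ks > 0:
        ratio = ka / ks
    if not flags:
        flags.append("ok")
    assert isclose(S + N, 3.0 * n_cod, rel_tol=0, abs_tol=1e-9)
    return KaKsResult(S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN,
                      Ka=ka, Ks=ks, ratio=ratio, flags=tuple(flags))


def kaks_pair(cds_a: str, cds_b: str) -> KaKsResult:
    """Convenience: align two CDS and estimate Ka/Ks in one call."""
    return compute_kaks(align_codons(cds_a, cds_b))
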