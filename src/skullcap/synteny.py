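"""Homologous gene pairs, colinearity (synteny) blocks, tandem arrays,
gene clusters and syntenic depth.

Homology search is an all-vs-all global protein alignment (BLOSUM62, affine
gaps) with a shared 5-mer prefilter and identity/coverage thresholds.
Colinearity chaining is a DAGchainer-style dynamic programme over gene-rank
anchors: unit anchor score, per-gene gap penalty, a maximum gene gap, and a
minimum anchor count per block; blocks may run parallel (same orientation)
or antiparallel (inverted).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._align import align_protein_pair, alignment_identity
from .io import Genome

__all__ = [
    "Anchor",
    "GeneCluster",
    "HomologyPair",
    "SyntenyBlock",
    "TandemArray",
    "align_proteins",
    "anchors_from_pairs",
    "chain_anchors",
    "chain_all",
    "detect_tandem_arrays",
    "find_gene_clusters",
    "find_homolog_pairs",
    "label_pairs",
    "syntenic_depth",
]

KMER = 5


@dataclass(frozen=True)
class HomologyPair:
    gene_a: str
    gene_b: str
    identity: float
    score: float
    relation: str  # cross_species | within_species

    def canonical(self) -> "HomologyPair":
        if self.relation == "within_species" and self.gene_b < self.gene_a:
            return HomologyPair(self.gene_b, self.gene_a, self.identity,
                                self.score, self.relation)
        return self


@dataclass(frozen=True)
class Anchor:
    chr_a: str
    chr_b: str
    ordinal_a: int
    ordinal_b: int
    pair: HomologyPair
    span_a: tuple[int, int] = (0, 0)  # bp interval of gene a
    span_b: tuple[int, int] = (0, 0)


@dataclass
class SyntenyBlock:
    anchors: list[Anchor]
    orientation: str  # same | inverted
    score: float

    def __post_init__(self) -> None:
        oa = [a.ordinal_a for a in self.anchors]
        ob = [a.ordinal_b for a in self.anchors]
        if any(y <= x for x, y in zip(oa, oa[1:])):
            raise ValueError("ordinal_a not strictly increasing")
        steps_b = [y - x for x, y in zip(ob, ob[1:])]
        if self.orientation == "same" and any(s <= 0 for s in steps_b):
            raise ValueError("ordinal_b not strictly increasing in a same block")
        if self.orientation == "inverted" and any(s >= 0 for s in steps_b):
            raise ValueError("ordinal_b not strictly decreasing in an inverted block")

    @property
    def chr_a(self) -> str:
        return self.anchors[0].chr_a

    @property
    def chr_b(self) -> str:
        return self.anchors[0].chr_b

    @property
    def span_a(self) -> tuple[int, int]:
        return (min(a.span_a[0] for a in self.anchors),
                max(a.span_a[1] for a in self.anchors))

    @property
    def span_b(self) -> tuple[int, int]:
        return (min(a.span_b[0] for a in self.anchors),
                max(a.span_b[1] for a in self.anchors))

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class TandemArray:
    genome: str
    chromosome: str
    members: list[str]  # coordinate order
    max_gap_bp: int


@dataclass
class GeneCluster:
    family: str
    chromosome: str
    members: list[str]
    window_bp: int


# ---------------------------------------------------------------- homology


def align_proteins(a: str, b: str) -> tuple[float, float, int]:
    """(score, percent identity, aligned columns) of a global alignment."""
    score, ga, gb = align_protein_pair(a, b)
    identity, cols = alignment_identity(ga, gb)
    return score, identity, cols


def _kmer_index(proteins: dict[str, str], k: int = KMER) -> dict[str, set[str]]:
    index: dict[str, set[str]] = defaultdict(set)
    for gid, seq in proteins.items():
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].add(gid)
    return index


def find_homolog_pairs(genome_a: Genome, genome_b: Genome,
                       min_identity: float = 40.0,
                       min_coverage: float = 0.5) -> list[HomologyPair]:
    """All-vs-all homolog search with a shared 5-mer prefilter.

    Candidate pairs must share at least one protein 5-mer; retained pairs
    meet the identity threshold over aligned columns and mutual coverage
    (aligned columns / length) in both sequences. When genome_a is genome_b
    the search runs in within-species mode: self-pairs are excluded and each
    unordered pair is reported once.
    """
    prot_a, prot_b = genome_a.proteins(), genome_b.proteins()
    if not prot_a or not prot_b:
        raise ValueError("empty proteome")
    within = genome_a is genome_b or (genome_a.name == genome_b.name)
    index_b = _kmer_index(prot_b)
    candidates: set[tuple[str, str]] = set()
    for gid_a, seq in prot_a.items():
        hits: set[str] = set()
        for i in range(len(seq) - KMER + 1):
            hits |= index_b.get(seq[i : i + KMER], set())
        for gid_b in hits:
            if within:
                if gid_a == gid_b:
                    continue
                candidates.add((min(gid_a, gid_b), max(gid_a, gid_b)))
            else:
                candidates.add((gid_a, gid_b))
    relation = "within_species" if within else "cross_species"
    pairs: list[HomologyPair] = []
    for gid_a, gid_b in sorted(candidates):
        pa, pb = prot_a[gid_a], prot_b[gid_b]
        score, identity, cols = align_proteins(pa, pb)
        if identity < min_identity:
            continue
        if cols / len(pa) < min_coverage or cols / len(pb) < min_coverage:
            continue
        pairs.append(HomologyPair(gid_a, gid_b, identity, score, relation))
    return pairs


# ---------------------------------------------------------------- chaining


def chain_anchors(anchors: list[Anchor], max_gap_genes: int = 25,
                  min_anchors: int = 5, match_score: float = 1.0,
                  gap_penalty: float = 0.05) -> list[SyntenyBlock]:
    """DAGchainer-style chaining of anchors from one chromosome pair.

    Anchor j extends a chain ending at i iff 0 < ordinal_a(j) - ordinal_a(i)
    <= max_gap_genes and the b-ordinal step lies in (0, max_gap_genes] (same
    orientation) or [-max_gap_genes, 0) (inverted). Chain score is
    sum(match) - gap_penalty * (skipped genes on both sides). Maximal-score
    chains are extracted iteratively; each anchor joins at most one block;
    blocks with fewer than min_anchors anchors are discarded. Blocks are
    returned sorted by score descending.
    """
    if not anchors:
        return []
    chroms = {(a.chr_a, a.chr_b) for a in anchors}
    if len(chroms) > 1:
        raise ValueError("anchors must come from a single chromosome pair")
    blocks: list[SyntenyBlock] = []
    remaining = list(anchors)
    while True:
        best = None
        for orientation in ("same", "inverted"):
            chain, score = _best_chain(remaining, orientation, max_gap_genes,
                                       match_score, gap_penalty)
            if chain and (best is None or score > best[1]):
                best = (chain, score, orientation)
        if best is None or len(best[0]) < min_anchors:
            break
        chain, score, orientation = best
        blocks.append(SyntenyBlock(anchors=chain, orientation=orientation,
                                   score=score))
        used = set(id(a) for a in chain)
        remaining = [a for a in remaining if id(a) not in used]
        if not remaining:
            break
    blocks.sort(key=lambda b: -b.score)
    return blocks


def _best_chain(anchors: list[Anchor], orientation: str, max_gap: int,
                match: float, gap_penalty: float
                ) -> tuple[list[Anchor], float]:
    """Highest-scoring single chain by dynamic programming."""
    order = sorted(range(len(anchors)),
                   key=lambda i: (anchors[i].ordinal_a, anchors[i].ordinal_b))
    n = len(order)
    score = [match] * n
    prev = [-1] * n
    for jj in range(n):
        j = order[jj]
        for ii in range(jj):
            i = order[ii]
            da = anchors[j].ordinal_a - anchors[i].ordinal_a
            db = anchors[j].ordinal_b - anchors[i].ordinal_b
            if not 0 < da <= max_gap:
                continue
            if orientation == "same":
                if not 0 < db <= max_gap:
                    continue
            else:
                if not -max_gap <= db < 0:
                    continue
            cand = score[ii] + match - gap_penalty * ((da - 1) + (abs(db) - 1))
            if cand > score[jj]:
                score[jj] = cand
                prev[jj] = ii
    if n == 0:
        return [], 0.0
    best_end = int(np.argmax(score))
    chain_idx = []
    k = best_end
    while k != -1:
        chain_idx.append(order[k])
        k = prev[k]
    chain = [anchors[i] for i in reversed(chain_idx)]
    return chain, score[best_end]


def anchors_from_pairs(genome_a: Genome, genome_b: Genome,
                       pairs: list[HomologyPair]
                       ) -> dict[tuple[str, str], list[Anchor]]:
    """Group homolog pairs into per-chromosome-pair anchor lists."""
    grouped: dict[tuple[str, str], list[Anchor]] = defaultdict(list)
    for p in pairs:
        ga, gb = genome_a.gene(p.gene_a), genome_b.gene(p.gene_b)
        anchor = Anchor(chr_a=ga.chromosome, chr_b=gb.chromosome,
                        ordinal_a=ga.ordinal, ordinal_b=gb.ordinal, pair=p,
                        span_a=(ga.start, ga.end), span_b=(gb.start, gb.end))
        grouped[(ga.chromosome, gb.chromosome)].append(anchor)
    return dict(grouped)


def chain_all(genome_a: Genome, genome_b: Genome, pairs: list[HomologyPair],
              **kwargs) -> list[SyntenyBlock]:
    """Chain every chromosome pair and pool the blocks, best first."""
    blocks: list[SyntenyBlock] = []
    grouped = anchors_from_pairs(genome_a, genome_b, pairs)
    for key in sorted(grouped):
        blocks.extend(chain_anchors(grouped[key], **kwargs))
    blocks.sort(key=lambda b: -b.score)
    return blocks


def label_pairs(blocks: list[SyntenyBlock], relation: str
                ) -> list[HomologyPair]:
    """One labeled syntenic pair per anchor of every retained block."""
    out = []
    for b in blocks:
        for a in b.anchors:
            p = a.pair
            if relation == "within_species" and p.gene_a == p.gene_b:
                continue
            out.append(HomologyPair(p.gene_a, p.gene_b, p.identity, p.score,
                                    relation))
    return out


# ---------------------------------------------------------------- tandem / clusters


def detect_tandem_arrays(genome: Genome, pairs: list[HomologyPair],
                         max_gap_bp: int = 30_000,
                         max_intervening_genes: int = 1) -> list[TandemArray]:
    """Tandem arrays: runs of mutually homologous neighbours on one chromosome.

    Homologous genes (connected components of the within-species pair graph)
    on the same chromosome are sorted by coordinate and linked while the
    physical gap stays below max_gap_bp and at most max_intervening_genes
    non-member genes intervene. Arrays of >= 2 members are reported.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in pairs:
        if p.gene_a in genome and p.gene_b in genome:
            ra, rb = find(p.gene_a), find(p.gene_b)
            if ra != rb:
                parent[ra] = rb
    families: dict[str, list[str]] = defaultdict(list)
    for gid in parent:
        families[find(gid)].append(gid)
    arrays: list[TandemArray] = []
    for root in sorted(families):
        members = families[root]
        by_chrom: dict[str, list] = defaultdict(list)
        for gid in members:
            g = genome.gene(gid)
            by_chrom[g.chromosome].append(g)
        for chrom in sorted(by_chrom):
            genes = sorted(by_chrom[chrom], key=lambda g: g.start)
            all_on_chrom = genome.genes_on(chrom)
            member_ids = {g.gene_id for g in genes}
            run = [genes[0]]
            for prev_g, g in zip(genes, genes[1:]):
                gap = g.start - prev_g.end
                between = [x for x in all_on_chrom
                           if prev_g.end <= x.start < g.start
                           and x.gene_id not in member_ids]
                if gap < max_gap_bp and len(between) <= max_intervening_genes:
                    run.append(g)
                else:
                    if len(run) >= 2:
                        arrays.append(TandemArray(genome.name, chrom,
                                                  [x.gene_id for x in run],
                                                  max_gap_bp))
                    run = [g]
            if len(run) >= 2:
                arrays.append(TandemArray(genome.name, chrom,
                                          [x.gene_id for x in run], max_gap_bp))
    return arrays


def find_gene_clusters(genome: Genome, family_members, window_bp: int = 500_000,
                       min_genes: int = 5, family: str = "family"
                       ) -> list[GeneCluster]:
    """Maximal windows of >= min_genes family genes within window_bp.

    A two-pointer scan finds every maximal run of family genes whose span
    (first start to last end) fits in the window; overlapping runs are
    merged into one cluster.
    """
    member_set = set(family_members)
    clusters: list[GeneCluster] = []
    for chrom in genome.chromosomes:
        genes = [g for g in genome.genes_on(chrom) if g.gene_id in member_set]
        if len(genes) < min_genes:
            continue
        runs: list[tuple[int, int]] = []
        j = 0
        for i in range(len(genes)):
            j = max(j, i)
            while j + 1 < len(genes) and genes[j + 1].end - genes[i].start <= window_bp:
                j += 1
            if j - i + 1 >= min_genes:
                runs.append((i, j))
        merged: list[list[int]] = []
        for i, j in runs:
            if merged and i <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], j)
            else:
                merged.append([i, j])
        for i, j in merged:
            clusters.append(GeneCluster(family=family, chromosome=chrom,
                                        members=[g.gene_id for g in genes[i:j + 1]],
                                        window_bp=window_bp))
    return clusters


# ---------------------------------------------------------------- depth


def syntenic_depth(blocks: list[SyntenyBlock], reference: Genome,
                   window_genes: int = 50, side: str = "b"
                   ) -> tuple[pd.DataFrame, int]:
    """Distinct-block coverage of fixed gene-rank windows on the reference.

    Each reference chromosome is cut into consecutive windows of
    ``window_genes`` ordinals; the depth of a window is the number of
    distinct blocks whose reference-side ordinal span overlaps it. Returns
    (per-window table, modal depth). Windows without blocks count as depth 0.
    """
    if side not in ("a", "b"):
        raise ValueError("side must be 'a' or 'b'")
    rows = []
    for chrom in reference.chromosomes:
        n = len(reference.genes_on(chrom))
        if n == 0:
            continue
        spans = []
        for bi, b in enumerate(blocks):
            bchrom = b.chr_b if side == "b" else b.chr_a
            if bchrom != chrom:
                continue
            ords = [a.ordinal_b if side == "b" else a.ordinal_a
                    for a in b.anchors]
            spans.append((bi, min(ords), max(ords)))
        for w0 in range(0, n, window_genes):
            w1 = min(w0 + window_genes, n)
            depth = sum(1 for _, lo, hi in spans if lo < w1 and hi >= w0)
            rows.append({"chromosome": chrom, "window_start_ordinal": w0,
                         "window_end_ordinal": w1, "depth": depth})
    table = pd.DataFrame(rows)
    if table.empty:
        return table, 0
    modal = int(table["depth"].mode().iloc[0])
    return table, modal


# ---------------------------------------------------------------- IO helpers


def pairs_to_frame(pairs: list[HomologyPair]) -> pd.DataFrame:
    return pd.DataFrame([{"gene_a": p.gene_a, "gene_b": p.gene_b,
                          "identity": p.identity, "score": p.score,
                          "relation": p.relation} for p in pairs])


def write_collinearity(blocks: list[SyntenyBlock], path) -> None:
    """MCScanX-like .collinearity text: block header line + anchor rows."""
    with open(path, "w") as fh:
        for i, b in enumerate(blocks):
            fh.write(f"## Alignment {i}: score={b.score:.2f} "
                     f"{b.chr_a}&{b.chr_b} {b.orientation} n={len(b)}\n")
            for j, a in enumerate(b.anchors):
                fh.write(f"{i}-{j}:\t{a.pair.gene_a}\t{a.pair.gene_b}\n")
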