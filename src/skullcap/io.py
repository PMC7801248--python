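"""Genome data model and FASTA/GFF3/BED/table input-output.

Coordinates are 0-based half-open in memory and 1-based inclusive in every
file written or read (GFF3 convention). All outputs are deterministically
ordered (chromosome, then start).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "Genome",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "translate",
    "reverse_complement",
]


def translate(cds: str) -> str:
    """Translate a CDS with the universal code; the terminal stop is dropped.

    An internal stop codon raises ValueError; the empty string translates to
    the empty string.
    """
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if not cds:
        return ""
    protein = str(Seq(cds.upper()).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError(f"internal stop codon at protein position {protein.index('*')}")
    return protein


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class GeneModel:
    """One protein-coding gene: coordinates, strand, CDS, protein, rank."""

    gene_id: str
    chromosome: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    cds: str
    ordinal: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def protein(self) -> str:
        return translate(self.cds)


class Genome:
    """An ordered collection of gene models indexable by id and by rank.

    Genes are kept sorted by (chromosome order, start); ordinals are the
    0-based ranks of the genes along their chromosome and are recomputed on
    every mutation of the gene set.
    """

    def __init__(self, name: str, genes: list[GeneModel],
                 chromosomes: list[str] | None = None) -> None:
        self.name = name
        if chromosomes is None:
            chromosomes = sorted({g.chromosome for g in genes})
        self.chromosomes = list(chromosomes)
        self._genes: list[GeneModel] = []
        self._by_id: dict[str, GeneModel] = {}
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            self._by_id[g.gene_id] = g
        order = {c: i for i, c in enumerate(self.chromosomes)}
        self._genes = sorted(genes, key=lambda g: (order.get(g.chromosome, 1 << 30),
                                                   g.start, g.gene_id))
        for g in self._genes:
            self._by_chrom.setdefault(g.chromosome, []).append(g)
        for chrom_genes in self._by_chrom.values():
            for i, g in enumerate(chrom_genes):
                g.ordinal = i

    @property
    def genes(self) -> list[GeneModel]:
        return list(self._genes)

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        return list(self._by_chrom.get(chromosome, []))

    def at(self, chromosome: str, ordinal: int) -> GeneModel:
        return self._by_chrom[chromosome][ordinal]

    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self._genes}

    def cds_map(self) -> dict[str, str]:
        return {g.gene_id: g.cds for g in self._genes}

    def subset(self, gene_ids) -> "Genome":
        keep = set(gene_ids)
        return Genome(self.name, [g for g in self._genes if g.gene_id in keep],
                      self.chromosomes)


# ---------------------------------------------------------------- FASTA


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {first-whitespace-token id: sequence}.

    Duplicate ids raise ValueError; an empty file returns {} with a warning.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    if not records:
        warnings.warn(f"no records found in {path}", stacklevel=2)
    return records


def write_fasta(seqs: dict[str, str], path, wrap: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


# ---------------------------------------------------------------- GFF3


def read_gff3(path, sequences: dict[str, str] | None = None,
              name: str | None = None) -> Genome:
    """Read gene/mRNA/CDS features into a Genome.

    If several mRNAs share a gene, the longest CDS is kept (logged). With
    ``sequences`` (chromosome id -> sequence) the CDS is extracted by
    coordinates, multi-exon CDS concatenated in transcription order and
    reverse-complemented on the minus strand. Genes whose CDS length is not
    divisible by 3, or with no CDS rows, are excluded with a warning.
    """
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    excluded = 0
    for gene in db.features_of_type("gene"):
        best_cds: list | None = None
        best_len = -1
        mrnas = list(db.children(gene, featuretype="mRNA")) or [gene]
        if len(mrnas) > 1:
            log.info("gene %s has %d mRNAs; keeping the longest CDS",
                     gene.id, len(mrnas))
        for mrna in mrnas:
            cds_rows = sorted(db.children(mrna, featuretype="CDS"),
                              key=lambda f: f.start)
            length = sum(f.end - f.start + 1 for f in cds_rows)
            if cds_rows and length > best_len:
                best_len, best_cds = length, cds_rows
        if not best_cds:
            warnings.warn(f"gene {gene.id} has no CDS rows; excluded", stacklevel=2)
            excluded += 1
            continue
        if best_len % 3:
            warnings.warn(f"gene {gene.id}: CDS length {best_len} not divisible "
                          "by 3; excluded", stacklevel=2)
            excluded += 1
            continue
        cds_seq = ""
        if sequences is not None:
            chrom_seq = sequences[gene.seqid]
            parts = [chrom_seq[f.start - 1 : f.end] for f in best_cds]
            cds_seq = "".join(parts)
            if gene.strand == "-":
                cds_seq = reverse_complement(cds_seq)
        genes.append(GeneModel(gene_id=gene.id, chromosome=gene.seqid,
                               start=gene.start - 1, end=gene.end,
                               strand=gene.strand, cds=cds_seq))
    if excluded:
        log.info("read_gff3: excluded %d genes", excluded)
    chroms = None
    if sequences is not None:
        chroms = list(sequences)
    return Genome(name or Path(str(path)).stem, genes, chroms)


def write_gff3(genome: Genome, path) -> None:
    """Write gene/mRNA/CDS rows, 1-based inclusive, ordered by (chrom, start)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            start, end = g.start + 1, g.end
            fh.write(f"{g.chromosome}\tskullcap\tgene\t{start}\t{end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.chromosome}\tskullcap\tmRNA\t{start}\t{end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n")
            fh.write(f"{g.chromosome}\tskullcap\tCDS\t{start}\t{end}\t.\t"
                     f"{g.strand}\t0\tID={g.gene_id}.cds;Parent={g.gene_id}.t1\n")


# ---------------------------------------------------------------- BED / tables


def write_bed(intervals, path) -> None:
    """Write (chrom, start, end, name[, score]) tuples as BED (0-based)."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_table(df, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
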