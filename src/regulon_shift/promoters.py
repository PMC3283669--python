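"""Promoter extraction from a genome and gene annotation.

A promoter is the region from the start codon up to ``max_len`` bp upstream
(800 bp by default), truncated where the next annotated gene is reached on
either strand.  The returned sequence reads 5'->3' toward the start codon,
i.e. minus-strand promoters are reverse complemented.  Coordinates are
0-based half-open internally; GFF3 input (1-based closed) is converted on
read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from regulon_shift.motifs import reverse_complement


@dataclass(frozen=True)
class GeneInterval:
    """One annotated gene: contig, [start, end) in 0-based half-open, strand."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: malformed interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")


@dataclass(frozen=True)
class PromoterRegion:
    """Upstream region of one gene, oriented 5'->3' on the coding strand.

    ``source`` records (contig, start, end, strand) of the genomic slice in
    0-based half-open coordinates.  Zero-length promoters (gene abutting its
    upstream neighbour) carry an empty sequence and ``is_empty`` True; they
    are kept in collections but excluded from density denominators by
    downstream code that filters on the flag.
    """

    gene_id: str
    sequence: str
    source: tuple[str, int, int, str]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_empty(self) -> bool:
        return not self.sequence


def read_genome(path) -> dict[str, str]:
    """Load a FASTA genome as a dict of contig name to uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gff_genes(path, feature_type: str = "gene") -> list[GeneInterval]:
    """Read gene intervals from GFF3, converting to 0-based half-open.

    Uses gffutils; the gene id is taken from the ID attribute (falling back
    to gene/Name).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type(feature_type):
        attrs = feat.attributes
        gene_id = (attrs.get("ID") or attrs.get("gene") or attrs.get("Name") or [feat.id])[0]
        genes.append(
            GeneInterval(gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
    return genes


def write_promoters_fasta(promoters: Sequence[PromoterRegion], path) -> None:
    with open(path, "w") as fh:
        for prom in promoters:
            fh.write(f">{prom.gene_id}\n{prom.sequence}\n")


def read_promoters_fasta(path) -> list[PromoterRegion]:
    """Read pre-extracted promoters; source coordinates are unknown."""
    promoters = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        promoters.append(PromoterRegion(rec.id, seq, ("?", 0, len(seq), "+")))
    return promoters


def extract_promoters(
    genome: Mapping[str, str],
    annotation: Iterable[GeneInterval],
    max_len: int = 800,
) -> list[PromoterRegion]:
    """Extract the upstream region of every annotated gene.

    For a +strand gene the region is [max(start - max_len, nearest upstream
    gene end, 0), start); for a -strand gene the mirror image downstream of
    its end, reverse complemented.  Truncation happens at the nearest
    boundary of ANY other annotated gene, regardless of its strand.  A gene
    whose neighbour abuts or overlaps its start gets an empty promoter.
    """
    genes = list(annotation)
    by_contig: dict[str, list[GeneInterval]] = {}
    for gene in genes:
        if gene.contig not in genome:
            raise KeyError(f"gene {gene.gene_id!r}: contig {gene.contig!r} not in genome")
        contig_len = len(genome[gene.contig])
        if gene.end > contig_len:
            raise ValueError(
                f"gene {gene.gene_id!r}: interval end {gene.end} beyond contig "
                f"length {contig_len}"
            )
        by_contig.setdefault(gene.contig, []).append(gene)

    promoters = []
    for gene in genes:
        others = [g for g in by_contig[gene.contig] if g is not gene]
        seq_contig = genome[gene.contig]
        if gene.strand == "+":
            lo = max(gene.start - max_len, 0)
            for other in others:
                # nearest boundary reaching into the candidate window
                if other.end <= gene.start:
                    lo = max(lo, other.end)
                elif other.start < gene.start:
                    lo = gene.start  # overlapping neighbour: empty promoter
            start, end = lo, gene.start
            seq = seq_contig[start:end]
        else:
            hi = min(gene.end + max_len, len(seq_contig))
            for other in others:
                if other.start >= gene.end:
                    hi = min(hi, other.start)
                elif other.end > gene.end:
                    hi = gene.end
            start, end = gene.end, hi
            seq = reverse_complement(seq_contig[start:end])
        promoters.append(
            PromoterRegion(gene.gene_id, seq.upper(), (gene.contig, start, end, gene.strand))
        )
    return promoters


def extract_promoters_from_files(
    genome_fasta, gff_path, max_len: int = 800, feature_type: str = "gene"
) -> list[PromoterRegion]:
    """Convenience wrapper: FASTA + GFF3 paths to promoter regions."""
    genome = read_genome(genome_fasta)
    annotation = read_gff_genes(gff_path, feature_type=feature_type)
    return extract_promoters(genome, annotation, max_len=max_len)
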