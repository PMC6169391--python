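"""Gene models and genome/annotation IO.

A :class:`GeneModel` is a single-transcript gene: ordered exons, a CDS
interval, and strand. Coordinates are 1-based fully-closed (GFF3
convention). Introns are derived, never stored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna import revcomp

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    transcript_id: str
    scaffold: str
    strand: str                       # '+' or '-'
    exons: tuple[Interval, ...]       # genomic order, ascending, 1-based closed
    cds_start: int                    # genomic min of the CDS
    cds_end: int                      # genomic max of the CDS

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for (a, b) in self.exons:
            if a > b:
                raise ValueError("exon interval reversed")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site (genomic coordinate)."""
        return self.start if self.strand == "+" else self.end

    @property
    def atg_pos(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        return self.cds_start if self.strand == "+" else self.cds_end

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Genomic intron intervals, ascending."""
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @property
    def introns_5to3(self) -> tuple[Interval, ...]:
        """Introns in transcript order (5'->3')."""
        ivs = self.introns
        return ivs if self.strand == "+" else tuple(reversed(ivs))

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def is_utr_intron(self, intron: Interval) -> bool:
        """True when the intron lies entirely upstream of the start codon."""
        if self.strand == "+":
            return intron[1] < self.cds_start
        return intron[0] > self.cds_end

    def intron_ordinal(self, intron: Interval) -> int:
        """1-based ordinal of an intron counted 5'->3' (UTR introns included)."""
        return self.introns_5to3.index(intron) + 1

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        """mRNA sequence (5'->3')."""
        seq = "".join(genome[self.scaffold][a - 1:b] for a, b in self.exons)
        return seq if self.strand == "+" else revcomp(seq)

    def exon_sequence(self, genome: dict[str, str], exon: Interval) -> str:
        """One exon's sequence in transcript orientation."""
        s = genome[self.scaffold][exon[0] - 1:exon[1]]
        return s if self.strand == "+" else revcomp(s)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _utr_pieces(gene: GeneModel) -> tuple[list[Interval], list[Interval]]:
    """(five_prime_UTR, three_prime_UTR) exon pieces in genomic coords."""
    five, three = [], []
    for a, b in gene.exons:
        lo = (a, min(b, gene.cds_start - 1))   # genomic-left of the CDS
        hi = (max(a, gene.cds_end + 1), b)     # genomic-right of the CDS
        for piece, left_side in ((lo, True), (hi, False)):
            if piece[0] > piece[1]:
                continue
            is_five = left_side if gene.strand == "+" else not left_side
            (five if is_five else three).append(piece)
    return five, three


def write_gff3(genes: list[GeneModel], path: str | Path,
               header_lines: list[str] | None = None) -> None:
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    for line in header_lines or []:
        buf.write(f"# {line}\n")
    for g in sorted(genes, key=lambda g: (g.scaffold, g.start)):
        def row(ftype, a, b, attrs):
            buf.write("\t".join([g.scaffold, "traptag", ftype, str(a), str(b),
                                 ".", g.strand, ".", attrs]) + "\n")
        row("gene", g.start, g.end, f"ID={g.gene_id}")
        row("mRNA", g.start, g.end, f"ID={g.transcript_id};Parent={g.gene_id}")
        for i, (a, b) in enumerate(g.exons, 1):
            row("exon", a, b, f"ID={g.transcript_id}.exon{i};Parent={g.transcript_id}")
            ca, cb = max(a, g.cds_start), min(b, g.cds_end)
            if ca <= cb:
                row("CDS", ca, cb, f"ID={g.transcript_id}.cds;Parent={g.transcript_id}")
        five, three = _utr_pieces(g)
        for j, (a, b) in enumerate(five, 1):
            row("five_prime_UTR", a, b,
                f"ID={g.transcript_id}.5utr{j};Parent={g.transcript_id}")
        for j, (a, b) in enumerate(three, 1):
            row("three_prime_UTR", a, b,
                f"ID={g.transcript_id}.3utr{j};Parent={g.transcript_id}")
    Path(path).write_text(buf.getvalue())


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 annotation back into :class:`GeneModel` objects."""
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = tuple(sorted((f.start, f.end)
                                 for f in db.children(mrna, featuretype="exon")))
            cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
            if not cds:
                raise ValueError(f"transcript {mrna.id} has no CDS")
            genes.append(GeneModel(
                gene_id=gene.id, transcript_id=mrna.id, scaffold=gene.seqid,
                strand=gene.strand, exons=exons,
                cds_start=min(a for a, _ in cds), cds_end=max(b for _, b in cds)))
    return genes
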