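"""Exact-match classification of paired-end reads into reporter fusions.

A read pair is called a promoter-trap fusion event when one mate spans
the splice junction (a genomic tag joined to the reporter's +1 prefix,
optionally through the 15-nt IRES tag) and the other mate lies deep
inside the reporter ORF. All matching is exact; the guarantees rest on
the reporter's leading k-mer being absent from the genome, which
:func:`verify_marker_uniqueness` asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dna import count_genome_hits, find_all, revcomp
from .genes import GeneModel


@dataclass(frozen=True)
class FinderParams:
    min_reporter_match: int = 14   # nt of the reporter +1 prefix in the junction mate
    min_mate_match: int = 47       # nt of exact reporter sequence in the other mate
    min_genomic_tag: int = 15      # nt of host sequence in the junction mate
    ires_tag: str | None = None    # 15-nt element tag abutting the reporter +1
    require_orientation: bool = True

    def __post_init__(self):
        for name in ("min_reporter_match", "min_mate_match", "min_genomic_tag"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.ires_tag is not None and len(self.ires_tag) != 15:
            raise ValueError("ires_tag must be exactly 15 nt")


@dataclass
class JunctionHit:
    pair_id: str
    junction_read: str                  # 'R1' or 'R2'
    reporter_match_len: int
    pre_junction_seq: str               # read sequence 5' of the reporter +1
    genomic_tag: str                    # pre-junction sequence after IRES-tag excision
    construct: str = "unresolved"       # non_IRES | IRES | unresolved
    junction_seq_context: str = ""      # <=21 nt of transcript ending at the fusion point
    mapped_locus: tuple[str, int, str] | None = None   # (scaffold, fusion pos, strand)
    multiplicity: int = 0
    junction_location: str = ""
    gene_id: str = ""
    acceptor_dinucleotide: str = ""


class PairingError(ValueError):
    pass


def verify_marker_uniqueness(genome: dict[str, str], reporter_orf: str,
                             k: int = 14) -> tuple[bool, list[tuple[str, int, str]]]:
    """True iff the reporter's first k nt occur nowhere in the genome, either strand."""
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    if k > len(reporter_orf):
        raise ValueError("k exceeds reporter length")
    hits = count_genome_hits(genome, reporter_orf[:k])
    return len(hits) == 0, hits


def _junction_candidate(seq: str, reporter: str, params: FinderParams
                        ) -> tuple[int, str] | None:
    """Reporter +1 prefix anchored in ``seq`` with the match running to the 3' end.

    Returns (reporter_match_len, pre_junction_seq) for the best (longest)
    valid anchor, or None.
    """
    prefix = reporter[:params.min_reporter_match]
    for p in find_all(seq, prefix):
        seg = seq[p:]
        if params.require_orientation:
            ok = seg == reporter[:len(seg)]
        else:
            ok = seg[:params.min_reporter_match] == prefix
            seg = seg[:next((i for i in range(len(seg))
                             if i >= len(reporter) or seg[i] != reporter[i]),
                            len(seg))]
        if ok and len(seg) >= params.min_reporter_match:
            return len(seg), seq[:p]
    return None


def _mate_matches_reporter(seq: str, reporter: str, min_len: int) -> bool:
    """Does ``seq`` carry an exact >= min_len nt substring of the reporter?"""
    for L in range(len(seq), min_len - 1, -1):
        for s in range(len(seq) - L + 1):
            if seq[s:s + L] in reporter:
                return True
    return False


def _excise_ires(pre: str, params: FinderParams) -> str:
    if params.ires_tag is not None and pre.endswith(params.ires_tag):
        return pre[:-len(params.ires_tag)]
    return pre


def classify_construct(hit: JunctionHit, params: FinderParams) -> str:
    """Which element produced a fusion, from the sequence abutting the +1.

    IRES when the full 15-nt tag is visible directly upstream of the
    reporter +1; non_IRES when any visible upstream base contradicts the
    tag; unresolved when fewer than 15 nt are visible and all of them
    are consistent with the tag's suffix.
    """
    pre = hit.pre_junction_seq
    tag = params.ires_tag
    if tag is None:
        return "non_IRES" if pre else "unresolved"
    if len(pre) >= len(tag):
        return "IRES" if pre.endswith(tag) else "non_IRES"
    if not pre or pre == tag[-len(pre):]:
        return "unresolved"           # too short to rule the tag in or out
    return "non_IRES"


def scan_read_pairs(pairs, reporter_orf: str, params: FinderParams,
                    ) -> list[JunctionHit]:
    """Classify read pairs into reporter-fusion junction hits.

    ``pairs`` is an iterable of ``(pair_id, r1, r2)``. A pair is emitted
    iff one mate anchors the reporter +1 prefix (>= min_reporter_match nt,
    running to its 3' end after orienting to the reporter strand), the
    other mate carries >= min_mate_match nt of exact reporter sequence on
    the opposite strand, and the junction mate retains a genomic tag of
    >= min_genomic_tag nt after excising the IRES tag. Pairs failing any
    rule are silently skipped.
    """
    reporter = reporter_orf.upper()
    hits: list[JunctionHit] = []
    for pair_id, r1, r2 in pairs:
        mates = {"R1": r1.upper(), "R2": r2.upper()}
        found = None
        for label in ("R1", "R2"):
            other = mates["R2" if label == "R1" else "R1"]
            for oriented, mate_oriented in (
                    (mates[label], revcomp(other)),    # junction mate on reporter strand
                    (revcomp(mates[label]), other)):
                cand = _junction_candidate(oriented, reporter, params)
                if cand is None:
                    continue
                match_len, pre = cand
                genomic = _excise_ires(pre, params)
                if len(genomic) < params.min_genomic_tag:
                    continue
                if not _mate_matches_reporter(mate_oriented, reporter,
                                              params.min_mate_match):
                    continue
                found = JunctionHit(
                    pair_id=pair_id, junction_read=label,
                    reporter_match_len=match_len, pre_junction_seq=pre,
                    genomic_tag=genomic,
                    junction_seq_context=genomic[-21:])
                break
            if found:
                break
        if found:
            found.construct = classify_construct(found, params)
            hits.append(found)
    return hits


def read_fastq_pairs(r1_path, r2_path):
    """Iterate id-matched read pairs from two FASTQ files."""
    from Bio import SeqIO
    it1 = SeqIO.parse(str(r1_path), "fastq")
    it2 = SeqIO.parse(str(r2_path), "fastq")
    for rec1, rec2 in zip(it1, it2, strict=True):
        id1 = rec1.id.removesuffix("/1")
        id2 = rec2.id.removesuffix("/2")
        if id1 != id2:
            raise PairingError(f"read id mismatch: {rec1.id} vs {rec2.id}")
        yield id1, str(rec1.seq).upper(), str(rec2.seq).upper()


def scan_fastq(r1_path, r2_path, reporter_orf: str, params: FinderParams
               ) -> list[JunctionHit]:
    return scan_read_pairs(read_fastq_pairs(r1_path, r2_path), reporter_orf, params)


# ---------------------------------------------------------------------------
# junction localization
# ---------------------------------------------------------------------------

def _junction_label(genes: list[GeneModel], scaffold: str, pos: int,
                    strand: str) -> tuple[str, str]:
    """(label, gene_id) for a fusion point at ``pos`` on ``strand``.

    '5'-UTR' when the fusion point lies upstream of the start codon,
    'Intron i of n' when it sits at the donor edge of intron i, 'exon'
    otherwise; 'unannotated' outside any gene.
    """
    cands = [g for g in genes
             if g.scaffold == scaffold and g.start <= pos <= g.end]
    same = [g for g in cands if g.strand == strand]
    cands = same or cands
    if not cands:
        return "unannotated", ""
    gene = min(cands, key=lambda g: abs(pos - g.tss))
    upstream_of_atg = (pos < gene.cds_start) if gene.strand == "+" else (pos > gene.cds_end)
    if upstream_of_atg:
        return "5'-UTR", gene.gene_id
    nxt = None
    for iv in gene.introns_5to3:
        past = (iv[0] > pos) if gene.strand == "+" else (iv[1] < pos)
        if past:
            nxt = iv
            break
    if nxt is not None:
        return (f"Intron {gene.intron_ordinal(nxt)} of {gene.n_introns}",
                gene.gene_id)
    return "exon", gene.gene_id


def locate_junction(hit: JunctionHit, genome: dict[str, str],
                    genes: list[GeneModel], min_tag: int = 15,
                    elements: dict | None = None) -> JunctionHit:
    """Exact-match the genomic tag (both strands) and annotate the fusion point.

    A unique hit maps the junction; multiple hits leave it unmapped with
    the multiplicity recorded. The acceptor dinucleotide is the element
    sequence immediately 5' of the construct's fusion point (canonically
    AG) when the element models are supplied.
    """
    tag = hit.genomic_tag
    if len(tag) < min_tag:
        raise ValueError(f"genomic tag shorter than min_tag={min_tag}")
    matches: list[tuple[str, int, str]] = []
    rc = revcomp(tag)
    for scaf, seq in genome.items():
        matches += [(scaf, i, "+") for i in find_all(seq, tag)]
        matches += [(scaf, i, "-") for i in find_all(seq, rc)]
    hit.multiplicity = len(matches)
    if len(matches) != 1:
        hit.mapped_locus = None
        return hit
    scaf, i0, strand = matches[0]
    # fusion point = transcript-3' end of the tag
    pos = i0 + len(tag) if strand == "+" else i0 + 1
    hit.mapped_locus = (scaf, pos, strand)
    hit.junction_location, hit.gene_id = _junction_label(genes, scaf, pos, strand)
    if elements is not None and hit.construct in elements:
        hit.acceptor_dinucleotide = elements[hit.construct].acceptor_dinucleotide
    return hit


def aggregate_hits(hits: list[JunctionHit]) -> pd.DataFrame:
    """Occurrence table of resolvable fusion events.

    Groups mapped hits by (gene, scaffold, fusion position, construct)
    and counts supporting read pairs; unmapped hits are summarized in a
    trailing row per construct.
    """
    rows = []
    for h in hits:
        if h.mapped_locus:
            scaf, pos, strand = h.mapped_locus
            rows.append({"gene_id": h.gene_id or "-", "construct": h.construct,
                         "locus": f"{scaf}:{pos}", "junction_location": h.junction_location})
        else:
            rows.append({"gene_id": "-", "construct": h.construct,
                         "locus": f"unmapped(x{h.multiplicity})",
                         "junction_location": "-"})
    if not rows:
        return pd.DataFrame(columns=["construct", "gene_id", "occurrences",
                                     "locus", "junction_location"])
    df = pd.DataFrame(rows)
    out = (df.groupby(["construct", "gene_id", "locus", "junction_location"])
           .size().rename("occurrences").reset_index())
    return out[["construct", "gene_id", "occurrences", "locus",
                "junction_location"]].sort_values(
        ["construct", "gene_id"]).reset_index(drop=True)
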