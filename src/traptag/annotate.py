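"""Insertion-site mapping and annotation against gene models.

Maps splinkerette flanking fragments back to the genome by exact match,
verifies the TTAA target site and element orientation, classifies each
insertion relative to the host transcript (5'-UTR intron / coding intron
i of n / exon / 3'-UTR / intergenic) and measures its distance to the
ORF start codon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dna import find_all, revcomp
from .genes import GeneModel

Interval = tuple[int, int]


class FlankFormatError(ValueError):
    """Flank does not begin with a recognizable element terminal tag."""


class AmbiguousFlankError(ValueError):
    def __init__(self, msg: str, multiplicity: int):
        super().__init__(msg)
        self.multiplicity = multiplicity


@dataclass
class InsertionRecord:
    insertion_id: str
    scaffold: str
    ttaa_start: int                 # 1-based start of the TTAA target site
    element_orientation: str        # '+' / '-' on the genome
    construct: str = ""             # 'IRES' / 'non_IRES' when known
    junction_is_ttaa: bool = True   # False -> integrity-flagged record
    line_id: str = ""


@dataclass
class FeatureCall:
    insertion_id: str
    feature_class: str              # five_prime_utr_intron | coding_intron |
                                    # exon | three_prime_utr | intergenic
    gene_id: str | None = None
    transcript_id: str | None = None
    intron_ordinal: int | None = None   # i of n_introns, 5'->3', UTR introns included
    n_introns: int | None = None
    reporting_orientation: bool | None = None
    distance_to_orf_start: float | None = None   # genomic bp, positive upstream
    spliced_distance_to_orf_start: float | None = None


# ---------------------------------------------------------------------------
# position classification (shared with the synthetic generator)
# ---------------------------------------------------------------------------

def classify_position(genes: list[GeneModel], scaffold: str, pos: int,
                      element_strand: str | None = None,
                      ) -> tuple[str, GeneModel | None, Interval | None]:
    """Feature class of a genomic position.

    When overlapping genes cover the position, a transcript in reporting
    orientation (same strand as ``element_strand``) wins; otherwise the
    transcript with the nearer transcription start.
    """
    hits = [g for g in genes
            if g.scaffold == scaffold and g.start <= pos <= g.end]
    if not hits:
        return "intergenic", None, None
    if len(hits) > 1 and element_strand is not None:
        reporting = [g for g in hits if g.strand == element_strand]
        hits = reporting or hits
    gene = min(hits, key=lambda g: abs(pos - g.tss))

    for iv in gene.introns:
        if iv[0] <= pos <= iv[1]:
            cls = "five_prime_utr_intron" if gene.is_utr_intron(iv) else "coding_intron"
            return cls, gene, iv
    # exonic: 3'-UTR when past the CDS in transcript direction
    past_cds = (pos > gene.cds_end) if gene.strand == "+" else (pos < gene.cds_start)
    return ("three_prime_utr" if past_cds else "exon"), gene, None


# ---------------------------------------------------------------------------
# flank mapping
# ---------------------------------------------------------------------------

def _match_tag(flank: str, element, min_tag: int = 20,
               tag_length: int = 30) -> tuple[str, str]:
    """Identify which element terminus starts the flank.

    Returns (side, genomic_portion). The tag reads outward from the
    terminus, i.e. the reverse complement of the start of the 5'
    terminus, or the end of the 3' terminus as-is.
    """
    for side in ("5p", "3p"):
        tag = element.terminal_tag(side, tag_length)
        for k in range(min(tag_length, len(flank)), min_tag - 1, -1):
            if flank[:k] == tag[:k]:
                return side, flank[k:]
    raise FlankFormatError(
        f"flank does not begin with >= {min_tag} nt of either element terminus")


def map_flank(flank_sequence: str, element, genome: dict[str, str],
              insertion_id: str = "", min_tag: int = 20) -> InsertionRecord:
    """Map one splinkerette fragment to a unique genomic TTAA site.

    Strips the element terminal tag, exact-matches the remaining genomic
    portion on both strands, requires a unique hit, and infers element
    orientation from which terminus was sequenced and the matched strand.
    A junction that is not TTAA is flagged, not rejected.
    """
    flank = flank_sequence.upper()
    side, genomic = _match_tag(flank, element, min_tag=min_tag)
    if len(genomic) < 8:
        raise FlankFormatError("genomic portion of flank too short to map")

    hits: list[tuple[str, int, str]] = []
    rc = revcomp(genomic)
    for scaf, seq in genome.items():
        hits += [(scaf, i, "+") for i in find_all(seq, genomic)]
        hits += [(scaf, i, "-") for i in find_all(seq, rc)]
    if not hits:
        raise AmbiguousFlankError("flank genomic portion not found in genome", 0)
    if len(hits) > 1:
        raise AmbiguousFlankError(
            f"flank genomic portion matches {len(hits)} loci", len(hits))

    scaf, i0, strand = hits[0]
    # the sequenced genomic portion begins at the duplicated TTAA, so a
    # plus-strand match starts at the TTAA and a minus-strand match ends at it
    if strand == "+":
        ttaa_start = i0 + 1
    else:
        ttaa_start = i0 + len(genomic) - 4 + 1
    orientation = "+" if (side == "3p") == (strand == "+") else "-"
    junction_ok = genomic[:4] == "TTAA"
    return InsertionRecord(insertion_id=insertion_id, scaffold=scaf,
                           ttaa_start=ttaa_start, element_orientation=orientation,
                           construct=getattr(element, "construct", ""),
                           junction_is_ttaa=junction_ok)


# ---------------------------------------------------------------------------
# feature calling
# ---------------------------------------------------------------------------

def distance_to_orf_start(rec: InsertionRecord, gene: GeneModel) -> int:
    """Genomic distance from the TTAA start to the start codon's first base.

    Positive when the insertion lies upstream (transcript direction) of
    the +1 ATG, negative when downstream.
    """
    if gene.strand == "+":
        return gene.atg_pos - rec.ttaa_start
    return rec.ttaa_start - gene.atg_pos


def spliced_distance_to_orf_start(rec: InsertionRecord, gene: GeneModel) -> int:
    """Exonic (mature-transcript) bases between the insertion and the +1 ATG."""
    lo, hi = sorted((rec.ttaa_start, gene.atg_pos))
    n = 0
    for a, b in gene.exons:
        n += max(0, min(b, hi - 1) - max(a, lo + 1) + 1)
    return n if distance_to_orf_start(rec, gene) >= 0 else -n


def call_feature(rec: InsertionRecord, genes: list[GeneModel]) -> FeatureCall:
    """Classify an insertion's TTAA site against the gene models.

    The classification point is the midpoint of the 4-bp target site
    (its second base). Intron ordinals count 5'-UTR and coding introns
    in one 5'->3' series per transcript.
    """
    pos = rec.ttaa_start + 1
    fclass, gene, intron = classify_position(genes, rec.scaffold, pos,
                                             element_strand=rec.element_orientation)
    if gene is None:
        return FeatureCall(insertion_id=rec.insertion_id, feature_class="intergenic")
    return FeatureCall(
        insertion_id=rec.insertion_id, feature_class=fclass,
        gene_id=gene.gene_id, transcript_id=gene.transcript_id,
        intron_ordinal=gene.intron_ordinal(intron) if intron else None,
        n_introns=gene.n_introns,
        reporting_orientation=(rec.element_orientation == gene.strand),
        distance_to_orf_start=distance_to_orf_start(rec, gene),
        spliced_distance_to_orf_start=spliced_distance_to_orf_start(rec, gene))


def annotate_flanks(flanks: pd.DataFrame, element_by_construct: dict,
                    genome: dict[str, str], genes: list[GeneModel],
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Map + call every flank fragment; one row per insertion side.

    Unmappable or ambiguous flanks are reported in the returned problem
    list rather than silently dropped.
    """
    rows, problems = [], []
    for r in flanks.itertuples():
        rec = None
        for element in element_by_construct.values():
            try:
                rec = map_flank(r.flank_sequence, element, genome,
                                insertion_id=r.insertion_id)
                break
            except FlankFormatError:
                continue
            except AmbiguousFlankError as e:
                problems.append(f"{r.insertion_id}/{r.side}: {e}")
                rec = None
                break
        if rec is None:
            if not any(p.startswith(f"{r.insertion_id}/{r.side}") for p in problems):
                problems.append(f"{r.insertion_id}/{r.side}: no element tag recognized")
            continue
        call = call_feature(rec, genes)
        rows.append({
            "insertion_id": r.insertion_id, "side": r.side,
            "scaffold": rec.scaffold, "ttaa_start": rec.ttaa_start,
            "element_orientation": rec.element_orientation,
            "construct": rec.construct,
            "junction_is_ttaa": rec.junction_is_ttaa,
            "feature_class": call.feature_class,
            "gene_id": call.gene_id or "",
            "intron_ordinal": call.intron_ordinal or 0,
            "n_introns": call.n_introns or 0,
            "reporting_orientation": bool(call.reporting_orientation),
            "distance_to_orf_start": call.distance_to_orf_start,
            "spliced_distance_to_orf_start": call.spliced_distance_to_orf_start,
        })
    return pd.DataFrame(rows), problems


def collapse_sides(annotated: pd.DataFrame) -> pd.DataFrame:
    """One row per insertion (the two splinkerette sides must agree)."""
    if annotated.empty:
        return annotated
    first = annotated.sort_values(["insertion_id", "side"]).groupby(
        "insertion_id", as_index=False).first()
    return first.drop(columns=["side"])


def tabulate_insertions(calls: pd.DataFrame,
                        arm_map: dict[str, str] | None = None) -> dict[str, pd.DataFrame]:
    """Screen-level tabulations of annotated insertions.

    Returns per-feature-class counts and fractions, intronic counts by
    ordinal, and per-scaffold (or per-chromosome-arm) counts.
    """
    if calls.empty:
        empty = pd.DataFrame()
        return {"by_feature_class": empty, "by_intron_ordinal": empty,
                "by_location": empty}
    by_class = (calls.groupby("feature_class").size()
                .rename("count").reset_index())
    by_class["fraction"] = by_class["count"] / by_class["count"].sum()

    intronic = calls[calls["intron_ordinal"] > 0]
    by_ordinal = (intronic.groupby("intron_ordinal").size()
                  .rename("count").reset_index())

    loc = calls["scaffold"]
    if arm_map is not None:
        loc = loc.map(lambda s: arm_map.get(s, "unplaced"))
    by_loc = loc.value_counts().rename("count").rename_axis(
        "arm" if arm_map is not None else "scaffold").reset_index()
    return {"by_feature_class": by_class, "by_intron_ordinal": by_ordinal,
            "by_location": by_loc}
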