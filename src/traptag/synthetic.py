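"""Synthetic promoter-trap screen data with a machine-readable truth set.

Generates a multi-scaffold genome with single-transcript gene models
(about half carrying a 5'-UTR intron), plants piggyBac promoter-trap
elements at TTAA tetranucleotides with the canonical target-site
duplication, simulates splinkerette flanking fragments (restriction
digest with BstYI or BglII) and 50-nt paired-end transcript reads
including reporter-fusion chimeras at the elements' splice acceptors.

Design choices the downstream analysis relies on:

* every intron starts GT, ends AG, has a pyrimidine-rich tract ahead of
  the terminal AG (so the acceptor matrix is learnable), and contains at
  least one TTAA;
* planted TTAA sites have a restriction site within 3 kb on both sides,
  sit >= 3.5 kb from scaffold ends, and are >= 8 kb apart, so every
  splinkerette fragment terminates in genuine flanking genome;
* chimeric read pairs are only produced for same-strand intronic
  insertions (an opposite-strand element cannot report);
* the genome is redrawn until the reporter's first 14 nt are absent from
  it on both strands, mirroring the uniqueness check the read classifier
  depends on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import classify_position
from .dna import ENZYME_SITES, count_genome_hits, enzyme_site_positions, find_all, revcomp
from .genes import GeneModel, write_fasta, write_gff3

# published construct sequences: the engineered (planned) 3' splice
# acceptor and the 21-nt window ending at the unplanned acceptor used by
# the IRES-carrying element (splice point 15 nt upstream of reporter +1)
PLANNED_SA = "TTCCCCCCTCCCAGCAG"
UNPLANNED_SA_WINDOW = "ATATCGTTAGTCTTTCAACAG"

FEATURE_CLASSES = ("five_prime_utr_intron", "coding_intron", "exon",
                   "three_prime_utr", "intergenic")

# per-construct planted feature-class mix, emulating the screen's
# observed insertion-site spectrum (~half in 5'-UTR introns, a strong
# first-intron preference, a few exonic and rare 3'-UTR events)
DEFAULT_CLASS_WEIGHTS = {
    "five_prime_utr_intron": 0.48,
    "coding_intron": 0.28,
    "exon": 0.11,
    "three_prime_utr": 0.04,
    "intergenic": 0.09,
}


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_scaffolds: int = 12
    scaffold_length: int = 400_000
    n_genes: int = 44
    frac_utr_intron: float = 0.5
    intron_length_range: tuple[int, int] = (200, 40_000)
    utr_intron_5p_distance_range: tuple[int, int] = (183, 44_882)
    n_insertions_per_construct: int = 20
    read_length: int = 50
    n_read_pairs: int = 4000
    chimera_fraction: float = 0.05
    enzyme: str = "BstYI"
    error_rate: float = 0.0

    def __post_init__(self):
        for name in ("n_scaffolds", "scaffold_length", "n_genes",
                     "n_insertions_per_construct", "read_length", "n_read_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_utr_intron", "chimera_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("intron_length_range", "utr_intron_5p_distance_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} must be an ordered non-negative pair")
        if self.enzyme not in ENZYME_SITES:
            raise ValueError(f"enzyme must be one of {sorted(ENZYME_SITES)}")


@dataclass(frozen=True)
class TrapElement:
    """The promoter-trap construct, modeled at sequence level.

    ``sa_offset`` conventions: offset of the fusion (splice) point
    relative to the reporter +1, so 0 means the spliced transcript joins
    genomic sequence directly to the reporter ATG and -15 means 15
    element nucleotides (the IRES tag) sit between the junction and +1.
    """
    reporter_orf: str
    left_terminus: str                 # piggyBac 5' terminal sequence (671 bp)
    right_terminus: str                # piggyBac 3' terminal sequence (690 bp)
    ires_tag: str | None = None        # 15-nt tag directly upstream of +1
    ires_body: str = ""                # IRES sequence ahead of the unplanned SA
    spacer: str = ""                   # marker cassette stand-in
    tail: str = ""                     # reporter 3' UTR stand-in
    planned_sa_offset: int = 0
    unplanned_sa_offset: int = -15

    def __post_init__(self):
        if len(self.left_terminus) != 671 or len(self.right_terminus) != 690:
            raise ValueError("piggyBac termini must be 671 bp (5') and 690 bp (3')")
        if self.ires_tag is not None and len(self.ires_tag) != 15:
            raise ValueError("IRES tag must be exactly 15 nt")
        if not self.reporter_orf.startswith("ATG"):
            raise ValueError("reporter ORF must start with ATG")

    @property
    def construct(self) -> str:
        return "IRES" if self.ires_tag is not None else "non_IRES"

    @property
    def sequence(self) -> str:
        """Full element sequence on the reporter's sense strand."""
        middle = self.spacer + PLANNED_SA
        if self.ires_tag is not None:
            middle += self.ires_body + UNPLANNED_SA_WINDOW + self.ires_tag
        return (self.left_terminus + middle + self.reporter_orf
                + self.tail + self.right_terminus)

    @property
    def fusion_offset(self) -> int:
        """Splice-point offset used by this construct's reporting fusions."""
        return self.unplanned_sa_offset if self.ires_tag is not None else self.planned_sa_offset

    @property
    def acceptor_dinucleotide(self) -> str:
        """Element dinucleotide immediately 5' of the fusion point."""
        if self.ires_tag is not None:
            return UNPLANNED_SA_WINDOW[-2:]
        return PLANNED_SA[-2:]

    def terminal_tag(self, side: str, length: int = 30) -> str:
        """Sequencing-primer-proximal tag reading outward from a terminus."""
        if side == "5p":
            return revcomp(self.left_terminus[:length])
        if side == "3p":
            return self.right_terminus[-length:]
        raise ValueError("side must be '5p' or '3p'")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_trap_elements(rng: np.random.Generator,
                       reporter_length: int = 300) -> dict[str, TrapElement]:
    """Draw a matched non-IRES / IRES element pair."""
    reporter = "ATG" + _rand_seq(rng, reporter_length - 3)
    left = _rand_seq(rng, 671)
    right = _rand_seq(rng, 690)
    spacer = _rand_seq(rng, 60)
    tail = _rand_seq(rng, 50)
    ires_body = _rand_seq(rng, 120)
    ires_tag = _rand_seq(rng, 15)
    non_ires = TrapElement(reporter_orf=reporter, left_terminus=left,
                           right_terminus=right, spacer=spacer, tail=tail)
    ires = TrapElement(reporter_orf=reporter, left_terminus=left,
                       right_terminus=right, ires_tag=ires_tag,
                       ires_body=ires_body, spacer=spacer, tail=tail)
    return {"non_IRES": non_ires, "IRES": ires}


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def _log_uniform(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo == hi:
        return lo
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _clamp(x: int, lo: int, hi: int) -> int:
    return max(lo, min(hi, x))


def _design_gene(rng: np.random.Generator, cfg: SyntheticConfig,
                 utr_intron: bool) -> dict:
    """Design one gene in transcript-local coordinates (1-based)."""
    ilo, ihi = cfg.intron_length_range
    exon_lens: list[int] = []
    intron_lens: list[int] = []

    exon1 = int(rng.integers(60, 151))
    if utr_intron:
        # target TSS->ATG genomic distance, log-uniform over the configured
        # range; realised via the 5'-UTR intron length where the intron
        # length range permits
        utr2 = int(rng.integers(20, 61))
        target = _log_uniform(rng, *cfg.utr_intron_5p_distance_range)
        utr_ilen = _clamp(target - exon1 - utr2, ilo, ihi)
    else:
        utr2 = 0
        utr_ilen = 0

    n_cds_exons = int(rng.integers(2, 4))          # 1-2 coding introns
    cds_lens = [int(rng.integers(90, 241)) for _ in range(n_cds_exons)]
    cds_lens = [l - l % 3 for l in cds_lens]       # keep frame tidy
    coding_ilens = [_clamp(_log_uniform(rng, ilo, ihi), ilo, ihi)
                    for _ in range(n_cds_exons - 1)]
    utr3 = int(rng.integers(80, 201))

    if utr_intron:
        exon_lens = [exon1, utr2 + cds_lens[0]] + cds_lens[1:-1] + [cds_lens[-1] + utr3]
        intron_lens = [utr_ilen] + coding_ilens
    else:
        exon_lens = [exon1 + cds_lens[0]] + cds_lens[1:-1] + [cds_lens[-1] + utr3]
        intron_lens = coding_ilens

    # local coordinates
    exons_local: list[tuple[int, int]] = []
    pos = 1
    for i, el in enumerate(exon_lens):
        exons_local.append((pos, pos + el - 1))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    total = pos - 1
    cds_local_start = exon1 + (utr_ilen + utr2 if utr_intron else 0) + 1
    cds_local_end = exons_local[-1][1] - utr3

    return {"exons_local": exons_local, "intron_lens": intron_lens,
            "total": total, "cds_local_start": cds_local_start,
            "cds_local_end": cds_local_end, "utr_intron": utr_intron}


def _render_gene_sequence(rng: np.random.Generator, design: dict) -> str:
    """Random local pre-mRNA sequence with splice signals and TTAA baked in."""
    seq = np.array(list(_rand_seq(rng, design["total"])))
    exons = design["exons_local"]
    pyr = np.array(list("CT"))
    for (a1, b1), (a2, _) in zip(exons, exons[1:]):
        istart, iend = b1 + 1, a2 - 1            # intron local coords, 1-based
        seq[istart - 1:istart + 1] = list("GT")   # donor
        # pyrimidine-rich tract then the terminal AG acceptor
        tract = rng.choice(pyr, size=15)
        mix = rng.random(15) < 0.80
        rand = np.array(list(_rand_seq(rng, 15)))
        seq[iend - 17:iend - 2] = np.where(mix, tract, rand)
        seq[iend - 2:iend] = list("AG")
        # guarantee a TTAA in the intron interior, clear of the signals
        interior = "".join(seq[istart + 9:iend - 25])
        if "TTAA" not in interior:
            mid = istart + 9 + max(0, (iend - 25 - istart - 9) // 2)
            seq[mid - 1:mid + 3] = list("TTAA")
    s, e = design["cds_local_start"], design["cds_local_end"]
    seq[s - 1:s + 2] = list("ATG")
    seq[e - 3:e] = list("TAA")
    # a plantable TTAA inside the coding sequence and the 3'-UTR, so exonic
    # and 3'-UTR insertions are always available to the truth set
    seq[s + 39:s + 43] = list("TTAA")
    last_end = exons[-1][1]
    seq[last_end - 40:last_end - 36] = list("TTAA")
    return "".join(seq)


def generate_genome(config: SyntheticConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[dict[str, str], list[GeneModel]]:
    """Random multi-scaffold genome plus single-transcript gene models.

    Deterministic for a fixed config seed. Raises if a scaffold cannot
    hold its share of genes.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    margin, gap_lo, gap_hi = 5000, 3000, 6000

    n_utr = round(config.frac_utr_intron * config.n_genes)
    flags = [True] * n_utr + [False] * (config.n_genes - n_utr)
    rng.shuffle(flags)

    scaffolds = {f"scaf{i + 1:02d}": np.array(list(_rand_seq(rng, config.scaffold_length)))
                 for i in range(config.n_scaffolds)}
    names = list(scaffolds)
    genes: list[GeneModel] = []
    cursors = {n: margin for n in names}

    for gi in range(config.n_genes):
        scaf = names[gi % len(names)]
        gstart = cursors[scaf] + int(rng.integers(gap_lo, gap_hi))
        design = None
        for _try in range(30):   # redesign an unluckily huge gene rather than fail
            cand = _design_gene(rng, config, flags[gi])
            if gstart + cand["total"] + margin <= config.scaffold_length:
                design = cand
                break
        if design is None:
            raise ValueError(
                f"scaffold {scaf} ({config.scaffold_length} bp) too short for "
                f"requested gene count")
        local_seq = _render_gene_sequence(rng, design)
        strand = "+" if rng.random() < 0.5 else "-"
        L = design["total"]
        placed = local_seq if strand == "+" else revcomp(local_seq)
        scaffolds[scaf][gstart - 1:gstart - 1 + L] = list(placed)

        def to_genomic(x: int) -> int:
            return gstart + x - 1 if strand == "+" else gstart + L - x

        exons = sorted(tuple(sorted((to_genomic(a), to_genomic(b))))
                       for a, b in design["exons_local"])
        cs = to_genomic(design["cds_local_start"])
        ce = to_genomic(design["cds_local_end"])
        gid = f"gene{gi + 1:03d}"
        genes.append(GeneModel(gene_id=gid, transcript_id=f"{gid}.t1",
                               scaffold=scaf, strand=strand,
                               exons=tuple(exons),
                               cds_start=min(cs, ce), cds_end=max(cs, ce)))
        cursors[scaf] = gstart + L
    genome = {n: "".join(a) for n, a in scaffolds.items()}
    return genome, genes


def generate_unique_marker_genome(config: SyntheticConfig, reporter_orf: str,
                                  k: int = 14, max_tries: int = 50,
                                  rng: np.random.Generator | None = None,
                                  ) -> tuple[dict[str, str], list[GeneModel]]:
    """Redraw the genome until the reporter's first k nt are absent (both strands)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    marker = reporter_orf[:k]
    for _ in range(max_tries):
        genome, genes = generate_genome(config, rng=rng)
        if not count_genome_hits(genome, marker):
            return genome, genes
    raise RuntimeError("could not draw a genome free of the reporter marker")


# ---------------------------------------------------------------------------
# insertion planting
# ---------------------------------------------------------------------------

def _class_counts(n: int, weights: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n insertions over feature classes."""
    raw = {c: n * w for c, w in weights.items()}
    counts = {c: int(v) for c, v in raw.items()}
    rem = n - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:rem]:
        counts[c] += 1
    return counts


def _eligible_ttaa_sites(genome: dict[str, str], genes: list[GeneModel],
                         edge_margin: int = 3500) -> dict[str, list[tuple[str, int]]]:
    """TTAA candidates bucketed by feature class, clear of scaffold ends."""
    buckets: dict[str, list[tuple[str, int]]] = {c: [] for c in FEATURE_CLASSES}
    for scaf, seq in genome.items():
        for i in find_all(seq, "TTAA"):
            pos = i + 1  # 1-based TTAA start
            if pos < edge_margin or pos > len(seq) - edge_margin:
                continue
            fclass, gene, intron = classify_position(genes, scaf, pos + 1)
            buckets[fclass].append((scaf, pos))
    return buckets


def _forbidden_zones(genes: list[GeneModel], chosen_sites: list[tuple[str, int]],
                     ) -> dict[str, list[tuple[int, int]]]:
    """Genomic intervals a planted restriction site must not disturb.

    Protects splice signals (donor start, acceptor tract), start/stop
    codons, and the chosen TTAA target sites themselves.
    """
    zones: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        zs = zones.setdefault(g.scaffold, [])
        for a, b in g.introns:
            zs.append((a, a + 9))          # donor end
            zs.append((b - 29, b))         # pyrimidine tract + AG
        zs.append((g.cds_start, g.cds_start + 2))
        zs.append((g.cds_end - 2, g.cds_end))
    for scaf, pos in chosen_sites:
        zones.setdefault(scaf, []).append((pos - 6, pos + 9))
    return zones


def _ensure_enzyme_sites(genome: dict[str, str], genes: list[GeneModel],
                         chosen: list[dict], enzyme: str, marker: str | None,
                         window: int = 1200) -> None:
    """Guarantee a recognition site within ``window`` bp on both sides of
    every chosen TTAA, writing an AGATCT (cut by both supported enzymes)
    into neutral sequence where none occurs naturally. Mutates ``genome``
    in place; base substitutions only, so no coordinate shifts.

    ``marker`` (the reporter's leading k-mer) is kept out of the edited
    neighbourhood so the uniqueness guarantee survives the edit.
    """
    zones = _forbidden_zones(genes, [(r["scaffold"], r["ttaa_start"]) for r in chosen])

    def blocked(scaf: str, a: int, b: int) -> bool:
        return any(not (b < za or a > zb) for za, zb in zones.get(scaf, []))

    for r in chosen:
        scaf, pos = r["scaffold"], r["ttaa_start"]
        seq = genome[scaf]
        i = pos - 1
        for side in ("left", "right"):
            if side == "left":
                region, rel0 = seq[max(0, i - window):i], max(0, i - window)
            else:
                region, rel0 = seq[i + 4:i + 4 + window], i + 4
            if enzyme_site_positions(region, enzyme):
                continue
            placed = False
            for off in range(window // 2, window - 10, 13):
                w0 = rel0 + off                      # 0-based write start
                a, b = w0 + 1, w0 + 6                # 1-based interval
                if blocked(scaf, a - 1, b + 1):
                    continue
                cand = seq[:w0] + "AGATCT" + seq[w0 + 6:]
                ctx = cand[max(0, w0 - 20):w0 + 26]
                if marker and (marker in ctx or revcomp(marker) in ctx):
                    continue
                seq = cand
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place a restriction site near {scaf}:{pos}")
        genome[scaf] = seq


def plant_insertions(genome: dict[str, str], genes: list[GeneModel],
                     elements: dict[str, TrapElement], config: SyntheticConfig,
                     rng: np.random.Generator | None = None,
                     class_weights: dict[str, float] | None = None,
                     min_spacing: int = 1500,
                     ) -> tuple[dict[str, str], pd.DataFrame]:
    """Insert elements at TTAA sites with target-site duplication.

    Each insertion replaces the single genomic TTAA with
    ``TTAA + element + TTAA``. Returns modified scaffolds and a truth
    table in ORIGINAL genome coordinates (plus the element span in
    modified coordinates, needed by the splinkerette simulator).

    NOTE: ``genome`` is adjusted in place where a chosen site lacks a
    nearby restriction site (base substitutions only, coordinates
    unchanged), so the returned truth set, the simulated flanks, and the
    genome the caller keeps stay mutually consistent.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    weights = class_weights or DEFAULT_CLASS_WEIGHTS
    buckets = _eligible_ttaa_sites(genome, genes)
    for c in buckets:
        rng.shuffle(buckets[c])

    chosen: list[dict] = []
    taken: dict[str, list[int]] = {s: [] for s in genome}

    def pick(fclass: str) -> tuple[str, int]:
        pool = buckets[fclass]
        while pool:
            scaf, pos = pool.pop()
            if all(abs(pos - p) >= min_spacing for p in taken[scaf]):
                taken[scaf].append(pos)
                return scaf, pos
        raise ValueError(f"no eligible TTAA site available in feature class {fclass!r}")

    counts = _class_counts(config.n_insertions_per_construct, weights)
    # scarce feature classes are drawn first so abundant ones cannot
    # crowd them out via the spacing rule
    demand = [(fclass, construct)
              for fclass in weights
              for construct in ("non_IRES", "IRES")
              for _ in range(counts.get(fclass, 0))]
    for k, (fclass, construct) in enumerate(demand):
        scaf, pos = pick(fclass)
        fclass2, gene, intron = classify_position(genes, scaf, pos + 1)
        # alternate orientation; bias genic picks toward same-strand so
        # enough insertions can report chimeric fusions
        if gene is not None:
            same = (k % 3) != 2
            strand = gene.strand if same else ("-" if gene.strand == "+" else "+")
        else:
            strand = "+" if k % 2 == 0 else "-"
        ordinal = gene.intron_ordinal(intron) if intron else None
        dist = None
        if gene is not None:
            dist = (gene.atg_pos - pos) if gene.strand == "+" else (pos - gene.atg_pos)
        chosen.append({
            "insertion_id": f"ins{k + 1:03d}", "scaffold": scaf,
            "ttaa_start": pos, "element_strand": strand,
            "orientation": ("na" if gene is None else
                            "same" if strand == gene.strand else "opposite"),
            "construct": construct,
            "gene_id": gene.gene_id if gene else "",
            "true_feature_class": fclass2,
            "intron_ordinal": ordinal if ordinal else 0,
            "n_introns": gene.n_introns if gene else 0,
            "true_distance_to_orf_start": dist if dist is not None else np.nan,
            "chimeric_read_ids": "",
        })

    # guarantee splinkerette termination near every chosen site
    marker = elements["non_IRES"].reporter_orf[:14] if "non_IRES" in elements else None
    _ensure_enzyme_sites(genome, genes, chosen, config.enzyme, marker)

    # splice elements in, per scaffold in descending coordinate order
    modified = dict(genome)
    for scaf in genome:
        rows = sorted((r for r in chosen if r["scaffold"] == scaf),
                      key=lambda r: -r["ttaa_start"])
        seq = genome[scaf]
        for r in rows:
            elem = elements[r["construct"]]
            placed = elem.sequence if r["element_strand"] == "+" else revcomp(elem.sequence)
            i = r["ttaa_start"] - 1
            assert seq[i:i + 4] == "TTAA"
            seq = seq[:i] + "TTAA" + placed + "TTAA" + seq[i + 4:]
        modified[scaf] = seq
        # modified-coordinate element span (shift by upstream insertions)
        for r in rows:
            shift = sum(len(elements[q["construct"]].sequence) + 4
                        for q in rows if q["ttaa_start"] < r["ttaa_start"])
            r["mod_elem_start"] = r["ttaa_start"] + shift + 4
            r["mod_elem_end"] = r["mod_elem_start"] + len(elements[r["construct"]].sequence) - 1

    truth = pd.DataFrame(chosen).sort_values("insertion_id").reset_index(drop=True)
    return modified, truth


# ---------------------------------------------------------------------------
# in-silico splinkerette
# ---------------------------------------------------------------------------

def simulate_splinkerette(modified: dict[str, str], truth: pd.DataFrame,
                          elements: dict[str, TrapElement], enzyme: str,
                          tag_length: int = 30) -> pd.DataFrame:
    """Element-terminus-to-first-restriction-site flanking fragments.

    One fragment per insertion side, reading element -> genome (fragments
    sequenced off the minus strand are reverse-complemented), prefixed by
    the terminal ``tag_length`` bp of the element. A side with no
    recognition site before the scaffold boundary is emitted truncated
    and flagged, not dropped.
    """
    if enzyme not in ENZYME_SITES:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    rows = []
    for r in truth.itertuples():
        seq = modified[r.scaffold]
        es, ee = r.mod_elem_start - 1, r.mod_elem_end  # 0-based half-open
        placed = seq[es:ee]
        left_sites = [p for p in enzyme_site_positions(seq[:es], enzyme) if p + 6 <= es - 4]
        right_rel = enzyme_site_positions(seq[ee + 4:], enzyme)

        if left_sites:
            p = max(left_sites)
            left_frag, left_trunc = revcomp(seq[p:es] + placed[:tag_length]), False
        else:
            left_frag, left_trunc = revcomp(seq[:es] + placed[:tag_length]), True
        if right_rel:
            p = min(right_rel)
            right_frag, right_trunc = placed[-tag_length:] + seq[ee:ee + 4 + p + 6], False
        else:
            right_frag, right_trunc = placed[-tag_length:] + seq[ee:], True

        # side labels follow the element's own termini
        if r.element_strand == "+":
            sides = (("5p", left_frag, left_trunc), ("3p", right_frag, right_trunc))
        else:
            sides = (("3p", left_frag, left_trunc), ("5p", right_frag, right_trunc))
        for side, frag, trunc in sides:
            rows.append({"insertion_id": r.insertion_id, "side": side,
                         "flank_sequence": frag, "truncated": trunc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paired-end reads
# ---------------------------------------------------------------------------

def _containing_intron(gene: GeneModel, pos: int) -> tuple[int, int] | None:
    for iv in gene.introns:
        if iv[0] <= pos <= iv[1]:
            return iv
    return None


def _upstream_exon(gene: GeneModel, intron: tuple[int, int]) -> tuple[int, int]:
    """Exon immediately 5' (transcript direction) of an intron."""
    idx = gene.introns.index(intron)
    return gene.exons[idx] if gene.strand == "+" else gene.exons[idx + 1]


def make_chimeric_pair(genome: dict[str, str], gene: GeneModel,
                       intron: tuple[int, int], element: TrapElement,
                       tag_len: int, mate_start: int, read_length: int,
                       flip: bool) -> tuple[str, str]:
    """One reporter-fusion read pair for an insertion in ``intron``.

    The junction mate carries ``tag_len`` genomic nt (the 3' end of the
    exon upstream of the insertion intron) spliced to the element's
    acceptor side: IRES tag + reporter +1 for the IRES construct, the
    reporter +1 directly otherwise. The other mate lies fully inside the
    reporter ORF. ``flip`` swaps which physical read carries the junction.
    """
    exon_seq = gene.exon_sequence(genome, _upstream_exon(gene, intron))
    if tag_len > len(exon_seq):
        raise ValueError("genomic tag longer than the upstream exon")
    tag = exon_seq[-tag_len:]
    insert = element.ires_tag if element.ires_tag is not None else ""
    junction = tag + insert + element.reporter_orf[:read_length - tag_len - len(insert)]
    mate = element.reporter_orf[mate_start:mate_start + read_length]
    if len(junction) != read_length or len(mate) != read_length:
        raise ValueError("read geometry does not fit the requested read length")
    if flip:
        return revcomp(mate), junction   # junction mate is R2
    return junction, revcomp(mate)       # junction mate is R1


def simulate_reads(genome: dict[str, str], genes: list[GeneModel],
                   truth: pd.DataFrame, elements: dict[str, TrapElement],
                   config: SyntheticConfig,
                   rng: np.random.Generator | None = None,
                   chimera_insertions: list[str] | None = None,
                   ) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Background transcript pairs plus reporter-fusion chimeras.

    Returns ``(pairs, truth)`` where pairs are ``(read_id, r1, r2)`` and
    the truth table gains the emitted chimeric read ids.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    R = config.read_length
    genes_by_id = {g.gene_id: g for g in genes}
    truth = truth.copy()
    truth["chimeric_read_ids"] = ""

    eligible = truth[(truth["orientation"] == "same")
                     & truth["true_feature_class"].isin(
                         ["five_prime_utr_intron", "coding_intron"])]
    if chimera_insertions is not None:
        req = truth[truth["insertion_id"].isin(chimera_insertions)]
        bad = req[req["orientation"] != "same"]
        if not bad.empty:
            raise ValueError(
                "chimeras requested for non-reporting (opposite-strand) insertions: "
                + ", ".join(bad["insertion_id"]))
        eligible = req

    n_chim = round(config.chimera_fraction * config.n_read_pairs)
    if n_chim > 0 and eligible.empty:
        raise ValueError("no same-strand intronic insertion available for chimeras")

    pairs: list[tuple[str, str, str]] = []
    chim_ids: dict[str, list[str]] = {i: [] for i in truth["insertion_id"]}
    elig_rows = list(eligible.itertuples())
    for k in range(n_chim):
        r = elig_rows[k % len(elig_rows)]
        gene = genes_by_id[r.gene_id]
        elem = elements[r.construct]
        intron = _containing_intron(gene, r.ttaa_start + 1)
        exon_len = (_upstream_exon(gene, intron)[1]
                    - _upstream_exon(gene, intron)[0] + 1)
        ires_len = 15 if elem.ires_tag is not None else 0
        gmax = min(R - 14 - ires_len, exon_len)
        tag_len = int(rng.integers(15, gmax + 1))
        mate_start = int(rng.integers(0, len(elem.reporter_orf) - R + 1))
        rid = f"chim_{r.insertion_id}_{k + 1}"
        r1, r2 = make_chimeric_pair(genome, gene, intron, elem, tag_len,
                                    mate_start, R, flip=bool(k % 2))
        pairs.append((rid, r1, r2))
        chim_ids[r.insertion_id].append(rid)

    transcripts = [g.spliced_sequence(genome) for g in genes]
    frag = max(2 * R + 10, 160)
    for k in range(config.n_read_pairs - n_chim):
        m = transcripts[int(rng.integers(0, len(transcripts)))]
        i = int(rng.integers(0, max(1, len(m) - frag + 1)))
        f = m[i:i + frag]
        r1, r2 = f[:R], revcomp(f[-R:])
        if k % 2:                               # opposite library strand
            r1, r2 = revcomp(f[-R:]), f[:R]
        pairs.append((f"bg{k + 1:06d}", r1, r2))

    if config.error_rate > 0:
        bases = "ACGT"
        noisy = []
        for rid, r1, r2 in pairs:
            def mutate(s: str) -> str:
                arr = list(s)
                for j in range(len(arr)):
                    if rng.random() < config.error_rate:
                        arr[j] = bases[int(rng.integers(0, 4))]
                return "".join(arr)
            noisy.append((rid, mutate(r1), mutate(r2)))
        pairs = noisy

    truth["chimeric_read_ids"] = truth["insertion_id"].map(
        lambda i: ",".join(chim_ids[i]))
    return pairs, truth


def write_fastq_pair(pairs: list[tuple[str, str, str]], r1_path: str | Path,
                     r2_path: str | Path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for rid, r1, r2 in pairs:
            f1.write(f"@{rid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    elements: dict[str, TrapElement]
    modified: dict[str, str]
    truth: pd.DataFrame
    flanks: pd.DataFrame
    pairs: list[tuple[str, str, str]]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fasta",
            "gff": out / "annotation.gff3",
            "modified": out / "genome_with_insertions.fasta",
            "truth": out / "truth.tsv",
            "flanks": out / "flanks.fasta",
            "r1": out / "reads_R1.fastq",
            "r2": out / "reads_R2.fastq",
            "element": out / "elements.fasta",
        }
        write_fasta(self.genome, paths["genome"])
        write_gff3(self.genes, paths["gff"])
        write_fasta(self.modified, paths["modified"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        write_fasta({f"{r.insertion_id}_{r.side}": r.flank_sequence
                     for r in self.flanks.itertuples()}, paths["flanks"])
        write_fastq_pair(self.pairs, paths["r1"], paths["r2"])
        elem_seqs = {}
        for name, e in self.elements.items():
            elem_seqs[f"{name}_reporter"] = e.reporter_orf
            elem_seqs[f"{name}_element"] = e.sequence
            if e.ires_tag is not None:
                elem_seqs[f"{name}_tag"] = e.ires_tag
        write_fasta(elem_seqs, paths["element"])
        return paths


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full synthetic screen: genome, insertions, flanks, and reads."""
    ss = np.random.SeedSequence(config.seed)
    r_elem, r_genome, r_plant, r_reads = (np.random.default_rng(s)
                                          for s in ss.spawn(4))
    elements = make_trap_elements(r_elem)
    genome, genes = generate_unique_marker_genome(
        config, elements["non_IRES"].reporter_orf, rng=r_genome)
    modified, truth = plant_insertions(genome, genes, elements, config, rng=r_plant)
    flanks = simulate_splinkerette(modified, truth, elements, config.enzyme)
    pairs, truth = simulate_reads(genome, genes, truth, elements, config, rng=r_reads)
    return SyntheticDataset(config=config, genome=genome, genes=genes,
                            elements=elements, modified=modified, truth=truth,
                            flanks=flanks, pairs=pairs)
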