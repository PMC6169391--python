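# Methods

## The screen being modeled

A piggyBac element carrying a promoterless reporter ORF behind a 3′ splice
acceptor (3′-SA) is remobilized through a host genome. piggyBac integrates
at TTAA tetranucleotides and duplicates the TTAA on both flanks; on
excision it restores the site precisely. The element reports when three
conditions coincide: it sits inside a transcribed gene, its reporter strand
matches the transcript strand, and the spliceosome joins the host's
upstream splice donor to the element's acceptor. Two construct variants are
modeled: a plain splice-acceptor element whose acceptor
(`TTCCCCCCTCCCAGCAG`) abuts the reporter +1 directly, and an IRES-carrying
element in which an unplanned acceptor (`ATATCGTTAGTCTTTCAACAG`) splices 15
nt upstream of the reporter +1, leaving a 15-nt element tag in the mRNA
that discriminates the two constructs in fusion reads.

Insertions are located two ways, mirroring the experimental design:

* **DNA level** — splinkerette PCR: genomic DNA is cut with BstYI
  (recognition `RGATCY`) or BglII (`AGATCT`), and fragments running from an
  element terminus into flanking genome are sequenced outward from the
  element. Both recognition sequences are degenerate-palindromic, so one
  strand is scanned.
* **RNA level** — paired-end 50-nt transcript reads are screened for
  reporter-fusion chimeras by exact matching.

## Junction classification rules

A read pair is a fusion event iff:

1. one mate (the junction mate) contains the reporter's +1 prefix, exact,
   ≥ 14 nt, anchored so the reporter segment runs to the read's 3′ end
   after orienting the read to the reporter strand ("oriented toward its
   mate pair" is operationalized as genomic tag 5′, reporter 3′, with the
   other mate on the opposite strand of the fusion transcript — the
   geometry of a fragment whose second mate lies deeper in the reporter);
2. the other mate is an exact substring of the reporter, ≥ 47 nt;
3. the junction mate's non-reporter segment, after excising a terminal
   15-nt IRES tag when present, is ≥ 15 nt of host sequence.

All matching is exact, with no mismatch tolerance; the classifier's
zero-false-positive property follows from the reporter's leading 14-mer
being absent from the genome on both strands, which is asserted before
scanning. Internal reporter matches (prefix not reaching the read end) are
rejected as junction evidence. Construct calls: IRES iff the full 15-nt tag
abuts the reporter +1; non-IRES iff any visible upstream base contradicts
the tag; unresolved when fewer than 15 nt are visible and all agree with
the tag suffix. Genomic tags are exact-matched against both strands;
multi-mapping tags are reported with their multiplicity but excluded from
downstream statistics. The fusion-point label is "5′-UTR" when the point
lies upstream of the start codon, otherwise "Intron *i* of *n*" for the
intron at whose donor edge the transcript fused. The acceptor dinucleotide
recorded for each mapped junction is the element sequence immediately 5′ of
the construct's splice point (canonically AG); non-AG junctions are visible
in the output rather than rejected, since the acceptor identity is a
property being measured, not enforced.

## Insertion annotation

Flank mapping requires a ≥ 20-nt exact match to an element terminal tag
(the reverse complement of the 5′ terminus start, or the 3′ terminus end,
as sequenced outward), then a unique exact match of the remaining genomic
portion on either strand. The genomic portion begins at the duplicated
TTAA, so a unique match pins the 1-based TTAA start; element orientation
follows from which terminus was sequenced and the matched strand. A
non-TTAA junction flags the record without dropping it.

Feature calling classifies the target-site midpoint (second base of the
TTAA). Intron ordinals count 5′-UTR and coding introns in one 5′→3′ series
per transcript, since a bare "intron *i* of *n*" label cannot distinguish
them. Overlapping genes are resolved by preferring the transcript in
reporting orientation, then the nearer transcription start. Distance to the
ORF start is the genomic-coordinate distance from the TTAA start to the
first base of the start codon, positive upstream; a spliced
(mature-transcript) distance is emitted alongside because either convention
is defensible for reporting upstream insertion spans. The insertion point
is the TTAA start regardless of element orientation, giving one canonical
coordinate per event.

## Splice-acceptor matrix

Training windows are the last *w* nucleotides of every annotated intron
(default *w* = 21, ending at the intron-terminal AG); shorter introns are
skipped and counted. Frequencies use a Laplace pseudocount of 1 by default
(0 permitted); per-position conservation is information content
IC_i = 2 + Σ_b p_i(b) log₂ p_i(b) ∈ [0, 2] bits. Two scoring modes exist
because "conservation by position" does not pin down an arithmetic:
frequency-weighted (default), score = Σ IC_i · p_i(s_i), and a
consensus-indicator mode, score = Σ IC_i · [s_i = consensus_i]. Under both,
the per-position consensus attains the matrix maximum, and shorter
sequences are right-aligned to the acceptor end with uncovered positions
contributing zero (acceptor-proximal anchoring — the biologically fixed end
is the terminal AG). `load_matrix` accepts an external per-base matrix TSV
so a published scoring table can be loaded and scored under either mode;
no published matrix ships with the package.

## Screen statistics

Remobilization frequency is 100 × events/screened, rounded half-up to two
decimals for presentation (unrounded values carried internally), with an
exact (Clopper–Pearson) binomial 95% CI as an auxiliary. Chi-square
goodness of fit uses Pearson's statistic with df = k − 1 and warns when any
expected count is below 5. The intron-position test's null makes every
intron of each hit gene equally likely, so a gene with *n* introns
contributes 1/*n* to each ordinal; the category layout is configurable
(per-ordinal with pooling above a cutoff, or first-vs-rest) because the
appropriate grouping depends on how many distinct ordinals a screen
observes. The local-hopping null defaults to uniform across chromosome
arms, with arm-length-proportional expectations available as an option.
Distance summaries are five-number summaries; the even-*n* median is the
mean of the central pair.

## Synthetic data generator

The generator is the package's validation instrument: it produces data
with the statistical structure the analysis assumes, plus a truth table,
so the pipeline's recovery properties are measurable rather than asserted.

Defaults (one value per knob, chosen once):

| parameter | default | rationale |
|---|---|---|
| scaffolds × length | 12 × 400 kb | enough room for genes with up to ~45 kb 5′-UTR spans |
| genes | 44 | capacity for the planted insertion mix at any seed |
| fraction with 5′-UTR intron | 0.5 | about half of trapped genes carried one |
| TSS→ATG distance range | 183–44,882 bp, log-uniform | matches the observed upstream-span range; log-uniform puts the median near the observed ~2.6 kb |
| intron length range | 200–40,000 bp | governs all introns; the 5′-UTR intron length is derived from the distance draw and clamped into this range |
| insertions per construct | 20 | ≥ 40 events total, both constructs, both orientations |
| read length / pairs / chimera fraction | 50 nt / 4000 / 0.05 | short-read transcript data with a few hundred fusion pairs |
| sequencing error rate | 0 | the classifier is exact-match; an error model is available but off |

Construction guarantees the analysis relies on: every intron starts GT,
ends AG, and carries a pyrimidine-rich tract before the terminal AG (so the
acceptor matrix is learnable); every intron, each gene's CDS, and each
3′-UTR contain a TTAA; the genome is redrawn until the reporter's first
14 nt are absent on both strands; planted TTAA sites sit ≥ 3.5 kb from
scaffold ends and ≥ 1.5 kb apart, and a restriction site is guaranteed
within 1.2 kb on both sides of each insertion (written into neutral
sequence when none occurs naturally — base substitutions only, clear of
splice signals, start/stop codons, and the reporter marker), so every
splinkerette fragment terminates in mappable flanking genome and
truth recovery is deterministic at any seed. Insertions replace the single
genomic TTAA with TTAA + element + TTAA (the canonical target-site
duplication; truth coordinates stay in original-genome coordinates).
Chimeric read pairs are produced only for same-strand intronic insertions —
an opposite-strand element cannot report, and requesting a chimera for one
is an error. The junction mate's host tag is drawn entirely from the exon
adjacent to the insertion intron (15 nt up to the read's capacity), so
tags map contiguously. Background pairs are drawn uniformly from spliced
transcripts (approximating poly-A selection); they cannot contain the
reporter prefix, which is what makes the zero-false-positive acceptance
check a structural property rather than a lucky draw.

What the generator does **not** emulate: base-quality structure, indels,
PCR duplicates, polymorphism, expression-level variation between genes,
multi-isoform genes, or 3′-UTR introns. Passing tests therefore demonstrate
the correctness of the classification logic and coordinate arithmetic under
clean data — not robustness to sequencing artifacts, which the exact-match
design deliberately trades away (on real data, reads failing exact match
are simply not counted, mirroring the original analysis).

## Pipeline and determinism

`traptag run` executes the stages in dependency order with file-based
handoffs; every TSV carries the tool version, seed, and a hash of the
scientific parameters, and a manifest records sha256 checksums — two runs
with the same config and seed reproduce every checksum. All randomness
derives from the single top-level seed via spawned generator streams.

Problem sizes used by the test suite and the acceptance script (a
full-scale synthetic screen of 12 × 400 kb scaffolds, 44 genes, 40
insertions, 4000 read pairs; 2000 null replicates for the chi-square
calibration; 10,000 random 21-mers for the score bound) were chosen as
desk-scale equivalents of the original screen's analyses and run in well
under a minute each.

## Validating against the original deposited data

The deposited short-read archive (SRA accession SRR3195175) and the AsteS1
assembly can validate the junction finder at full scale: trim adapters,
extract unmapped read pairs, and run `traptag find-junctions` with the
AmCyan ORF as the reporter and the published 15-nt IRES-proximal tag; the
published analysis recovered 145 fusion pairs (112 non-IRES + 33 IRES)
under the same 14/47/15-nt thresholds. This requires a multi-gigabyte
download and external alignment tooling, so it is documented here as a
manual integration procedure rather than an automated test.

## Known limitations

* Exact matching means a single sequencing error in the diagnostic
  segments silently drops a pair; sensitivity on real data is bounded by
  per-base accuracy, and the optional error-rate knob exists precisely to
  measure that decay on synthetic data.
* The annotator classifies against single-isoform gene models; with
  multi-isoform annotations the longest transcript should be supplied.
* The acceptor matrix models only the 21-nt acceptor-proximal window — no
  branch point or extended polypyrimidine tract.
* Published per-insertion coordinates and the published acceptor scoring
  table are not bundled; where they are available to a user, the
  insertions TSV schema and `pssm.load_matrix` accept them directly.
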