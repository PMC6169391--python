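"""Reporter-fusion read classification: marker uniqueness, threshold
boundaries, construct discrimination, and junction localization."""

import dataclasses

import pytest

from traptag.dna import revcomp
from traptag.junctions import (FinderParams, JunctionHit, PairingError,
                               aggregate_hits, classify_construct,
                               locate_junction, read_fastq_pairs,
                               scan_read_pairs, verify_marker_uniqueness)

def _seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# deterministic toy sequences; the module-level assertions pin the
# no-cross-match properties every engineered-pair test relies on
import numpy as np

_rng = np.random.default_rng(20180822)
REPORTER = "ATG" + _seq(_rng, 117)
IRES_TAG = _seq(_rng, 15)
GENOMIC = _seq(_rng, 160)

assert REPORTER[:14] not in GENOMIC and revcomp(REPORTER[:14]) not in GENOMIC
assert revcomp(REPORTER[:14]) not in REPORTER
assert IRES_TAG not in GENOMIC and IRES_TAG not in REPORTER


def make_pair(tag_len=20, reporter_len=30, ires=False, mate_len=50,
              mate_offset=5, flip=False):
    """Engineer one fusion pair with controllable segment lengths."""
    insert = IRES_TAG if ires else ""
    junction = GENOMIC[-tag_len:] + insert + REPORTER[:reporter_len]
    mate = REPORTER[mate_offset:mate_offset + mate_len]
    if flip:
        return "p", revcomp(mate), junction
    return "p", junction, revcomp(mate)


@pytest.fixture()
def params():
    return FinderParams(ires_tag=IRES_TAG)


class TestMarkerUniqueness:
    def test_absent_marker_reports_clean(self):
        ok, hits = verify_marker_uniqueness({"s": GENOMIC}, REPORTER, 14)
        assert ok and hits == []

    def test_planted_marker_is_found_once(self):
        g = {"s": GENOMIC + REPORTER[:14] + GENOMIC}
        ok, hits = verify_marker_uniqueness(g, REPORTER, 14)
        assert not ok and len(hits) == 1
        scaf, pos, strand = hits[0]
        assert (scaf, pos, strand) == ("s", len(GENOMIC) + 1, "+")
        # minus-strand plant is also caught
        g2 = {"s": GENOMIC + revcomp(REPORTER[:14]) + GENOMIC}
        ok2, hits2 = verify_marker_uniqueness(g2, REPORTER, 14)
        assert not ok2 and hits2[0][2] == "-"

    def test_full_orf_query_with_partial_prefix_only(self):
        # brute-force oracle: no window of the genome equals the full ORF
        g = {"s": GENOMIC + REPORTER[:40] + GENOMIC}
        ok, hits = verify_marker_uniqueness(g, REPORTER, len(REPORTER))
        seq = g["s"]
        oracle = any(seq[i:i + len(REPORTER)] in (REPORTER, revcomp(REPORTER))
                     for i in range(len(seq) - len(REPORTER) + 1))
        assert ok and not oracle

    def test_empty_genome_is_an_error(self):
        with pytest.raises(ValueError):
            verify_marker_uniqueness({}, REPORTER, 14)


class TestScanThresholds:
    def test_minimal_passing_pair(self, params):
        hits = scan_read_pairs([make_pair(tag_len=15, reporter_len=14,
                                          mate_len=47)], REPORTER, params)
        assert len(hits) == 1
        h = hits[0]
        assert h.reporter_match_len == 14
        assert h.genomic_tag == GENOMIC[-15:]
        assert h.construct == "non_IRES"

    @pytest.mark.parametrize("kwargs,expected", [
        (dict(tag_len=15, reporter_len=14, mate_len=47), 1),   # at thresholds
        (dict(tag_len=15, reporter_len=13, mate_len=47), 0),   # 13-nt reporter
        (dict(tag_len=15, reporter_len=14, mate_len=46), 0),   # 46-nt mate
        (dict(tag_len=14, reporter_len=14, mate_len=47), 0),   # 14-nt tag
        (dict(tag_len=14, reporter_len=15, mate_len=47), 0),   # still short tag
    ])
    def test_paper_threshold_boundaries(self, params, kwargs, expected):
        """13/14-nt reporter, 46/47-nt mate and 14/15-nt tag flip acceptance."""
        assert len(scan_read_pairs([make_pair(**kwargs)], REPORTER, params)) == expected

    def test_ires_tag_is_excised_before_tag_length_check(self, params):
        # 15 genomic + 15 IRES + 14 reporter: passes; 14 genomic + IRES: fails
        ok = make_pair(tag_len=15, reporter_len=50 - 30, ires=True)
        short = make_pair(tag_len=14, reporter_len=50 - 29, ires=True)
        assert len(scan_read_pairs([ok], REPORTER, params)) == 1
        assert len(scan_read_pairs([short], REPORTER, params)) == 0

    def test_orientation_requirement_rejects_internal_reporter_segment(self, params):
        # reporter prefix not at the junction read's 3' side
        junction = GENOMIC[-15:] + REPORTER[:14] + GENOMIC[:21]
        mate = revcomp(REPORTER[5:52])
        assert scan_read_pairs([("p", junction, mate)], REPORTER, params) == []

    def test_junction_mate_may_be_either_read(self, params):
        flipped = make_pair(tag_len=20, reporter_len=30, flip=True)
        hits = scan_read_pairs([flipped], REPORTER, params)
        assert len(hits) == 1 and hits[0].junction_read == "R2"

    def test_mate_pair_must_lie_on_opposite_strand(self, params):
        # both mates on the same strand of the fusion transcript: rejected
        junction = GENOMIC[-20:] + REPORTER[:30]
        mate_same_strand = REPORTER[5:55]
        assert scan_read_pairs([("p", junction, mate_same_strand)],
                               REPORTER, params) == []


class TestConstructCalls:
    def make_hit(self, pre):
        return JunctionHit(pair_id="p", junction_read="R1",
                           reporter_match_len=14, pre_junction_seq=pre,
                           genomic_tag=pre)

    def test_full_ires_tag_calls_ires(self, params):
        assert classify_construct(self.make_hit(GENOMIC[-20:] + IRES_TAG),
                                  params) == "IRES"

    def test_genomic_abutting_plus_one_calls_non_ires(self, params):
        assert classify_construct(self.make_hit(GENOMIC[-20:]),
                                  params) == "non_IRES"

    @pytest.mark.parametrize("visible", range(1, 15))
    def test_truncated_tag_is_unresolved(self, params, visible):
        """1-14 visible nt, all consistent with the tag suffix -> unresolved."""
        assert classify_construct(self.make_hit(IRES_TAG[-visible:]),
                                  params) == "unresolved"

    def test_contradicting_base_rules_out_the_tag(self, params):
        bad = ("A" if IRES_TAG[-1] != "A" else "C")
        assert classify_construct(self.make_hit(IRES_TAG[-5:-1] + bad),
                                  params) == "non_IRES"


class TestLocate:
    def test_unique_tag_maps_and_multimapper_is_excluded(self, params):
        genome = {"s1": GENOMIC + "ACGT" * 30, "s2": "GGCC" * 50}
        h = JunctionHit(pair_id="p", junction_read="R1", reporter_match_len=14,
                        pre_junction_seq=GENOMIC[-20:], genomic_tag=GENOMIC[-20:])
        locate_junction(h, genome, [], 15)
        assert h.mapped_locus == ("s1", len(GENOMIC), "+")
        assert h.multiplicity == 1

        dup = {"s1": GENOMIC + "A" * 40 + GENOMIC[-20:]}
        h2 = JunctionHit(pair_id="p", junction_read="R1", reporter_match_len=14,
                         pre_junction_seq=GENOMIC[-20:], genomic_tag=GENOMIC[-20:])
        locate_junction(h2, dup, [], 15)
        assert h2.mapped_locus is None and h2.multiplicity == 2

    def test_short_tag_is_a_precondition_error(self, params):
        h = JunctionHit(pair_id="p", junction_read="R1", reporter_match_len=14,
                        pre_junction_seq="ACGTACGTAC", genomic_tag="ACGTACGTAC")
        with pytest.raises(ValueError):
            locate_junction(h, {"s": GENOMIC}, [], 15)


class TestOnSyntheticScreen:
    def test_perfect_sensitivity_and_no_false_positives(
            self, dataset, reporter, finder_params, truth_chimeric_ids):
        """With the 14-mer unique and error rate 0, hits equal the truth set."""
        hits = scan_read_pairs(dataset.pairs, reporter, finder_params)
        assert {h.pair_id for h in hits} == truth_chimeric_ids

    def test_construct_counts_match_planted_chimeras(
            self, dataset, reporter, finder_params):
        hits = scan_read_pairs(dataset.pairs, reporter, finder_params)
        got = {}
        for h in hits:
            got[h.construct] = got.get(h.construct, 0) + 1
        want = {}
        for r in dataset.truth.itertuples():
            n = len([i for i in r.chimeric_read_ids.split(",") if i])
            if n:
                want[r.construct] = want.get(r.construct, 0) + n
        assert got == want

    def test_threshold_monotonicity(self, dataset, reporter, finder_params):
        base = len(scan_read_pairs(dataset.pairs, reporter, finder_params))
        for field, value in (("min_reporter_match", 20), ("min_mate_match", 50),
                             ("min_genomic_tag", 20)):
            tightened = dataclasses.replace(finder_params, **{field: value})
            assert len(scan_read_pairs(dataset.pairs, reporter, tightened)) <= base

    def test_strand_symmetry(self, dataset, reporter, finder_params):
        """Reverse-complementing both files and swapping mates keeps pair ids."""
        sub = dataset.pairs[:500]
        swapped = [(i, revcomp(r2), revcomp(r1)) for i, r1, r2 in sub]
        a = {h.pair_id for h in scan_read_pairs(sub, reporter, finder_params)}
        b = {h.pair_id for h in scan_read_pairs(swapped, reporter, finder_params)}
        assert a == b

    def test_locate_labels_and_acceptor_dinucleotide(
            self, dataset, reporter, finder_params):
        hits = scan_read_pairs(dataset.pairs, reporter, finder_params)
        truth = dataset.truth.set_index("insertion_id")
        for h in hits:
            locate_junction(h, dataset.genome, dataset.genes, 15,
                            elements=dataset.elements)
            if h.mapped_locus is None:
                continue
            ins = "_".join(h.pair_id.split("_")[1:-1])
            row = truth.loc[ins]
            assert h.mapped_locus[0] == row["scaffold"]
            assert h.gene_id == row["gene_id"]
            assert h.acceptor_dinucleotide == "AG"
            if row["true_feature_class"] == "five_prime_utr_intron":
                assert h.junction_location == "5'-UTR"
            else:
                assert h.junction_location == (
                    f"Intron {row['intron_ordinal']} of {row['n_introns']}")

    def test_aggregation_conserves_hit_count(self, dataset, reporter,
                                             finder_params):
        hits = scan_read_pairs(dataset.pairs, reporter, finder_params)
        for h in hits:
            locate_junction(h, dataset.genome, dataset.genes, 15)
        table = aggregate_hits(hits)
        assert table["occurrences"].sum() == len(hits)
        assert set(table["construct"]) <= {"non_IRES", "IRES", "unresolved"}


def test_fastq_pairing_error(tmp_path):
    r1 = tmp_path / "r1.fastq"
    r2 = tmp_path / "r2.fastq"
    r1.write_text("@a/1\nACGT\n+\nIIII\n")
    r2.write_text("@b/2\nACGT\n+\nIIII\n")
    with pytest.raises(PairingError):
        list(read_fastq_pairs(r1, r2))
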