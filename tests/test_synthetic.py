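"""Synthetic screen generator: determinism, gene structure, planting,
splinkerette fragments, and read geometry."""

import dataclasses

import pandas as pd
import pytest

from traptag.dna import count_genome_hits, revcomp
from traptag.genes import read_gff3, write_gff3
from traptag.synthetic import (SyntheticConfig, TrapElement, generate_genome,
                               make_trap_elements, plant_insertions,
                               simulate_dataset, simulate_reads,
                               simulate_splinkerette)

from conftest import small_config


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        SyntheticConfig(frac_utr_intron=1.5)
    with pytest.raises(ValueError):
        SyntheticConfig(intron_length_range=(500, 100))
    with pytest.raises(ValueError):
        SyntheticConfig(enzyme="EcoRI")


def test_element_invariants():
    import numpy as np
    elems = make_trap_elements(np.random.default_rng(0))
    assert len(elems["IRES"].left_terminus) == 671
    assert len(elems["IRES"].right_terminus) == 690
    assert len(elems["IRES"].ires_tag) == 15
    assert elems["non_IRES"].ires_tag is None
    assert elems["IRES"].reporter_orf.startswith("ATG")
    # both constructs splice at an AG acceptor
    assert elems["non_IRES"].acceptor_dinucleotide == "AG"
    assert elems["IRES"].acceptor_dinucleotide == "AG"
    with pytest.raises(ValueError):
        TrapElement(reporter_orf="ATGAAA", left_terminus="A" * 670,
                    right_terminus="A" * 690)


def test_utr_intron_gene_count_is_exact():
    cfg = small_config(n_genes=10, frac_utr_intron=0.5, n_scaffolds=3,
                       scaffold_length=200_000)
    _, genes = generate_genome(cfg)
    n_utr = sum(1 for g in genes if any(g.is_utr_intron(iv) for iv in g.introns))
    assert n_utr == 5
    assert all(g.n_introns >= 1 for g in genes)


def test_pinned_intron_length_range_pins_every_annotated_intron(tmp_path):
    cfg = small_config(intron_length_range=(500, 500))
    _, genes = generate_genome(cfg)
    gff = tmp_path / "a.gff3"
    write_gff3(genes, gff)
    parsed = read_gff3(gff)
    lengths = {b - a + 1 for g in parsed for a, b in g.introns}
    assert lengths == {500}


def test_generator_is_deterministic_and_gff_roundtrips(tmp_path):
    cfg = small_config()
    a = simulate_dataset(cfg)
    b = simulate_dataset(cfg)
    assert a.genome == b.genome
    assert a.pairs == b.pairs
    assert a.truth.equals(b.truth)
    pa, pb = tmp_path / "a", tmp_path / "b"
    fa, fb = a.write(pa), b.write(pb)
    for key in fa:
        assert fa[key].read_bytes() == fb[key].read_bytes(), key
    assert sorted(read_gff3(fa["gff"]), key=lambda g: g.gene_id) == \
        sorted(a.genes, key=lambda g: g.gene_id)


def test_intron_sequence_signals(small_dataset):
    ds = small_dataset
    for g in ds.genes:
        for iv in g.introns:
            s = ds.genome[g.scaffold][iv[0] - 1:iv[1]]
            if g.strand == "-":
                s = revcomp(s)
            assert s.startswith("GT") and s.endswith("AG")
            assert "TTAA" in s


def test_reporter_marker_absent_from_genome(small_dataset):
    marker = small_dataset.elements["non_IRES"].reporter_orf[:14]
    assert count_genome_hits(small_dataset.genome, marker) == []


def test_planting_duplicates_ttaa_around_element(small_dataset):
    ds = small_dataset
    assert len(ds.truth) == 2 * ds.config.n_insertions_per_construct
    assert set(ds.truth["construct"]) == {"non_IRES", "IRES"}
    assert {"+", "-"} <= set(ds.truth["element_strand"])
    for r in ds.truth.itertuples():
        # target site verifies against the unmodified genome
        assert ds.genome[r.scaffold][r.ttaa_start - 1:r.ttaa_start + 3] == "TTAA"
        # modified scaffold carries TTAA + element + TTAA
        mod = ds.modified[r.scaffold]
        elem = ds.elements[r.construct].sequence
        placed = elem if r.element_strand == "+" else revcomp(elem)
        s, e = r.mod_elem_start, r.mod_elem_end
        assert mod[s - 1:e] == placed
        assert mod[s - 5:s - 1] == "TTAA" and mod[e:e + 4] == "TTAA"


def test_planting_fails_when_class_unavailable():
    cfg = small_config()
    import numpy as np
    rng = np.random.default_rng(0)
    elems = make_trap_elements(rng)
    genome = {"s1": "ACGT" * 3000}        # no genes, no eligible genic TTAA
    with pytest.raises(ValueError, match="five_prime_utr_intron"):
        plant_insertions(genome, [], elems, cfg, rng=rng)


def test_splinkerette_fragments_read_element_to_first_site(small_dataset):
    ds = small_dataset
    flanks = ds.flanks
    assert len(flanks) == 2 * len(ds.truth)
    by_id = {r.insertion_id: r for r in ds.truth.itertuples()}
    for r in flanks.itertuples():
        elem = ds.elements[by_id[r.insertion_id].construct]
        tags = {elem.terminal_tag("5p"), elem.terminal_tag("3p")}
        assert r.flank_sequence[:30] in tags
        assert r.flank_sequence[30:34] == "TTAA"
    assert not flanks["truncated"].any()
    assert set(flanks["side"]) == {"5p", "3p"}


def test_splinkerette_first_site_rule_and_truncation():
    """BglII fragment stops at the first AGATCT; no site -> flagged."""
    import numpy as np
    rng = np.random.default_rng(0)
    elems = make_trap_elements(rng)
    elem = elems["non_IRES"]
    # left genome with one site far out, right genome with site then another
    left = "C" * 200 + "AGATCT" + "C" * 100
    right = "G" * 50 + "AGATCT" + "G" * 40 + "AGATCT" + "G" * 50
    scaffold = left + "TTAA" + elem.sequence + "TTAA" + right
    truth = pd.DataFrame([{
        "insertion_id": "x1", "scaffold": "s", "element_strand": "+",
        "construct": "non_IRES",
        "mod_elem_start": len(left) + 5, "mod_elem_end": len(left) + 4 + len(elem.sequence)}])
    fr = simulate_splinkerette({"s": scaffold}, truth, elems, "BglII")
    right_frag = fr[fr["side"] == "3p"].iloc[0]
    assert right_frag["flank_sequence"] == (
        elem.sequence[-30:] + "TTAA" + "G" * 50 + "AGATCT")
    left_frag = fr[fr["side"] == "5p"].iloc[0]
    assert left_frag["flank_sequence"].startswith(revcomp(elem.sequence[:30]) + "TTAA")
    assert left_frag["flank_sequence"].endswith(revcomp("AGATCT"))
    assert not fr["truncated"].any()

    # site-free flanks are truncated at the scaffold boundary, not dropped
    bare = "C" * 300 + "TTAA" + elem.sequence + "TTAA" + "G" * 300
    fr2 = simulate_splinkerette({"s": bare}, truth.assign(
        mod_elem_start=305, mod_elem_end=304 + len(elem.sequence)), elems, "BglII")
    assert fr2["truncated"].all()


def test_reads_chimera_free_run_lacks_reporter_kmer():
    cfg = small_config(chimera_fraction=0.0, n_read_pairs=200)
    ds = simulate_dataset(cfg)
    marker = ds.elements["non_IRES"].reporter_orf[:14]
    for _, r1, r2 in ds.pairs:
        for s in (r1, r2, revcomp(r1), revcomp(r2)):
            assert marker not in s
    assert len(ds.pairs) == 200
    assert (ds.truth["chimeric_read_ids"] == "").all()


def test_ires_chimeras_carry_tag_abutting_reporter_plus_one(small_dataset):
    ds = small_dataset
    tag = ds.elements["IRES"].ires_tag
    rep14 = ds.elements["IRES"].reporter_orf[:14]
    ires_rows = ds.truth[(ds.truth["construct"] == "IRES")
                         & (ds.truth["chimeric_read_ids"] != "")]
    assert len(ires_rows) > 0
    reads = {rid: (r1, r2) for rid, r1, r2 in ds.pairs}
    for ids in ires_rows["chimeric_read_ids"]:
        for rid in ids.split(","):
            r1, r2 = reads[rid]
            assert any((tag + rep14) in s
                       for s in (r1, r2, revcomp(r1), revcomp(r2)))


def test_chimera_request_refused_for_opposite_strand_insertion(small_dataset):
    ds = small_dataset
    opp = ds.truth[ds.truth["orientation"] == "opposite"]["insertion_id"].iloc[0]
    with pytest.raises(ValueError, match="non-reporting"):
        simulate_reads(ds.genome, ds.genes, ds.truth, ds.elements, ds.config,
                       chimera_insertions=[opp])


def test_scaffold_too_short_raises_sizing_error():
    cfg = small_config(scaffold_length=12_000, n_genes=8, n_scaffolds=1,
                       utr_intron_5p_distance_range=(40_000, 44_882))
    with pytest.raises(ValueError, match="too short"):
        generate_genome(cfg)
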