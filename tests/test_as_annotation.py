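import numpy as np
import pytest

from conftest import make_gene, make_transcript
from episplice.as_annotation import (
    annotate_gene,
    classify_pairwise,
    encode_decimal,
    filter_positional,
    segment_gene,
    select_splice_sites,
)
from oracle import brute_force_annotate, random_gene


def event_keys(events):
    return {
        (e.event_type, frozenset((s.kind, s.pos) for s in select_splice_sites(e)))
        for e in events
    }


# ---------------------------------------------------------------------------
# binary/decimal coding


def test_segmentation_of_two_isoform_gene():
    g = make_gene([[(0, 10), (20, 30)], [(0, 10), (20, 25)]])
    seg = segment_gene(g)
    assert seg.boundaries == [0, 10, 20, 25, 30]
    assert seg.segments == [(0, 10), (10, 20), (20, 25), (25, 30)]
    assert seg.inclusion["t1"] == (1, 0, 1, 1)
    assert seg.inclusion["t2"] == (1, 0, 1, 0)
    assert seg.decimal_codes["t1"] == 0b1011


def test_segmentation_reconstructs_transcripts(rng):
    for i in range(100):
        g = random_gene(rng, gene_id=f"g{i}", n_transcripts=3)
        seg = segment_gene(g)
        for t in g.transcripts:
            assert seg.reconstruct(t.transcript_id) == [
                (e.start, e.end) for e in t.exons
            ]


def test_decimal_code_msb_is_transcript_five_prime():
    minus = make_gene([[(0, 10), (20, 30)]], strand="-")
    seg = segment_gene(minus)
    # genomic bits (1, 0, 1) read 3'->5' on the minus strand
    assert seg.decimal_codes["t1"] == 0b101


def test_encode_decimal_matches_positional_sum(rng):
    assert encode_decimal([1, 0, 1, 1]) == 11
    assert encode_decimal([0, 0, 0, 0]) == 0
    with pytest.raises(ValueError):
        encode_decimal([])
    for _ in range(50):
        bits = rng.integers(0, 2, size=rng.integers(1, 16))
        expected = sum(int(b) << (len(bits) - 1 - i) for i, b in enumerate(bits))
        assert encode_decimal(bits) == expected


# ---------------------------------------------------------------------------
# pairwise classification


@pytest.mark.parametrize("strand", ["+", "-"])
def test_exon_skipping_configuration(strand):
    tA = make_transcript([(100, 200), (300, 400), (500, 600)], tid="tA", strand=strand)
    tB = make_transcript([(100, 200), (500, 600)], tid="tB", strand=strand)
    (e,) = classify_pairwise(tA, tB)
    assert e.event_type == "ES"
    assert [(x.start, x.end) for x in e.exons] == [(300, 400)]


def test_mutually_exclusive_configuration():
    tA = make_transcript([(100, 200), (300, 400), (700, 800)], tid="tA")
    tB = make_transcript([(100, 200), (500, 600), (700, 800)], tid="tB")
    (e,) = classify_pairwise(tA, tB)
    assert e.event_type == "ME"
    assert [(x.start, x.end) for x in e.exons] == [(300, 400), (500, 600)]
    assert len(select_splice_sites(e)) == 4  # both exons counted independently


@pytest.mark.parametrize(
    "strand,expected", [("+", "A3SS"), ("-", "A5SS")]
)
def test_alternative_start_boundary_class_depends_on_strand(strand, expected):
    tA = make_transcript([(100, 200), (300, 500), (700, 800)], tid="tA", strand=strand)
    tB = make_transcript([(100, 200), (350, 500), (700, 800)], tid="tB", strand=strand)
    (e,) = classify_pairwise(tA, tB)
    assert e.event_type == expected
    # longer-exon rule: the analysed boundary comes from the longer exon
    sites = {(s.kind, s.pos) for s in select_splice_sites(e)}
    if strand == "+":
        assert sites == {("acceptor", 300), ("donor", 500)}
    else:
        assert sites == {("donor", 300), ("acceptor", 500)}


def test_intron_retention_configuration():
    tA = make_transcript([(100, 200), (300, 600), (700, 800)], tid="tA")
    tB = make_transcript([(100, 200), (300, 400), (500, 600), (700, 800)], tid="tB")
    (e,) = classify_pairwise(tA, tB)
    assert e.event_type == "IR"
    assert e.retained_intron == (400, 500)
    sites = {(s.kind, s.pos) for s in select_splice_sites(e)}
    assert sites == {("donor", 400), ("acceptor", 500)}  # retained-intron boundaries


def test_minus_strand_intron_retention_sites_swap():
    tA = make_transcript([(100, 200), (300, 600), (700, 800)], tid="tA", strand="-")
    tB = make_transcript(
        [(100, 200), (300, 400), (500, 600), (700, 800)], tid="tB", strand="-"
    )
    (e,) = classify_pairwise(tA, tB)
    sites = {(s.kind, s.pos) for s in select_splice_sites(e)}
    assert sites == {("donor", 500), ("acceptor", 400)}


def test_classifier_matches_brute_force_oracle(rng):
    mismatches = []
    for i in range(100):
        g = random_gene(rng, gene_id=f"g{i}", n_transcripts=2)
        if event_keys(annotate_gene(g)) != brute_force_annotate(g):
            mismatches.append(g.gene_id)
    assert mismatches == []


# ---------------------------------------------------------------------------
# gene-level annotation


def test_single_transcript_gene_yields_cne_only():
    g = make_gene([[(100, 200), (300, 400), (500, 600)]])
    (e,) = annotate_gene(g)
    assert e.event_type == "CNE"
    assert [(x.start, x.end) for x in e.exons] == [(300, 400)]
    assert e.exon_ordinal == 2


def test_event_discovered_from_multiple_pairs_is_emitted_once():
    g = make_gene([
        [(100, 200), (300, 400), (500, 600)],
        [(100, 200), (500, 600)],
        [(100, 200), (500, 600), (700, 800)],
    ])
    es = [e for e in annotate_gene(g) if e.event_type == "ES"]
    assert len(es) == 1


def test_annotation_invariant_to_transcript_order(rng):
    for i in range(30):
        g = random_gene(rng, gene_id=f"g{i}")
        flipped = make_gene(
            [[(e.start, e.end) for e in t.exons] for t in reversed(g.transcripts)],
            strand=g.strand,
            gene_id=g.gene_id,
        )
        assert event_keys(annotate_gene(g)) == event_keys(annotate_gene(flipped))


def test_event_sites_are_existing_exon_boundaries(rng):
    for i in range(100):
        g = random_gene(rng, gene_id=f"g{i}")
        bounds = {c for t in g.transcripts for e in t.exons for c in (e.start, e.end)}
        for ev in annotate_gene(g):
            for s in ev.splice_sites:
                assert s.pos in bounds


def test_cne_and_ase_sites_are_disjoint(rng):
    for i in range(100):
        g = random_gene(rng, gene_id=f"g{i}")
        events = annotate_gene(g)
        ase = {s.pos for e in events if e.event_type != "CNE" for s in e.splice_sites}
        cne = {s.pos for e in events if e.event_type == "CNE" for s in e.splice_sites}
        assert not (ase & cne)


# ---------------------------------------------------------------------------
# positional filter


def es_gene(first_len=3000, intron=1000, exon=150, last_len=3000):
    s1 = first_len + intron
    s2 = s1 + exon + intron
    return make_gene([
        [(0, first_len), (s1, s1 + exon), (s2, s2 + last_len)],
        [(0, first_len), (s2, s2 + last_len)],
    ])


def test_event_near_tss_is_removed():
    g = es_gene(first_len=1300, intron=200)  # event exon starts 1500 bp in
    events = [e for e in annotate_gene(g) if e.event_type == "ES"]
    assert events and filter_positional(events) == []


def test_event_clear_of_both_ends_is_retained():
    g = es_gene(first_len=2400, intron=100)  # exon at [2500, 2650] of ~10 kb span
    events = [e for e in annotate_gene(g) if e.event_type == "ES"]
    assert filter_positional(events) == events


def test_zero_window_filter_is_identity():
    g = es_gene(first_len=1300, intron=200)
    events = annotate_gene(g)
    assert filter_positional(events, window=0) == events
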