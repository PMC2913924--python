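import random

import pytest

from vartree import (
    AnnotationSet,
    ClassifierParams,
    GeneModel,
    Interval,
    ReferenceRegion,
    TranscriptModel,
    classify,
    exon_subregion,
    gene_context,
    splice_site_class,
    transcript_context,
    tree_label_set,
)

from .conftest import build_toy, make_variant, mirror_fixture

PARAMS = ClassifierParams()


def toy_transcript(ann):
    return ann.genes[0].transcripts[0]


# ---------------------------------------------------------------------------
# gene_context: promoter / downstream windows
# ---------------------------------------------------------------------------


def test_upstream_distance_is_zero_space_gap(toy):
    _, ann = toy
    t = toy_transcript(ann)  # first exon begins at 2000
    label, d = gene_context(make_variant(1500, 1501, "A"), t, PARAMS)
    assert (label, d) == ("upstream_promoter", 499)


def test_upstream_window_excludes_past_1000(toy):
    _, ann = toy
    t = toy_transcript(ann)
    # covering the 1000th upstream residue: still promoter
    label, _ = gene_context(make_variant(1000, 1001, "A"), t, PARAMS)
    assert label == "upstream_promoter"
    # the 1001st upstream residue: outside
    label, _ = gene_context(make_variant(999, 1000, "A"), t, PARAMS)
    assert label == "outside"


def test_downstream_window(toy):
    _, ann = toy
    t = toy_transcript(ann)  # last exon ends at 2290
    label, d = gene_context(make_variant(2390, 2391, "A"), t, PARAMS)
    assert (label, d) == ("downstream_transcript", 100)


def test_minus_strand_upstream_is_right_of_rightmost_exon(toy):
    _, ann = toy
    t_plus = toy_transcript(ann)
    t_minus = TranscriptModel(transcript_id="tm", strand="-", exons=list(t_plus.exons),
                              cds_span=t_plus.cds_span)
    label, d = gene_context(make_variant(2390, 2391, "A"), t_minus, PARAMS)
    assert (label, d) == ("upstream_promoter", 100)
    label, _ = gene_context(make_variant(1500, 1501, "A"), t_minus, PARAMS)
    assert label == "downstream_transcript"


# ---------------------------------------------------------------------------
# intron / exon and splice windows
# ---------------------------------------------------------------------------


def test_intronic_with_distance(toy):
    _, ann = toy
    t = toy_transcript(ann)  # intron 1 is (2060, 2100)
    labels, dist = transcript_context(make_variant(2070, 2071, "A"), t)
    assert labels == ["intronic"]
    assert dist == 10  # gap to exon 1


def test_exonic_overlap(toy):
    _, ann = toy
    t = toy_transcript(ann)
    labels, _ = transcript_context(make_variant(2010, 2011, "A"), t)
    assert labels == ["exonic"]


def test_boundary_spanning_deletion_gets_both_labels(toy):
    region, ann = toy
    t = toy_transcript(ann)
    v = make_variant(2055, 2065, "")  # spans exon1 / intron1 boundary
    labels, _ = transcript_context(v, t)
    assert labels == ["exonic", "intronic"]
    tree = classify(v, ann, region)
    tb = tree.gene_branches[0].transcript_branches[0]
    assert set(tb.region_labels) == {"exonic", "intronic"}
    assert "boundary_spanning" in tb.notes


def test_insertion_point_at_exon_boundary_attaches_to_both(toy):
    _, ann = toy
    t = toy_transcript(ann)
    labels, _ = transcript_context(make_variant(2060, 2060, "AAA"), t)
    assert set(labels) == {"exonic", "intronic"}


@pytest.mark.parametrize("strand", ["+", "-"])
def test_splice_window_monotone_transition(toy, strand):
    """Moving away from the exon, the splice label drops exactly at the window edge."""
    _, ann = toy
    t_plus = toy_transcript(ann)
    t = TranscriptModel(transcript_id="t", strand=strand, exons=list(t_plus.exons),
                        cds_span=t_plus.cds_span)
    a, b = 2060, 2100  # intron 1
    donor_flags, acceptor_flags = [], []
    for off in range(1, 21):
        if strand == "+":
            donor_v = make_variant(a + off - 1, a + off, "A")
            acceptor_v = make_variant(b - off, b - off + 1, "A")
        else:
            donor_v = make_variant(b - off, b - off + 1, "A")
            acceptor_v = make_variant(a + off - 1, a + off, "A")
        donor_flags.append("five_prime_splice_site" in splice_site_class(donor_v, t, PARAMS))
        acceptor_flags.append("three_prime_splice_site" in splice_site_class(acceptor_v, t, PARAMS))
    assert donor_flags == [True] * 10 + [False] * 10
    assert acceptor_flags == [True] * 6 + [False] * 14


def test_short_intron_gets_both_splice_labels():
    # intron of 8 bases: donor (10) and acceptor (6) windows overlap
    t = TranscriptModel(transcript_id="t", strand="+",
                        exons=[Interval(0, 20), Interval(28, 50)], cds_span=None)
    labels = splice_site_class(make_variant(24, 25, "A"), t, PARAMS)
    assert set(labels) == {"five_prime_splice_site", "three_prime_splice_site"}


def test_splice_windows_are_configurable(toy):
    _, ann = toy
    t = toy_transcript(ann)
    v = make_variant(2064, 2065, "A")  # donor offset 5
    assert splice_site_class(v, t, PARAMS) == ("five_prime_splice_site",)
    assert splice_site_class(v, t, ClassifierParams(donor_window=2)) == ()


# ---------------------------------------------------------------------------
# exon subregions
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pos,strand,expect",
    [
        (2010, "+", "five_prime_UTR"),  # before CDS begin (2030)
        (2031, "+", "CDS"),
        (2250, "+", "three_prime_UTR"),  # after CDS end (2245)
        (2250, "-", "five_prime_UTR"),  # mirrored reading direction
        (2010, "-", "three_prime_UTR"),
    ],
)
def test_exon_subregion_labels(toy, pos, strand, expect):
    _, ann = toy
    t_plus = toy_transcript(ann)
    t = TranscriptModel(transcript_id="t", strand=strand, exons=list(t_plus.exons),
                        cds_span=t_plus.cds_span)
    assert exon_subregion(make_variant(pos, pos + 1, "A"), t) == (expect,)


def test_noncoding_transcript_label(toy):
    _, ann = toy
    t_plus = toy_transcript(ann)
    t = TranscriptModel(transcript_id="t", strand="+", exons=list(t_plus.exons), cds_span=None)
    assert exon_subregion(make_variant(2031, 2032, "A"), t) == ("noncoding_exon",)


def test_utr_cds_boundary_insertion_gets_both(toy):
    _, ann = toy
    t = toy_transcript(ann)
    labels = exon_subregion(make_variant(2030, 2030, "AAA"), t)
    assert set(labels) == {"five_prime_UTR", "CDS"}


# ---------------------------------------------------------------------------
# full classification
# ---------------------------------------------------------------------------


def test_known_and_repeat_collocation(toy):
    region, ann = toy
    tree = classify(make_variant(120, 121, "A"), ann, region)
    assert tree.known_ids == ["rs123"]
    tree = classify(make_variant(405, 406, "A"), ann, region)
    assert tree.repeat_names == ["rep_toy"]


def test_intergenic_snp(toy):
    region, ann = toy
    tree = classify(make_variant(500, 501, "A"), ann, region)
    assert tree.intergenic and not tree.gene_branches


def test_promoter_of_one_gene_and_exon_of_another(toy):
    region, ann = toy
    g2 = GeneModel(gene_id="G2", strand="+", span=Interval(2350, 2400))
    g2.transcripts.append(TranscriptModel(transcript_id="t2", strand="+",
                                          exons=[Interval(2350, 2400)], cds_span=None))
    ann2 = AnnotationSet(genes=ann.genes + [g2], domains=ann.domains,
                         repeats=ann.repeats, known=ann.known)
    tree = classify(make_variant(2352, 2353, "A"), ann2, region)
    by_gene = {gb.gene_id: gb.transcript_branches[0] for gb in tree.gene_branches}
    assert by_gene["G2"].region_labels == ("exonic",)
    assert by_gene["G1"].region_labels == ("downstream_transcript",)


def test_every_branch_has_region_label(fixture1, panel1):
    """Exhaustiveness: accepted variants always get flags and labelled branches."""
    from vartree import read_variants_tsv

    rows, _ = panel1
    import os
    import tempfile
    with tempfile.TemporaryDirectory() as d:
        p = os.path.join(d, "v.tsv")
        with open(p, "w") as fh:
            fh.write("\n".join(rows) + "\n")
        variants, errors = read_variants_tsv(p, ref_length=fixture1.region.length)
    assert not errors
    for v in variants:
        tree = classify(v, fixture1.annotation, fixture1.region)
        assert tree.intergenic == (not tree.gene_branches)
        for gb in tree.gene_branches:
            assert gb.transcript_branches
            for tb in gb.transcript_branches:
                assert tb.region_labels


def test_strand_symmetry(fixture1):
    """Mirroring sequence, annotation and variants mirrors the classification."""
    mirrored = mirror_fixture(fixture1)
    s = fixture1.region.length
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rng = random.Random(5)
    for _ in range(300):
        p = rng.randrange(0, s)
        alt = rng.choice([x for x in "ACGT" if x != fixture1.region.sequence[p]])
        v = make_variant(p, p + 1, alt)
        vm = make_variant(s - p - 1, s - p, comp[alt])
        t1 = classify(v, fixture1.annotation, fixture1.region)
        t2 = classify(vm, mirrored.annotation, mirrored.region)
        assert tree_label_set(t1) == tree_label_set(t2), (p, alt)
        d1 = {(gb.gene_id, tb.transcript_id): tb.distance_to_nearest_exon
              for gb in t1.gene_branches for tb in gb.transcript_branches}
        d2 = {(gb.gene_id, tb.transcript_id): tb.distance_to_nearest_exon
              for gb in t2.gene_branches for tb in gb.transcript_branches}
        assert d1 == d2
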