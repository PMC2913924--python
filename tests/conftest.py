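import random

import pytest
from Bio.Seq import reverse_complement

from vartree import (
    AnnotationSet,
    Fixture,
    FixtureSpec,
    GeneModel,
    Interval,
    KnownVariant,
    ProteinDomain,
    QueryVariant,
    ReferenceRegion,
    RepeatFeature,
    TranscriptModel,
    generate_fixture,
    generate_variant_panel,
)

# deterministic coding sequence for the hand-built toy gene:
# ATG + 43 sense codons + TAA = 135 nt, protein of 44 residues
_TOY_RNG = random.Random(7)
_SENSE = sorted(
    c
    for c in ("".join(x) for x in __import__("itertools").product("ACGT", repeat=3))
    if c not in ("TAA", "TAG", "TGA")
)
TOY_CODONS = ["ATG"] + [_TOY_RNG.choice(_SENSE) for _ in range(43)] + ["TAA"]
TOY_CDS = "".join(TOY_CODONS)  # 135 nt


def make_variant(begin, end, allele, orient="+", vid="v"):
    return QueryVariant(variant_id=vid, span=Interval(begin, end), orientation=orient, allele=allele)


def build_toy():
    """Plus-strand 3-exon gene with known geometry.

    exons (2000,2060), (2100,2160), (2200,2290); CDS span (2030,2245) whose
    pieces contribute 30 + 60 + 45 = 135 coding bases.
    """
    rng = random.Random(42)
    seq = [rng.choice("ACGT") for _ in range(3000)]
    pieces = [(2030, 2060), (2100, 2160), (2200, 2245)]
    i = 0
    for b, e in pieces:
        for p in range(b, e):
            seq[p] = TOY_CDS[i]
            i += 1
    region = ReferenceRegion(name="toy", sequence="".join(seq))
    t = TranscriptModel(
        transcript_id="t1",
        strand="+",
        exons=[Interval(2000, 2060), Interval(2100, 2160), Interval(2200, 2290)],
        cds_span=Interval(2030, 2245),
        protein_id="p1",
    )
    gene = GeneModel(gene_id="G1", strand="+", span=Interval(2000, 2290), transcripts=[t])
    ann = AnnotationSet(
        genes=[gene],
        domains=[ProteinDomain(parent_id="t1", domain_name="PFTEST", aa_begin=5, aa_end=12)],
        repeats=[RepeatFeature(span=Interval(400, 430), repeat_name="rep_toy")],
        known=[KnownVariant(span=Interval(120, 121), dbsnp_id="rs123")],
    )
    return region, ann


def mirror_fixture(fixture: Fixture) -> Fixture:
    """Reverse-complement an entire fixture: b' = s - e, e' = s - b, strands flipped."""
    s = fixture.region.length
    miv = lambda iv: Interval(s - iv.end, s - iv.begin)
    flip = {"+": "-", "-": "+"}
    genes = []
    for g in fixture.annotation.genes:
        ng = GeneModel(gene_id=g.gene_id, strand=flip[g.strand], span=miv(g.span))
        for t in g.transcripts:
            ng.transcripts.append(
                TranscriptModel(
                    transcript_id=t.transcript_id,
                    strand=flip[t.strand],
                    exons=sorted(miv(ex) for ex in t.exons),
                    cds_span=miv(t.cds_span) if t.cds_span else None,
                    protein_id=t.protein_id,
                )
            )
        genes.append(ng)
    ann = AnnotationSet(
        genes=genes,
        domains=list(fixture.annotation.domains),
        repeats=[RepeatFeature(span=miv(r.span), repeat_name=r.repeat_name)
                 for r in fixture.annotation.repeats],
        known=[KnownVariant(span=miv(k.span), dbsnp_id=k.dbsnp_id)
               for k in fixture.annotation.known],
    )
    region = ReferenceRegion(
        name=fixture.region.name + "_mirror",
        sequence=reverse_complement(fixture.region.sequence),
    )
    return Fixture(region=region, annotation=ann, proteins=dict(fixture.proteins),
                   cds_sequences=dict(fixture.cds_sequences), spec=fixture.spec)


@pytest.fixture(scope="session")
def toy():
    return build_toy()


@pytest.fixture(scope="session")
def fixture1():
    return generate_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def panel1(fixture1):
    return generate_variant_panel(fixture1)
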