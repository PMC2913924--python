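"""Deterministic toy-genome generator, targeted variant panels and an
independent brute-force position labeler.

The generator builds each coding sequence codon-wise (ATG start, uniform
sense codons, one stop), so every transcript's CDS is a multiple of 3 with
no internal stop *by construction*, and records the reference protein from
the chosen codons — an independent path from the classifier's splice-and-
translate machinery.  ``oracle_label`` classifies single-base substitutions
with straight-line scans over the feature lists and shares no code with
classifier_core.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

from .genome_model import (
    AnnotationSet,
    GeneModel,
    Interval,
    KnownVariant,
    ProteinDomain,
    ReferenceRegion,
    RepeatFeature,
    TranscriptModel,
    validate_annotation,
    write_annotation_tsv,
)
from .protein_effect import cds_to_genomic, load_blosum30

_CODON_AA = dict(standard_dna_table.forward_table)
_STOP_CODONS = sorted(standard_dna_table.stop_codons)
_SENSE_CODONS = sorted(_CODON_AA)  # 61 non-stop codons
_FOURFOLD_PREFIXES = {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_FLIP = {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}


@dataclass
class FixtureSpec:
    seed: int = 1
    region_length: int = 12000
    gene_count: int = 2
    strand_mix: float = 0.5  # fraction of minus-strand genes
    transcripts_per_gene: int = 1
    exons_per_transcript: tuple[int, int] = (2, 4)
    intron_length: tuple[int, int] = (40, 80)  # >= ~18 keeps splice windows separable
    utr_length: tuple[int, int] = (12, 30)
    cds_codons: tuple[int, int] = (30, 50)  # coding codons incl. start, excl. stop
    domain_count: int = 1  # per protein
    repeat_count: int = 2
    known_variant_count: int = 2
    intergenic_gap: int = 2300  # room for promoter sweeps and intergenic variants


@dataclass
class Fixture:
    region: ReferenceRegion
    annotation: AnnotationSet
    proteins: dict[str, str]  # transcript_id -> reference protein
    cds_sequences: dict[str, str] = field(default_factory=dict)
    spec: FixtureSpec | None = None


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _build_gene_cassette(rng: random.Random, spec: FixtureSpec):
    """Plus-strand layout of one gene: (sequence, exons, cds_span, codons)."""
    n_ex = rng.randint(*spec.exons_per_transcript)
    n_cod = rng.randint(*spec.cds_codons)
    codons = ["ATG"] + [rng.choice(_SENSE_CODONS) for _ in range(n_cod - 1)] + [
        rng.choice(_STOP_CODONS)
    ]
    cds_nt = "".join(codons)
    utr5 = _random_seq(rng, rng.randint(*spec.utr_length))
    utr3 = _random_seq(rng, rng.randint(*spec.utr_length))

    # split the CDS into n_ex non-empty genomic chunks
    if n_ex > 1:
        cuts = sorted(rng.sample(range(1, len(cds_nt)), n_ex - 1))
    else:
        cuts = []
    bounds = [0] + cuts + [len(cds_nt)]
    chunks = [cds_nt[a:b] for a, b in zip(bounds, bounds[1:])]

    exon_seqs = []
    for i, chunk in enumerate(chunks):
        s = chunk
        if i == 0:
            s = utr5 + s
        if i == len(chunks) - 1:
            s = s + utr3
        exon_seqs.append(s)
    intron_seqs = [_random_seq(rng, rng.randint(*spec.intron_length)) for _ in range(n_ex - 1)]

    seq_parts, exons, pos = [], [], 0
    for i, ex in enumerate(exon_seqs):
        exons.append(Interval(pos, pos + len(ex)))
        seq_parts.append(ex)
        pos += len(ex)
        if i < len(intron_seqs):
            seq_parts.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    cassette = "".join(seq_parts)
    # the CDS runs from the end of the 5' UTR to the start of the 3' UTR
    cds_span = Interval(len(utr5), len(cassette) - len(utr3))
    return cassette, exons, cds_span, codons


def _mirror(iv: Interval, length: int) -> Interval:
    return Interval(length - iv.end, length - iv.begin)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Deterministic annotated toy region; raises if the spec does not fit."""
    rng = random.Random(spec.seed)

    n_minus = round(spec.strand_mix * spec.gene_count)
    strands = ["+"] * (spec.gene_count - n_minus) + ["-"] * n_minus
    rng.shuffle(strands)

    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    cds_sequences: dict[str, str] = {}
    domains: list[ProteinDomain] = []
    sequence = list(_random_seq(rng, spec.region_length))

    offset = spec.intergenic_gap
    for gi in range(spec.gene_count):
        cassette, exons, cds_span, codons = _build_gene_cassette(rng, spec)
        strand = strands[gi]
        if strand == "-":
            cassette = reverse_complement(cassette)
            exons = sorted(_mirror(ex, len(cassette)) for ex in exons)
            cds_span = _mirror(cds_span, len(cassette))

        if offset + len(cassette) + spec.intergenic_gap > spec.region_length:
            raise ValueError(
                f"fixture spec infeasible: region_length {spec.region_length} too small "
                f"for {spec.gene_count} genes with intergenic_gap {spec.intergenic_gap}"
            )
        sequence[offset : offset + len(cassette)] = cassette

        gene_id = f"g{gi + 1}"
        protein = "".join(_CODON_AA[c] for c in codons[:-1])
        shift = offset
        g_exons = [Interval(ex.begin + shift, ex.end + shift) for ex in exons]
        g_cds = Interval(cds_span.begin + shift, cds_span.end + shift)
        gene = GeneModel(
            gene_id=gene_id,
            strand=strand,
            span=Interval(g_exons[0].begin, g_exons[-1].end),
        )
        for ti in range(spec.transcripts_per_gene):
            tid = f"{gene_id}t{ti + 1}"
            t = TranscriptModel(
                transcript_id=tid,
                strand=strand,
                exons=list(g_exons),
                cds_span=g_cds,
                protein_id=f"{tid}p",
            )
            gene.transcripts.append(t)
            proteins[tid] = protein
            cds_sequences[tid] = "".join(codons)
        genes.append(gene)

        plen = len(protein)
        for di in range(spec.domain_count):
            lo = rng.randint(2, max(2, plen - 10))
            hi = min(plen - 1, lo + rng.randint(3, 10))
            domains.append(
                ProteinDomain(
                    parent_id=gene.transcripts[0].transcript_id,
                    domain_name=f"PF{gi + 1:03d}{di + 1}",
                    aa_begin=lo,
                    aa_end=hi,
                )
            )
        offset += len(cassette) + spec.intergenic_gap

    repeats = []
    for ri in range(spec.repeat_count):
        length = rng.randint(20, 50)
        b = rng.randrange(0, spec.region_length - length)
        repeats.append(RepeatFeature(span=Interval(b, b + length), repeat_name=f"rep{ri + 1}"))
    known = []
    for ki in range(spec.known_variant_count):
        b = rng.randrange(0, spec.region_length - 1)
        known.append(KnownVariant(span=Interval(b, b + 1), dbsnp_id=f"rs{1000 + ki}"))

    region = ReferenceRegion(name=f"region_seed{spec.seed}", sequence="".join(sequence))
    ann = AnnotationSet(genes=genes, domains=domains, repeats=repeats, known=known)
    hard = [v for v in validate_annotation(ann, region) if not v.startswith("warning:")]
    if hard:
        raise AssertionError(f"generator produced inconsistent annotation: {hard}")
    return Fixture(region=region, annotation=ann, proteins=proteins,
                   cds_sequences=cds_sequences, spec=spec)


def write_fixture(fixture: Fixture, directory) -> tuple[str, str]:
    """Write region FASTA + annotation TSV (the dialects the tool reads)."""
    import os

    fasta = os.path.join(str(directory), "region.fasta")
    tsv = os.path.join(str(directory), "annotation.tsv")
    with open(fasta, "w") as fh:
        fh.write(f">{fixture.region.name}\n")
        seq = fixture.region.sequence
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
    with open(tsv, "w") as fh:
        fh.write(write_annotation_tsv(fixture.annotation))
    return fasta, tsv


# ---------------------------------------------------------------------------
# Targeted variant panel
# ---------------------------------------------------------------------------


def generate_variant_panel(fixture: Fixture, seed: int = 0):
    """Variants covering every leaf of the decision tree, with expected labels.

    Returns (tsv_rows, expected) where each row is a tab-joined variants-file
    line and expected maps variant_id to the labels the variant was
    constructed to receive.
    """
    rows: list[str] = []
    expected: dict[str, dict] = {}
    seq = fixture.region.sequence
    matrix = load_blosum30()

    def add(vid, b, e, allele, **exp):
        rows.append("\t".join([vid, str(b), str(e), "+", allele]))
        expected[vid] = exp

    def snp_allele(p):
        return _FLIP[seq[p]]

    for gene in fixture.annotation.genes:
        t = gene.transcripts[0]
        tid = t.transcript_id
        env = t.envelope
        plus = t.strand == "+"
        base = dict(gene_id=gene.gene_id, transcript_id=tid)

        def upstream_span(k):
            return (env.begin - k, env.begin - k + 1) if plus else (env.end + k - 1, env.end + k)

        def downstream_span(k):
            return (env.end + k - 1, env.end + k) if plus else (env.begin - k, env.begin - k + 1)

        for k in (1, 500, 1000):
            b, e = upstream_span(k)
            add(f"{tid}_prom_{k}", b, e, snp_allele(b), region="upstream_promoter", **base)
        b, e = upstream_span(1001)
        add(f"{tid}_prom_1001", b, e, snp_allele(b), intergenic=True)
        b, e = downstream_span(5)
        add(f"{tid}_down_5", b, e, snp_allele(b), region="downstream_transcript", **base)

        intron = max(t.introns, key=lambda iv: iv.length)
        a, bnd = intron.begin, intron.end

        def donor_span(k):
            return (a + k - 1, a + k) if plus else (bnd - k, bnd - k + 1)

        def acceptor_span(k):
            return (bnd - k, bnd - k + 1) if plus else (a + k - 1, a + k)

        for k in (1, 10):
            b, e = donor_span(k)
            add(f"{tid}_donor_{k}", b, e, snp_allele(b),
                region="intronic", splice="five_prime_splice_site", **base)
        b, e = donor_span(11)
        add(f"{tid}_donor_11", b, e, snp_allele(b), region="intronic", splice=None, **base)
        for k in (1, 6):
            b, e = acceptor_span(k)
            add(f"{tid}_acceptor_{k}", b, e, snp_allele(b),
                region="intronic", splice="three_prime_splice_site", **base)
        b, e = acceptor_span(7)
        add(f"{tid}_acceptor_7", b, e, snp_allele(b), region="intronic", splice=None, **base)
        mid = a + intron.length // 2
        add(f"{tid}_intron_mid", mid, mid + 1, snp_allele(mid),
            region="intronic", splice=None, **base)

        c = t.cds_span
        utr5_pos = c.begin - 2 if plus else c.end + 1
        utr3_pos = c.end + 1 if plus else c.begin - 2
        add(f"{tid}_utr5", utr5_pos, utr5_pos + 1, snp_allele(utr5_pos),
            region="exonic", exon_sub="five_prime_UTR", **base)
        add(f"{tid}_utr3", utr3_pos, utr3_pos + 1, snp_allele(utr3_pos),
            region="exonic", exon_sub="three_prime_UTR", **base)

        cds = fixture.cds_sequences[tid]
        n_aa = len(fixture.proteins[tid])

        def genomic_snp(cds_index, alt_base):
            """(begin, plus_allele) for a substitution at a 1-based CDS index."""
            p = cds_to_genomic(cds_index, t)
            return p, (alt_base if plus else _COMPLEMENT[alt_base])

        # synonymous: third position of a four-fold degenerate codon
        for k in range(1, n_aa):
            codon = cds[3 * k : 3 * k + 3]
            if codon[:2] in _FOURFOLD_PREFIXES:
                alt = next(x for x in "ACGT" if x != codon[2])
                p, allele = genomic_snp(3 * k + 3, alt)
                add(f"{tid}_syn", p, p + 1, allele,
                    region="exonic", exon_sub="CDS", sub_class="synonymous", **base)
                break

        def find_substitution(pred):
            for k in range(1, n_aa):
                codon = cds[3 * k : 3 * k + 3]
                ref_aa = _CODON_AA[codon]
                for pos in range(3):
                    for alt in "ACGT":
                        if alt == codon[pos]:
                            continue
                        alt_codon = codon[:pos] + alt + codon[pos + 1 :]
                        alt_aa = _CODON_AA.get(alt_codon, "*")
                        if alt_aa != ref_aa and pred(ref_aa, alt_aa, k):
                            return k, pos, alt, ref_aa, alt_aa
            return None

        specs = [
            ("nonsyn_cons", lambda r, x, k: x != "*" and matrix.score(r, x) >= 0,
             dict(sub_class="nonsynonymous", cons_class="conserved")),
            ("nonsyn_uncons", lambda r, x, k: x != "*" and matrix.score(r, x) < 0,
             dict(sub_class="nonsynonymous", cons_class="unconserved")),
            ("stopgain", lambda r, x, k: x == "*",
             dict(sub_class="nonsynonymous", cons_class="unconserved", stop_gain=True)),
        ]
        for name, pred, exp in specs:
            hit = find_substitution(pred)
            if hit is None:
                continue
            k, pos, alt, ref_aa, alt_aa = hit
            p, allele = genomic_snp(3 * k + pos + 1, alt)
            extra = dict(exp)
            if name == "stopgain":
                extra["protein_len"] = k  # truncated right before codon k+1
            add(f"{tid}_{name}", p, p + 1, allele,
                region="exonic", exon_sub="CDS", **base, **extra)

        # a codon whose three bases are genomically contiguous (single exon piece)
        def contiguous_codon():
            for k in range(1, n_aa - 1):
                g = [cds_to_genomic(3 * k + i + 1, t) for i in range(3)]
                step = -1 if not plus else 1
                if g[1] == g[0] + step and g[2] == g[1] + step:
                    return k, g
            return None

        cc = contiguous_codon()
        if cc is not None:
            k, g = cc
            lo, hi = min(g), max(g) + 1
            prot = fixture.proteins[tid]
            add(f"{tid}_inframe_del", lo, hi, "",
                region="exonic", exon_sub="CDS", indel_class="amino_acid_indel",
                protein=prot[:k] + prot[k + 1 :], **base)
            add(f"{tid}_frameshift_del", lo, lo + 1, "",
                region="exonic", exon_sub="CDS", indel_class="frameshift", **base)
            add(f"{tid}_inframe_ins", lo + 1, lo + 1, "GGG",
                region="exonic", exon_sub="CDS", indel_class="amino_acid_indel", **base)
            add(f"{tid}_frameshift_ins", lo + 1, lo + 1, "G",
                region="exonic", exon_sub="CDS", indel_class="frameshift", **base)

        for d in fixture.annotation.domains_for(t):
            if d.aa_begin >= n_aa:
                continue
            k0 = max(1, d.aa_begin - 1)  # 0-based codon index of the domain's first aa
            codon = cds[3 * k0 : 3 * k0 + 3]
            ref_aa = _CODON_AA[codon]
            hit = None
            for pos in range(3):
                for alt in "ACGT":
                    if alt == codon[pos]:
                        continue
                    alt_aa = _CODON_AA.get(codon[:pos] + alt + codon[pos + 1 :], "*")
                    if alt_aa not in (ref_aa, "*"):
                        hit = (pos, alt)
                        break
                if hit:
                    break
            if hit is None:
                continue
            pos, alt = hit
            p, allele = genomic_snp(3 * k0 + pos + 1, alt)
            add(f"{tid}_domain", p, p + 1, allele,
                region="exonic", exon_sub="CDS", domain=d.domain_name, **base)
            break

    if fixture.annotation.known:
        k = fixture.annotation.known[0]
        add("panel_known", k.span.begin, k.span.begin + 1, snp_allele(k.span.begin),
            known=k.dbsnp_id)
    if fixture.annotation.repeats:
        r = fixture.annotation.repeats[0]
        add("panel_repeat", r.span.begin, r.span.begin + 1, snp_allele(r.span.begin),
            repeat=r.repeat_name)
    add("panel_intergenic", 100, 101, snp_allele(100), intergenic=True)
    return rows, expected


# ---------------------------------------------------------------------------
# Independent brute-force oracle
# ---------------------------------------------------------------------------


def oracle_label(
    position: int,
    allele: str,
    fixture: Fixture,
    promoter_window: int = 1000,
    donor_window: int = 10,
    acceptor_window: int = 6,
) -> frozenset:
    """Label set for a single-base substitution, by naive linear scans.

    Shares no logic with classifier_core: every rule is re-derived with
    plain per-position arithmetic.
    """
    p = position
    labels: set[tuple] = set()
    ann = fixture.annotation

    def hits(b, e):  # does feature (b, e) overlap the SNP (p, p+1)?
        if b == e:
            return p <= b <= p + 1
        return b <= p < e

    for kv in ann.known:
        if hits(kv.span.begin, kv.span.end):
            labels.add(("known", kv.dbsnp_id))
    for rp in ann.repeats:
        if hits(rp.span.begin, rp.span.end):
            labels.add(("repeat", rp.repeat_name))

    genic = False
    for g in ann.genes:
        for t in g.transcripts:
            exs = sorted(t.exons, key=lambda iv: iv.begin)
            lo, hi = exs[0].begin, exs[-1].end
            tl: set[tuple] = set()
            key = (g.gene_id, t.transcript_id)
            if lo <= p < hi:
                in_exon = any(ex.begin <= p < ex.end for ex in exs)
                if in_exon:
                    tl.add(("region", *key, "exonic"))
                    if t.cds_span is None:
                        tl.add(("exon_sub", *key, "noncoding_exon"))
                    else:
                        cb, ce = t.cds_span.begin, t.cds_span.end
                        if p < cb:
                            sub = "five_prime_UTR" if t.strand == "+" else "three_prime_UTR"
                        elif p >= ce:
                            sub = "three_prime_UTR" if t.strand == "+" else "five_prime_UTR"
                        else:
                            sub = "CDS"
                        tl.add(("exon_sub", *key, sub))
                else:
                    tl.add(("region", *key, "intronic"))
                    for ex_a, ex_b in zip(exs, exs[1:]):
                        a, b = ex_a.end, ex_b.begin
                        if a <= p < b:
                            if t.strand == "+":
                                if p - a + 1 <= donor_window:
                                    tl.add(("splice", *key, "five_prime_splice_site"))
                                if b - p <= acceptor_window:
                                    tl.add(("splice", *key, "three_prime_splice_site"))
                            else:
                                if b - p <= donor_window:
                                    tl.add(("splice", *key, "five_prime_splice_site"))
                                if p - a + 1 <= acceptor_window:
                                    tl.add(("splice", *key, "three_prime_splice_site"))
            else:
                if t.strand == "+":
                    if lo - promoter_window <= p < lo:
                        tl.add(("region", *key, "upstream_promoter"))
                    if hi <= p < hi + promoter_window:
                        tl.add(("region", *key, "downstream_transcript"))
                else:
                    if hi <= p < hi + promoter_window:
                        tl.add(("region", *key, "upstream_promoter"))
                    if lo - promoter_window <= p < lo:
                        tl.add(("region", *key, "downstream_transcript"))
            if tl:
                genic = True
                labels |= tl
    if not genic:
        labels.add(("intergenic",))
    return frozenset(labels)


def tree_label_set(tree) -> frozenset:
    """Flatten a ClassificationTree to the oracle's label-set vocabulary."""
    labels: set[tuple] = set()
    for kid in tree.known_ids:
        labels.add(("known", kid))
    for rep in tree.repeat_names:
        labels.add(("repeat", rep))
    if tree.intergenic:
        labels.add(("intergenic",))
    for gb in tree.gene_branches:
        for tb in gb.transcript_branches:
            key = (gb.gene_id, tb.transcript_id)
            for rl in tb.region_labels:
                labels.add(("region", *key, rl))
            for sp in tb.splice_labels:
                labels.add(("splice", *key, sp))
            for sub in tb.exon_sublabels:
                labels.add(("exon_sub", *key, sub))
    return frozenset(labels)
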