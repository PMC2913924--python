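"""Hierarchical decision-tree classification of one variant.

For every variant the tree first records collocation with known variants and
repeats, then classifies the variant against every overlapping gene and each
of its alternative transcripts: upstream promoter / downstream transcript
windows (default 1 kb from the transcript's first/last exon in coding
orientation), intronic with donor/acceptor splice-site windows (default
10 / 6 intronic bases in coding orientation, boundary included), or exonic
with 5' UTR / CDS / 3' UTR sub-regions.  CDS hits descend further into
codon-level effects (protein_effect module).

Variants that span a boundary receive every label they touch, on a single
branch per transcript, with a ``boundary_spanning`` note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_model import AnnotationSet, Interval, ReferenceRegion, TranscriptModel
from .protein_effect import BlosumMatrix, TranscriptEffect, load_blosum30, transcript_effect
from .variants_io import QueryVariant

UPSTREAM = "upstream_promoter"
DOWNSTREAM = "downstream_transcript"
INTRONIC = "intronic"
EXONIC = "exonic"

FIVE_SPLICE = "five_prime_splice_site"
THREE_SPLICE = "three_prime_splice_site"

UTR5 = "five_prime_UTR"
CDS = "CDS"
UTR3 = "three_prime_UTR"
NONCODING_EXON = "noncoding_exon"

REGION_ORDER = [UPSTREAM, EXONIC, INTRONIC, DOWNSTREAM]
SUBREGION_ORDER = [UTR5, CDS, UTR3, NONCODING_EXON]


@dataclass
class ClassifierParams:
    promoter_window: int = 1000  # bases upstream of first / downstream of last exon
    donor_window: int = 10  # intronic bases 3' of an exon (coding orientation)
    acceptor_window: int = 6  # intronic bases 5' of the next exon
    flank_len: int = 50


@dataclass
class TranscriptBranch:
    transcript_id: str
    region_labels: tuple[str, ...]
    distance_to_nearest_exon: int | None = None
    splice_labels: tuple[str, ...] = ()
    exon_sublabels: tuple[str, ...] = ()
    effect: TranscriptEffect | None = None
    notes: list[str] = field(default_factory=list)


@dataclass
class GeneBranch:
    gene_id: str
    transcript_branches: list[TranscriptBranch] = field(default_factory=list)


@dataclass
class ClassificationTree:
    variant: QueryVariant
    known_ids: list[str] = field(default_factory=list)
    repeat_names: list[str] = field(default_factory=list)
    gene_branches: list[GeneBranch] = field(default_factory=list)
    left_flank: str = ""
    right_flank: str = ""

    @property
    def intergenic(self) -> bool:
        return not self.gene_branches


# ---------------------------------------------------------------------------
# Per-transcript geometry
# ---------------------------------------------------------------------------


def _upstream_window(t: TranscriptModel, w: int) -> Interval:
    """Promoter window 5' of the transcript's first exon, in coding orientation."""
    env = t.envelope
    if t.strand == "-":
        return Interval(env.end, env.end + w)
    return Interval(max(0, env.begin - w), env.begin)


def _downstream_window(t: TranscriptModel, w: int) -> Interval:
    env = t.envelope
    if t.strand == "-":
        return Interval(max(0, env.begin - w), env.begin)
    return Interval(env.end, env.end + w)


def _splice_windows(intron: Interval, strand: str, params: ClassifierParams) -> tuple[Interval, Interval]:
    """(donor, acceptor) windows of one intron, clipped to the intron."""
    a, b = intron.begin, intron.end
    if strand == "-":
        donor = Interval(max(a, b - params.donor_window), b)
        acceptor = Interval(a, min(b, a + params.acceptor_window))
    else:
        donor = Interval(a, min(b, a + params.donor_window))
        acceptor = Interval(max(a, b - params.acceptor_window), b)
    return donor, acceptor


def gene_context(v: QueryVariant, transcript: TranscriptModel, params: ClassifierParams):
    """Coarse placement relative to one transcript.

    Returns ("within", None), ("upstream_promoter", d), ("downstream_transcript", d)
    or ("outside", None); d is the 0-space gap between the variant and the
    first (resp. last) exon in coding orientation.
    """
    env = transcript.envelope
    if v.span.overlaps(env):
        return "within", None
    first_exon = transcript.exons[-1] if transcript.strand == "-" else transcript.exons[0]
    last_exon = transcript.exons[0] if transcript.strand == "-" else transcript.exons[-1]
    if v.span.overlaps(_upstream_window(transcript, params.promoter_window)):
        return UPSTREAM, v.span.gap_to(first_exon)
    if v.span.overlaps(_downstream_window(transcript, params.promoter_window)):
        return DOWNSTREAM, v.span.gap_to(last_exon)
    return "outside", None


def transcript_context(v: QueryVariant, transcript: TranscriptModel):
    """("exonic", None) / ("intronic", distance) / both labels for spanning variants.

    Returns (labels, distance_to_nearest_exon); distance only when intronic.
    """
    labels = []
    if any(v.span.overlaps(ex) for ex in transcript.exons):
        labels.append(EXONIC)
    if any(v.span.overlaps(i) for i in transcript.introns):
        labels.append(INTRONIC)
    dist = None
    if INTRONIC in labels:
        dist = min(v.span.gap_to(ex) for ex in transcript.exons)
    return labels, dist


def splice_site_class(
    v: QueryVariant, transcript: TranscriptModel, params: ClassifierParams
) -> tuple[str, ...]:
    """Splice labels for an intronic variant (both when windows collide)."""
    labels = []
    for intron in transcript.introns:
        if not v.span.overlaps(intron):
            continue
        donor, acceptor = _splice_windows(intron, transcript.strand, params)
        if donor.length and v.span.overlaps(donor):
            labels.append(FIVE_SPLICE)
        if acceptor.length and v.span.overlaps(acceptor):
            labels.append(THREE_SPLICE)
    return tuple(dict.fromkeys(labels))


def exon_subregion(v: QueryVariant, transcript: TranscriptModel) -> tuple[str, ...]:
    """5' UTR / CDS / 3' UTR labels for an exonic variant (all touched)."""
    if transcript.cds_span is None:
        return (NONCODING_EXON,)
    c = transcript.cds_span
    labels = set()
    for ex in transcript.exons:
        for stripe, plus_label, minus_label in (
            (Interval(0, c.begin), UTR5, UTR3),
            (c, CDS, CDS),
            (Interval(c.end, max(c.end, ex.end)), UTR3, UTR5),
        ):
            piece = ex.intersect(stripe)
            if piece is None:
                # zero-length stripes still matter for insertion points at
                # the CDS boundary, but only the CDS stripe itself can match
                continue
            if v.span.overlaps(piece):
                labels.add(plus_label if transcript.strand == "+" else minus_label)
    return tuple(l for l in SUBREGION_ORDER if l in labels)


# ---------------------------------------------------------------------------
# Full classification
# ---------------------------------------------------------------------------


def classify(
    v: QueryVariant,
    ann: AnnotationSet,
    ref: ReferenceRegion,
    params: ClassifierParams | None = None,
    matrix: BlosumMatrix | None = None,
) -> ClassificationTree:
    """Traverse the decision tree for one variant.

    Total over valid inputs: every accepted variant receives the known/repeat
    assessments and either the intergenic verdict or at least one transcript
    branch across the overlapping genes.
    """
    params = params or ClassifierParams()
    matrix = matrix or _default_matrix()

    tree = ClassificationTree(variant=v)
    tree.known_ids = [k.dbsnp_id for k in ann.known_overlapping(v.span)]
    tree.repeat_names = [r.repeat_name for r in ann.repeats_overlapping(v.span)]
    tree.left_flank, tree.right_flank = _flanks(v, ref, params.flank_len)

    for gene in ann.genes_near(v.span, pad=params.promoter_window):
        gb = GeneBranch(gene_id=gene.gene_id)
        for t in gene.transcripts:
            branch = _classify_transcript(v, t, ann, ref, params, matrix)
            if branch is not None:
                gb.transcript_branches.append(branch)
        if gb.transcript_branches:
            tree.gene_branches.append(gb)
    return tree


def _classify_transcript(v, t, ann, ref, params, matrix) -> TranscriptBranch | None:
    region_labels: list[str] = []
    distance = None
    splice_labels: tuple[str, ...] = ()
    sublabels: tuple[str, ...] = ()
    effect = None
    notes: list[str] = []

    env = t.envelope
    if v.span.overlaps(env):
        inner, intron_dist = transcript_context(v, t)
        region_labels.extend(inner)
        if INTRONIC in inner:
            distance = intron_dist
            splice_labels = splice_site_class(v, t, params)
        if EXONIC in inner:
            sublabels = exon_subregion(v, t)
            if CDS in sublabels and t.cds_span is not None:
                effect = transcript_effect(v, t, ref, matrix, ann.domains_for(t))

    up = _upstream_window(t, params.promoter_window)
    if up.length and v.span.overlaps(up) and not v.span.overlaps(env):
        region_labels.append(UPSTREAM)
        first_exon = t.exons[-1] if t.strand == "-" else t.exons[0]
        d = v.span.gap_to(first_exon)
        distance = d if distance is None else min(distance, d)
    down = _downstream_window(t, params.promoter_window)
    if down.length and v.span.overlaps(down) and not v.span.overlaps(env):
        region_labels.append(DOWNSTREAM)
        last_exon = t.exons[0] if t.strand == "-" else t.exons[-1]
        d = v.span.gap_to(last_exon)
        distance = d if distance is None else min(distance, d)

    if not region_labels:
        return None
    ordered = tuple(l for l in REGION_ORDER if l in region_labels)
    if len(ordered) > 1 or len(sublabels) > 1:
        notes.append("boundary_spanning")
    return TranscriptBranch(
        transcript_id=t.transcript_id,
        region_labels=ordered,
        distance_to_nearest_exon=distance,
        splice_labels=splice_labels,
        exon_sublabels=sublabels,
        effect=effect,
        notes=notes,
    )


def _flanks(v: QueryVariant, ref: ReferenceRegion, flank_len: int) -> tuple[str, str]:
    left = ref.sequence[max(0, v.span.begin - flank_len) : v.span.begin]
    right = ref.sequence[v.span.end : v.span.end + flank_len]
    return left, right


_MATRIX_CACHE: dict[str, BlosumMatrix] = {}


def _default_matrix() -> BlosumMatrix:
    if "blosum30" not in _MATRIX_CACHE:
        _MATRIX_CACHE["blosum30"] = load_blosum30()
    return _MATRIX_CACHE["blosum30"]
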