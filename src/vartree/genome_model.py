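"""Reference region and annotation data model.

All coordinates are 0-space-based: a position is the gap *between* residues,
running from 0 to the region length ``s``.  An interval ``(b, e)`` covers
residues ``b+1 .. e`` in 1-residue-based terms, and ``b == e`` denotes an
insertion point between two residues.  This single convention describes
substitutions, insertions and deletions uniformly.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger("vartree")

VALID_BASES = frozenset("ACGTN")

ANNOTATION_COLUMNS = [
    "feature_type",
    "feature_id",
    "parent_id",
    "begin",
    "end",
    "strand",
    "attributes",
]


class InputError(Exception):
    """Fatal problem with an input file (unreadable, inconsistent, empty)."""


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Interval:
    """0-space-based interval; ``begin == end`` is an insertion point."""

    begin: int
    end: int

    def __post_init__(self) -> None:
        if self.begin < 0 or self.begin > self.end:
            raise ValueError(f"invalid 0-space interval ({self.begin}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.begin

    @property
    def is_point(self) -> bool:
        return self.begin == self.end

    def overlaps(self, other: "Interval") -> bool:
        """Exact 0-space overlap.

        Non-degenerate intervals overlap when they share at least one
        residue; an insertion point at coordinate ``c`` overlaps any
        interval ``(b, e)`` with ``b <= c <= e``, so a boundary insertion
        attaches to the features on both sides.
        """
        if self.is_point:
            return other.begin <= self.begin <= other.end
        if other.is_point:
            return self.begin <= other.begin <= self.end
        return self.begin < other.end and other.begin < self.end

    def gap_to(self, other: "Interval") -> int:
        """Number of residues strictly between the two intervals (0 if they touch)."""
        return max(0, other.begin - self.end, self.begin - other.end)

    def intersect(self, other: "Interval") -> "Interval | None":
        b, e = max(self.begin, other.begin), min(self.end, other.end)
        return Interval(b, e) if b < e else None


# ---------------------------------------------------------------------------
# Feature types
# ---------------------------------------------------------------------------


@dataclass
class ReferenceRegion:
    """The region-of-interest sequence providing the local coordinate frame."""

    name: str
    sequence: str
    genome_offset: int | None = None  # 1-based genomic start, if known

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, iv: Interval) -> str:
        return self.sequence[iv.begin : iv.end]


@dataclass
class TranscriptModel:
    transcript_id: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds_span: Interval | None = None
    protein_id: str | None = None

    @property
    def envelope(self) -> Interval:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        return Interval(self.exons[0].begin, self.exons[-1].end)

    @property
    def introns(self) -> list[Interval]:
        return [
            Interval(a.end, b.begin)
            for a, b in zip(self.exons, self.exons[1:])
            if b.begin > a.end
        ]

    def coding_pieces(self) -> list[Interval]:
        """exon ∩ cds_span pieces in genomic (plus-strand) order."""
        if self.cds_span is None:
            return []
        pieces = [p for ex in self.exons if (p := ex.intersect(self.cds_span))]
        return pieces


@dataclass
class GeneModel:
    gene_id: str
    strand: str
    span: Interval
    transcripts: list[TranscriptModel] = field(default_factory=list)


@dataclass
class ProteinDomain:
    parent_id: str  # transcript or protein id
    domain_name: str
    aa_begin: int  # 1-based inclusive
    aa_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.aa_begin <= self.aa_end):
            raise ValueError(f"invalid domain range {self.aa_begin}..{self.aa_end}")


@dataclass
class RepeatFeature:
    span: Interval
    repeat_name: str


@dataclass
class KnownVariant:
    span: Interval
    dbsnp_id: str


class AnnotationSet:
    """Indexed container for every feature class of one region of interest.

    Interval indexes give O(log n + k) candidate retrieval; candidates are
    re-filtered with the exact 0-space overlap rule (the index stores
    ``(begin, end + 1)`` so boundary-touching and point features are never
    missed).
    """

    def __init__(
        self,
        genes: list[GeneModel] | None = None,
        domains: list[ProteinDomain] | None = None,
        repeats: list[RepeatFeature] | None = None,
        known: list[KnownVariant] | None = None,
    ):
        self.genes = genes or []
        self.domains = domains or []
        self.repeats = repeats or []
        self.known = known or []
        self._gene_tree = IntervalTree()
        for g in self.genes:
            self._gene_tree.addi(g.span.begin, g.span.end + 1, g)
        self._repeat_tree = IntervalTree()
        for r in self.repeats:
            self._repeat_tree.addi(r.span.begin, r.span.end + 1, r)
        self._known_tree = IntervalTree()
        for k in self.known:
            self._known_tree.addi(k.span.begin, k.span.end + 1, k)

    # -- queries ---------------------------------------------------------

    @staticmethod
    def _exact(tree: IntervalTree, iv: Interval) -> list:
        hits = tree.overlap(iv.begin, iv.end + 1)
        return [h.data for h in hits if iv.overlaps(_feature_span(h.data))]

    def genes_near(self, iv: Interval, pad: int = 0) -> list[GeneModel]:
        """Genes whose span, widened by ``pad`` bases, overlaps ``iv``."""
        padded = Interval(max(0, iv.begin - pad), iv.end + pad)
        hits = self._gene_tree.overlap(padded.begin, padded.end + 1)
        out = [
            h.data
            for h in hits
            if padded.overlaps(Interval(h.data.span.begin, h.data.span.end))
        ]
        return sorted(out, key=lambda g: (g.span, g.gene_id))

    def repeats_overlapping(self, iv: Interval) -> list[RepeatFeature]:
        return sorted(self._exact(self._repeat_tree, iv), key=lambda r: (r.span, r.repeat_name))

    def known_overlapping(self, iv: Interval) -> list[KnownVariant]:
        return sorted(self._exact(self._known_tree, iv), key=lambda k: (k.span, k.dbsnp_id))

    def domains_for(self, transcript: TranscriptModel) -> list[ProteinDomain]:
        ids = {transcript.transcript_id}
        if transcript.protein_id:
            ids.add(transcript.protein_id)
        return [d for d in self.domains if d.parent_id in ids]

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return [t for g in self.genes for t in g.transcripts]


def _feature_span(feature) -> Interval:
    return feature.span


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _mask_sequence(seq: str) -> tuple[str, int]:
    """Uppercase and mask characters outside {A,C,G,T,N} to N."""
    seq = seq.upper()
    bad = sum(1 for c in seq if c not in VALID_BASES)
    if bad:
        seq = "".join(c if c in VALID_BASES else "N" for c in seq)
    return seq, bad


def read_reference_fasta(path) -> ReferenceRegion:
    """Load the first FASTA record as the region of interest."""
    try:
        record = next(SeqIO.parse(str(path), "fasta"), None)
    except FileNotFoundError as exc:
        raise InputError(f"reference FASTA not found: {path}") from exc
    if record is None or len(record.seq) == 0:
        raise InputError(f"reference FASTA {path} has no non-empty record")
    seq, masked = _mask_sequence(str(record.seq))
    if masked:
        log.warning("reference %s: %d non-ACGTN characters masked to N", record.id, masked)
    return ReferenceRegion(name=record.id, sequence=seq)


def read_annotation_tsv(path) -> AnnotationSet:
    """Parse the native annotation TSV into a linked, indexed AnnotationSet.

    Schema (tab-separated, header required)::

        feature_type  feature_id  parent_id  begin  end  strand  attributes

    feature_type ∈ {gene, transcript, exon, cds, domain, repeat,
    known_variant}; attributes is a semicolon-separated key=value list.
    Domain rows carry 1-based inclusive amino-acid coordinates in begin/end;
    every other row is in local 0-space coordinates.
    """
    with open(path, newline="") as fh:
        return _parse_annotation(fh, str(path))


def parse_annotation_text(text: str) -> AnnotationSet:
    return _parse_annotation(io.StringIO(text), "<string>")


def _parse_attrs(raw: str) -> dict[str, str]:
    attrs = {}
    for part in raw.split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            attrs[k] = v
    return attrs


KNOWN_FEATURE_TYPES = {"gene", "transcript", "exon", "cds", "domain", "repeat", "known_variant"}


def _parse_annotation(fh, source: str) -> AnnotationSet:
    reader = csv.reader(fh, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise InputError(f"{source}: empty annotation file (header required)")
    if header != ANNOTATION_COLUMNS:
        raise InputError(
            f"{source}: bad annotation header {header!r}; expected {ANNOTATION_COLUMNS!r}"
        )

    rows = []
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(ANNOTATION_COLUMNS):
            raise InputError(f"{source}:{lineno}: expected {len(ANNOTATION_COLUMNS)} columns")
        ftype, fid, parent, b, e, strand, attrs = row
        if ftype not in KNOWN_FEATURE_TYPES:
            raise InputError(f"{source}:{lineno}: unknown feature_type {ftype!r}")
        try:
            begin, end = int(b), int(e)
        except ValueError:
            raise InputError(f"{source}:{lineno}: non-integer coordinates {b!r}/{e!r}")
        if begin > end:
            raise InputError(f"{source}:{lineno}: begin > end ({begin} > {end})")
        rows.append((lineno, ftype, fid, parent, begin, end, strand, _parse_attrs(attrs)))

    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, TranscriptModel] = {}
    t_parent: dict[str, str] = {}
    domains, repeats, known = [], [], []

    for lineno, ftype, fid, parent, begin, end, strand, attrs in rows:
        if ftype == "gene":
            genes[fid] = GeneModel(gene_id=fid, strand=strand, span=Interval(begin, end))
    for lineno, ftype, fid, parent, begin, end, strand, attrs in rows:
        if ftype == "transcript":
            if parent not in genes:
                raise InputError(f"{source}:{lineno}: transcript {fid} references unknown gene {parent!r}")
            t = TranscriptModel(
                transcript_id=fid,
                strand=genes[parent].strand,
                protein_id=attrs.get("protein_id"),
            )
            transcripts[fid] = t
            t_parent[fid] = parent
            genes[parent].transcripts.append(t)
    for lineno, ftype, fid, parent, begin, end, strand, attrs in rows:
        if ftype == "exon":
            if parent not in transcripts:
                raise InputError(f"{source}:{lineno}: exon {fid} references unknown transcript {parent!r}")
            transcripts[parent].exons.append(Interval(begin, end))
        elif ftype == "cds":
            if parent not in transcripts:
                raise InputError(f"{source}:{lineno}: cds {fid} references unknown transcript {parent!r}")
            transcripts[parent].cds_span = Interval(begin, end)
        elif ftype == "domain":
            if begin < 1:
                raise InputError(f"{source}:{lineno}: domain coordinates are 1-based (got {begin})")
            domains.append(ProteinDomain(parent_id=parent, domain_name=fid, aa_begin=begin, aa_end=end))
        elif ftype == "repeat":
            repeats.append(RepeatFeature(span=Interval(begin, end), repeat_name=fid))
        elif ftype == "known_variant":
            known.append(KnownVariant(span=Interval(begin, end), dbsnp_id=fid))

    for t in transcripts.values():
        t.exons.sort()

    return AnnotationSet(genes=list(genes.values()), domains=domains, repeats=repeats, known=known)


def write_annotation_tsv(ann: AnnotationSet) -> str:
    """Serialize an AnnotationSet back to the native TSV dialect."""
    out = io.StringIO()
    w = csv.writer(out, delimiter="\t", lineterminator="\n")
    w.writerow(ANNOTATION_COLUMNS)
    for g in ann.genes:
        w.writerow(["gene", g.gene_id, "", g.span.begin, g.span.end, g.strand, ""])
        for t in g.transcripts:
            attrs = f"protein_id={t.protein_id}" if t.protein_id else ""
            env = t.envelope if t.exons else g.span
            w.writerow(["transcript", t.transcript_id, g.gene_id, env.begin, env.end, t.strand, attrs])
            for i, ex in enumerate(t.exons, 1):
                w.writerow(["exon", f"{t.transcript_id}.e{i}", t.transcript_id, ex.begin, ex.end, t.strand, ""])
            if t.cds_span is not None:
                w.writerow(["cds", f"{t.transcript_id}.cds", t.transcript_id,
                            t.cds_span.begin, t.cds_span.end, t.strand, ""])
    for d in ann.domains:
        w.writerow(["domain", d.domain_name, d.parent_id, d.aa_begin, d.aa_end, ".", ""])
    for r in ann.repeats:
        w.writerow(["repeat", r.repeat_name, "", r.span.begin, r.span.end, ".", ""])
    for k in ann.known:
        w.writerow(["known_variant", k.dbsnp_id, "", k.span.begin, k.span.end, ".", ""])
    return out.getvalue()


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_annotation(ann: AnnotationSet, ref: ReferenceRegion) -> list[str]:
    """Report human-readable consistency violations (empty list == clean).

    CDS-length-not-multiple-of-3 is a warning-class entry (prefixed
    "warning:"); everything else is a hard violation.
    """
    issues: list[str] = []

    def check_range(iv: Interval, what: str) -> None:
        if iv.begin < 0 or iv.end > ref.length:
            issues.append(f"{what}: interval ({iv.begin}, {iv.end}) out of range 0..{ref.length}")

    for g in ann.genes:
        check_range(g.span, f"gene {g.gene_id}")
        for t in g.transcripts:
            if not t.exons:
                issues.append(f"transcript {t.transcript_id}: no exons")
                continue
            for ex in t.exons:
                check_range(ex, f"exon of {t.transcript_id}")
            for a, b in zip(t.exons, t.exons[1:]):
                if b.begin < a.end:
                    issues.append(f"transcript {t.transcript_id}: overlapping exons "
                                  f"({a.begin},{a.end}) and ({b.begin},{b.end})")
            env = t.envelope
            if not (g.span.begin <= env.begin and env.end <= g.span.end):
                issues.append(f"gene {g.gene_id}: span does not contain transcript {t.transcript_id}")
            if t.cds_span is not None:
                c = t.cds_span
                if not (env.begin <= c.begin and c.end <= env.end):
                    issues.append(f"transcript {t.transcript_id}: CDS span outside exon envelope")
                if not any(ex.begin <= c.begin < ex.end for ex in t.exons):
                    issues.append(f"transcript {t.transcript_id}: CDS begin not inside an exon")
                if not any(ex.begin < c.end <= ex.end for ex in t.exons):
                    issues.append(f"transcript {t.transcript_id}: CDS end not inside an exon")
                cds_len = sum(p.length for p in t.coding_pieces())
                if cds_len % 3 != 0:
                    issues.append(f"warning: transcript {t.transcript_id}: CDS length {cds_len} "
                                  "not a multiple of 3")
    for r in ann.repeats:
        check_range(r.span, f"repeat {r.repeat_name}")
    for k in ann.known:
        check_range(k.span, f"known variant {k.dbsnp_id}")
    for d in ann.domains:
        if d.parent_id not in {t.transcript_id for t in ann.transcripts} | {
            t.protein_id for t in ann.transcripts if t.protein_id
        }:
            issues.append(f"domain {d.domain_name}: unknown parent {d.parent_id}")
    return issues


# ---------------------------------------------------------------------------
# GFF3 / BED adapter
# ---------------------------------------------------------------------------


def gff3_to_annotation(
    gff3_path,
    region_name: str,
    region_interval_1based: tuple[int, int],
    repeats_bed=None,
    known_bed=None,
) -> str:
    """Project GFF3 gene models (and optional BED tracks) into the local TSV.

    ``region_interval_1based`` is the (start, end) of the region of interest
    on seqid ``region_name``, in the GFF3's 1-based inclusive coordinates.
    Genomic residue ``r`` maps to local 0-space interval
    ``(r - start, r - start + 1)``; features partially outside the region are
    clipped (with a warning), features wholly outside are dropped.
    CDS fragments of a transcript are merged into a single CDS span.
    """
    import gffutils

    r_start, r_end = region_interval_1based
    if r_start < 1 or r_start > r_end:
        raise InputError(f"bad region interval {region_interval_1based}")
    s = r_end - r_start + 1

    def project(g_start: int, g_end: int, what: str) -> Interval | None:
        b = g_start - r_start
        e = g_end - r_start + 1
        if e <= 0 or b >= s:
            log.warning("%s at %d..%d outside region, dropped", what, g_start, g_end)
            return None
        if b < 0 or e > s:
            log.warning("%s at %d..%d clipped to region", what, g_start, g_end)
            b, e = max(0, b), min(s, e)
        return Interval(b, e)

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )

    genes, domains, repeats, known = [], [], [], []
    transcript_types = {"mRNA", "transcript"}
    for gf in db.features_of_type("gene"):
        if gf.seqid != region_name:
            continue
        g_iv = project(gf.start, gf.end, f"gene {gf.id}")
        if g_iv is None:
            continue
        gene = GeneModel(gene_id=gf.id, strand=gf.strand, span=g_iv)
        for tf in db.children(gf, level=1):
            if tf.featuretype not in transcript_types:
                continue
            t = TranscriptModel(transcript_id=tf.id, strand=gf.strand,
                                protein_id=tf.attributes.get("protein_id", [None])[0])
            cds_lo, cds_hi = None, None
            for child in db.children(tf, level=1):
                if child.featuretype == "exon":
                    iv = project(child.start, child.end, f"exon of {tf.id}")
                    if iv is not None:
                        t.exons.append(iv)
                elif child.featuretype == "CDS":
                    iv = project(child.start, child.end, f"CDS of {tf.id}")
                    if iv is not None:
                        cds_lo = iv.begin if cds_lo is None else min(cds_lo, iv.begin)
                        cds_hi = iv.end if cds_hi is None else max(cds_hi, iv.end)
            t.exons.sort()
            if cds_lo is not None:
                t.cds_span = Interval(cds_lo, cds_hi)
            if t.exons:
                gene.transcripts.append(t)
        if gene.transcripts:
            env_b = min(t.envelope.begin for t in gene.transcripts)
            env_e = max(t.envelope.end for t in gene.transcripts)
            gene.span = Interval(min(gene.span.begin, env_b), max(gene.span.end, env_e))
            genes.append(gene)

    for bed_path, sink, cls in (
        (repeats_bed, repeats, RepeatFeature),
        (known_bed, known, KnownVariant),
    ):
        if bed_path is None:
            continue
        with open(bed_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                chrom, b0, e0 = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else f"{chrom}:{b0}-{e0}"
                if chrom != region_name:
                    continue
                # BED is 0-based half-open on the genome; shift to local frame
                iv = project(b0 + 1, e0, name)
                if iv is None:
                    continue
                if cls is RepeatFeature:
                    sink.append(RepeatFeature(span=iv, repeat_name=name))
                else:
                    sink.append(KnownVariant(span=iv, dbsnp_id=name))

    ann = AnnotationSet(genes=genes, domains=domains, repeats=repeats, known=known)
    return write_annotation_tsv(ann)
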