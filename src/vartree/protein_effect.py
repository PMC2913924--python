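"""Codon-level consequence prediction.

Maps CDS-overlapping variants into coding and amino-acid coordinates,
classifies substitutions (synonymous / non-synonymous, conserved /
unconserved by BLOSUM30 sign) and indels (frameshift / amino-acid indel by
net length change mod 3), rebuilds and translates the mutant coding
sequence, and reports impacted protein domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

from .genome_model import Interval, ProteinDomain, ReferenceRegion, TranscriptModel

STOP = "*"
_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = STOP

STANDARD_AAS = "ARNDCQEGHILKMFPSTWYV"


# ---------------------------------------------------------------------------
# Substitution matrix
# ---------------------------------------------------------------------------


class BlosumMatrix:
    """Integer substitution scores over the 20 standard amino acids.

    Parsed from NCBI matrix text format; extra columns (B, Z, X, *) in the
    file are ignored — the stop rule is applied *before* any matrix lookup.
    """

    def __init__(self, scores: dict[tuple[str, str], int], name: str = "BLOSUM"):
        self.name = name
        self._scores = scores
        for a in STANDARD_AAS:
            for b in STANDARD_AAS:
                if (a, b) not in scores:
                    raise ValueError(f"{name}: missing pair {a}/{b}")
                if scores[a, b] != scores[b, a]:
                    raise ValueError(f"{name}: asymmetric pair {a}/{b}")

    def score(self, a: str, b: str) -> int:
        try:
            return self._scores[a, b]
        except KeyError:
            raise KeyError(f"amino acid pair {a}/{b} not in {self.name}")

    @classmethod
    def from_text(cls, text: str, name: str = "BLOSUM") -> "BlosumMatrix":
        cols: list[str] = []
        scores: dict[tuple[str, str], int] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if not cols:
                cols = fields
                continue
            row_aa, values = fields[0], fields[1:]
            for col_aa, val in zip(cols, values):
                if row_aa in STANDARD_AAS and col_aa in STANDARD_AAS:
                    scores[row_aa, col_aa] = int(val)
        if not cols:
            raise ValueError(f"{name}: no matrix content found")
        return cls(scores, name=name)

    @classmethod
    def from_file(cls, path) -> "BlosumMatrix":
        with open(path) as fh:
            return cls.from_text(fh.read(), name=str(path))


def load_blosum30() -> BlosumMatrix:
    """The packaged BLOSUM30 matrix (blocks clustered at 30% identity)."""
    text = resources.files("vartree").joinpath("data/BLOSUM30.txt").read_text()
    return BlosumMatrix.from_text(text, name="BLOSUM30")


# ---------------------------------------------------------------------------
# Coordinate mapping and translation
# ---------------------------------------------------------------------------


def spliced_cds_sequence(transcript: TranscriptModel, ref: ReferenceRegion) -> str:
    """Concatenated exon ∩ CDS pieces in coding order (revcomp on minus)."""
    pieces = transcript.coding_pieces()
    if not pieces:
        raise ValueError(f"transcript {transcript.transcript_id} has no CDS pieces")
    seq = "".join(ref.slice(p) for p in pieces)
    return reverse_complement(seq) if transcript.strand == "-" else seq


def genomic_to_cds(position: int, transcript: TranscriptModel) -> int:
    """1-based CDS index of the base covering (position, position+1).

    Counts coding bases in coding orientation; raises if the base is not
    coding (caller pre-filters intronic/UTR positions).
    """
    pieces = transcript.coding_pieces()
    if transcript.strand == "-":
        offset = 0
        for p in reversed(pieces):
            if p.begin <= position < p.end:
                return offset + (p.end - position - 1) + 1
            offset += p.length
    else:
        offset = 0
        for p in pieces:
            if p.begin <= position < p.end:
                return offset + (position - p.begin) + 1
            offset += p.length
    raise ValueError(f"position {position} is not coding in {transcript.transcript_id}")


def cds_to_genomic(cds_index: int, transcript: TranscriptModel) -> int:
    """Inverse of genomic_to_cds: 0-space begin of the cds_index-th coding base."""
    pieces = transcript.coding_pieces()
    remaining = cds_index - 1
    ordered = list(reversed(pieces)) if transcript.strand == "-" else pieces
    for p in ordered:
        if remaining < p.length:
            if transcript.strand == "-":
                return p.end - remaining - 1
            return p.begin + remaining
        remaining -= p.length
    raise ValueError(f"CDS index {cds_index} beyond CDS of {transcript.transcript_id}")


def cds_to_aa(cds_index: int) -> tuple[int, int]:
    """(1-based codon number, 0-based offset within the codon)."""
    if cds_index < 1:
        raise ValueError("CDS indexes are 1-based")
    return math.ceil(cds_index / 3), (cds_index - 1) % 3


def translate(cds: str) -> str:
    """Standard-code translation, truncated at (and excluding) the first stop.

    Codons containing anything outside {A,C,G,T} translate to 'X'; a
    trailing partial codon is ignored.
    """
    protein = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        aa = _CODON_TO_AA.get(codon, "X")
        if aa == STOP:
            break
        protein.append(aa)
    return "".join(protein)


def codon_aa(codon: str) -> str:
    return _CODON_TO_AA.get(codon, "X")


# ---------------------------------------------------------------------------
# Classification primitives
# ---------------------------------------------------------------------------

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
CONSERVED = "conserved"
UNCONSERVED = "unconserved"
FRAMESHIFT = "frameshift"
AA_INDEL = "amino_acid_indel"


def classify_substitution(ref_codon: str, alt_codon: str) -> tuple[str, str, str]:
    """(class, ref_aa, alt_aa) for a single-codon substitution.

    Synonymous iff both codons encode the same product (stop counts as a
    product, so stop→stop is synonymous).  Codons containing N are the
    caller's problem — it must omit the class and attach a note.
    """
    if len(ref_codon) != 3 or len(alt_codon) != 3:
        raise ValueError("codons must be trinucleotides")
    ref_aa, alt_aa = codon_aa(ref_codon), codon_aa(alt_codon)
    cls = SYNONYMOUS if ref_aa == alt_aa else NONSYNONYMOUS
    return cls, ref_aa, alt_aa


def conservation_class(ref_aa: str, alt_aa: str, matrix: BlosumMatrix) -> str:
    """Unconserved iff the matrix score is negative or the change hits a stop."""
    if ref_aa == alt_aa:
        raise ValueError("conservation is defined for non-synonymous changes only")
    if STOP in (ref_aa, alt_aa):
        return UNCONSERVED
    return UNCONSERVED if matrix.score(ref_aa, alt_aa) < 0 else CONSERVED


def classify_indel(net_length_change: int) -> str:
    if net_length_change == 0:
        raise ValueError("not an indel: net length change is 0")
    return FRAMESHIFT if net_length_change % 3 != 0 else AA_INDEL


def impacted_domains(aa_begin: int, aa_end: int, domains: list[ProteinDomain]) -> list[str]:
    """Names of domains whose 1-based inclusive aa range overlaps [aa_begin, aa_end]."""
    return [d.domain_name for d in domains if d.aa_begin <= aa_end and aa_begin <= d.aa_end]


# ---------------------------------------------------------------------------
# Mutant protein prediction
# ---------------------------------------------------------------------------


def _map_piece(piece: Interval, b: int, e: int, a_len: int) -> Interval | None:
    """Project an exonic piece through the edit (b, e) → allele of a_len bases.

    Coordinates outside the edit shift by the net length change; boundaries
    that fall strictly inside the edited span clamp so that the replacement
    allele attaches to the piece in which the edit begins.  A pure insertion
    point at a piece boundary attaches to the genomically-following piece.
    """
    shift = a_len - (e - b)

    def map_boundary(x: int) -> int:
        if x <= b:
            return x
        if x >= e:
            return x + shift
        # strictly inside the edited span
        if shift == 0:
            return x  # block substitution: 1:1 alignment
        return b + a_len

    map_begin = map_end = map_boundary

    nb, ne = map_begin(piece.begin), map_end(piece.end)
    return Interval(nb, ne) if ne > nb else None


@dataclass
class MutantPrediction:
    protein: str
    ref_protein: str
    mutant_cds_length: int
    ref_cds_length: int
    notes: list[str] = field(default_factory=list)

    @property
    def net_cds_change(self) -> int:
        return self.mutant_cds_length - self.ref_cds_length

    def mutant_cds(self) -> str | None:  # pragma: no cover - debugging aid
        return None


def _analyze_mutant(transcript: TranscriptModel, variant, ref: ReferenceRegion) -> MutantPrediction:
    b, e = variant.span.begin, variant.span.end
    allele = variant.plus_allele
    mseq = ref.sequence[:b] + allele + ref.sequence[e:]

    cds_pieces = transcript.coding_pieces()
    if not cds_pieces:
        raise ValueError(f"transcript {transcript.transcript_id} has no CDS")
    env = transcript.envelope
    # Extend from the translation start through the transcript's last exon so
    # that stop-loss / frameshift read-through can find a downstream stop.
    if transcript.strand == "-":
        tail_window = Interval(env.begin, transcript.cds_span.end)
    else:
        tail_window = Interval(transcript.cds_span.begin, env.end)
    ext_pieces = [p for ex in transcript.exons if (p := ex.intersect(tail_window))]

    def splice(pieces: list[Interval], seq: str) -> str:
        s = "".join(seq[p.begin : p.end] for p in pieces)
        return reverse_complement(s) if transcript.strand == "-" else s

    mut_cds_pieces = [mp for p in cds_pieces if (mp := _map_piece(p, b, e, len(allele)))]
    mut_ext_pieces = [mp for p in ext_pieces if (mp := _map_piece(p, b, e, len(allele)))]

    ref_cds = splice(cds_pieces, ref.sequence)
    mut_cds_len = sum(p.length for p in mut_cds_pieces)
    mut_ext = splice(mut_ext_pieces, mseq)

    notes: list[str] = []
    ref_protein = translate(ref_cds)
    if mut_ext[:3] != "ATG":
        notes.append("start_lost")
        protein = ""
    else:
        protein = translate(mut_ext)
        net = mut_cds_len - len(ref_cds)
        if net % 3 == 0 and 3 * (len(protein) + 1) > mut_cds_len:
            # in-frame translation ran past the annotated CDS end
            notes.append("stop_lost")
    return MutantPrediction(
        protein=protein,
        ref_protein=ref_protein,
        mutant_cds_length=mut_cds_len,
        ref_cds_length=len(ref_cds),
        notes=notes,
    )


def predict_mutant_protein(transcript: TranscriptModel, variant, ref: ReferenceRegion) -> str:
    """Mutant protein after splicing the plus-strand allele into the genome.

    The mutant spliced CDS is rebuilt from the (edit-projected) exon
    structure and translated with stop-codon truncation; translation may run
    into the 3' exonic sequence when the annotated stop is destroyed.
    """
    return _analyze_mutant(transcript, variant, ref).protein


# ---------------------------------------------------------------------------
# Full per-transcript effect
# ---------------------------------------------------------------------------


@dataclass
class TranscriptEffect:
    cds_position: int
    aa_position: int
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    substitution_class: str | None = None
    conservation_class: str | None = None
    indel_class: str | None = None
    impacted_domains: list[str] = field(default_factory=list)
    predicted_protein: str | None = None
    notes: list[str] = field(default_factory=list)


def _coding_bases_in_span(variant, transcript: TranscriptModel) -> list[int]:
    """0-space begins of reference coding bases covered by the variant span."""
    out = []
    for p in transcript.coding_pieces():
        lo, hi = max(p.begin, variant.span.begin), min(p.end, variant.span.end)
        out.extend(range(lo, hi))
    return out


def _insertion_cds_anchor(variant, transcript: TranscriptModel) -> int | None:
    """CDS index of the first coding base at/after an insertion point, in coding orientation."""
    c = variant.span.begin
    if transcript.strand == "-":
        candidates = [(c - 1, 0), (c, 1)]
    else:
        candidates = [(c, 0), (c - 1, 1)]
    for pos, bump in candidates:
        try:
            return genomic_to_cds(pos, transcript) + bump
        except ValueError:
            continue
    return None


def transcript_effect(
    variant,
    transcript: TranscriptModel,
    ref: ReferenceRegion,
    matrix: BlosumMatrix,
    domains: list[ProteinDomain],
) -> TranscriptEffect | None:
    """Complete CDS/protein-level consequence of one variant on one transcript.

    Returns None when the variant does not actually touch a coding base (the
    classifier may still have flagged a CDS boundary insertion point that the
    edit convention places outside the coding sequence).
    """
    affected = _coding_bases_in_span(variant, transcript)
    if affected:
        cds_idxs = [genomic_to_cds(p, transcript) for p in affected]
        first_cds, last_cds = min(cds_idxs), max(cds_idxs)
    else:
        anchor = _insertion_cds_anchor(variant, transcript)
        if anchor is None:
            return None
        first_cds = last_cds = anchor

    aa_first, _ = cds_to_aa(first_cds)
    aa_last, _ = cds_to_aa(last_cds)

    analysis = _analyze_mutant(transcript, variant, ref)
    eff = TranscriptEffect(
        cds_position=first_cds,
        aa_position=aa_first,
        predicted_protein=analysis.protein,
        notes=list(variant.notes) + analysis.notes,
    )

    net = analysis.net_cds_change
    if variant.variant_type == "substitution" and net == 0:
        if aa_first == aa_last and len(affected) == variant.span.length:
            ref_cds = spliced_cds_sequence(transcript, ref)
            mut_cds_full = _mutant_cds_string(transcript, variant, ref)
            lo = 3 * (aa_first - 1)
            eff.ref_codon = ref_cds[lo : lo + 3]
            eff.alt_codon = mut_cds_full[lo : lo + 3]
            if "N" in eff.ref_codon or "N" in eff.alt_codon:
                eff.notes.append("ambiguous_codon")
            else:
                cls, ref_aa, alt_aa = classify_substitution(eff.ref_codon, eff.alt_codon)
                eff.substitution_class, eff.ref_aa, eff.alt_aa = cls, ref_aa, alt_aa
                if cls == NONSYNONYMOUS:
                    eff.conservation_class = conservation_class(ref_aa, alt_aa, matrix)
        else:
            eff.notes.append("multi_codon_substitution")
    elif net != 0:
        eff.indel_class = classify_indel(net)
    elif variant.variant_type != "substitution":
        eff.notes.append("indel_without_coding_length_change")

    if eff.indel_class == FRAMESHIFT:
        dom_range = (aa_first, max(aa_first, len(analysis.ref_protein)))
    else:
        dom_range = (aa_first, aa_last)
    eff.impacted_domains = impacted_domains(dom_range[0], dom_range[1], domains)
    return eff


def _mutant_cds_string(transcript: TranscriptModel, variant, ref: ReferenceRegion) -> str:
    """Mutant spliced CDS (no stop truncation) — substitution codon lookup."""
    b, e = variant.span.begin, variant.span.end
    allele = variant.plus_allele
    mseq = ref.sequence[:b] + allele + ref.sequence[e:]
    pieces = [mp for p in transcript.coding_pieces() if (mp := _map_piece(p, b, e, len(allele)))]
    s = "".join(mseq[p.begin : p.end] for p in pieces)
    return reverse_complement(s) if transcript.strand == "-" else s
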