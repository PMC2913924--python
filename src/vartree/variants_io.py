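"""Query-variant parsing, type inference and strand normalization.

A query row gives a 0-space span on the plus strand of the region plus the
assayed allele on either strand.  The reference allele's length is the span
length, so the variant type follows from comparing the two lengths: equal →
substitution (single-base or block), allele longer → insertion, allele
shorter → deletion.  Mixed-length events (e.g. span 3, allele length 1) fall
under the length rule too and are additionally flagged ``complex``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

from Bio.Seq import reverse_complement

from .genome_model import Interval

log = logging.getLogger("vartree")

ALLELE_ALPHABET = frozenset("ACGTN")

VARIANT_COLUMNS = ["variant_id", "begin", "end", "orientation", "allele"]

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"


@dataclass
class QueryVariant:
    variant_id: str
    span: Interval
    orientation: str
    allele: str  # as assayed, on `orientation` strand; "" for pure deletion
    plus_allele: str = ""
    variant_type: str = ""
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.plus_allele and not self.variant_type:
            derived = orient_to_plus(self)
            self.plus_allele = derived.plus_allele
            self.variant_type = derived.variant_type
            self.notes = derived.notes

    @property
    def net_length_change(self) -> int:
        return len(self.plus_allele) - self.span.length


def orient_to_plus(v: QueryVariant) -> QueryVariant:
    """Express the allele on the plus strand and infer the variant type.

    The span is always interpreted on the plus strand; only the allele
    string is strand-sensitive.  Applying this with the orientation flipped
    twice returns the original allele (involution).
    """
    allele = "" if v.allele in ("", "-") else v.allele.upper()
    bad = set(allele) - ALLELE_ALPHABET
    if bad:
        raise ValueError(f"variant {v.variant_id}: non-DNA characters {sorted(bad)} in allele")
    plus = reverse_complement(allele) if v.orientation == "-" else allele

    ref_len = v.span.length
    notes = list(v.notes)
    if len(plus) == ref_len:
        if ref_len == 0:
            raise ValueError(f"variant {v.variant_id}: zero-length span with empty allele (no-op)")
        vtype = SUBSTITUTION
    elif len(plus) > ref_len:
        vtype = INSERTION
        if ref_len > 0:
            notes.append("complex")
    else:
        vtype = DELETION
        if plus:
            notes.append("complex")
    return QueryVariant(
        variant_id=v.variant_id,
        span=v.span,
        orientation=v.orientation,
        allele=v.allele,
        plus_allele=plus,
        variant_type=vtype,
        notes=notes,
    )


def read_variants_tsv(path, ref_length: int | None = None) -> tuple[list[QueryVariant], list[str]]:
    """Parse the query-variants TSV.

    Columns: variant_id, begin, end, orientation, allele (header optional —
    detected by a non-numeric begin field).  Returns accepted variants and a
    list of per-row rejection messages; rejected rows never abort the run.
    """
    variants: list[QueryVariant] = []
    errors: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 4:
                errors.append(f"line {lineno}: expected ≥4 tab-separated fields")
                continue
            if lineno == 1 and not _is_int(row[1]):
                continue  # header row
            vid, b_raw, e_raw, orient = row[0], row[1], row[2], row[3]
            allele = row[4] if len(row) > 4 else ""
            if not _is_int(b_raw) or not _is_int(e_raw):
                errors.append(f"line {lineno} ({vid}): non-integer coordinates")
                continue
            begin, end = int(b_raw), int(e_raw)
            if begin > end:
                errors.append(f"line {lineno} ({vid}): begin > end")
                continue
            if begin < 0 or (ref_length is not None and end > ref_length):
                errors.append(f"line {lineno} ({vid}): coordinates outside the reference")
                continue
            if orient not in ("+", "-"):
                errors.append(f"line {lineno} ({vid}): orientation must be + or -")
                continue
            try:
                v = QueryVariant(
                    variant_id=vid, span=Interval(begin, end), orientation=orient, allele=allele
                )
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            variants.append(v)
    for msg in errors:
        log.warning("variants file %s: rejected %s", path, msg)
    return variants, errors


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False
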