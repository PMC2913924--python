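"""Serialization of classification trees.

Two equivalent text outputs: a *normalized* report where the indentation
depth (tab count) encodes the classification hierarchy, meant for
spreadsheet viewing, and a *denormalized* flat TSV with one line per
variant × gene × transcript for line-based parsers.
"""

from __future__ import annotations

import io

from .classifier_core import ClassificationTree

NORMALIZED_HEADER = "# vartree normalized classification report"

DENORMALIZED_COLUMNS = [
    "variant_id",
    "begin",
    "end",
    "variant_type",
    "known_ids",
    "repeat_names",
    "gene_id",
    "transcript_id",
    "gene_context",
    "distance_to_exon",
    "transcript_region",
    "splice_site",
    "exon_region",
    "impacted_domains",
    "cds_position",
    "aa_position",
    "ref_codon",
    "alt_codon",
    "ref_aa",
    "alt_aa",
    "substitution_class",
    "conservation_class",
    "indel_class",
    "predicted_protein",
]
FLANK_COLUMNS = ["left_flank", "right_flank"]


def flanking_sequence(v, ref, flank_len: int) -> tuple[str, str]:
    """Plus-strand sequence flanking the variant, truncated at region edges."""
    left = ref.sequence[max(0, v.span.begin - flank_len) : v.span.begin]
    right = ref.sequence[v.span.end : v.span.end + flank_len]
    return left, right


# ---------------------------------------------------------------------------
# Normalized (tab-indented) writer
# ---------------------------------------------------------------------------


def format_normalized(trees: list[ClassificationTree]) -> str:
    out = io.StringIO()
    out.write(NORMALIZED_HEADER + "\n")
    for tree in trees:
        _write_tree(out, tree)
    return out.getvalue()


def write_normalized(trees: list[ClassificationTree], out_path) -> None:
    with open(out_path, "w") as fh:
        fh.write(format_normalized(trees))


def _line(out, depth: int, *fields) -> None:
    out.write("\t" * depth + " ".join(str(f) for f in fields) + "\n")


def _write_tree(out, tree: ClassificationTree) -> None:
    v = tree.variant
    header = [v.variant_id, v.span.begin, v.span.end, v.variant_type,
              f"allele={v.plus_allele or '-'}"]
    if tree.left_flank or tree.right_flank:
        header.append(f"flanks={tree.left_flank}|{tree.right_flank}")
    _line(out, 0, *header)
    for note in v.notes:
        _line(out, 1, "note", note)
    for kid in tree.known_ids:
        _line(out, 1, "known", kid)
    for rep in tree.repeat_names:
        _line(out, 1, "repeat", rep)
    if tree.intergenic:
        _line(out, 1, "intergenic")
        return
    for gb in tree.gene_branches:
        _line(out, 1, "gene", gb.gene_id)
        for tb in gb.transcript_branches:
            _line(out, 2, "transcript", tb.transcript_id)
            for note in tb.notes:
                _line(out, 3, "note", note)
            for region in tb.region_labels:
                if region in ("upstream_promoter", "downstream_transcript", "intronic"):
                    _line(out, 3, region, f"distance_to_exon={tb.distance_to_nearest_exon}")
                else:
                    _line(out, 3, region)
                if region == "intronic":
                    for sp in tb.splice_labels:
                        _line(out, 4, sp)
                if region == "exonic":
                    for sub in tb.exon_sublabels:
                        _line(out, 4, sub)
                        if sub == "CDS" and tb.effect is not None:
                            _write_effect(out, tb.effect)


def _write_effect(out, eff) -> None:
    _line(out, 5, "cds_position", eff.cds_position)
    _line(out, 5, "aa_position", eff.aa_position)
    if eff.ref_codon is not None:
        _line(out, 5, "codon", f"{eff.ref_codon}>{eff.alt_codon}")
    if eff.substitution_class is not None:
        parts = [f"aa {eff.ref_aa}>{eff.alt_aa}", eff.substitution_class]
        if eff.conservation_class is not None:
            parts.append(eff.conservation_class)
        _line(out, 5, *parts)
    if eff.indel_class is not None:
        _line(out, 5, "indel", eff.indel_class)
    if eff.impacted_domains:
        _line(out, 5, "impacted_domains", ",".join(eff.impacted_domains))
    for note in eff.notes:
        _line(out, 5, "note", note)
    if eff.predicted_protein is not None:
        _line(out, 5, "protein", eff.predicted_protein)


# ---------------------------------------------------------------------------
# Denormalized (flat TSV) writer
# ---------------------------------------------------------------------------


def format_denormalized(trees: list[ClassificationTree], flanks: bool = True) -> str:
    out = io.StringIO()
    for tree in trees:
        for row in _tree_rows(tree, flanks):
            out.write("\t".join(row) + "\n")
    return out.getvalue()


def write_denormalized(trees: list[ClassificationTree], out_path, flanks: bool = True) -> None:
    with open(out_path, "w") as fh:
        fh.write(format_denormalized(trees, flanks=flanks))


def _tree_rows(tree: ClassificationTree, flanks: bool) -> list[list[str]]:
    v = tree.variant
    base = {
        "variant_id": v.variant_id,
        "begin": str(v.span.begin),
        "end": str(v.span.end),
        "variant_type": v.variant_type,
        "known_ids": ",".join(tree.known_ids),
        "repeat_names": ",".join(tree.repeat_names),
    }
    if flanks:
        base["left_flank"] = tree.left_flank
        base["right_flank"] = tree.right_flank

    rows = []
    if tree.intergenic:
        rows.append({**base, "gene_context": "intergenic"})
    else:
        for gb in tree.gene_branches:
            for tb in gb.transcript_branches:
                row = {
                    **base,
                    "gene_id": gb.gene_id,
                    "transcript_id": tb.transcript_id,
                    "gene_context": "genic",
                    "transcript_region": ",".join(tb.region_labels),
                    "splice_site": ",".join(tb.splice_labels),
                    "exon_region": ",".join(tb.exon_sublabels),
                }
                if tb.distance_to_nearest_exon is not None:
                    row["distance_to_exon"] = str(tb.distance_to_nearest_exon)
                eff = tb.effect
                if eff is not None:
                    row.update(
                        {
                            "impacted_domains": ",".join(eff.impacted_domains),
                            "cds_position": str(eff.cds_position),
                            "aa_position": str(eff.aa_position),
                            "ref_codon": eff.ref_codon or "",
                            "alt_codon": eff.alt_codon or "",
                            "ref_aa": eff.ref_aa or "",
                            "alt_aa": eff.alt_aa or "",
                            "substitution_class": eff.substitution_class or "",
                            "conservation_class": eff.conservation_class or "",
                            "indel_class": eff.indel_class or "",
                            "predicted_protein": eff.predicted_protein or "",
                        }
                    )
                rows.append(row)

    columns = DENORMALIZED_COLUMNS + (FLANK_COLUMNS if flanks else [])
    return [[row.get(col, "") for col in columns] for row in rows]


def parse_denormalized(text: str, flanks: bool = True) -> list[dict[str, str]]:
    """Re-parse a denormalized report into one dict per line (round-trip aid)."""
    columns = DENORMALIZED_COLUMNS + (FLANK_COLUMNS if flanks else [])
    records = []
    for line in text.splitlines():
        fields = line.split("\t")
        if len(fields) != len(columns):
            raise ValueError(f"expected {len(columns)} fields, got {len(fields)}: {line!r}")
        records.append(dict(zip(columns, fields)))
    return records
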