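# vartree

Hierarchical, annotation-driven classification of genomic variants.

Resequencing projects produce long lists of substitutions, insertions and
deletions against a well-annotated reference, and the first question for each
one is always the same: *where does it land, and what could it do?*  `vartree`
answers this by walking each variant down a decision tree of genomic feature
contexts — known-variant and repeat collocation first, then intergenic vs
genic, promoter/downstream windows, introns with donor/acceptor splice-site
windows, 5' UTR / CDS / 3' UTR — and, for coding hits, down to codon level:
synonymous vs non-synonymous, conserved vs unconserved (by BLOSUM30 score
sign), frameshift vs in-frame indel, impacted Pfam domains, and the predicted
(possibly truncated) mutant protein.

## Coordinate model

Everything lives in the local frame of one *region of interest* of length
*s*, using **0-space-based coordinates**: positions are the gaps between
residues, running 0..*s*.  An interval *(b, e)* covers residues *b*+1..*e*;
*b* = *e* is an insertion point between two residues.  This one convention
describes SNPs, block substitutions, insertions and deletions uniformly: the
reference allele's length is simply *e* − *b*, so comparing it with the
assayed allele's length determines the variant type (equal → substitution,
longer assayed allele → insertion, shorter → deletion).

## Decision rules (defaults, all run-time configurable)

| rule | default |
| --- | --- |
| upstream promoter / downstream transcript window | 1000 bases from the first/last exon, per transcript, in coding orientation |
| 5' splice site (donor) | ≤ 10 intronic bases 3' of an exon, coding orientation |
| 3' splice site (acceptor) | ≤ 6 intronic bases 5' of the next exon |
| conservation | non-synonymous change is *unconserved* iff BLOSUM30(ref, alt) < 0 or alt is a stop |
| frameshift | net coding-length change not a multiple of 3 |
| flanking sequence | 50 bases each side (for assay design) |

## Inputs

1. **Reference FASTA** — first record is the region of interest.
2. **Annotation TSV** — all features, in local 0-space coordinates:

   ```
   feature_type  feature_id  parent_id  begin  end  strand  attributes
   ```

   with `feature_type` one of `gene`, `transcript`, `exon`, `cds`, `domain`,
   `repeat`, `known_variant`.  Exons parent to transcripts, transcripts to
   genes; `cds` rows give the translation start/stop span per transcript;
   `domain` rows use 1-based inclusive amino-acid coordinates on the
   transcript's protein.  Example:

   ```
   feature_type	feature_id	parent_id	begin	end	strand	attributes
   gene	geneA		0	100	+	
   transcript	tA	geneA	0	100	+	protein_id=pA
   exon	tA.e1	tA	0	40	+	
   exon	tA.e2	tA	60	100	+	
   cds	tA.cds	tA	9	90	+	
   domain	PF00001	tA	3	12	.	
   known_variant	rs123		25	26	.	
   ```

   `vartree adapt` generates this file from standard formats (GFF3 for gene
   models, BED for repeats and known variants), projecting 1-based genomic
   coordinates into the local frame.

3. **Query variants TSV** — `variant_id  begin  end  orientation  allele`
   (header optional).  The span is always on the plus strand; a `-`
   orientation means the allele is given on the minus strand and is
   reverse-complemented on load.  Empty or `-` allele denotes a pure deletion.

## Outputs

* `<prefix>.normalized.txt` — one block per variant, hierarchy encoded as tab
  indentation (open it in a spreadsheet; equal depth = equal tab stop).
* `<prefix>.denormalized.tsv` — one line per variant × gene × transcript for
  line-based parsers, 24 fixed columns (`variant_id, begin, end,
  variant_type, known_ids, repeat_names, gene_id, transcript_id,
  gene_context, distance_to_exon, transcript_region, splice_site,
  exon_region, impacted_domains, cds_position, aa_position, ref_codon,
  alt_codon, ref_aa, alt_aa, substitution_class, conservation_class,
  indel_class, predicted_protein`) plus `left_flank, right_flank` unless
  `--no-flanks` is given.  Intergenic variants produce exactly one line.
  Multi-valued cells are comma-joined.

Both formats carry the same classification facts.

## Worked example

The package ships a deterministic toy-genome generator, so a full run needs
no external data:

```python
from vartree import FixtureSpec, generate_fixture, generate_variant_panel, write_fixture
fx = generate_fixture(FixtureSpec(seed=1))
write_fixture(fx, ".")                      # region.fasta + annotation.tsv
rows, expected = generate_variant_panel(fx) # variants hitting every tree leaf
open("variants.tsv", "w").write("\n".join(rows) + "\n")
```

```sh
vartree classify --fasta region.fasta --annotation annotation.tsv \
    --variants variants.tsv --out-prefix demo
```

A non-synonymous CDS substitution block from `demo.normalized.txt`:

```
g2t1_nonsyn_uncons 4854 4855 substitution allele=C
	gene g2
		transcript g2t1
			exonic
				CDS
					cds_position 5
					aa_position 2
					codon TTT>TCT
					aa F>S nonsynonymous unconserved
					protein MSAAFCKFIMPWRFTRETIRILQRCPGSDTPVAKIVYSIQDSTLSGLTN
```

Read bottom-up: the SNP at 0-space position 4854 hits coding base 5 (codon 2)
of transcript `g2t1`, changing TTT→TCT, i.e. Phe→Ser; BLOSUM30(F,S) = −1 < 0,
so the change is unconserved; the full mutant protein is re-translated and
printed (here it equals the reference except for the S at position 2).  A
promoter variant instead reports its distance, e.g.
`upstream_promoter distance_to_exon=499` for a SNP whose nearest exon starts
500 residues away.

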