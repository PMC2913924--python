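# Methods

## Model

`vartree` implements a rule-based, annotation-driven consequence model: a
variant's biological interest is assessed by positional overlap with
annotated features, traversed as a decision tree from coarse to fine
context.  The tree has no scoring or ranking — every label a variant earns
is reported, and consumers sort the flat output themselves.  The assessments
are, in order:

1. **Collocation** with known (catalogued) variants and annotated repeats.
   Collocation means positional overlap of spans, not allele identity —
   the inputs carry no catalogued alleles to compare against.
2. **Gene context.**  A variant overlapping no transcript envelope and no
   promoter/downstream window of any gene is *intergenic*.  Otherwise it is
   classified independently against every overlapping gene and each of its
   alternative transcripts.
3. **Transcript region:** upstream promoter / downstream transcript window
   (1 kb from the first/last exon, resolved in coding orientation, per
   transcript), intronic (with donor/acceptor splice-site windows of 10 and
   6 intronic bases in coding orientation), or exonic (5' UTR / CDS /
   3' UTR by position relative to the transcript's CDS span).
4. **Codon-level effect** for CDS hits: substitutions confined to a single
   codon are synonymous or non-synonymous; non-synonymous changes are
   conserved when their BLOSUM30 score is ≥ 0 and unconserved otherwise,
   with any change to or from a stop codon unconserved unconditionally.
   Indels are frameshift when the net coding-length change is not a
   multiple of 3, otherwise amino-acid indels.  The mutant protein is
   always re-derived by splicing the allele into the genomic sequence,
   rebuilding the spliced CDS and translating to the first stop.

## Coordinates

All positions are 0-space-based (gaps between residues, 0..s).  An interval
(b, e) covers residues b+1..e; b = e is an insertion point.  Overlap is
sharing at least one residue for non-degenerate intervals; an insertion
point at coordinate c overlaps any feature (b, e) with b ≤ c ≤ e, so a
boundary insertion deliberately attaches to the features on *both* sides —
the geometry is genuinely ambiguous there and reporting both is the
conservative choice.

Reported distances (`distance_to_exon`) are 0-space gap sizes: the number of
residues strictly between the variant and the nearest exon.  A SNP directly
abutting an exon therefore reports distance 0, and the promoter label covers
gap sizes 0–999 (equivalently: the 1st through 1000th residue upstream).
Splice-site offsets, by contrast, follow the field's 1-based convention (the
first intronic base is offset 1), and both windows are closed: offset 10 is
still a donor hit, offset 11 is not.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `promoter_window` | 1000 bases | upstream-promoter *and* downstream-transcript window width |
| `donor_window` | 10 bases | intronic bases 3' of an exon labelled 5' splice site |
| `acceptor_window` | 6 bases | intronic bases 5' of the next exon labelled 3' splice site |
| `flank_len` | 50 bases | flanking sequence reported per side |
| substitution matrix | BLOSUM30 | packaged NCBI-format text file, swappable via `--matrix` |

The defaults are the tool's published operating points; all are exposed as
CLI flags so the same engine can be re-tuned.

## Numerical and tie-break choices

* **Multi-label spans.**  A span touching several categories (e.g. a
  deletion across an exon/intron boundary) earns every touched label on one
  branch per transcript, plus a `boundary_spanning` note.  When a variant
  overlaps a transcript's exon envelope, the envelope labels win over the
  promoter/downstream windows for that transcript (windows and envelope
  are disjoint for point-like variants, so this only affects long spans).
* **Single-codon rule.**  Synonymous/non-synonymous is only defined for
  substitutions confined to one codon; multi-codon block substitutions get
  a `multi_codon_substitution` note, no class, and a predicted protein.
* **Edit projection.**  Mutant CDS rebuilding maps each exon∩CDS piece
  through the edit: coordinates outside the edited span shift by the net
  length change; boundaries strictly inside clamp so the replacement
  allele attaches to the piece in which the edit begins (an edit starting
  in an intron keeps its allele non-coding).  A pure insertion point at an
  exon boundary attaches to the genomically-following piece.  Block
  substitutions map 1:1.
* **Start/stop disruption.**  If the mutant CDS no longer begins with ATG
  the predicted protein is empty with a `start_lost` note.  If an in-frame
  mutant has no stop within its CDS, translation continues through the
  transcript's remaining 3' exonic sequence to the next stop (or sequence
  end) with a `stop_lost` note.
* **Frameshift domain range.**  Impacted domains for frameshifts are
  computed over the first affected codon through the end of the reference
  protein, since everything downstream changes.
* **Ambiguity.**  Non-ACGTN reference characters are masked to N on load
  (counted in a warning) rather than rejected; codons containing N
  translate to X and leave the substitution class unset with an
  `ambiguous_codon` note.
* **Known-variant matching** is positional overlap only (see above).

## Synthetic data

The fixture generator emulates a compact annotated region: i.i.d. uniform
ACGT background, genes laid out with fixed intergenic gaps (default 2300
bases, leaving room for promoter sweeps and genuinely intergenic
positions), exon/intron structures drawn from configurable ranges, and
CDSs built *codon-wise* — ATG, uniform sense codons, one stop — so that
every generated CDS is a multiple of 3 with no internal stop by
construction, and the stored reference protein comes from the chosen
codons rather than from the package's own translator.  Default problem
sizes (12 kb region, 2 genes, 25–50 codons per CDS, introns of 40–80
bases) keep whole-region exhaustive sweeps cheap while exercising both
strands and every tree leaf.

What it does **not** model: realistic base composition or codon bias,
overlapping genes, structurally distinct alternative isoforms (extra
transcripts of a gene share the first transcript's structure), non-coding
transcripts, or nested/fragmented annotation.  Passing tests therefore
demonstrate the correctness of the classification *rules* on clean
annotation, not robustness to messy real-world gene models.

A separate brute-force labeler (`oracle_label`) re-derives every positional
label with straight-line per-position arithmetic and no shared code; the
test suite requires exact agreement with the classifier on every position ×
allele single-base substitution of several seeded fixtures, on both strands.

## Known limitations

* One region of interest per run; no whole-genome indexing and no network
  annotation retrieval (the GFF3/BED adapter replaces it).
* VCF is not ingested directly; indel left-normalization is the caller's
  responsibility.
* The conservation call is a single-matrix sign test — deliberately cheap;
  alignment-based deleteriousness scoring is out of scope.
* Variants are assumed independent: compound effects of multiple variants
  on one transcript are not composed.
* The length-based variant-type rule labels mixed-length replacements as
  insertion/deletion with a `complex` note rather than decomposing them.
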