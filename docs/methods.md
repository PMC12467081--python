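# Methods

This note documents the models, procedures and numerical choices behind
`panclass`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate about real data.

## Marker representation and filtering

Markers are biallelic SNP/indel sites carrying per-accession *dosages* —
the count of alternate alleles, in {0, 1, 2, missing}. The encoding
collapses phase (none of the downstream methods uses it) and treats
half-missing genotypes (`0/.`) as fully missing, the conservative choice
that avoids fractional dosages. Indels follow the VCF left-anchored
convention; a site is a SNP iff both alleles are single bases. Camelina is
an allohexaploid, but genotypes are called and stored diploid-style, and
the toolkit follows that convention throughout.

Filtering removes multi-allelic sites and markers with ≥ 20% missing
genotypes (retention is strict-less-than the threshold). Both filters are
idempotent and commute; read-level quality filters (depth, base quality)
belong to the upstream caller, not here.

## LD decay and the linked-region half-width

r² is the squared Pearson correlation of dosages over pairwise-complete
accessions — the composite, PLINK-style estimator. Haplotype-phase EM
estimation was rejected as unnecessary given the dosage encoding. Missing
data are handled by pairwise deletion per marker pair; a marker constant
after deletion contributes r² = 0 rather than an undefined value, so
monomorphic sites cannot poison distance bins. Inter-chromosome pairs have
no physical distance and are excluded.

The decay curve averages r² in distance bins (defaults: 1 kb bins to
200 kb). Bins with no pairs report NaN, never zero. The *linked-region
half-width* is the left edge of the first bin whose mean r² drops below a
threshold (default 0.1); if the curve never crosses, the maximum distance
is returned with an explicit not-crossed flag so callers widen the window
rather than trust a fabricated number.

## Association scan

The per-marker test is OLS: trait ~ intercept + dosage + principal
components. PCs come from the SVD of the centered, per-marker mean-imputed
dosage matrix (4 components by default, a typical choice for diversity
panels of a few hundred accessions). The p-value is the two-sided t-test
of the dosage coefficient; the effect is that coefficient (trait units per
alternate-allele copy, positive = alt carriers higher); PVE is 100 × R² of
the dosage-only regression on the covariate-residualised trait. Within a
test, accessions missing the dosage or trait are dropped (pairwise-complete
deletion, exact at panel scale), and markers monomorphic after deletion are
skipped with a flag. Kinship correction is deliberately omitted: the OLS
test is a pluggable stand-in behind a function contract, and published
multi-locus models that handle kinship internally can be substituted. On
structured panels the OLS p-values will be anticonservative; the iterative
procedure below is the contribution, not the test.

The iterative region scan repeats: test all remaining markers genome-wide,
apply a Bonferroni threshold α/n_tested (α = 0.05 default — a standard
choice where no genome-wide threshold is otherwise specified), and if the
most significant marker *inside the region of interest* passes, record it,
remove it from the panel, and rescan. The loop stops when no in-region
marker is significant or at `max_iter` (flagged truncated). Testing
genome-wide while stopping region-locally mirrors repeated full GWAS runs
read out over one locus; which of the two readings the procedure should
take was genuinely open, and this one is surfaced in the function contract.
A corollary worth knowing: when two markers are in perfect LD, which is
recorded first is decided by the (p-value, position) tie-break, and the
second appears on a later iteration — the procedure resolves linked
signals one removal at a time, by design.

## Regions and haplotypes

A "50 kb interval" around a marker is a one-sided flank (total span
~100 kb): that reading is the one consistent with both the stated
20/100/200 kb linkage areas and the expected gene counts at the observed
density (650 Mbp / 138 k gene models ⇒ ~4710 bp per gene ⇒ 20–25 genes per
100 kb). Intervals on one chromosome merge transitively when their gap is
≤ `gap_tol` (default 1 kb); the tolerance exists because two markers whose
flanked intervals miss each other by a few hundred bases are one locus for
candidate-gene purposes — the bundled chromosome-1 panel contains exactly
such a pair (804 bp apart after flanking) and merges into four distinct
regions. Coordinates are 1-based inclusive internally (VCF/GFF
convention); BED output converts to 0-based half-open. Genes attach to
regions by gene-span overlap of ≥ 1 bp (not CDS overlap), once per merged
region.

Haplotype grouping: an accession *carries* a marker when its dosage ≥ 1
(heterozygous carriage counts; configurable to 2, since the field
convention is unsettled), and accessions carrying at least `min_count`
(default 7) of the defining set form haplotype 2. Missing calls never
count toward carriage. Total additive effects are Σ effect × dosage with
missing treated as 0 copies and flagged incomplete. Group comparison is
one-way fixed-effects ANOVA; the degenerate all-identical case returns
(F = 0, p = 1) instead of NaN.

## Pangenome classification

Per gene × member the chain is extract → search → align → classify:

- **Extraction.** Default mode is *genomic*: the unspliced gene with every
  position labelled CDS (with its spliced-CDS index), UTR, or intron, plus
  `flank` bp of genomic context labelled non-coding. A spliced-mRNA mode
  exists as a switch, but genomic is the default because the non-coding
  category explicitly includes introns, and a spliced query cannot see an
  intronic difference at all. Minus-strand genes are reverse-complemented
  into transcript orientation, labels carried along.
- **Search.** Exact 15-mers of the query (both orientations) are looked up
  in a per-member k-mer index, clustered by (contig, strand, diagonal band
  of 400 bp), and the densest clusters are extended by banded local
  alignment. The best extension passing identity ≥ 0.8 and query coverage
  ≥ 0.5 wins; ties break to the lowest (contig, start). No qualifying hit
  is a value (*no match*), not an error. The thresholds are choices near
  common nucleotide-search defaults, exposed in config. A deleted gene is
  reported no-match because only its flanks can align, and flanks are kept
  well under half the query length.
- **Alignment.** Global alignment with match +2, mismatch −3, and affine
  gaps costing 5 + 2L for length L (Bio.Align's C implementation with
  open −7 / extend −2 in its first-gap-base convention). Reference feature
  labels project onto columns; member-insertion columns inherit the
  enclosing reference feature's label. Terminal gap runs — window
  overhangs, not biology — are trimmed before classification.
- **Classification cascade.** (1) any protein-altering CDS change — a
  non-synonymous substitution, any CDS indel (frameshift or in-frame), a
  gained/lost stop or start — ⇒ protein difference; else (2) any CDS
  nucleotide difference ⇒ silent CDS; else (3) any difference in UTR,
  intron or flank columns ⇒ non-coding only; else (4) no difference.
  Substitution effects are decided by substituting the member bases into
  the spliced reference CDS and comparing translations, so codon phase and
  splice structure are respected. Ambiguous bases (N) never count as
  differences — masked sequence should not manufacture variation.
- **Aggregation.** With P = number of members showing a protein
  difference: P ≥ 4 ⇒ category 1; 1 ≤ P ≤ 3 ⇒ category 2; else any silent
  ⇒ category 3; else any non-coding ⇒ category 4; else category 5
  (no-match-or-no-difference, one shared bucket). The cascade makes the
  five counts a partition of the gene total on every input, which the
  summary type enforces structurally. Alignment is pairwise
  reference↔member rather than one joint multiple alignment: the verdict
  is defined per member pair, so a joint alignment adds cost without
  information. Only the primary (longest) mRNA per gene is analysed;
  per-gene failures are logged and scored no-match, never fatal.

## Synthetic data: what it models and what it does not

The generator exists to give every method a known answer, not to imitate
camelina. Gene models are compact (70–140 codons, 2–4 exons, canonical
GT..AG introns, ATG start, clean stop, no internal stops, ≥ 900 bp
intergenic gaps so classification flanks never collide). Nine mutation
classes are plantable per gene × member — non-synonymous, synonymous
(codon-table-verified third positions), frameshift indel, in-frame 3 bp
indel, UTR / intron / flank substitutions (flank subs at ±100 bp, inside
the 200 bp classification flank), whole-gene deletion, and none — each
with its implied verdict recorded in a truth table. Edits are planted ≥ 8
bp from feature boundaries so alignment gap placement cannot drift across
a label boundary.

LD is modelled as block-copied latent haplotypes with per-copy flip noise
(default 2%), not a coalescent: r² is high within a block and ~1/n across
blocks, a square wave that pins the expected decay half-width at the block
length (25 kb in the tests, inside the bracket where real panels show r²
between 0.25 and 0.1). Phenotypes are strictly additive with Gaussian
noise scaled to a target heritability (0.8–0.85 in recovery tests; panels
of 100–200 accessions, matching the order of a real diversity panel).

Consequently, passing tests show the machinery is correct on its own
terms: filters match brute-force recounts, r² matches covariance
arithmetic to 1e−12, alignment scores match a full dynamic-programming
oracle, merging matches a union-find oracle, and 520 planted mutation
events across all nine classes classify with 100% agreement. They do not
show robustness to allopolyploid homeologs, repeat-dense genomes,
annotation errors, kinship confounding, or non-additive genetics — all of
which real panels have and the generator deliberately omits.

## Problem sizes and determinism

Test and acceptance workloads are sized for a laptop core: the classifier
truth-recovery run uses 20 genes × 26 members (520 events, ~40 s), panels
are ≤ 300 markers × ≤ 200 accessions, and oracle sweeps use hundreds to a
thousand small random instances. All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give byte-identical
FASTA/GFF3/VCF outputs, and the acceptance script derives all sub-seeds
from its `--seed` argument.

## Known limitations

- The OLS test ignores kinship and will be anticonservative on structured
  panels; it is a stand-in behind a pluggable contract.
- PVE has no single canonical definition; the residualised-R² choice here
  is one of several defensible ones.
- Hexaploid subgenome structure is not modelled anywhere; homeologous
  cross-mapping would appear as spurious best hits on real assemblies.
- The seed-and-extend search needs one exact 15-mer to see a locus;
  extremely diverged homologs (identity ≲ 0.8) are reported as no-match by
  construction.
- Multi-isoform genes collapse to the longest mRNA.
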