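# panclass

A marker-to-candidate-gene toolkit for interpreting QTL hits in a crop
diversity panel, built around the genomics of *Camelina sativa* seed
fatty-acid composition. Given trait-associated markers from a GWAS, it
answers the question that follows every association scan: *which genes near
these markers plausibly cause the trait difference, and what kind of
sequence variation do they carry across a pangenome?*

The toolkit covers five steps:

1. **Marker filtering** (`vcf_markers`) — read biallelic SNP/indel markers
   with per-accession genotype dosages from VCF, drop multi-allelic sites
   and markers with ≥ 20% missing genotypes, and compute minor allele
   frequencies.
2. **LD decay** (`ld_decay`) — pairwise r² (squared Pearson correlation of
   dosages, pairwise-complete), the genome-wide decay curve in distance
   bins, and the *linked-region half-width*: the distance at which mean r²
   first falls below a threshold (conventionally 0.1, or half the initial
   LD), which sets how far from a marker candidate genes should be sought.
3. **Association scanning** (`assoc_scan`) — single-marker OLS tests with
   principal-component covariates (trait ~ dosage + PCs + intercept), and
   an iterative *remove-and-rescan* loop: test everything, record the most
   significant marker in a region of interest if it passes Bonferroni,
   remove it, and rescan — resolving multiple linked signals that a single
   pass reports as one hit.
4. **Regions and haplotypes** (`regions`, `haplotype`) — flank each marker
   by the LD half-width (default 50 kb per side), merge near-touching
   intervals into distinct composite regions so shared genes are analysed
   once, attach overlapping genes from a GFF3 annotation, group accessions
   into haplotypes by how many of a defined marker set they carry, score
   additive total effects (Σ effect × dosage), and compare haplotype trait
   distributions by one-way ANOVA.
5. **Pangenome classification** (`pangenome_classify`) — for every gene in
   every region: extract the reference gene (spliced mRNA or unspliced with
   labelled introns, plus non-coding flanks), find its best hit in each
   pangenome member genome by k-mer seed-and-extend search, align the pair
   globally with affine gap penalties, and classify the differences
   codon-aware into protein-altering / silent-CDS / non-coding-only /
   no-difference / no-match. Genes aggregate into five conditionally
   exclusive categories: protein differences in ≥ 4 members, in 1–3
   members, silent CDS differences, non-coding differences only, and
   no-match-or-no-difference — ordered so the most consequential variation
   wins, and the five counts always partition the gene total.

A `synthetic_data` module generates reference genomes with multi-exon gene
models, pangenome members with planted mutation classes, marker panels with
block-structured LD, and additive phenotypes — all with recorded ground
truth, so every step above is tested against known answers.

## Worked example

The twelve chromosome-1 markers associated with oleic (18:1) and linoleic
(18:2) acid ship with the package. Flanking each by 50 kb and merging
intervals closer than 1 kb yields four distinct candidate regions:

```python
from panclass import datasets, regions

panel = datasets.chr1_oleic_marker_panel()
merged = regions.merge_intervals(
    regions.build_intervals(list(panel.itertuples()), flank=50_000),
    gap_tol=1_000,
)
for r in merged:
    print(f"{r.chrom}:{r.start}-{r.end}  markers={','.join(r.member_marker_ids)}")
```

```
1:2561818-2762622  markers=SNP_591,SNP_653
1:3013926-3297468  markers=INDEL_458_1,SNP_739,SNP_742,INDEL_480,SNP_753,SNP_754,INDEL_483,SNP_763
1:4950540-5050540  markers=SNP_1392
1:5849218-5949218  markers=SNP_1558
```

The first region pairs two markers whose 50 kb intervals miss each other by
804 bp — the 1 kb gap tolerance treats them as one locus. At the genome's
average gene density (650 Mbp, 138 k gene models ⇒ one gene per ~4710 bp) a
100 kb region like the third is expected to hold ~21 genes:

```python
print(round(regions.expected_gene_count(100_000, datasets.GENOME_SIZE_BP,
                                        datasets.N_GENE_MODELS), 1))  # 21.2
```

Additive effects stack per allele copy. An accession carrying one
alternate allele at each of the three linolenic-acid (18:3) markers shifts
the trait by the sum of their per-allele effects:

```python
from panclass.haplotype import total_additive_effect
eff = datasets.linolenic_sd_na_effects()   # {0.876, -1.165, -1.035}
print(total_additive_effect({k: 1 for k in eff}, eff).value)  # -1.324
```

For the full pipeline on synthetic data, the command line mirrors the
library:

```bash
panclass simulate --preset small --seed 42 --out fixtures/
panclass filter --vcf fixtures/panel.vcf --max-missing 0.2 --out filtered.vcf
panclass ld --vcf filtered.vcf --max-dist 100000 --bin 5000 --out curve.tsv
panclass classify --ref fixtures/ref.fa --gff fixtures/genes.gff3 \
    --members fixtures/members/*.fa --regions regions.bed --out classified/
```

## Scope

The toolkit starts from a called VCF: read mapping, variant calling and
genotype-likelihood handling belong upstream. The OLS test is a documented
stand-in for multi-locus GWAS models (BLINK/FarmCPU) whose internals are
out of scope — the contribution here is the iteration-and-removal
procedure, the region machinery, and the pangenome classifier. Population
structure inference (STRUCTURE/ΔK) and phylogenetics are likewise out of
scope.
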