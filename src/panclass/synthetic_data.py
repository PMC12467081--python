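"""Synthetic genomes, pangenomes, marker panels and phenotypes with planted
ground truth — the oracle for every other module.

The generator makes no attempt at realism beyond what the downstream
methods exercise: gene models are compact (canonical GT..AG introns, ATG
start, clean stop, no internal stops), LD is modelled by block-copied
latent haplotypes with per-marker flip noise rather than a coalescent, and
genotypes are diploid-style dosages.  Every planted event is recorded in a
:class:`TruthTable` so tests can demand exact recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import CapacityError, PlanningError, ScalingError
from .gene_models import GeneModel, GenomeAnnotation, write_gff3
from .pangenome_classify import (
    GeneCategory,
    PairwiseClassification,
    categorize_gene,
    revcomp,
    write_fasta,
)
from .vcf_markers import MISSING, MarkerRecord, MarkerSet

__all__ = [
    "MUTATION_CLASSES",
    "CLASS_TO_VERDICT",
    "ReferenceBundle",
    "TruthTable",
    "make_reference",
    "make_pangenome",
    "make_population",
    "make_phenotypes",
    "write_phenotypes",
]

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}

#: The nine plantable mutation classes.
MUTATION_CLASSES = (
    "nonsyn_sub",
    "syn_sub",
    "frameshift_indel",
    "inframe_indel",
    "utr_sub",
    "intron_sub",
    "flank_sub",
    "gene_deletion",
    "none",
)

#: Expected pairwise verdict for each planted class (the classification
#: cascade's ground truth).
CLASS_TO_VERDICT = {
    "nonsyn_sub": PairwiseClassification.PROTEIN_DIFF,
    "frameshift_indel": PairwiseClassification.PROTEIN_DIFF,
    "inframe_indel": PairwiseClassification.PROTEIN_DIFF,
    "syn_sub": PairwiseClassification.SILENT_CDS,
    "utr_sub": PairwiseClassification.NONCODING_ONLY,
    "intron_sub": PairwiseClassification.NONCODING_ONLY,
    "flank_sub": PairwiseClassification.NONCODING_ONLY,
    "gene_deletion": PairwiseClassification.NO_MATCH,
    "none": PairwiseClassification.NO_DIFF,
}


def cycled_mutation_plan(
    gene_ids: Sequence[str], n_members: int
) -> dict[str, dict[str, str]]:
    """A pangenome plan cycling every gene x member pair through all nine
    mutation classes, so each class is planted roughly equally often."""
    k = len(MUTATION_CLASSES)
    return {
        f"member{m + 1:02d}": {
            g: MUTATION_CLASSES[(m + i) % k] for i, g in enumerate(gene_ids)
        }
        for m in range(n_members)
    }


@dataclass
class ReferenceBundle:
    """A synthetic reference genome with its annotation."""

    genome: dict[str, str]
    annotation: GenomeAnnotation

    def write(self, fasta_path: str, gff_path: str) -> None:
        write_fasta(sorted(self.genome.items()), fasta_path)
        write_gff3(self.annotation, gff_path)


@dataclass
class TruthTable:
    """Planted ground truth across generator outputs."""

    pairwise: dict[tuple[str, str], PairwiseClassification] = field(
        default_factory=dict
    )  # (gene_id, member_id) -> verdict
    gene_category: dict[str, GeneCategory] = field(default_factory=dict)
    marker_effects: dict[str, float] = field(default_factory=dict)
    marker_block: dict[str, int] = field(default_factory=dict)
    block_len: int | None = None

    def finalize_categories(self) -> None:
        by_gene: dict[str, dict[str, PairwiseClassification]] = {}
        for (gid, mid), v in self.pairwise.items():
            by_gene.setdefault(gid, {})[mid] = v
        self.gene_category = {
            gid: categorize_gene(cls) for gid, cls in by_gene.items()
        }


# ----------------------------------------------------------------- reference


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        c = _random_seq(rng, 3)
        if c not in STOPS:
            return c


def _make_gene_parts(rng: np.random.Generator):
    """Transcript-level layout: (utr5, cds, utr3, intron insertion points,
    intron sequences)."""
    utr5 = _random_seq(rng, int(rng.integers(25, 60)))
    utr3 = _random_seq(rng, int(rng.integers(25, 60)))
    n_codons = int(rng.integers(70, 140))
    cds = "ATG" + "".join(_random_codon(rng) for _ in range(n_codons))
    cds += ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    transcript = utr5 + cds + utr3
    n_introns = int(rng.integers(1, 4))  # 2-4 exons
    # cut points >= 15 bp from transcript ends and from each other so small
    # alignment drift around planted indels stays inside one feature segment
    cuts: list[int] = []
    for _ in range(200):
        c = int(rng.integers(15, len(transcript) - 15))
        if all(abs(c - o) >= 15 for o in cuts):
            cuts.append(c)
        if len(cuts) == n_introns:
            break
    cuts.sort()
    introns = [
        "GT" + _random_seq(rng, int(rng.integers(35, 80))) + "AG"
        for _ in cuts
    ]
    return utr5, cds, utr3, cuts, introns


def _assemble_gene(
    gene_id: str, chrom: str, offset: int, strand: str, rng: np.random.Generator
) -> tuple[str, GeneModel]:
    """Build one gene's genomic sequence and model at genomic ``offset``
    (1-based start)."""
    utr5, cds, utr3, cuts, introns = _make_gene_parts(rng)
    transcript = utr5 + cds + utr3
    tlen = len(transcript)

    # gene-local (plus orientation) coordinates
    pieces: list[tuple[str, bool]] = []  # (seq, is_exon)
    prev = 0
    for cut, intron in zip(cuts, introns):
        pieces.append((transcript[prev:cut], True))
        pieces.append((intron, False))
        prev = cut
    pieces.append((transcript[prev:], True))

    gseq = "".join(p for p, _ in pieces)
    glen = len(gseq)

    # transcript position -> gene-local genomic position (1-based)
    t2g = np.empty(tlen + 1, dtype=int)
    g = 1
    t = 1
    for seq, is_exon in pieces:
        if is_exon:
            for _ in seq:
                t2g[t] = g
                t += 1
                g += 1
        else:
            g += len(seq)

    def t_interval_to_segments(ts: int, te: int) -> list[tuple[int, int]]:
        """Map a transcript interval to genomic segments (split at introns)."""
        segs = []
        s = t2g[ts]
        prev_g = t2g[ts]
        for tt in range(ts + 1, te + 1):
            gg = t2g[tt]
            if gg != prev_g + 1:
                segs.append((int(s), int(prev_g)))
                s = gg
            prev_g = gg
        segs.append((int(s), int(prev_g)))
        return segs

    u5_end = len(utr5)
    cds_start_t, cds_end_t = u5_end + 1, u5_end + len(cds)
    exon_segs = t_interval_to_segments(1, tlen)
    utr_segs = t_interval_to_segments(1, u5_end) + t_interval_to_segments(
        cds_end_t + 1, tlen
    )
    cds_segs_plain = t_interval_to_segments(cds_start_t, cds_end_t)

    # GFF phase per CDS segment, in translation (here: plus) order
    cds_segs = []
    done = 0
    for s, e in cds_segs_plain:
        phase = (3 - done % 3) % 3
        cds_segs.append((s, e, phase))
        done += e - s + 1

    if strand == "-":
        gseq = revcomp(gseq)

        def flip(seg):
            s, e = seg[0], seg[1]
            return (glen - e + 1, glen - s + 1) + tuple(seg[2:])

        exon_segs = [flip(s) for s in exon_segs]
        utr_segs = [flip(s) for s in utr_segs]
        cds_segs = [flip(s) for s in cds_segs]

    shift = offset - 1

    def shifted(segs):
        return tuple(tuple(x + shift if i < 2 else x for i, x in enumerate(s)) for s in segs)

    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple((s + shift, e + shift) for s, e in exon_segs),
        cds_segments=shifted(cds_segs),
        utr_segments=tuple((s + shift, e + shift) for s, e in utr_segs),
    )
    return gseq, model


def make_reference(
    n_chrom: int = 1,
    chrom_len: int = 60_000,
    n_genes: int = 10,
    seed: int = 0,
    min_gap: int = 900,
) -> ReferenceBundle:
    """Random reference genome with non-overlapping multi-exon genes.

    ``min_gap`` keeps neighbouring genes (and their classification flanks)
    from touching.  Identical seeds produce byte-identical outputs.
    """
    rng = np.random.default_rng(seed)
    per_chrom = [n_genes // n_chrom + (1 if c < n_genes % n_chrom else 0) for c in range(n_chrom)]
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    gi = 0
    for c in range(n_chrom):
        chrom = str(c + 1)
        seq = list(_random_seq(rng, chrom_len))
        k = per_chrom[c]
        # draft genes first to learn their lengths, then pack left to right
        drafts = []
        for _ in range(k):
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            drafts.append((f"gene{gi:03d}", strand, rng.integers(0, 2**31)))
        cursor = min_gap + 1
        for gene_id, strand, gseed in drafts:
            grng = np.random.default_rng(int(gseed))
            gseq, model = _assemble_gene(gene_id, chrom, cursor, strand, grng)
            end = cursor + len(gseq) - 1
            if end > chrom_len - min_gap:
                raise CapacityError(
                    f"chromosome {chrom} (len {chrom_len}) cannot pack {k} genes "
                    f"with min_gap {min_gap}"
                )
            seq[cursor - 1 : end] = list(gseq)
            genes.append(model)
            cursor = end + min_gap + 1
        genome[chrom] = "".join(seq)
    return ReferenceBundle(
        genome=genome, annotation=GenomeAnnotation.from_genes(genes)
    )


# ----------------------------------------------------------------- pangenome


def _spliced_index_to_genomic(gene: GeneModel) -> list[int]:
    """Spliced-CDS index (translation order) -> genomic position."""
    segs = list(gene.cds_segments)
    if gene.strand == "-":
        segs = segs[::-1]
    out = []
    for s, e, _ in segs:
        walk = range(s, e + 1) if gene.strand == "+" else range(e, s - 1, -1)
        out.extend(walk)
    return out


def _segment_margin_ok(gene: GeneModel, pos: int, margin: int) -> bool:
    """True when ``pos`` sits >= margin bp inside whichever CDS segment
    holds it (alignment gap drift must not escape the segment)."""
    for s, e, _ in gene.cds_segments:
        if s <= pos <= e:
            return pos - s >= margin and e - pos >= margin
    return False


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[int(rng.integers(0, 3))]


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class _Edit:
    """One genome edit in reference coordinates (applied high-to-low)."""

    chrom: str
    pos: int  # 1-based anchor
    kind: str  # sub | ins | del
    payload: str = ""  # new base(s) for sub/ins
    del_len: int = 0


def _plan_edit(
    gene: GeneModel,
    genome: Mapping[str, str],
    mclass: str,
    rng: np.random.Generator,
    flank_offset: int,
) -> list[_Edit]:
    chrom_seq = genome[gene.chrom]
    cds_genomic = _spliced_index_to_genomic(gene)
    n_codons = len(cds_genomic) // 3
    margin = 8

    def codon_positions(ci: int) -> list[int]:
        return cds_genomic[3 * ci : 3 * ci + 3]

    def codon_str(ci: int) -> str:
        bases = [chrom_seq[p - 1] for p in codon_positions(ci)]
        if gene.strand == "-":
            bases = [revcomp(b) for b in bases]
        return "".join(bases)

    if mclass == "none":
        return []

    if mclass == "gene_deletion":
        return [
            _Edit(
                chrom=gene.chrom,
                pos=gene.start,
                kind="del",
                del_len=gene.end - gene.start + 1,
            )
        ]

    if mclass == "flank_sub":
        side = -1 if rng.random() < 0.5 else 1
        pos = gene.start - flank_offset if side < 0 else gene.end + flank_offset
        if pos < 1 or pos > len(chrom_seq):
            pos = gene.end + flank_offset
        return [
            _Edit(
                gene.chrom, pos, "sub",
                _other_base(rng, chrom_seq[pos - 1]),
            )
        ]

    if mclass == "utr_sub":
        for _ in range(100):
            s, e = gene.utr_segments[int(rng.integers(0, len(gene.utr_segments)))]
            if e - s < 2 * margin:
                continue
            pos = int(rng.integers(s + margin, e - margin + 1))
            return [
                _Edit(gene.chrom, pos, "sub", _other_base(rng, chrom_seq[pos - 1]))
            ]
        raise PlanningError(f"{gene.gene_id}: no plantable UTR position")

    if mclass == "intron_sub":
        introns = gene.introns
        if not introns:
            raise PlanningError(f"{gene.gene_id}: gene has no introns")
        for _ in range(100):
            s, e = introns[int(rng.integers(0, len(introns)))]
            if e - s < 2 * margin:
                continue
            pos = int(rng.integers(s + margin, e - margin + 1))
            return [
                _Edit(gene.chrom, pos, "sub", _other_base(rng, chrom_seq[pos - 1]))
            ]
        raise PlanningError(f"{gene.gene_id}: no plantable intron position")

    # CDS classes: pick an internal codon fully inside one segment with margin
    candidates = [
        ci
        for ci in range(1, n_codons - 1)
        if all(_segment_margin_ok(gene, p, margin) for p in codon_positions(ci))
    ]
    if not candidates:
        raise PlanningError(f"{gene.gene_id}: no internal codon clear of junctions")

    if mclass in ("frameshift_indel", "inframe_indel"):
        ci = candidates[int(rng.integers(0, len(candidates)))]
        anchor = sorted(codon_positions(ci))[1]
        if mclass == "frameshift_indel":
            if rng.random() < 0.5:
                return [_Edit(gene.chrom, anchor, "del", del_len=1)]
            return [_Edit(gene.chrom, anchor, "ins", _other_base(rng, chrom_seq[anchor - 1]))]
        return [_Edit(gene.chrom, anchor, "ins", _random_seq(rng, 3))]

    if mclass == "syn_sub":
        order = rng.permutation(len(candidates))
        for oi in order[:100]:
            ci = candidates[int(oi)]
            codon = codon_str(ci)
            aa = _translate_codon(codon)
            alts = [
                b
                for b in BASES
                if b != codon[2] and _translate_codon(codon[:2] + b) == aa
            ]
            if not alts:
                continue
            new_b = alts[int(rng.integers(0, len(alts)))]
            gpos = codon_positions(ci)[2]
            planted = new_b if gene.strand == "+" else revcomp(new_b)
            return [_Edit(gene.chrom, gpos, "sub", planted)]
        raise PlanningError(f"{gene.gene_id}: no synonymous site found")

    if mclass == "nonsyn_sub":
        order = rng.permutation(len(candidates))
        for oi in order[:100]:
            ci = candidates[int(oi)]
            codon = codon_str(ci)
            aa = _translate_codon(codon)
            alts = [
                b
                for b in BASES
                if b != codon[1]
                and codon[0] + b + codon[2] not in STOPS
                and _translate_codon(codon[0] + b + codon[2]) != aa
            ]
            if not alts:
                continue
            new_b = alts[int(rng.integers(0, len(alts)))]
            gpos = codon_positions(ci)[1]
            planted = new_b if gene.strand == "+" else revcomp(new_b)
            return [_Edit(gene.chrom, gpos, "sub", planted)]
        raise PlanningError(f"{gene.gene_id}: no non-synonymous site found")

    raise ValueError(f"unknown mutation class {mclass!r}")


def _apply_edits(genome: Mapping[str, str], edits: Sequence[_Edit]) -> dict[str, str]:
    out = {c: s for c, s in genome.items()}
    by_chrom: dict[str, list[_Edit]] = {}
    for e in edits:
        by_chrom.setdefault(e.chrom, []).append(e)
    for chrom, ch_edits in by_chrom.items():
        seq = out[chrom]
        for e in sorted(ch_edits, key=lambda e: -e.pos):
            i = e.pos - 1
            if e.kind == "sub":
                seq = seq[:i] + e.payload + seq[i + 1 :]
            elif e.kind == "ins":
                seq = seq[: i + 1] + e.payload + seq[i + 1 :]
            elif e.kind == "del":
                seq = seq[:i] + seq[i + e.del_len :]
            else:
                raise ValueError(e.kind)
        out[chrom] = seq
    return out


def make_pangenome(
    ref: ReferenceBundle,
    plan: Mapping[str, Mapping[str, str]],
    seed: int = 0,
    flank_offset: int = 100,
) -> tuple[dict[str, dict[str, str]], TruthTable]:
    """Member genomes derived from the reference by planted, class-labelled
    edits.

    ``plan[member_id][gene_id]`` names one of :data:`MUTATION_CLASSES`;
    genes absent from a member's plan default to ``none``.  ``flank_offset``
    is where flank substitutions land relative to the gene span (keep it
    below the classification flank).  The returned :class:`TruthTable`
    carries the implied pairwise verdicts and gene categories.
    """
    rng = np.random.default_rng(seed)
    truth = TruthTable()
    members: dict[str, dict[str, str]] = {}
    all_genes = [g.gene_id for g in ref.annotation]
    for member_id in sorted(plan):
        edits: list[_Edit] = []
        gene_plan = plan[member_id]
        for gid in all_genes:
            mclass = gene_plan.get(gid, "none")
            if mclass not in MUTATION_CLASSES:
                raise ValueError(f"unknown mutation class {mclass!r} for {gid}")
            gene = ref.annotation.genes[gid]
            edits.extend(_plan_edit(gene, ref.genome, mclass, rng, flank_offset))
            truth.pairwise[(gid, member_id)] = CLASS_TO_VERDICT[mclass]
        members[member_id] = _apply_edits(ref.genome, edits)
    truth.finalize_categories()
    return members, truth


# ---------------------------------------------------------------- population


def make_population(
    n_accessions: int = 100,
    n_markers: int = 200,
    chrom_len: int = 1_000_000,
    block_len: int = 25_000,
    maf_range: tuple[float, float] = (0.1, 0.5),
    missing_rate: float = 0.02,
    flip_rate: float = 0.02,
    frac_multiallelic: float = 0.0,
    frac_indel: float = 0.1,
    chrom: str = "1",
    seed: int = 0,
) -> tuple[MarkerSet, TruthTable]:
    """Diploid marker panel with block-structured LD.

    Markers inside one ``block_len`` window copy a shared latent haplotype
    pair (frequency drawn from ``maf_range``) with per-chromosome-copy flip
    noise ``flip_rate``; blocks are independent, so r² is high within a
    block and near zero across blocks — a square-wave caricature of LD
    decay that pins the expected half-width at the block length.
    """
    rng = np.random.default_rng(seed)
    positions = np.sort(
        rng.choice(np.arange(1, chrom_len + 1), size=n_markers, replace=False)
    )
    block_ids = positions // block_len
    truth = TruthTable(block_len=block_len)

    latents: dict[int, np.ndarray] = {}
    markers = []
    for i, (pos, blk) in enumerate(zip(positions, block_ids)):
        if blk not in latents:
            q = rng.uniform(*maf_range)
            latents[blk] = (rng.random((n_accessions, 2)) < q).astype(np.int8)
        hap = latents[blk].copy()
        if flip_rate > 0:
            flips = rng.random(hap.shape) < flip_rate
            hap[flips] = 1 - hap[flips]
        dos = hap.sum(axis=1).astype(np.int8)
        if missing_rate > 0:
            dos[rng.random(n_accessions) < missing_rate] = MISSING

        if rng.random() < frac_indel:
            ref_a = "A" + "".join(rng.choice(list(BASES), size=2))
            alts: tuple[str, ...] = ("A",)
        else:
            ref_a, alt_a = rng.choice(list(BASES), size=2, replace=False)
            alts = (str(alt_a),)
        if frac_multiallelic > 0 and rng.random() < frac_multiallelic:
            extra = next(b for b in BASES if b != ref_a and b not in alts)
            alts = alts + (extra,)
        mid = f"m{i + 1:04d}"
        truth.marker_block[mid] = int(blk)
        markers.append(
            MarkerRecord(
                id=mid,
                chrom=chrom,
                pos=int(pos),
                ref_allele=str(ref_a),
                alt_alleles=alts,
                dosages=dos,
            )
        )
    ms = MarkerSet(
        accession_ids=tuple(f"acc{i + 1:03d}" for i in range(n_accessions)),
        markers=tuple(markers),
    )
    return ms, truth


def make_phenotypes(
    ms: MarkerSet,
    qtl: Mapping[str, float],
    heritability: float = 0.8,
    n_traits: int = 1,
    seed: int = 0,
    trait_names: Sequence[str] | None = None,
):
    """Additive phenotypes: trait = sum(effect x dosage) + scaled noise.

    Noise variance is set so the genetic fraction of trait variance equals
    ``heritability`` in expectation; missing dosages are mean-substituted
    only for the genetic value.  Column names follow the
    ``trait_location_N`` convention of multi-environment trials.
    """
    import pandas as pd

    if not 0.0 < heritability <= 1.0:
        raise ValueError("heritability must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = ms.n_accessions
    g = np.zeros(n)
    for mid, eff in qtl.items():
        d = ms.by_id(mid).dosages.astype(float)
        miss = d == MISSING
        if miss.all():
            continue
        d[miss] = d[~miss].mean()
        g += eff * d
    var_g = float(np.var(g))
    if var_g == 0.0 and heritability < 1.0 and qtl:
        raise ScalingError("planted QTL effects produce zero genetic variance")
    noise_sd = 0.0 if heritability == 1.0 else np.sqrt(var_g * (1 - heritability) / heritability)
    names = list(trait_names) if trait_names else [
        f"trait{t + 1}_SD_NA" for t in range(n_traits)
    ]
    cols = {}
    for name in names:
        cols[name] = g + rng.normal(0.0, noise_sd, size=n) if noise_sd else g.copy()
    return pd.DataFrame(cols, index=pd.Index(ms.accession_ids, name="accession"))


def write_phenotypes(df, path: str) -> None:
    df.to_csv(path, sep="\t")
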