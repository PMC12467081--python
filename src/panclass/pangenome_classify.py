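"""Pangenome gene classification: locate each QTL-region gene in every
pangenome member, align it to the reference copy, and sort the differences
into protein-altering / silent-CDS / non-coding / no-difference / no-match
categories.

The chain per gene x member is: extract the reference query (spliced mRNA,
or the unspliced gene in genomic mode, optionally with non-coding flanks) →
seed-and-extend homology search for the best hit in the member genome →
affine-gap global alignment of query and hit → codon-aware classification
of the aligned differences.  Per-member verdicts aggregate into the five
conditionally exclusive gene categories (protein differences in >= 4
members; in 1-3 members; silent CDS only; non-coding only; no match or no
difference) — ordered from more consequential differences to fewer, so a
gene with a protein change is never also counted under silent or
non-coding.

Search and alignment are implemented internally (k-mer seeding with banded
candidate windows; Needleman-Wunsch-style affine global alignment via
Bio.Align) so the whole chain is deterministic and testable without
external binaries.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .errors import CoordinateError
from .gene_models import GeneModel, GenomeAnnotation
from .regions import MarkerRegion

__all__ = [
    "PairwiseClassification",
    "GeneCategory",
    "FeatureMap",
    "HomologyHit",
    "PairAlignment",
    "GeneReport",
    "SummaryRow",
    "GenomeIndex",
    "read_fasta",
    "revcomp",
    "extract_mrna",
    "extract_query",
    "best_hit_search",
    "extract_hit_with_flanks",
    "align_pair",
    "classify_alignment",
    "categorize_gene",
    "classify_regions",
]

# ---------------------------------------------------------------- sequences

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA into an in-memory {contig: sequence} map (uppercased)."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: Sequence[tuple[str, str]], path: str, width: int = 70):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------------------------- labels


class Label(enum.IntEnum):
    """Functional label of one query position (and, projected, one column)."""

    CDS = 0
    UTR = 1
    INTRON = 2
    FLANK = 3


class PairwiseClassification(enum.Enum):
    """Verdict for one gene in one pangenome member."""

    PROTEIN_DIFF = "protein_diff"
    SILENT_CDS = "silent_cds"
    NONCODING_ONLY = "noncoding_only"
    NO_DIFF = "no_diff"
    NO_MATCH = "no_match"


class GeneCategory(enum.Enum):
    """Five-way gene bucket; mutually exclusive, collectively exhaustive."""

    PROTEIN_DIFF_4PLUS = "protein_diff_4plus"
    PROTEIN_DIFF_1TO3 = "protein_diff_1to3"
    SILENT_CDS = "silent_cds"
    NONCODING_ONLY = "noncoding_only"
    NO_MATCH_OR_NO_DIFF = "no_match_or_no_diff"


CATEGORY_ORDER = (
    GeneCategory.PROTEIN_DIFF_4PLUS,
    GeneCategory.PROTEIN_DIFF_1TO3,
    GeneCategory.SILENT_CDS,
    GeneCategory.NONCODING_ONLY,
    GeneCategory.NO_MATCH_OR_NO_DIFF,
)


@dataclass(frozen=True)
class FeatureMap:
    """Per-position annotation of a reference query sequence.

    ``labels[i]`` is the :class:`Label` of query position i; ``cds_index[i]``
    is that position's 0-based offset in the spliced CDS (translation order),
    or -1 off-CDS.  ``cds_seq`` is the full spliced reference CDS and
    ``phase`` the number of leading bases to skip before the first complete
    codon.
    """

    labels: np.ndarray
    cds_index: np.ndarray
    cds_seq: str
    phase: int = 0

    def __post_init__(self):
        if len(self.labels) != len(self.cds_index):
            raise ValueError("labels and cds_index lengths differ")


def _cds_position_map(gene: GeneModel) -> tuple[dict[int, int], str, int]:
    """Genomic position -> spliced-CDS index (translation order), + phase."""
    segs = list(gene.cds_segments)
    if gene.strand == "-":
        segs = segs[::-1]
    phase = segs[0][2] if segs else 0
    pos_map: dict[int, int] = {}
    idx = 0
    for s, e, _ in segs:
        walk = range(s, e + 1) if gene.strand == "+" else range(e, s - 1, -1)
        for g in walk:
            pos_map[g] = idx
            idx += 1
    return pos_map, "", phase


def _build_query(
    gene: GeneModel,
    genome: Mapping[str, str],
    pieces: list[tuple[int, int]],
    flank: int,
) -> tuple[str, FeatureMap]:
    """Assemble query sequence + labels from plus-strand genomic pieces."""
    chrom_seq = genome.get(gene.chrom)
    if chrom_seq is None:
        raise CoordinateError(f"{gene.gene_id}: chromosome {gene.chrom} not in genome")
    clen = len(chrom_seq)
    if gene.end > clen or gene.start < 1:
        raise CoordinateError(
            f"{gene.gene_id}: span {gene.start}-{gene.end} outside {gene.chrom} (len {clen})"
        )
    cds_map, _, phase = _cds_position_map(gene)
    cds_pos = {p for s, e, _ in gene.cds_segments for p in (s, e)}
    utr = [(s, e) for s, e in gene.utr_segments]
    introns = gene.introns

    def label_of(g: int) -> Label:
        if g in cds_map:
            return Label.CDS
        for s, e in introns:
            if s <= g <= e:
                return Label.INTRON
        for s, e in utr:
            if s <= g <= e:
                return Label.UTR
        if gene.start <= g <= gene.end:
            return Label.UTR  # exon bases outside CDS default to UTR
        return Label.FLANK

    if flank > 0:
        left = (max(1, gene.start - flank), gene.start - 1)
        right = (gene.end + 1, min(clen, gene.end + flank))
        all_pieces = []
        if left[0] <= left[1]:
            all_pieces.append(left)
        all_pieces.extend(pieces)
        if right[0] <= right[1]:
            all_pieces.append(right)
    else:
        all_pieces = list(pieces)

    chars: list[str] = []
    labels: list[int] = []
    cds_index: list[int] = []
    for s, e in all_pieces:
        chars.append(chrom_seq[s - 1 : e])
        for g in range(s, e + 1):
            labels.append(int(label_of(g)))
            cds_index.append(cds_map.get(g, -1))
    seq = "".join(chars)
    lab = np.array(labels, dtype=np.int8)
    cdsi = np.array(cds_index, dtype=np.int64)

    if gene.strand == "-":
        seq = revcomp(seq)
        lab = lab[::-1].copy()
        cdsi = cdsi[::-1].copy()

    # spliced CDS in translation orientation, straight from the genome
    segs = list(gene.cds_segments)
    cds_parts = [chrom_seq[s - 1 : e] for s, e, _ in segs]
    cds_seq = "".join(cds_parts)
    if gene.strand == "-":
        cds_seq = revcomp(cds_seq)

    n = seq.count("N") + seq.count("n")
    if len(seq) and n / len(seq) > 0.5:
        import warnings

        warnings.warn(f"{gene.gene_id}: query is >50% ambiguous bases")
    return seq, FeatureMap(labels=lab, cds_index=cdsi, cds_seq=cds_seq, phase=phase)


def extract_mrna(
    gene: GeneModel, genome: Mapping[str, str], flank: int = 0
) -> tuple[str, FeatureMap]:
    """Spliced mRNA (exons concatenated 5'→3', minus-strand genes
    reverse-complemented) with a per-position feature map.

    ``flank`` bases of genomic context on each side are included and
    labelled non-coding; introns are absent by construction.
    """
    return _build_query(gene, genome, list(gene.exons), flank)


def extract_query(
    gene: GeneModel,
    genome: Mapping[str, str],
    mode: str = "genomic",
    flank: int = 0,
) -> tuple[str, FeatureMap]:
    """Reference query for the classification chain.

    ``mode='spliced'`` gives the mRNA; ``mode='genomic'`` keeps introns in
    the query (labelled, so intronic differences are classifiable as
    non-coding rather than invisible).
    """
    if mode == "spliced":
        return extract_mrna(gene, genome, flank)
    if mode == "genomic":
        return _build_query(gene, genome, [(gene.start, gene.end)], flank)
    raise ValueError(f"unknown mode {mode!r}; use 'spliced' or 'genomic'")


# ----------------------------------------------------------- homology search


@dataclass(frozen=True)
class HomologyHit:
    """Best locus of a query in one member genome (plus-strand coordinates)."""

    member_id: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive
    end: int
    score: float
    identity: float
    coverage: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("hit start > end")
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ValueError("identity and coverage must be fractions")


class GenomeIndex:
    """Exact k-mer index of one genome, reusable across queries."""

    def __init__(self, genome: Mapping[str, str], k: int = 15):
        self.genome = genome
        self.k = k
        self.kmers: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom in sorted(genome):
            seq = genome[chrom]
            for i in range(len(seq) - k + 1):
                self.kmers[seq[i : i + k]].append((chrom, i))


def _local_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -7  # first gap base: open(5) + extend(2)
    a.extend_gap_score = -2
    return a


def _global_aligner() -> PairwiseAligner:
    a = _local_aligner()
    a.mode = "global"
    return a


def _alignment_stats(aln, qlen: int) -> tuple[float, float, int, int]:
    """(identity, coverage, target_start0, target_end0) of a local alignment."""
    blocks_t, blocks_q = aln.aligned
    matches = 0
    aligned_cols = 0
    t = aln.target
    q = aln.query
    prev_t_end = prev_q_end = None
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if prev_t_end is not None:
            aligned_cols += (ts - prev_t_end) + (qs - prev_q_end)  # gap columns
        seg_t = t[ts:te]
        seg_q = q[qs:qe]
        matches += sum(1 for x, y in zip(seg_t, seg_q) if x == y)
        aligned_cols += te - ts
        prev_t_end, prev_q_end = te, qe
    identity = matches / aligned_cols if aligned_cols else 0.0
    q_span = blocks_q[-1][1] - blocks_q[0][0] if len(blocks_q) else 0
    coverage = q_span / qlen if qlen else 0.0
    return identity, coverage, int(blocks_t[0][0]), int(blocks_t[-1][1])


def best_hit_search(
    query: str,
    member_genome: Mapping[str, str],
    member_id: str = "",
    seed_k: int = 15,
    min_identity: float = 0.8,
    min_coverage: float = 0.5,
    index: GenomeIndex | None = None,
    band: int = 400,
    max_candidates: int = 4,
) -> HomologyHit | None:
    """Seed-and-extend search for the query's best locus in a member genome.

    Exact ``seed_k``-mers of the query (both orientations) are looked up in
    the genome index, clustered by (contig, strand, diagonal band), and the
    densest clusters are extended by local alignment over their candidate
    window.  The highest-scoring extension passing the identity and
    coverage thresholds wins; ties break to the lexicographically lowest
    (contig, start).  Returns None when nothing qualifies — absence of a
    homolog is a value, not an error.
    """
    if len(query) < seed_k:
        raise ValueError(f"query shorter than seed_k={seed_k}")
    idx = index if index is not None else GenomeIndex(member_genome, k=seed_k)
    if idx.k != seed_k:
        raise ValueError("index k does not match seed_k")
    aligner = _local_aligner()
    qlen = len(query)

    candidates = []  # (n_seeds, chrom, strand, win_start0, win_end0, qseq)
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        clusters: dict[tuple[str, int], list[tuple[int, int]]] = defaultdict(list)
        for i in range(0, qlen - seed_k + 1):
            for chrom, gpos in idx.kmers.get(qseq[i : i + seed_k], ()):
                clusters[(chrom, (gpos - i) // band)].append((gpos, i))
        for (chrom, _), seeds in clusters.items():
            starts = [g - i for g, i in seeds]
            win_s = max(0, min(starts) - band)
            win_e = min(len(idx.genome[chrom]), max(starts) + qlen + band)
            candidates.append((len(seeds), chrom, strand, win_s, win_e, qseq))

    candidates.sort(key=lambda c: (-c[0], c[1], c[3], c[2]))
    best: HomologyHit | None = None
    for n_seeds, chrom, strand, win_s, win_e, qseq in candidates[:max_candidates]:
        window = idx.genome[chrom][win_s:win_e]
        alns = aligner.align(window, qseq)
        if len(alns) == 0:
            continue
        aln = alns[0]
        identity, coverage, t0, t1 = _alignment_stats(aln, qlen)
        if identity < min_identity or coverage < min_coverage:
            continue
        hit = HomologyHit(
            member_id=member_id,
            chrom=chrom,
            strand=strand,
            start=win_s + t0 + 1,
            end=win_s + t1,
            score=float(aln.score),
            identity=identity,
            coverage=coverage,
        )
        key = (-hit.score, hit.chrom, hit.start)
        if best is None or key < (-best.score, best.chrom, best.start):
            best = hit
    return best


def extract_hit_with_flanks(
    hit: HomologyHit, member_genome: Mapping[str, str], flank: int = 0
) -> str:
    """Member subsequence over the hit span plus ``flank`` bp each side,
    clipped at contig bounds and co-oriented with the query (minus-strand
    hits are reverse-complemented)."""
    seq = member_genome[hit.chrom]
    s = max(1, hit.start - flank)
    e = min(len(seq), hit.end + flank)
    sub = seq[s - 1 : e]
    return revcomp(sub) if hit.strand == "-" else sub


# -------------------------------------------------------------- alignment


@dataclass(frozen=True)
class PairAlignment:
    """Global alignment of a reference query and a member sequence, with the
    reference feature map projected onto alignment columns.

    Columns where the reference row is a gap (member insertions) inherit
    the label of the enclosing reference feature interval.
    """

    ref_row: str
    member_row: str
    col_labels: np.ndarray
    col_cds_index: np.ndarray
    score: float
    feature_map: FeatureMap


def align_pair(
    ref_seq: str, feature_map: FeatureMap, member_seq: str
) -> PairAlignment:
    """Affine-gap global alignment (match +2, mismatch -3, a gap of length L
    costs 5 + 2L) with feature labels projected onto columns."""
    if not ref_seq or not member_seq:
        raise ValueError("both sequences must be non-empty")
    if len(ref_seq) != len(feature_map.labels):
        raise ValueError("feature map does not match reference length")
    aligner = _global_aligner()
    aln = aligner.align(ref_seq, member_seq)[0]
    ref_row, member_row = str(aln[0]), str(aln[1])

    ncol = len(ref_row)
    col_labels = np.empty(ncol, dtype=np.int8)
    col_cds = np.full(ncol, -1, dtype=np.int64)
    ri = 0
    last_label = int(feature_map.labels[0])
    for c in range(ncol):
        if ref_row[c] == "-":
            col_labels[c] = last_label
        else:
            last_label = int(feature_map.labels[ri])
            col_labels[c] = last_label
            col_cds[c] = feature_map.cds_index[ri]
            ri += 1
    return PairAlignment(
        ref_row=ref_row,
        member_row=member_row,
        col_labels=col_labels,
        col_cds_index=col_cds,
        score=float(aln.score),
        feature_map=feature_map,
    )


def _core_span(ref_row: str, member_row: str) -> tuple[int, int]:
    """Trim terminal gap runs: first/last column where both rows have bases."""
    n = len(ref_row)
    lo = 0
    while lo < n and (ref_row[lo] == "-" or member_row[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (ref_row[hi - 1] == "-" or member_row[hi - 1] == "-"):
        hi -= 1
    return lo, hi


def _translate(cds: str, phase: int) -> str:
    s = cds[phase:]
    s = s[: len(s) - len(s) % 3]
    return str(Seq(s).translate())


def classify_alignment(alignment: PairAlignment) -> PairwiseClassification:
    """Decision cascade over the aligned columns.

    1. any protein-altering CDS change — a non-synonymous substitution, any
       CDS indel (frameshift or in-frame), a gained/lost stop or start —
       → PROTEIN_DIFF;
    2. else any CDS nucleotide difference → SILENT_CDS;
    3. else any difference in non-coding columns (UTR, intron, flank)
       → NONCODING_ONLY;
    4. else NO_DIFF.

    Terminal gap runs (window overhangs) are trimmed before classification;
    ambiguous bases (N) are never counted as differences.
    """
    lo, hi = _core_span(alignment.ref_row, alignment.member_row)
    cds_indel = False
    cds_subs: dict[int, str] = {}  # spliced-CDS index -> member base
    noncoding_diff = False
    for c in range(lo, hi):
        r = alignment.ref_row[c]
        m = alignment.member_row[c]
        if r == m:
            continue
        if "N" in (r.upper(), m.upper()):
            continue  # masked tolerance
        label = int(alignment.col_labels[c])
        if label == Label.CDS:
            if r == "-" or m == "-":
                cds_indel = True
            else:
                ci = int(alignment.col_cds_index[c])
                if ci >= 0:
                    cds_subs[ci] = m
                else:  # member insertion labelled CDS
                    cds_indel = True
        else:
            noncoding_diff = True
    if cds_indel:
        return PairwiseClassification.PROTEIN_DIFF
    if cds_subs:
        fm = alignment.feature_map
        ref_cds = fm.cds_seq
        member_cds = list(ref_cds)
        for ci, base in cds_subs.items():
            member_cds[ci] = base
        if _translate(ref_cds, fm.phase) != _translate("".join(member_cds), fm.phase):
            return PairwiseClassification.PROTEIN_DIFF
        return PairwiseClassification.SILENT_CDS
    if noncoding_diff:
        return PairwiseClassification.NONCODING_ONLY
    return PairwiseClassification.NO_DIFF


# ------------------------------------------------------------- aggregation


def categorize_gene(
    classifications: Mapping[str, PairwiseClassification],
) -> GeneCategory:
    """Fold per-member verdicts into the five-way gene category.

    Protein differences dominate (split at >= 4 members), then silent CDS,
    then non-coding; genes with only no-match/no-difference members land in
    the final shared bucket.
    """
    if not classifications:
        raise ValueError("need at least one member classification")
    vals = list(classifications.values())
    n_protein = sum(v is PairwiseClassification.PROTEIN_DIFF for v in vals)
    if n_protein >= 4:
        return GeneCategory.PROTEIN_DIFF_4PLUS
    if n_protein >= 1:
        return GeneCategory.PROTEIN_DIFF_1TO3
    if any(v is PairwiseClassification.SILENT_CDS for v in vals):
        return GeneCategory.SILENT_CDS
    if any(v is PairwiseClassification.NONCODING_ONLY for v in vals):
        return GeneCategory.NONCODING_ONLY
    return GeneCategory.NO_MATCH_OR_NO_DIFF


@dataclass(frozen=True)
class GeneReport:
    gene_id: str
    classifications: dict[str, PairwiseClassification]
    category: GeneCategory
    failed_members: tuple[str, ...] = ()


@dataclass(frozen=True)
class SummaryRow:
    """One Table-style summary row: the five category counts always
    partition the total."""

    marker_set: str
    total_genes: int
    counts: dict[GeneCategory, int]

    def __post_init__(self):
        if sum(self.counts.values()) != self.total_genes:
            raise ValueError("category counts do not partition the gene total")

    def as_tuple(self) -> tuple:
        return (self.marker_set, self.total_genes) + tuple(
            self.counts[c] for c in CATEGORY_ORDER
        )


def classify_regions(
    regions: Sequence[MarkerRegion],
    reference: Mapping[str, str],
    annotation: GenomeAnnotation,
    members: Mapping[str, Mapping[str, str]],
    flank: int = 200,
    mode: str = "genomic",
    seed_k: int = 15,
    min_identity: float = 0.8,
    min_coverage: float = 0.5,
    marker_set_label: str = "all",
    out_dir: str | None = None,
) -> tuple[SummaryRow, list[GeneReport]]:
    """Run the full extract → search → align → classify → categorize chain
    for every gene overlapping the given regions.

    Genes spanning several regions are processed once.  Per-gene failures
    are logged on the report (counted as NO_MATCH for that member), never
    fatal.  When ``out_dir`` is given, a per-gene aligned FASTA is written
    for visual assessment.
    """
    if not members:
        raise ValueError("no pangenome member genomes supplied")
    gene_ids: list[str] = []
    seen = set()
    for region in regions:
        for gid in annotation.overlapping(region.chrom, region.start, region.end):
            if gid not in seen:
                seen.add(gid)
                gene_ids.append(gid)

    indexes = {
        mid: GenomeIndex(genome, k=seed_k) for mid, genome in members.items()
    }
    out_path = Path(out_dir) if out_dir else None
    if out_path:
        out_path.mkdir(parents=True, exist_ok=True)

    reports: list[GeneReport] = []
    for gid in gene_ids:
        gene = annotation.genes[gid]
        query, fmap = extract_query(gene, reference, mode=mode, flank=flank)
        verdicts: dict[str, PairwiseClassification] = {}
        failures: list[str] = []
        fasta_rows = [(f"{gid}|reference", query)]
        for mid in sorted(members):
            try:
                hit = best_hit_search(
                    query,
                    members[mid],
                    member_id=mid,
                    seed_k=seed_k,
                    min_identity=min_identity,
                    min_coverage=min_coverage,
                    index=indexes[mid],
                )
                if hit is None:
                    verdicts[mid] = PairwiseClassification.NO_MATCH
                    continue
                member_seq = extract_hit_with_flanks(hit, members[mid], flank=0)
                aln = align_pair(query, fmap, member_seq)
                verdicts[mid] = classify_alignment(aln)
                fasta_rows.append((f"{gid}|{mid}|{verdicts[mid].value}", aln.member_row.replace("-", "")))
            except Exception:
                verdicts[mid] = PairwiseClassification.NO_MATCH
                failures.append(mid)
        reports.append(
            GeneReport(
                gene_id=gid,
                classifications=verdicts,
                category=categorize_gene(verdicts),
                failed_members=tuple(failures),
            )
        )
        if out_path:
            write_fasta(fasta_rows, out_path / f"{gid}.aln.fa")

    counts = {c: 0 for c in CATEGORY_ORDER}
    for rep in reports:
        counts[rep.category] += 1
    summary = SummaryRow(
        marker_set=marker_set_label, total_genes=len(reports), counts=counts
    )
    return summary, reports
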