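"""mRNA extraction, homology search, global alignment vs a DP oracle,
codon-aware classification, and category aggregation."""

import numpy as np
import pytest

from panclass import synthetic_data as sd
from panclass.gene_models import GeneModel
from panclass.pangenome_classify import (
    FeatureMap,
    GeneCategory,
    Label,
    PairwiseClassification as PC,
    align_pair,
    best_hit_search,
    categorize_gene,
    classify_alignment,
    classify_regions,
    extract_hit_with_flanks,
    extract_mrna,
    extract_query,
    revcomp,
)
from panclass.regions import MarkerRegion

# --------------------------------------------------------- independent oracles

from tests_codon import CODON_TABLE as _T, translate_oracle


def affine_dp_score(a, b, match=2, mismatch=-3, gap_open=5, gap_ext=2):
    """Quadratic-space affine-gap global alignment score (gap of length L
    costs gap_open + gap_ext * L)."""
    neg = -1e18
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_ext * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_ext * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_ext, X[i - 1][j] - gap_ext
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_ext, Y[i][j - 1] - gap_ext
            )
    return max(M[n][m], X[n][m], Y[n][m])


def _flat_map(n, label=Label.CDS, cds_seq="", phase=0):
    labels = np.full(n, int(label), dtype=np.int8)
    cds = np.arange(n, dtype=np.int64) if label == Label.CDS else np.full(n, -1)
    return FeatureMap(labels=labels, cds_index=cds, cds_seq=cds_seq or "", phase=phase)


# --------------------------------------------------------------- extraction


def test_single_exon_mrna_is_literal_substring():
    seq = "ACGTACGTACGTACGTACGT"
    gene = GeneModel(
        gene_id="g", chrom="c", strand="+", exons=((11, 19),),
        cds_segments=((11, 19, 0),),
    )
    mrna, fmap = extract_mrna(gene, {"c": seq})
    assert mrna == seq[10:19]
    assert all(l == Label.CDS for l in fmap.labels)
    minus = GeneModel(
        gene_id="g", chrom="c", strand="-", exons=((11, 19),),
        cds_segments=((11, 19, 0),),
    )
    mrna_m, _ = extract_mrna(minus, {"c": seq})
    assert mrna_m == revcomp(seq[10:19])


def test_two_exon_mrna_drops_the_intron(small_reference):
    genome = small_reference.genome
    for gene in small_reference.annotation:
        mrna, fmap = extract_mrna(gene, genome)
        manual = "".join(genome[gene.chrom][s - 1 : e] for s, e in gene.exons)
        if gene.strand == "-":
            manual = revcomp(manual)
        assert mrna == manual
        for s, e in gene.introns:
            intron = genome[gene.chrom][s - 1 : e]
            if gene.strand == "-":
                intron = revcomp(intron)
            # canonical splice donors/acceptors in transcript orientation
            assert intron[:2] == "GT" and intron[-2:] == "AG"
        # CDS always begins with the start codon
        assert fmap.cds_seq.startswith("ATG")
        assert "*" not in translate_oracle(fmap.cds_seq)[:-1]
        assert translate_oracle(fmap.cds_seq)[-1] == "*"


def test_genomic_mode_labels_introns_and_flanks(small_reference):
    gene = next(g for g in small_reference.annotation if g.introns)
    seq, fmap = extract_query(gene, small_reference.genome, mode="genomic", flank=50)
    assert len(seq) == (gene.end - gene.start + 1) + 100
    labels = set(int(l) for l in fmap.labels)
    assert {int(Label.CDS), int(Label.INTRON), int(Label.FLANK)} <= labels
    assert int(fmap.labels[0]) == int(Label.FLANK)
    assert int(fmap.labels[-1]) == int(Label.FLANK)


# ----------------------------------------------------------------- search


def test_planted_query_found_exactly(small_reference):
    genome = small_reference.genome
    gene = next(iter(small_reference.annotation))
    query, _ = extract_query(gene, genome, mode="genomic")
    hit = best_hit_search(query, genome, member_id="self")
    assert hit is not None
    assert hit.identity == pytest.approx(1.0)
    assert hit.coverage == pytest.approx(1.0)
    assert (hit.start, hit.end) == (gene.start, gene.end)
    assert extract_hit_with_flanks(hit, genome, flank=0) == query


def test_absent_query_returns_no_match():
    # a homopolymer genome shares no 15-mer with a mixed-composition query
    genome = {"1": "T" * 3_000}
    assert best_hit_search("ACGAG" * 40, genome) is None


def test_minus_strand_planting_found_with_strand_flag(small_reference):
    genome = small_reference.genome
    gene = next(iter(small_reference.annotation))
    query, _ = extract_query(gene, genome, mode="genomic")
    flipped = {c: revcomp(s) for c, s in genome.items()}
    hit = best_hit_search(query, flipped)
    plus_hit = best_hit_search(query, genome)
    assert hit is not None and hit.strand != plus_hit.strand
    assert hit.score == pytest.approx(plus_hit.score)
    assert extract_hit_with_flanks(hit, flipped, flank=0) == query


def test_hit_extraction_clips_at_contig_bounds(small_reference):
    genome = small_reference.genome
    gene = next(iter(small_reference.annotation))
    query, _ = extract_query(gene, genome, mode="genomic")
    hit = best_hit_search(query, genome)
    padded = extract_hit_with_flanks(hit, genome, flank=10**9)
    assert padded == genome[hit.chrom] if hit.strand == "+" else revcomp(genome[hit.chrom])


# ---------------------------------------------------------------- alignment


def test_identical_and_single_substitution_alignments():
    fmap = _flat_map(30, Label.UTR)
    seq = "ACGTACGTACGTACGTACGTACGTACGTAC"
    aln = align_pair(seq, fmap, seq)
    assert aln.ref_row == aln.member_row == seq
    mutated = seq[:7] + "G" + seq[8:]  # position 7 holds T
    aln2 = align_pair(seq, fmap, mutated)
    diffs = [i for i, (a, b) in enumerate(zip(aln2.ref_row, aln2.member_row)) if a != b]
    assert len(diffs) == 1


@pytest.mark.parametrize("trial", range(20))
def test_alignment_score_matches_dp_oracle(trial, rng):
    n = int(rng.integers(20, 200))
    a = "".join(rng.choice(list("ACGT"), size=n))
    b = list(a)
    for _ in range(int(rng.integers(1, 8))):
        op = rng.integers(0, 3)
        i = int(rng.integers(0, len(b)))
        if op == 0:
            b[i] = "ACGT"[int(rng.integers(0, 4))]
        elif op == 1 and len(b) > 10:
            del b[i]
        else:
            b.insert(i, "ACGT"[int(rng.integers(0, 4))])
    b = "".join(b)
    aln = align_pair(a, _flat_map(len(a), Label.UTR), b)
    assert aln.score == pytest.approx(affine_dp_score(a, b))


def test_member_insertion_columns_inherit_enclosing_label():
    seq = "AAAACCCCGGGG"
    fmap = _flat_map(12, Label.UTR)
    member = seq[:6] + "TTT" + seq[6:]
    aln = align_pair(seq, fmap, member)
    gap_cols = [i for i, c in enumerate(aln.ref_row) if c == "-"]
    assert gap_cols
    assert all(aln.col_labels[c] == int(Label.UTR) for c in gap_cols)


# ----------------------------------------------------------- classification


def _gene_with_map(small_reference, with_intron=True):
    ann = small_reference.annotation
    gene = next(g for g in ann if (len(g.introns) > 0) == with_intron)
    seq, fmap = extract_query(gene, small_reference.genome, mode="genomic", flank=60)
    return gene, seq, fmap


def _classify_edit(seq, fmap, member_seq):
    return classify_alignment(align_pair(seq, fmap, member_seq))


def test_synonymous_third_position_change_is_silent(small_reference):
    gene, seq, fmap = _gene_with_map(small_reference)
    # find a query position holding CDS index of a codon third base with a
    # synonymous alternative, via the independent codon table
    cds = fmap.cds_seq
    for qpos in range(len(seq)):
        ci = int(fmap.cds_index[qpos])
        if ci < 3 or ci % 3 != 2 or ci >= len(cds) - 3:
            continue
        codon = cds[ci - 2 : ci + 1]
        for b in "ACGT":
            if b == codon[2] or _T[codon[:2] + b] != _T[codon]:
                continue
            # the query is in transcript orientation, so the planted base is
            # the codon base itself regardless of genomic strand
            member = seq[:qpos] + b + seq[qpos + 1 :]
            assert _classify_edit(seq, fmap, member) is PC.SILENT_CDS
            return
    pytest.fail("no synonymous site found")


def test_nonsynonymous_change_is_protein_diff(small_reference):
    gene, seq, fmap = _gene_with_map(small_reference)
    cds = fmap.cds_seq
    for qpos in range(len(seq)):
        ci = int(fmap.cds_index[qpos])
        if ci < 3 or ci % 3 != 0 or ci >= len(cds) - 3:
            continue
        codon = cds[ci : ci + 3]
        for b in "ACGT":
            if b == codon[0] or _T[b + codon[1:]] == _T[codon]:
                continue
            member = seq[:qpos] + b + seq[qpos + 1 :]
            assert _classify_edit(seq, fmap, member) is PC.PROTEIN_DIFF
            return
    pytest.fail("no nonsynonymous site found")


def test_utr_intron_and_flank_changes_are_noncoding(small_reference):
    gene, seq, fmap = _gene_with_map(small_reference)
    for label in (Label.UTR, Label.INTRON, Label.FLANK):
        positions = [
            i
            for i in range(5, len(seq) - 5)
            if fmap.labels[i] == int(label)
            and fmap.labels[i - 2] == int(label)
            and fmap.labels[i + 2] == int(label)
        ]
        qpos = positions[len(positions) // 2]
        b = next(x for x in "ACGT" if x != seq[qpos])
        member = seq[:qpos] + b + seq[qpos + 1 :]
        assert _classify_edit(seq, fmap, member) is PC.NONCODING_ONLY


def test_cds_indels_are_protein_diffs(small_reference):
    gene, seq, fmap = _gene_with_map(small_reference)
    mid_cds = [
        i
        for i in range(10, len(seq) - 10)
        if all(fmap.labels[j] == int(Label.CDS) for j in range(i - 6, i + 7))
    ]
    qpos = mid_cds[len(mid_cds) // 2]
    frameshift = seq[:qpos] + seq[qpos + 1 :]  # 1 bp deletion
    assert _classify_edit(seq, fmap, frameshift) is PC.PROTEIN_DIFF
    inframe = seq[:qpos] + "GAC" + seq[qpos:]  # 3 bp insertion
    assert _classify_edit(seq, fmap, inframe) is PC.PROTEIN_DIFF


def test_identical_member_is_no_diff(small_reference):
    _, seq, fmap = _gene_with_map(small_reference)
    assert _classify_edit(seq, fmap, seq) is PC.NO_DIFF


def test_ambiguous_bases_do_not_count_as_differences(small_reference):
    _, seq, fmap = _gene_with_map(small_reference)
    member = seq[:50] + "N" + seq[51:]
    assert _classify_edit(seq, fmap, member) is PC.NO_DIFF


# ------------------------------------------------------------- aggregation


def test_categorize_gene_cascade():
    nd = PC.NO_DIFF
    assert categorize_gene({f"m{i}": nd for i in range(12)}) is GeneCategory.NO_MATCH_OR_NO_DIFF
    four = {f"m{i}": PC.PROTEIN_DIFF for i in range(4)}
    four.update({f"x{i}": nd for i in range(8)})
    assert categorize_gene(four) is GeneCategory.PROTEIN_DIFF_4PLUS
    three = {f"m{i}": PC.PROTEIN_DIFF for i in range(3)}
    three["z"] = PC.SILENT_CDS
    assert categorize_gene(three) is GeneCategory.PROTEIN_DIFF_1TO3
    mixed = {"a": PC.SILENT_CDS, "b": PC.NONCODING_ONLY, "c": PC.NONCODING_ONLY,
             "d": PC.NONCODING_ONLY, "e": nd}
    assert categorize_gene(mixed) is GeneCategory.SILENT_CDS  # precedence
    assert categorize_gene({"a": PC.NO_MATCH}) is GeneCategory.NO_MATCH_OR_NO_DIFF
    with pytest.raises(ValueError):
        categorize_gene({})


def test_classify_regions_recovers_planted_truth(small_reference, small_pangenome):
    members, truth = small_pangenome
    regs = [MarkerRegion("1", 1, 40_000, ("m",))]
    summary, reports = classify_regions(
        regs, small_reference.genome, small_reference.annotation, members,
        flank=200, mode="genomic",
    )
    assert summary.total_genes == len(reports) == 8
    assert sum(summary.counts.values()) == summary.total_genes
    for rep in reports:
        assert not rep.failed_members
        for mid, verdict in rep.classifications.items():
            assert verdict is truth.pairwise[(rep.gene_id, mid)]
        assert rep.category is truth.gene_category[rep.gene_id]


def test_identical_member_genome_all_no_diff(small_reference):
    regs = [MarkerRegion("1", 1, 40_000, ("m",))]
    summary, reports = classify_regions(
        regs, small_reference.genome, small_reference.annotation,
        {"twin": dict(small_reference.genome)}, flank=200,
    )
    assert all(
        v is PC.NO_DIFF for r in reports for v in r.classifications.values()
    )
    assert summary.counts[GeneCategory.NO_MATCH_OR_NO_DIFF] == summary.total_genes


def test_strand_invariance_of_classification(small_reference, small_pangenome):
    members, truth = small_pangenome
    mid = sorted(members)[0]
    flipped = {c: revcomp(s) for c, s in members[mid].items()}
    regs = [MarkerRegion("1", 1, 40_000, ("m",))]
    _, reports = classify_regions(
        regs, small_reference.genome, small_reference.annotation,
        {mid: flipped}, flank=200,
    )
    for rep in reports:
        assert rep.classifications[mid] is truth.pairwise[(rep.gene_id, mid)]


def test_zero_members_is_an_error(small_reference):
    with pytest.raises(ValueError):
        classify_regions(
            [MarkerRegion("1", 1, 100, ("m",))],
            small_reference.genome, small_reference.annotation, {},
        )
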