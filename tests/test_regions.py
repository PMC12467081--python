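"""Interval construction, merging vs a union-find oracle, gene attachment,
and gene-density arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panclass.datasets import (
    GENOME_SIZE_BP,
    N_GENE_MODELS,
    chr1_oleic_marker_panel,
)
from panclass.regions import (
    RawInterval,
    build_intervals,
    expected_gene_count,
    genes_in_region,
    merge_intervals,
    MarkerRegion,
)


class _M:
    def __init__(self, id, chrom, pos):
        self.id, self.chrom, self.pos = id, chrom, pos


def test_flank_interval_and_clipping():
    ivs = build_intervals([_M("a", "1", 60_000), _M("b", "1", 20_000)], flank=50_000)
    assert (ivs[0].start, ivs[0].end) == (10_000, 110_000)
    assert (ivs[1].start, ivs[1].end) == (1, 70_000)  # clipped at chromosome start


def test_chr1_panel_interval_widths():
    panel = chr1_oleic_marker_panel()
    ivs = build_intervals(list(panel.itertuples()), flank=50_000)
    assert len(ivs) == 12
    assert all(iv.end - iv.start + 1 == 100_001 for iv in ivs)  # none clip


def test_chr1_panel_merges_into_four_regions():
    panel = chr1_oleic_marker_panel()
    merged = merge_intervals(
        build_intervals(list(panel.itertuples()), flank=50_000), gap_tol=1_000
    )
    assert len(merged) == 4
    sizes = sorted(len(r.member_marker_ids) for r in merged)
    assert sizes == [1, 1, 2, 8]
    # the two-marker region pairs the near-touching leftmost markers
    two = next(r for r in merged if len(r.member_marker_ids) == 2)
    assert set(two.member_marker_ids) == {"SNP_591", "SNP_653"}


def test_two_intervals_ten_kb_apart_stay_separate():
    ivs = [RawInterval("1", 100, 200, "a"), RawInterval("1", 10_200, 10_300, "b")]
    assert len(merge_intervals(ivs, gap_tol=1_000)) == 2


def merge_oracle(ivs, gap_tol):
    """Union-find over pairwise gap tests; returns sorted (chrom,start,end,members)."""
    parent = list(range(len(ivs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ivs)):
        for j in range(i + 1, len(ivs)):
            a, b = ivs[i], ivs[j]
            if a.chrom != b.chrom:
                continue
            lo, hi = (a, b) if a.start <= b.start else (b, a)
            if hi.start - lo.end - 1 <= gap_tol:
                parent[find(i)] = find(j)
    groups = {}
    for i, iv in enumerate(ivs):
        groups.setdefault(find(i), []).append(iv)
    out = []
    for g in groups.values():
        out.append(
            (
                g[0].chrom,
                min(iv.start for iv in g),
                max(iv.end for iv in g),
                tuple(sorted(iv.marker_id for iv in g)),
            )
        )
    return sorted(out)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=200, derandomize=True)
def test_merge_matches_union_find_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 25))
    ivs = []
    for i in range(n):
        chrom = str(rng.integers(1, 3))
        start = int(rng.integers(1, 5_000))
        ivs.append(RawInterval(chrom, start, start + int(rng.integers(0, 800)), f"m{i}"))
    gap_tol = int(rng.integers(0, 300))
    got = sorted(
        (r.chrom, r.start, r.end, tuple(sorted(r.member_marker_ids)))
        for r in merge_intervals(ivs, gap_tol)
    )
    assert got == merge_oracle(ivs, gap_tol)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=50, derandomize=True)
def test_merge_idempotent_order_free_and_complete(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 20))
    ivs = []
    for i in range(n):
        start = int(rng.integers(1, 3_000))
        ivs.append(RawInterval("1", start, start + int(rng.integers(0, 500)), f"m{i}"))
    merged = merge_intervals(ivs, gap_tol=100)
    # shuffled input gives identical output
    shuffled = [ivs[i] for i in rng.permutation(n)]
    assert merge_intervals(shuffled, gap_tol=100) == merged
    # re-merging the merged regions changes nothing
    again = merge_intervals(
        [RawInterval(r.chrom, r.start, r.end, r.member_marker_ids[0]) for r in merged],
        gap_tol=100,
    )
    assert [(r.chrom, r.start, r.end) for r in again] == [
        (r.chrom, r.start, r.end) for r in merged
    ]
    # every marker lands in exactly one region; regions are disjoint and sorted
    members = [m for r in merged for m in r.member_marker_ids]
    assert sorted(members) == sorted(f"m{i}" for i in range(n))
    for a, b in zip(merged, merged[1:]):
        if a.chrom == b.chrom:
            assert a.end < b.start
    # with overlap-only merging (no gap bridging) total merged width never
    # exceeds total raw width
    tight = merge_intervals(ivs, gap_tol=0)
    assert sum(r.width for r in tight) <= sum(iv.end - iv.start + 1 for iv in ivs)


def test_genes_attached_by_one_bp_overlap(small_reference):
    ann = small_reference.annotation
    gene = next(iter(ann))
    # region ending exactly at the gene's first base -> included
    region = MarkerRegion(gene.chrom, max(1, gene.start - 500), gene.start, ("m",))
    assert gene.gene_id in genes_in_region(region, ann)
    # fully intergenic region -> empty
    gap = MarkerRegion(gene.chrom, 1, 5, ("m",))
    hits = genes_in_region(gap, ann)
    assert all(ann.genes[g].start <= 5 for g in hits)


def test_genes_in_region_matches_bruteforce(small_reference):
    ann = small_reference.annotation
    region = MarkerRegion("1", 5_000, 25_000, ("m",))
    expected = sorted(
        g.gene_id for g in ann if g.start <= region.end and g.end >= region.start
    )
    assert sorted(genes_in_region(region, ann)) == expected


def test_gene_density_arithmetic():
    per_gene = GENOME_SIZE_BP / N_GENE_MODELS
    assert round(per_gene) == 4710
    assert round(per_gene / 100) * 100 == 4700
    genes_100kb = expected_gene_count(100_000, GENOME_SIZE_BP, N_GENE_MODELS)
    assert 20 <= genes_100kb <= 25
    assert expected_gene_count(0, GENOME_SIZE_BP, N_GENE_MODELS) == 0.0
    with pytest.raises(ZeroDivisionError):
        expected_gene_count(100, 1000, 0)
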