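"""Strand-aware gene structures and GFF3-backed genome annotations.

A :class:`GeneModel` is the primary-transcript view of a gene: exons, CDS
segments (with phase) and UTR segments, all in 1-based inclusive genomic
coordinates on the plus strand, with ``strand`` recording transcription
direction.  :class:`GenomeAnnotation` indexes gene spans per chromosome for
interval queries.  Multi-isoform genes collapse to the longest mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .errors import LookupError_

__all__ = ["GeneModel", "GenomeAnnotation", "read_gff3", "write_gff3"]

Segment = tuple[int, int]  # 1-based inclusive


def _check_sorted_disjoint(segs: list[Segment], what: str, gene_id: str):
    for s, e in segs:
        if s > e:
            raise ValueError(f"{gene_id}: {what} segment {s}-{e} reversed")
    for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
        if s2 <= e1:
            raise ValueError(f"{gene_id}: {what} segments overlap or are unsorted")


@dataclass(frozen=True)
class GeneModel:
    """One gene's primary transcript structure.

    ``cds_segments`` carry the GFF3 phase (bases to skip before the first
    complete codon, in translation order).  Structural soundness (CDS inside
    exons, spliced CDS length divisible by 3) is checked on construction;
    real-world annotations that violate translation-level invariants (start
    codon, internal stops) are flagged downstream, not rejected here.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[Segment, ...]
    cds_segments: tuple[tuple[int, int, int], ...]  # (start, end, phase)
    utr_segments: tuple[Segment, ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        exons = tuple(sorted(self.exons))
        cds = tuple(sorted(self.cds_segments))
        utr = tuple(sorted(self.utr_segments))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds_segments", cds)
        object.__setattr__(self, "utr_segments", utr)
        _check_sorted_disjoint(list(exons), "exon", self.gene_id)
        _check_sorted_disjoint([(s, e) for s, e, _ in cds], "CDS", self.gene_id)
        for s, e, _ in cds:
            if not any(es <= s and e <= ee for es, ee in exons):
                raise ValueError(f"{self.gene_id}: CDS {s}-{e} not inside an exon")
        total = sum(e - s + 1 for s, e, _ in cds)
        first_phase = 0
        if cds:
            ordered = cds if self.strand == "+" else cds[::-1]
            first_phase = ordered[0][2]
        if cds and (total - first_phase) % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: spliced CDS length {total} (phase {first_phase}) "
                "not divisible by 3"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Segment:
        return (self.start, self.end)

    @property
    def introns(self) -> tuple[Segment, ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)


@dataclass
class GenomeAnnotation:
    """Gene models indexed by id and by genomic span per chromosome."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    @classmethod
    def from_genes(cls, genes) -> "GenomeAnnotation":
        ann = cls()
        for g in genes:
            ann.add(g)
        return ann

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene id {gene.gene_id}")
        self.genes[gene.gene_id] = gene
        # IntervalTree is half-open; +1 converts the inclusive end
        self._trees.setdefault(gene.chrom, IntervalTree()).addi(
            gene.start, gene.end + 1, gene.gene_id
        )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted(self._trees))

    def overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """Gene ids whose span overlaps [start, end] (1-based inclusive) by >= 1 bp."""
        if chrom not in self._trees:
            raise LookupError_(f"no annotation for chromosome {chrom}")
        hits = self._trees[chrom].overlap(start, end + 1)
        found = sorted(hits, key=lambda iv: (iv.begin, iv.data))
        return [iv.data for iv in found]


def read_gff3(path: str) -> GenomeAnnotation:
    """Load gene models from GFF3, keeping the longest mRNA per gene."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            mrnas.sort(key=lambda m: (-(m.end - m.start + 1), m.id))
            parent = mrnas[0]
        else:
            parent = gene
        exons = [
            (f.start, f.end) for f in db.children(parent, featuretype="exon")
        ]
        cds = [
            (f.start, f.end, 0 if f.frame == "." else int(f.frame))
            for f in db.children(parent, featuretype="CDS")
        ]
        utr = [
            (f.start, f.end)
            for t in ("five_prime_UTR", "three_prime_UTR", "UTR")
            for f in db.children(parent, featuretype=t)
        ]
        if not exons and cds:
            exons = [(s, e) for s, e, _ in cds]
        if not exons:
            continue  # gene with no usable structure
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=tuple(sorted(exons)),
                cds_segments=tuple(sorted(cds)),
                utr_segments=tuple(sorted(utr)),
            )
        )
    return GenomeAnnotation.from_genes(genes)


def write_gff3(annotation: GenomeAnnotation, path: str) -> None:
    """Write gene/mRNA/exon/UTR/CDS rows (one mRNA per gene)."""

    def row(chrom, ftype, s, e, strand, attrs, phase="."):
        return f"{chrom}\tpanclass\t{ftype}\t{s}\t{e}\t.\t{strand}\t{phase}\t{attrs}\n"

    genes = sorted(annotation, key=lambda g: (g.chrom, g.start, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gid, mid = g.gene_id, f"{g.gene_id}.t1"
            fh.write(row(g.chrom, "gene", g.start, g.end, g.strand, f"ID={gid}"))
            fh.write(
                row(g.chrom, "mRNA", g.start, g.end, g.strand, f"ID={mid};Parent={gid}")
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    row(g.chrom, "exon", s, e, g.strand, f"ID={mid}.exon{i};Parent={mid}")
                )
            cds_sorted = g.cds_segments
            cds_min = cds_sorted[0][0] if cds_sorted else None
            cds_max = cds_sorted[-1][1] if cds_sorted else None
            for i, (s, e) in enumerate(g.utr_segments, 1):
                if cds_min is None:
                    ftype = "UTR"
                elif (e < cds_min) == (g.strand == "+"):
                    ftype = "five_prime_UTR"
                else:
                    ftype = "three_prime_UTR"
                fh.write(
                    row(g.chrom, ftype, s, e, g.strand, f"ID={mid}.utr{i};Parent={mid}")
                )
            for i, (s, e, ph) in enumerate(cds_sorted, 1):
                fh.write(
                    row(
                        g.chrom,
                        "CDS",
                        s,
                        e,
                        g.strand,
                        f"ID={mid}.cds;Parent={mid}",
                        phase=str(ph),
                    )
                )
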