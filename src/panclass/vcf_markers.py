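"""Marker sets: VCF reading/writing, biallelic and missingness filters, MAF.

Markers are biallelic SNP/indel sites with per-accession genotype dosages
(0, 1, 2 copies of the alternate allele; -1 encodes missing).  Dosage
encoding collapses phase; half-missing genotypes (``0/.``) are treated as
fully missing.  Read-level filters (depth, base quality) belong to the
upstream variant caller and are outside this module's boundary: the
toolkit starts from a called VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyPanelError, UndefinedFrequencyError, VcfParseError

MISSING = -1

__all__ = [
    "MISSING",
    "MarkerRecord",
    "MarkerSet",
    "read_vcf",
    "write_vcf",
    "filter_biallelic",
    "filter_missingness",
    "minor_allele_frequency",
]


@dataclass(frozen=True)
class MarkerRecord:
    """One variant site with per-accession alt-allele dosages.

    ``alt_alleles`` holds every ALT allele so multi-allelic records survive
    reading and can be removed by :func:`filter_biallelic`; dosages at a
    multi-allelic site count any non-reference allele.
    """

    id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_alleles: tuple[str, ...]
    dosages: np.ndarray  # int8 vector over accessions; -1 = missing

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"marker {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele in self.alt_alleles:
            raise ValueError(f"marker {self.id}: ref allele equals an alt allele")
        d = np.asarray(self.dosages, dtype=np.int8)
        if not np.all(np.isin(d, (0, 1, 2, MISSING))):
            raise ValueError(f"marker {self.id}: dosages must be in {{0,1,2,missing}}")
        object.__setattr__(self, "dosages", d)
        d.setflags(write=False)

    @property
    def alt_allele(self) -> str:
        return self.alt_alleles[0]

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    @property
    def marker_type(self) -> str:
        """``snp`` iff ref and every alt are single bases, else ``indel``."""
        if len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles):
            return "snp"
        return "indel"

    @property
    def n_missing(self) -> int:
        return int(np.count_nonzero(self.dosages == MISSING))

    def missing_fraction(self) -> float:
        return self.n_missing / self.dosages.size


@dataclass(frozen=True)
class MarkerSet:
    """An ordered marker panel over a fixed accession list.

    Markers are kept sorted by (chrom, pos); every filter preserves both the
    accession axis and the sort order.
    """

    accession_ids: tuple[str, ...]
    markers: tuple[MarkerRecord, ...] = field(default_factory=tuple)

    def __post_init__(self):
        n = len(self.accession_ids)
        for m in self.markers:
            if m.dosages.size != n:
                raise ValueError(
                    f"marker {m.id}: {m.dosages.size} dosages for {n} accessions"
                )
        key = [(m.chrom, m.pos) for m in self.markers]
        if key != sorted(key):
            object.__setattr__(
                self,
                "markers",
                tuple(sorted(self.markers, key=lambda m: (m.chrom, m.pos))),
            )

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def dosage_matrix(self) -> np.ndarray:
        """(n_markers, n_accessions) int8 matrix; -1 marks missing."""
        if not self.markers:
            return np.empty((0, self.n_accessions), dtype=np.int8)
        return np.vstack([m.dosages for m in self.markers])

    def by_id(self, marker_id: str) -> MarkerRecord:
        for m in self.markers:
            if m.id == marker_id:
                return m
        from .errors import LookupError_

        raise LookupError_(f"unknown marker id: {marker_id}")

    def subset(self, keep) -> "MarkerSet":
        return replace(self, markers=tuple(m for m in self.markers if keep(m)))


def _gt_to_dosage(gt_bases: list[int]) -> int:
    """Allele index list (cyvcf2 style, -1 = missing) -> dosage.

    Any half-missing call is treated as fully missing; any non-reference
    allele index counts one alt copy.
    """
    if any(a < 0 for a in gt_bases):
        return MISSING
    return sum(1 for a in gt_bases if a > 0)


def read_vcf(path: str) -> MarkerSet:
    """Read a VCF (plain or bgzipped) into a :class:`MarkerSet`.

    Both phased and unphased genotypes map to dosage.  Multi-allelic
    records are retained (flagged via ``is_biallelic``) for downstream
    filtering.  Raises :class:`EmptyPanelError` if the VCF has no samples
    and :class:`VcfParseError` on malformed records.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = tuple(vcf.samples)
    if not samples:
        raise EmptyPanelError(f"VCF {path} declares no samples")

    markers = []
    # header line count so parse errors can name the offending line
    n_header = 0
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic != b"\x1f\x8b":
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    n_header += 1
                else:
                    break
    try:
        for i, rec in enumerate(vcf):
            gts = rec.genotypes  # [[a0, a1, phased], ...]
            dosages = np.array(
                [_gt_to_dosage(g[:-1]) for g in gts], dtype=np.int8
            )
            mid = rec.ID or f"{rec.CHROM}_{rec.POS}"
            markers.append(
                MarkerRecord(
                    id=mid,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref_allele=rec.REF,
                    alt_alleles=tuple(rec.ALT) if rec.ALT else ("<NON_REF>",),
                    dosages=dosages,
                )
            )
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF record in {path}: {exc}",
            line_number=n_header + len(markers) + 1 if n_header else None,
        ) from exc
    return MarkerSet(accession_ids=samples, markers=tuple(markers))


_DOSAGE_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(ms: MarkerSet, path: str) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype columns."""
    chroms = []
    for m in ms.markers:
        if m.chrom not in chroms:
            chroms.append(m.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ms.accession_ids)
            + "\n"
        )
        for m in ms.markers:
            gts = "\t".join(_DOSAGE_GT[int(d)] for d in m.dosages)
            fh.write(
                f"{m.chrom}\t{m.pos}\t{m.id}\t{m.ref_allele}\t"
                f"{','.join(m.alt_alleles)}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def filter_biallelic(ms: MarkerSet) -> MarkerSet:
    """Keep only sites with exactly one REF and one ALT allele."""
    return ms.subset(lambda m: m.is_biallelic)


def filter_missingness(ms: MarkerSet, max_missing_frac: float = 0.2) -> MarkerSet:
    """Drop markers whose missing fraction is >= ``max_missing_frac``.

    Retention is strict-less-than: a marker with exactly the threshold
    fraction missing (e.g. 20%) is removed.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    return ms.subset(lambda m: m.missing_fraction() < max_missing_frac)


def minor_allele_frequency(m: MarkerRecord) -> float:
    """min(p, 1-p) with p the alt-allele frequency over non-missing calls."""
    d = m.dosages[m.dosages != MISSING]
    if d.size == 0:
        raise UndefinedFrequencyError(f"marker {m.id}: all genotypes missing")
    p = float(d.sum()) / (2 * d.size)
    return min(p, 1.0 - p)
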