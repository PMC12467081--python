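"""Small published data bundled as inputs for worked examples.

These are inputs to the toolkit (marker coordinates and effect sizes as
printed in the source study of camelina seed fatty acids), not outputs it
claims to recompute.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "chr1_oleic_marker_panel",
    "linolenic_sd_na_effects",
    "pangenome_survey_rows",
    "GENOME_SIZE_BP",
    "N_GENE_MODELS",
]

#: Assembled camelina reference genome size and annotated gene-model count,
#: used for gene-density arithmetic.
GENOME_SIZE_BP = 650_000_000
N_GENE_MODELS = 138_000

# The twelve chromosome-1 markers associated with oleic (18:1) and linoleic
# (18:2) acid, with their positions and per-allele effects.
_CHR1_MARKERS = [
    # (id, chrom, pos, effect, maf, trait)
    ("SNP_591", "1", 2_611_818, -0.930, 0.110, "18:2"),
    ("SNP_653", "1", 2_712_622, 1.027, 0.0896, "18:1"),
    ("INDEL_458_1", "1", 3_063_926, 1.318, 0.117, "18:1"),
    ("SNP_739", "1", 3_125_731, 0.852, 0.101, "18:1"),
    ("SNP_742", "1", 3_148_736, 1.197, 0.075, "18:1"),
    ("INDEL_480", "1", 3_198_922, 0.808, 0.150, "18:2"),
    ("SNP_753", "1", 3_225_897, 0.596, 0.126, "18:1"),
    ("SNP_754", "1", 3_226_206, 0.620, 0.133, "18:1"),
    ("INDEL_483", "1", 3_230_709, 1.131, 0.088, "18:1"),
    ("SNP_763", "1", 3_247_468, -1.673, 0.076, "18:2"),
    ("SNP_1392", "1", 5_000_540, 0.968, 0.0744, "18:1"),
    ("SNP_1558", "1", 5_899_218, -0.934, 0.138, "18:2"),
]


def chr1_oleic_marker_panel() -> pd.DataFrame:
    """The chromosome-1 oleic/linoleic marker list (id, chrom, pos, effect,
    maf, trait) used by the region and haplotype worked examples."""
    return pd.DataFrame(
        _CHR1_MARKERS, columns=["id", "chrom", "pos", "effect", "maf", "trait"]
    )


def linolenic_sd_na_effects() -> dict[str, float]:
    """Per-allele effects of the three linolenic-acid (18:3) markers from the
    Sidney average-N trial, for the additive total-effect worked example."""
    return {"SNP_72835": 0.876, "SNP_151966": -1.165, "SNP_187379": -1.035}


def pangenome_survey_rows() -> pd.DataFrame:
    """Published pangenome gene-category survey rows (total plus the five
    conditionally exclusive category counts) for partition-arithmetic checks."""
    rows = [
        ("all_118_fatty_acid_markers", 2676, 880, 507, 144, 806, 339),
        ("chr1_oleic_linoleic_markers", 254, 56, 61, 24, 101, 12),
        ("SNP_1392", 33, 4, 3, 5, 20, 1),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "marker_set",
            "total_genes",
            "protein_diff_4plus",
            "protein_diff_1to3",
            "silent_cds",
            "noncoding_only",
            "no_match_or_no_diff",
        ],
    )
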