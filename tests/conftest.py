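import numpy as np
import pytest

from panclass import synthetic_data as sd


@pytest.fixture(scope="session")
def small_reference():
    """A compact one-chromosome reference with 8 multi-exon genes."""
    return sd.make_reference(n_chrom=1, chrom_len=40_000, n_genes=8, seed=3)


@pytest.fixture(scope="session")
def small_pangenome(small_reference):
    """Five member genomes cycling through all nine mutation classes."""
    gene_ids = [g.gene_id for g in small_reference.annotation]
    classes = sd.MUTATION_CLASSES
    plan = {
        f"mem{m}": {
            g: classes[(m + i) % len(classes)] for i, g in enumerate(gene_ids)
        }
        for m in range(5)
    }
    members, truth = sd.make_pangenome(small_reference, plan, seed=7)
    return members, truth


@pytest.fixture(scope="session")
def ld_panel():
    """100 accessions, 300 markers, 25 kb LD blocks."""
    return sd.make_population(
        n_accessions=100,
        n_markers=300,
        chrom_len=1_000_000,
        block_len=25_000,
        flip_rate=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def scan_panel():
    """200 accessions, 200 markers, tiny blocks so markers are ~independent."""
    return sd.make_population(
        n_accessions=200,
        n_markers=200,
        chrom_len=1_000_000,
        block_len=2_000,
        flip_rate=0.0,
        missing_rate=0.0,
        seed=12,
    )


def singleton_block_markers(ms, truth, n):
    """Marker ids that are the only occupant of their LD block, well spread."""
    from collections import Counter

    counts = Counter(truth.marker_block.values())
    solo = [m.id for m in ms if counts[truth.marker_block[m.id]] == 1]
    step = max(1, len(solo) // n)
    return solo[::step][:n]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
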