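import numpy as np
import pytest

from startseq.core_io import AlignedRead, GeneRecord
from startseq.synth import GeneratorConfig, simulate_all


def flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def mirror_read(read: AlignedRead, length: int) -> AlignedRead:
    """Coordinate-map a read onto the reverse-complemented genome."""
    return AlignedRead(read.chrom, length - read.end, length - read.start, flip(read.strand))


def mirror_gene(gene: GeneRecord, length: int) -> GeneRecord:
    return GeneRecord(
        gene.gene_id, gene.chrom, flip(gene.strand),
        length - gene.body_end, length - gene.body_start, gene.occurrence,
    )


def random_reads(rng, n, chrom="chr1", span=10_000, max_len=47):
    reads = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(AlignedRead(chrom, start, start + length, strand))
    return reads


@pytest.fixture(scope="session")
def small_bundle():
    """A modest synthetic study shared by read-only tests."""
    cfg = GeneratorConfig(seed=20_240_601, n_genes=80, n_elements=10, chrom_length=400_000)
    return simulate_all(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(4242)
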