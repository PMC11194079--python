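import numpy as np
import pytest

from pirnakit.io_formats import AlignedPiRNA, GenomicInterval


def make_read(
    chrom="chr1",
    start=100,
    length=30,
    strand="+",
    copies=1,
    name="read",
    sample="s",
):
    return AlignedPiRNA(
        interval=GenomicInterval(
            chrom=chrom, start=start, end=start + length, name=name, strand=strand
        ),
        copies=copies,
        sample=sample,
    )


@pytest.fixture
def read_factory():
    return make_read


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


def random_reads(rng, n, chrom_len=10_000, min_len=24, max_len=40, n_chroms=2):
    """Random stranded reads with heavy-ish copy numbers."""
    reads = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, chrom_len - length))
        reads.append(
            make_read(
                chrom=f"chr{rng.integers(1, n_chroms + 1)}",
                start=start,
                length=length,
                strand="+" if rng.random() < 0.5 else "-",
                copies=int(rng.integers(1, 20)),
                name=f"r{i}",
            )
        )
    return reads


@pytest.fixture
def random_read_factory():
    return random_reads


def random_genome(rng, length=10_000):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def genome_factory():
    return random_genome
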