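import numpy as np
import pytest

from lincrip.catalog import GenomicInterval, TranscriptCatalog, TranscriptRecord
from lincrip.simulate import SimParams, simulate_dataset


def random_catalog(rng, n, chroms=("chrA", "chrB"), source="novel",
                   prefix="t", max_exons=4):
    """A catalog of random multi-exon transcripts for round-trip and
    geometry tests."""
    records = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, max_exons + 1))
        pos = int(rng.integers(0, 100_000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(1, 500))
            exons.append(GenomicInterval(chrom, pos, pos + length, strand))
            pos += length + int(rng.integers(1, 2_000))
        records.append(
            TranscriptRecord(
                transcript_id=f"{prefix}{i}",
                gene_id=f"g{i}",
                exons=tuple(exons),
                source=source,
            )
        )
    return TranscriptCatalog.from_records(records)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest simulated screen shared by read-only tests."""
    return simulate_dataset(SimParams(seed=7, n_novel=200,
                                      n_reference_genes=60))


def single_exon(chrom, start, end, strand="+", tid="t", gid=None,
                source="novel"):
    return TranscriptRecord(
        transcript_id=tid,
        gene_id=gid or tid,
        exons=(GenomicInterval(chrom, start, end, strand),),
        source=source,
    )
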