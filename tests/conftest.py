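"""Shared fixtures: the default simulated dataset and its pipeline run.

The default dataset (seed 0, study conditions) is generated once per session
and shared read-only across tests; anything mutating should build its own.
"""

import numpy as np
import pytest

from leafatac.intervals import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    Peak,
)
from leafatac.pipeline import evaluate_recovery, run_pipeline
from leafatac.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(SimConfig(seed=0))


@pytest.fixture(scope="session")
def pipeline_result(default_dataset):
    return run_pipeline(default_dataset, seed=0)


@pytest.fixture(scope="session")
def recovery(default_dataset, pipeline_result):
    return evaluate_recovery(pipeline_result, default_dataset.truth)


@pytest.fixture()
def toy_annotation():
    """10 kb genome, one plus-strand gene at [4000, 6000) with terminal UTRs."""
    gene = GeneModel(
        gene_id="g1", chrom="chr1", strand="+", start=4000, end=6000,
        exons=[(4000, 4800), (5200, 6000)],
        utr5=[(4000, 4150)], utr3=[(5850, 6000)],
    )
    return GenomeAnnotation({"chr1": 10000}, [gene])


def make_peak(chrom, start, end, pid="p", summit=None, **kw):
    return Peak(GenomicInterval(chrom, start, end), pid,
                summit_offset=summit, **kw)


def random_intervals(rng, n, genome_size=100_000, max_len=2000, chrom="chr1"):
    starts = rng.integers(0, genome_size - max_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    ivs = [
        GenomicInterval(chrom, int(s), int(s + l))
        for s, l in zip(starts, lengths)
    ]
    ivs.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return ivs
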