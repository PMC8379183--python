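import logging

import numpy as np
import pandas as pd
import pytest

from chromduet.core import GeneModel, GenomicInterval
from chromduet.pipeline import PipelineConfig, run_pipeline
from chromduet.simulate import GroundTruth, SimulationConfig

logging.getLogger("chromduet").setLevel(logging.WARNING)


@pytest.fixture
def toy_genes():
    """Three genes on chr1 (two strands) and one on chr2."""
    return [
        GeneModel(
            "geneA",
            "chr1",
            "+",
            20_000,
            30_000,
            [GenomicInterval("chr1", 20_000, 21_000), GenomicInterval("chr1", 25_000, 30_000)],
        ),
        GeneModel(
            "geneB",
            "chr1",
            "-",
            60_000,
            70_000,
            [GenomicInterval("chr1", 60_000, 62_000), GenomicInterval("chr1", 68_000, 70_000)],
        ),
        GeneModel("geneC", "chr1", "+", 100_000, 105_000),
        GeneModel("geneD", "chr2", "+", 10_000, 15_000),
    ]


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default simulated dataset (seed 7),
    shared by the recovery and directionality tests."""
    outdir = tmp_path_factory.mktemp("run7")
    config = PipelineConfig(outdir=str(outdir), seed=7, simulate=SimulationConfig(seed=7))
    report = run_pipeline(config)
    truth_df = pd.read_csv(outdir / "inputs" / "truth.tsv", sep="\t")
    truth = GroundTruth.from_frame(truth_df, [])
    return {"outdir": outdir, "report": report, "truth": truth}


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=400):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out
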