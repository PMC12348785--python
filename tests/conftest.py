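"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rddmscan import methylome, refmodel, synthetic_data


SMALL_CFG = dict(
    n_chrom=1,
    chrom_len=100_000,
    n_genes=40,
    n_tes=30,
    n_planted_dmr=12,
    n_planted_dsr=8,
    n_planted_deg=10,
    n_planted_rddm=3,
    n_srna_clusters=60,
)


@pytest.fixture(scope="session")
def small_cfg() -> synthetic_data.SimConfig:
    return synthetic_data.SimConfig(**SMALL_CFG)


@pytest.fixture(scope="session")
def small_sim(small_cfg, tmp_path_factory):
    """One small simulated dataset on disk, shared read-only by tests."""
    outdir = tmp_path_factory.mktemp("sim")
    paths = synthetic_data.simulate_all(small_cfg, seed=20_240_101, outdir=outdir)
    return paths


@pytest.fixture(scope="session")
def small_truth(small_sim):
    return synthetic_data.read_truth(small_sim["truth_dir"])


def make_sample(site_rows, sample_id="s", dpt=0, rep=1) -> methylome.MethylomeSample:
    """Build a MethylomeSample from (chrom, pos, strand, context, meth, total) tuples."""
    df = pd.DataFrame(site_rows, columns=["chrom", "pos", "strand", "context", "meth", "total"])
    return methylome.MethylomeSample(sample_id=sample_id, timepoint_dpt=dpt, replicate=rep, sites=df)


@pytest.fixture
def toy_genes():
    """Two genes on one 30 kb chromosome, one per strand."""
    plus = refmodel.GeneModel(
        gene_id="gP", chrom="c", strand="+", tss=10_001, tes=12_000,
        exons=[(10_001, 10_600), (11_001, 12_000)],
        five_utr=[(10_001, 10_100)], three_utr=[(11_901, 12_000)],
    )
    minus = refmodel.GeneModel(
        gene_id="gM", chrom="c", strand="-", tss=22_000, tes=20_001,
        exons=[(20_001, 21_000), (21_401, 22_000)],
        five_utr=[(21_901, 22_000)], three_utr=[(20_001, 20_100)],
    )
    return [plus, minus]
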