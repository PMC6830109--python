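import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import retroscan as rs

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic dataset shared by integration-style tests."""
    cfg = rs.SimulationConfig(
        seed=11,
        n_chromosomes=2,
        chrom_length=2_000_000,
        n_genes=300,
        n_cell_lines=2,
        n_pathways=40,
        pathway_size=12,
        n_terms=40,
        term_size=12,
        n_planted_pathways=2,
        n_planted_terms=2,
    )
    return rs.simulate(cfg)


@pytest.fixture(scope="session")
def small_scores(small_dataset):
    """Aggregate gene scores computed from the small dataset."""
    ds = small_dataset
    frames = [
        rs.compute_gene_scores(rs.count_tags(ds.genes, ds.res, tags, line))
        for line, tags in ds.tags.items()
    ]
    return rs.aggregate_cell_lines(pd.concat(frames, ignore_index=True))
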