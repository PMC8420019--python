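import numpy as np
import pandas as pd
import pytest

import devhypoxia as dh
from devhypoxia.simulate import promoter_methylation_by_gene


@pytest.fixture(scope="session")
def small_config():
    return dh.SimulationConfig(
        seed=7, chrom_length=400_000, n_genes=30, n_planted_islands=8
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One simulated genome + methylome + expression set shared by tests."""
    genome, annotation, islands = dh.simulate_genome_and_annotation(small_config)
    matrix, groups, dm_truth = dh.simulate_methylome(small_config, genome, annotation)
    pm = promoter_methylation_by_gene(small_config, annotation, matrix, groups)
    counts, design, lengths, de_truth = dh.simulate_expression(
        small_config, annotation, pm
    )
    return {
        "config": small_config,
        "genome": genome,
        "annotation": annotation,
        "islands": islands,
        "matrix": matrix,
        "groups": groups,
        "dm_truth": dm_truth,
        "promoter_meth": pm,
        "counts": counts,
        "design": design,
        "gene_lengths": lengths,
        "de_truth": de_truth,
    }


@pytest.fixture()
def toy_matrix():
    """Hand-built 4-site, 2x3-sample count matrix."""
    sites = pd.DataFrame(
        {"chrom": ["chr1"] * 4, "pos": [10, 50, 120, 300]}
    )
    total = np.array(
        [
            [12, 9, 11, 15, 10, 0],
            [9, 9, 12, 20, 20, 20],
            [30, 30, 30, 30, 30, 30],
            [10, 10, 10, 10, 10, 10],
        ]
    )
    meth = np.array(
        [
            [6, 4, 5, 7, 5, 0],
            [0, 1, 0, 10, 10, 10],
            [30, 30, 30, 0, 0, 0],
            [5, 5, 5, 5, 5, 5],
        ]
    )
    samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
    groups = {s: s[0] for s in samples}
    return dh.CpGSiteMatrix(sites, meth, total, samples), groups
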