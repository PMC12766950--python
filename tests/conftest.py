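import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from wntaxis.io_formats import ExpressionMatrix, SingleCellCounts

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_expression():
    """Two-tissue, 24-sample matrix with a handful of genes."""
    rng = np.random.default_rng(7)
    samples = [f"s{i:02d}" for i in range(24)]
    tissues = ["lung"] * 12 + ["stomach"] * 12
    genes = ["WNT7B", "ITGA2", "TSPAN1", "ZZZ1"]
    values = pd.DataFrame(
        rng.uniform(0, 8, size=(len(genes), len(samples))), index=genes, columns=samples
    )
    return ExpressionMatrix(values=values, sample_tissue=pd.Series(tissues, index=samples))


@pytest.fixture
def small_sc_counts():
    """120 cells, two genotypes, two clusters, five genes with a planted shift."""
    rng = np.random.default_rng(11)
    n = 120
    genotype = np.array(["RZ"] * 60 + ["RZK"] * 60)
    cluster = np.tile(["W", "P"], n // 2)
    counts = rng.poisson(2.0, size=(n, 5))
    counts[genotype == "RZK", 0] = rng.poisson(8.0, size=60)  # shifted gene
    cells = [f"c{i:03d}" for i in range(n)]
    return SingleCellCounts(
        counts=counts.astype(np.int64),
        cell_ids=cells,
        gene_ids=["Shifted", "Wnt7b", "Bgd1", "Bgd2", "Bgd3"],
        cell_genotype=pd.Series(genotype, index=cells),
        cell_cluster=pd.Series(cluster, index=cells),
    )
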