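import numpy as np
import pandas as pd
import pytest

import strychmine as sm


@pytest.fixture(scope="session")
def small_counts() -> sm.CountsMatrix:
    """A tiny hand-checkable counts matrix: 4 genes, 2 tissues x 2 replicates."""
    genes = ["gA", "gB", "gC", "gD"]
    samples = ["root_rep1", "root_rep2", "leaf_rep1", "leaf_rep2"]
    values = pd.DataFrame(
        [[100, 120, 10, 14], [50, 40, 60, 50], [0, 0, 5, 3], [1000, 900, 1000, 1100]],
        index=pd.Index(genes, name="gene_id"),
        columns=samples,
    )
    lengths = pd.Series([1000, 2000, 500, 1500], index=values.index, name="length")
    design = pd.Series(
        ["root", "root", "leaf", "leaf"], index=pd.Index(samples, name="sample")
    )
    return sm.CountsMatrix(values=values, gene_lengths=lengths, design=design)


@pytest.fixture(scope="session")
def planted_dataset() -> sm.SyntheticDataset:
    """Default planted-module simulation, shared across read-only tests."""
    return sm.simulate_transcriptome(sm.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def planted_expr(planted_dataset) -> sm.ExpressionMatrix:
    ds = planted_dataset
    return sm.compute_fpkm(sm.CountsMatrix(ds.counts, ds.gene_lengths, ds.design))


@pytest.fixture(scope="session")
def proteome_pair() -> sm.SyntheticProteome:
    return sm.simulate_proteome_pair(n_proteins=8, length=200, target_identity=0.9, seed=21)


def make_expression(values: np.ndarray, n_root: int = 2) -> sm.ExpressionMatrix:
    """Wrap a raw matrix as FPKM with the first ``n_root`` samples labelled root."""
    n_genes, n_samples = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    tissues = ["root" if j < n_root else "leaf" for j in range(n_samples)]
    fpkm = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    design = pd.Series(tissues, index=pd.Index(samples, name="sample"))
    return sm.ExpressionMatrix(fpkm=fpkm, design=design)
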