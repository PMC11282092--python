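import numpy as np
import pytest

from rmsstates import preprocess as pp
from rmsstates import scoring as sc
from rmsstates.signatures import GeneSignature
from rmsstates.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default-configuration cohort (6 samples x 300 cells, 4 states),
    log-normalized; shared read-only across tests."""
    adata, truth = generate_cohort(SimConfig(seed=7))
    pp.lognormalize(adata)
    return adata, truth


@pytest.fixture(scope="session")
def truth_signatures(default_cohort):
    _, truth = default_cohort
    sigs = {
        state: GeneSignature(state, genes)
        for state, genes in truth.marker_assignment.items()
    }
    return sigs


@pytest.fixture(scope="session")
def scored_cohort(default_cohort, truth_signatures):
    """Scaled state scores + cell-cycle calls on the default cohort."""
    adata, truth = default_cohort
    cs = sc.score_states(
        adata,
        truth_signatures,
        sc.ScoreParams(seed=5),
        s_genes=GeneSignature("S", truth.cycle_genes["S"]),
        g2m_genes=GeneSignature("G2M", truth.cycle_genes["G2M"]),
    )
    return cs


@pytest.fixture(scope="session")
def tiny_matrix():
    """5 cells x 20 genes deterministic dense count matrix for oracles."""
    import anndata as ad
    import pandas as pd
    import scipy.sparse as sp

    rng = np.random.default_rng(123)
    X = rng.integers(0, 8, size=(5, 20))
    genes = [f"G{i:02d}" for i in range(20)]
    adata = ad.AnnData(
        X=sp.csr_matrix(X),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(5)]),
        var=pd.DataFrame({"is_mitochondrial": [False] * 20}, index=genes),
    )
    pp.lognormalize(adata)
    return adata
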