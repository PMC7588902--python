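import numpy as np
import pandas as pd
import pytest

from nrf_targetscope import ExpressionMatrix


def make_matrix(values, gene_ids=None, groups=("vector", "overexpression")):
    """Two-group expression matrix from a (genes x 2*nrep) array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    nrep = n_samples // 2
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"{groups[0]}_{i}" for i in range(nrep)] + [
        f"{groups[1]}_{i}" for i in range(nrep)
    ]
    design = pd.DataFrame(
        {"group": [groups[0]] * nrep + [groups[1]] * nrep,
         "replicate": list(range(nrep)) * 2},
        index=pd.Index(sample_ids, name="sample"),
    )
    return ExpressionMatrix(gene_ids, sample_ids, values, design)


@pytest.fixture
def two_group_matrix():
    rng = np.random.default_rng(0)
    vals = 2.0 ** rng.normal(6, 1, size=(50, 6))
    return make_matrix(vals)
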