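import numpy as np
import pandas as pd
import pytest

from scregnet import simulate


@pytest.fixture(scope="session")
def rna_adata():
    spec = simulate.ScRnaSimSpec(n_cells=600, n_genes=80, n_clusters=3, seed=11)
    return simulate.simulate_scrna(spec)


@pytest.fixture(scope="session")
def atac_triple():
    spec = simulate.ScAtacSimSpec(n_cells=400, n_peaks=200, seed=7)
    return simulate.simulate_scatac(spec)


@pytest.fixture(scope="session")
def truth_grn():
    return simulate.random_grn(n_genes=30, n_regulators=5, noise_sd=0.5, seed=2)


@pytest.fixture(scope="session")
def grn_expression(truth_grn):
    adata = simulate.simulate_grn_expression(truth_grn, n_cells=1500, seed=3)
    return pd.DataFrame(np.asarray(adata.X), columns=list(adata.var_names))
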