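import numpy as np
import pytest

import gxemix as gx
from gxemix.penalized_path import PathData, fit_null_state


@pytest.fixture(scope="session")
def small_cohort():
    """A small structured cohort with causal main and GEI effects."""
    ds = gx.simulate_dataset(
        n=200, p=60, n_causal_main=8, n_causal_gei=4,
        n_kinship_snps=400, seed=42,
    )
    Z = np.column_stack([np.ones(ds.config.n), ds.age])
    return ds, Z


@pytest.fixture(scope="session")
def fitted_null(small_cohort):
    ds, Z = small_cohort
    null = gx.fit_null_pql_aireml(ds.y, Z, ds.sex, ds.kin.K, ds.kin.K_D)
    basis = gx.spectral_decompose(
        max(null.tau_g, 1e-8), null.tau_d, ds.kin.K, ds.kin.K_D
    )
    data = PathData(y=ds.y, Z=Z, D=ds.sex, G_std=ds.G_std)
    null_state = fit_null_state(data, basis, null)
    return ds, data, null, basis, null_state
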