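import numpy as np
import pytest

from dsf_isofit import (
    AssayConfig,
    MeltCurve,
    c_to_k,
    generate_dataset,
    mbp_like_spec,
    run_pipeline,
)
from dsf_isofit.thermo import ku_unfolding


@pytest.fixture(scope="session")
def mbp_spec():
    """MBP-like simulation parameters: Tm 50 C, K_d(Tm) 1 uM, 2 uM protein."""
    return mbp_like_spec()


@pytest.fixture(scope="session")
def noiseless_curves(mbp_spec):
    return generate_dataset(mbp_spec)


@pytest.fixture(scope="session")
def noiseless_report(noiseless_curves):
    cfg = AssayConfig(protein_conc_total=2e-6, slice_temperatures=[50.0],
                      dcp_u=4.0)
    return run_pipeline(cfg, noiseless_curves)


def make_raw_curve(
    tm_c=50.0,
    dh=120.0,
    dcp=4.0,
    baselines=(10.0, 1000.0, -20.0, 9000.0),
    grid=None,
    ligand=0.0,
):
    """Raw-style trace built from the two-state model wrapped in linear
    dye baselines; the independent generator used as a fitting oracle."""
    if grid is None:
        grid = np.arange(tm_c - 15.0, tm_c + 15.0 + 1e-9, 0.25)
    ku = ku_unfolding(c_to_k(grid), c_to_k(tm_c), dh, dcp)
    f = ku / (1.0 + ku)
    m_f, b_f, m_u, b_u = baselines
    y = (1.0 - f) * (m_f * grid + b_f) + f * (m_u * grid + b_u)
    return MeltCurve(grid, y, ligand_conc_total=ligand, normalized=False)


@pytest.fixture
def raw_curve():
    return make_raw_curve()
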