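import numpy as np
import pandas as pd
import pytest

from autoreact.simdata import BeadArrayDataset, SimConfig, generate_bead_array


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_cases=12, n_controls=12, n_analytes=40, n_differential=3, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_bead_array(small_config)


@pytest.fixture(scope="session")
def study_dataset():
    """One cohort at the full study design (30+30, 256 analytes, 7 spiked)."""
    return generate_bead_array(SimConfig(seed=1))


def make_manual_dataset(rep1, rep2, roles, groups=None, analytes=None):
    """Hand-built BeadArrayDataset for boundary-value fixtures."""
    rep1 = np.asarray(rep1, float)
    rep2 = np.asarray(rep2, float)
    n_wells, n_analytes = rep1.shape
    analytes = analytes or [f"A{j + 1}" for j in range(n_analytes)]
    wells = [f"w{i + 1}" for i in range(n_wells)]
    groups = groups or [None] * n_wells
    wm = pd.DataFrame({"role": roles, "group": groups}, index=pd.Index(wells, name="well"))
    am = pd.DataFrame(
        {"genes": [f"G{j + 1}" for j in range(n_analytes)], "block": 0},
        index=pd.Index(analytes, name="analyte"),
    )
    cols = pd.Index(analytes, name="analyte")
    return BeadArrayDataset(
        mfi_rep1=pd.DataFrame(rep1, index=wm.index, columns=cols),
        mfi_rep2=pd.DataFrame(rep2, index=wm.index, columns=cols),
        well_meta=wm,
        analyte_meta=am,
    )
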