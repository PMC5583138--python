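import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from washout.tables_io import CountTable
from washout.washout_sim import scenario_paper_like, simulate, simulate_scenario


@pytest.fixture
def small_counts() -> CountTable:
    """3 taxa x 4 samples: one granular/effluent pair per reactor for R1, R2."""
    return CountTable(
        pd.DataFrame(
            {
                "R1R_d10": [20, 30, 50],
                "R1E_d10": [10, 30, 60],
                "R2R_d10": [5, 5, 90],
                "R2E_d10": [25, 25, 50],
            },
            index=["g__Zoogloea", "g__Thauera", "OTU_6"],
            dtype=np.int64,
        )
    )


@pytest.fixture
def small_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["R1R_d10", "R1E_d10", "R2R_d10", "R2E_d10"],
            "reactor": ["R1", "R1", "R2", "R2"],
            "compartment": ["granular", "effluent", "granular", "effluent"],
            "day": [10, 10, 10, 10],
        }
    )


@pytest.fixture(scope="session")
def scenario_output():
    """One simulated three-reactor study (78 samples), shared across tests."""
    return simulate_scenario(scenario_paper_like(seed=7))


@pytest.fixture(scope="session")
def single_reactor_output(scenario_output):
    """The beta = 1.5 reactor of the bundled scenario."""
    return scenario_output.outputs["R2"]
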