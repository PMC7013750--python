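import numpy as np
import pandas as pd
import pytest

from gravicomp.io import ExpressionMatrix, Platform, SampleSheet
from gravicomp.simulate import SimulationConfig, generate_study


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    values = pd.DataFrame(
        {
            "s1": [2.0, 8.0, 1.5],
            "s2": [4.0, 16.0, 1.5],
        },
        index=pd.Index(["tc1", "tc2", "tc3"], name="tc_id"),
    )
    symbols = pd.Series(["GENEA", "", "GENEC"], index=values.index)
    return ExpressionMatrix(values, symbols)


@pytest.fixture
def gbf_sheet() -> SampleSheet:
    rows = []
    for group in ("BL", "CONTROL_1G", "CLINOSTAT_2D", "CENTRIFUGE_9G"):
        for r in range(1, 7):
            rows.append(
                {"sample_id": f"GBF_{group}_{r}", "platform": "GBF", "group": group}
            )
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_study():
    """A modest planted study shared by several read-only tests."""
    config = SimulationConfig(n_tc=1500, seed=42)
    return generate_study(config)


@pytest.fixture(scope="session")
def noisefree_study():
    config = SimulationConfig(n_tc=800, noise_sd=0.0, seed=7)
    return generate_study(config)
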