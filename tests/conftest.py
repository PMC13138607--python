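import pandas as pd
import pytest


@pytest.fixture()
def synthetic_grid_table():
    """Hand-crafted Monte Carlo grid table with round numbers, for tests that
    exercise the sensitivity arithmetic without running the transport code.
    Columns follow the mc_grid.csv schema; rf_platform is at reference
    photometry (n0, eps0, QY0)."""
    return pd.DataFrame(
        [
            {"mu_a": 0.02, "mu_s_reduced": 20.0, "rd_platform": 0.8,
             "rf_platform": 1.0e-7, "ratio_rf_rd": 1.25e-7},
            {"mu_a": 0.40, "mu_s_reduced": 15.0, "rd_platform": 0.45,
             "rf_platform": 3.6e-7, "ratio_rf_rd": 8.0e-7},
        ]
    )
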