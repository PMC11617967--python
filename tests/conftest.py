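import numpy as np
import pandas as pd
import pytest

from transpirest import ClimateLog, ProduceItem, SimulationSpec


@pytest.fixture
def apple_item() -> ProduceItem:
    """A mean-mass apple; area comes from the calibrated regression."""
    return ProduceItem(item_id="apple-01", species="apple", mass_g=131.0)


@pytest.fixture
def apple_spec(apple_item) -> SimulationSpec:
    """Noiseless 24 h free-convection apple experiment at 20 degC / 50 % rH."""
    return SimulationSpec(
        item=apple_item,
        r_T_s_cm=391.0,
        r_B_s_cm=4.8,
        temperature_c=20.0,
        rh_pct=50.0,
        duration_h=24.0,
        weighing_interval_h=2.0,
        balance_resolution_mg=0.0,
        seed=7,
    )


def constant_climate(temp_c=20.0, rh_pct=50.0, pbar_pa=101325.0, hours=24, step_h=1.0):
    ts = pd.Timestamp("2024-01-01") + pd.to_timedelta(
        np.arange(0, hours + 1e-9, step_h), unit="h"
    )
    return ClimateLog(
        data=pd.DataFrame(
            {"timestamp": ts, "temp_c": temp_c, "rh_pct": rh_pct, "pbar_pa": pbar_pa}
        )
    )


@pytest.fixture
def climate_20_50():
    return constant_climate()
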