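"""Published tissue and boundary-layer resistances, as a reference fixture.

The table collects measured values for 'Jonagold' apples (individual fruit
at 20 and 1 deg C, and a ~20 kg bulk container at 20 deg C) together with
literature ranges for freshly harvested produce. Measured rows carry equal
min and max; literature rows carry the published range. Values are in
s cm^-1.

These numbers are context and cross-check material — e.g. the roughly
twofold rise of apple tissue resistance from 20 to 1 deg C that anchors the
Arrhenius temperature adjustment — not calibration inputs to the estimators.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import pandas as pd

__all__ = ["load_reference_resistances", "measured_apple_resistance"]


def load_reference_resistances() -> pd.DataFrame:
    """Load the published-resistance table shipped with the package."""
    with resources.files("transpirest").joinpath(
        "data/reference_resistances.csv"
    ).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def measured_apple_resistance(
    temperature_c: float, configuration: str = "individual"
) -> dict:
    """Measured 'Jonagold' apple resistances at a given temperature.

    Returns a dict with ``r_T`` (mean), ``r_T_sd`` and ``r_B`` in s cm^-1.
    """
    df = load_reference_resistances()
    row = df[
        (df["produce"] == "apple_jonagold")
        & (df["configuration"] == configuration)
        & (df["temperature_c"] == temperature_c)
    ]
    if row.empty:
        raise KeyError(
            f"no measured apple entry at {temperature_c} deg C / {configuration!r}"
        )
    r = row.iloc[0]
    return {
        "r_T": float(r["r_t_min_s_cm"]),
        "r_T_sd": float(r["r_t_sd_s_cm"]),
        "r_B": float(r["r_b_min_s_cm"]),
    }
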