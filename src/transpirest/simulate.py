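"""Forward transpiration model and synthetic-data generator.

Given true resistances (rT, rB) and a climate, the forward model integrates
the mass-loss trajectory dm/dt = -E(t) A with E(t) = 3.6 dx(t) / (rT + rB),
samples it on the weighing schedule, quantizes to the balance resolution
(0.1 mg by default), and writes the weighing and climate logs in exactly the
shape the estimation chain consumes. Because the generating resistances are
known, the entire chain — psychrometrics, surface-area regression, rate
estimation, partitioning — can be tested as an inverse problem: simulate,
estimate, compare.

The dynamics are quasi-static (fractional mass loss per protocol is well
below 1 %), so a fixed 1-minute explicit step suffices and the surface area
is held at its initial value. Optional climate drift is a first-order
autoregressive perturbation of temperature and humidity, off by default:
the study conditions are a climatised room.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import psychro, resistance
from .constants import RESISTANCE_UNIT_FACTOR
from .errors import TranspirestError
from .experiment_io import ClimateLog, ProtocolConfig, WeighingSeries
from .geometry import ProduceItem, resolve_area

__all__ = ["SimulationSpec", "RecoveryReport", "forward_simulate", "recovery_experiment"]

_EPOCH = pd.Timestamp("2024-01-01T00:00:00")
_STEP_MIN = 1.0  # internal integration step [minutes]


class SimulationSpec(BaseModel):
    """Everything needed to generate one synthetic weighing experiment."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    item: ProduceItem
    r_T_s_cm: float = Field(ge=0.0, description="true tissue resistance [s cm^-1]")
    r_B_s_cm: float = Field(ge=0.0, description="true boundary-layer resistance [s cm^-1]")
    temperature_c: float = 20.0
    rh_pct: float = Field(default=50.0, ge=0.0, le=100.0)
    pressure_pa: float = Field(default=101325.0, gt=0.0)
    drift_std_temp_c: float = Field(default=0.0, ge=0.0)
    drift_std_rh_pct: float = Field(default=0.0, ge=0.0)
    drift_ar_coefficient: float = Field(default=0.98, ge=0.0, lt=1.0)
    duration_h: float = Field(default=24.0, gt=0.0)
    weighing_interval_h: float = Field(default=2.0, gt=0.0)
    climate_log_interval_min: float = Field(default=10.0, gt=0.0)
    balance_resolution_mg: float = Field(default=0.1, ge=0.0)
    is_bulk: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.r_T_s_cm + self.r_B_s_cm <= 0.0:
            raise ValueError("total resistance must be positive")
        if self.weighing_interval_h >= self.duration_h + 1e-12:
            raise ValueError("weighing interval must be shorter than the duration")
        return self


@dataclass
class RecoveryReport:
    """True vs estimated resistances for one simulated experiment."""

    protocol: str
    r_T_true: float
    r_B_true: float
    r_T_est: float
    r_B_est: float
    r_tot_est: float
    rel_error_r_T: float
    rel_error_r_B: Optional[float]
    result: resistance.ResistanceResult


def _ar1(rng: np.random.Generator, n: int, std: float, phi: float) -> np.ndarray:
    """Stationary AR(1) path with marginal standard deviation ``std``."""
    if std == 0.0:
        return np.zeros(n)
    innovations = rng.standard_normal(n) * std * np.sqrt(1.0 - phi**2)
    path = np.empty(n)
    path[0] = rng.standard_normal() * std
    for k in range(1, n):
        path[k] = phi * path[k - 1] + innovations[k]
    return path


def forward_simulate(spec: SimulationSpec) -> Tuple[WeighingSeries, ClimateLog]:
    """Generate (weighing series, climate log) from known resistances.

    Deterministic for a fixed seed. Raises if the produce mass would be
    exhausted within the simulated period (unphysical spec).
    """
    rng = np.random.default_rng(spec.seed)
    item = spec.item
    area_cm2 = resolve_area(item)
    if item.mass_g is None:
        raise TranspirestError("simulation needs the item's fresh mass")

    n_steps = int(round(spec.duration_h * 60.0 / _STEP_MIN))
    t_min = np.arange(n_steps + 1) * _STEP_MIN
    t_h = t_min / 60.0

    temp = spec.temperature_c + _ar1(
        rng, n_steps + 1, spec.drift_std_temp_c, spec.drift_ar_coefficient
    )
    rh = np.clip(
        spec.rh_pct
        + _ar1(rng, n_steps + 1, spec.drift_std_rh_pct, spec.drift_ar_coefficient),
        0.0,
        100.0,
    )

    t_produce = (
        item.produce_temperature_c
        if item.produce_temperature_c is not None
        else spec.temperature_c
    )
    x_p = psychro.intercellular_water_content(
        t_produce, item.water_activity, spec.pressure_pa
    )
    x_a = psychro.volume_water_content_chain(temp, rh, spec.pressure_pa)

    # E in mg cm^-2 h^-1; explicit left-endpoint stepping
    E = RESISTANCE_UNIT_FACTOR * (x_p - x_a) / (spec.r_T_s_cm + spec.r_B_s_cm)
    dt_h = _STEP_MIN / 60.0
    loss_mg = np.concatenate(([0.0], np.cumsum(E[:-1] * area_cm2 * dt_h)))
    mass_g = item.mass_g - loss_mg / 1000.0
    if np.any(mass_g <= 0):
        raise TranspirestError("simulated produce mass exhausted; check the spec")

    # sample the weighing schedule on the internal grid
    weigh_t_h = np.arange(0.0, spec.duration_h + 1e-9, spec.weighing_interval_h)
    weigh_idx = np.rint(weigh_t_h * 60.0 / _STEP_MIN).astype(int)
    weigh_mass = mass_g[weigh_idx]
    if spec.balance_resolution_mg > 0:
        res_g = spec.balance_resolution_mg / 1000.0
        weigh_mass = np.round(weigh_mass / res_g) * res_g
    weigh_ts = _EPOCH + pd.to_timedelta(t_h[weigh_idx], unit="h")

    series = WeighingSeries(
        item_id=item.item_id,
        timestamps=pd.DatetimeIndex(weigh_ts),
        mass_g=weigh_mass,
        is_bulk=spec.is_bulk,
    )

    log_idx = np.rint(
        np.arange(0.0, spec.duration_h * 60.0 + 1e-9, spec.climate_log_interval_min)
        / _STEP_MIN
    ).astype(int)
    if log_idx[-1] != n_steps:
        log_idx = np.append(log_idx, n_steps)
    climate = ClimateLog(
        data=pd.DataFrame(
            {
                "timestamp": _EPOCH + pd.to_timedelta(t_h[log_idx], unit="h"),
                "temp_c": temp[log_idx],
                "rh_pct": rh[log_idx],
                "pbar_pa": spec.pressure_pa,
            }
        )
    )
    return series, climate


def recovery_experiment(spec: SimulationSpec, config: ProtocolConfig) -> RecoveryReport:
    """Simulate, estimate, and report the recovery error of (rT, rB).

    free
        One run with the authentic boundary layer; the estimator assumes
        ``config.rb_default_s_cm`` for the partition.
    forced / wetted
        A paired design on the same fruit and climate: one authentic-rB run
        and one stripped run (rB = 0). The stripped total gives rT; the
        difference of totals gives rB.
    bulk
        A bulk run plus a stripped individual run; rT from the stripped run,
        bulk rB from the difference.
    """
    item = spec.item

    if config.protocol == "free":
        series, climate = forward_simulate(spec)
        result = resistance.run_protocol(series, climate, item, config)
        r_t_est, r_b_est = result.r_T, result.r_B
    elif config.protocol in ("forced", "wetted"):
        stripped_spec = spec.model_copy(update={"r_B_s_cm": 0.0})
        series_auth, climate = forward_simulate(spec)
        series_strip, _ = forward_simulate(stripped_spec)
        result = resistance.run_protocol(series_strip, climate, item, config)
        free_cfg = config.model_copy(update={"protocol": "free", "rb_default_s_cm": 0.0})
        r_tot_free = resistance.run_protocol(series_auth, climate, item, free_cfg).r_tot
        r_t_est = result.r_T
        r_b_est = resistance.boundary_layer_by_difference(r_tot_free, result.r_tot)
    elif config.protocol == "bulk":
        stripped_spec = spec.model_copy(update={"r_B_s_cm": 0.0, "is_bulk": False})
        series_bulk, climate = forward_simulate(spec)
        series_strip, climate_strip = forward_simulate(stripped_spec)
        forced_cfg = config.model_copy(update={"protocol": "forced"})
        r_t_est = resistance.run_protocol(
            series_strip, climate_strip, item, forced_cfg
        ).r_T
        bulk_cfg = config.model_copy(update={"tissue_resistance_s_cm": r_t_est})
        result = resistance.run_protocol(series_bulk, climate, item, bulk_cfg)
        r_b_est = result.r_B
    else:  # pragma: no cover
        raise TranspirestError(f"unknown protocol {config.protocol!r}")

    rel_t = abs(r_t_est - spec.r_T_s_cm) / spec.r_T_s_cm if spec.r_T_s_cm else 0.0
    rel_b = (
        abs(r_b_est - spec.r_B_s_cm) / spec.r_B_s_cm if spec.r_B_s_cm > 0 else None
    )
    return RecoveryReport(
        protocol=config.protocol,
        r_T_true=spec.r_T_s_cm,
        r_B_true=spec.r_B_s_cm,
        r_T_est=r_t_est,
        r_B_est=r_b_est,
        r_tot_est=result.r_tot,
        rel_error_r_T=rel_t,
        rel_error_r_B=rel_b,
        result=result,
    )
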