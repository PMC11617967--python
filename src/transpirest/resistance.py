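"""Transpiration-resistance determination: the core of the method.

Water loss from fresh produce is modelled as vapour diffusion through two
series resistances,

    E = (xp - xa) / (rT + rB) = dx / rtot,

where ``E`` is the area-related transpiration rate [mg cm^-2 h^-1], ``xp``
the water-vapour concentration of the saturated (or near-saturated)
intercellular air [g m^-3], ``xa`` the ambient concentration, ``rT`` the
tissue resistance of the epidermis and ``rB`` the boundary-layer resistance
of the stagnant air film [s cm^-1]. ``E`` is measured by differential
weighing, E = dFM / (A dt); equating the two expressions yields the total
resistance, which the four measurement protocols partition differently:

* free convection: ``rB`` assumed (4.0 s/cm for individual apples), rT by
  subtraction;
* forced convection (>2 m/s) and wetted surface: ``rB = 0``, so rtot = rT;
* the difference between an authentic-rB and a stripped run gives rB of an
  individual fruit;
* bulk (packed container): rB = rtot_bulk - rT with rT known from a prior
  individual measurement; restricted air exchange makes this bulk rB an
  order of magnitude above the single-fruit value.

With the boundary-layer resistance known, the surface vapour concentration
follows from E = (xpS - xa)/rB, and inverting the psychrometric chain at the
surface temperature gives the relative humidity at the produce surface.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from . import psychro
from .constants import KELVIN_OFFSET, R_GAS, RESISTANCE_UNIT_FACTOR
from .errors import (
    AssumptionWarning,
    CondensationWarning,
    DrivingForceError,
    InsufficientDataError,
    NoTranspirationError,
    ResistanceInconsistencyError,
    SupersaturationError,
    TranspirestError,
)
from .experiment_io import ClimateLog, ProtocolConfig, WeighingSeries, mean_climate
from .geometry import ProduceItem, resolve_area

logger = logging.getLogger("transpirest")

__all__ = [
    "ResistanceResult",
    "transpiration_rate",
    "total_resistance",
    "tissue_resistance",
    "boundary_layer_by_difference",
    "bulk_boundary_layer",
    "surface_conditions",
    "arrhenius_adjust",
    "estimate_activation_energy",
    "run_protocol",
]


@dataclass
class ResistanceResult:
    """Full outcome of one resistance determination, with provenance."""

    E: float  # transpiration rate [mg cm^-2 h^-1]
    x_p: float  # intercellular vapour concentration [g m^-3]
    x_a: float  # ambient vapour concentration [g m^-3]
    delta_x: float  # driving force [g m^-3]
    r_tot: float  # total resistance [s cm^-1]
    r_T: float  # tissue resistance [s cm^-1]
    r_B: float  # boundary-layer resistance [s cm^-1]
    x_pS: float  # surface vapour concentration [g m^-3]
    rh_surface_pct: float  # relative humidity at the produce surface [%]
    protocol: str
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "E_mg_cm2_h": self.E,
            "x_p_g_m3": self.x_p,
            "x_a_g_m3": self.x_a,
            "delta_x_g_m3": self.delta_x,
            "r_tot_s_cm": self.r_tot,
            "r_T_s_cm": self.r_T,
            "r_B_s_cm": self.r_B,
            "x_pS_g_m3": self.x_pS,
            "rh_surface_pct": self.rh_surface_pct,
            "protocol": self.protocol,
            **{f"prov_{k}": v for k, v in self.provenance.items()},
        }


def transpiration_rate(delta_fm_mg: float, area_cm2: float, delta_t_h: float) -> float:
    """Area-related transpiration rate E = dFM / (A dt) [mg cm^-2 h^-1].

    A negative fresh-matter change (mass gain) is allowed but flagged with a
    :class:`CondensationWarning`; downstream resistance computation will
    reject it.
    """
    if area_cm2 <= 0:
        raise TranspirestError(f"surface area must be positive, got {area_cm2}")
    if delta_t_h <= 0:
        raise TranspirestError(f"time interval must be positive, got {delta_t_h}")
    if delta_fm_mg < 0:
        warnings.warn(
            f"mass gain of {-delta_fm_mg} mg over the interval: condensation "
            "or handling artefact",
            CondensationWarning,
            stacklevel=2,
        )
    return delta_fm_mg / (area_cm2 * delta_t_h)


def total_resistance(E: float, x_p: float, x_a: float) -> float:
    """Total resistance rtot = 3.6 (xp - xa) / E [s cm^-1].

    The factor 3.6 converts (g m^-3) / (mg cm^-2 h^-1) to s cm^-1; it is the
    single named unit constant :data:`~transpirest.constants.RESISTANCE_UNIT_FACTOR`.
    """
    if E <= 0:
        raise NoTranspirationError(
            f"transpiration rate E = {E} mg cm^-2 h^-1 is not positive; "
            "resistance is undefined"
        )
    if x_p <= x_a:
        raise DrivingForceError(
            f"intercellular concentration ({x_p} g m^-3) does not exceed the "
            f"ambient one ({x_a} g m^-3): condensation regime"
        )
    return RESISTANCE_UNIT_FACTOR * (x_p - x_a) / E


def tissue_resistance(r_tot: float, r_B: float) -> float:
    """Tissue resistance rT = rtot - rB [s cm^-1]; negative results are errors."""
    if r_tot < 0 or r_B < 0:
        raise TranspirestError("resistances must be non-negative")
    if r_B > r_tot:
        raise ResistanceInconsistencyError(
            f"boundary-layer resistance ({r_B} s cm^-1) exceeds the total "
            f"({r_tot} s cm^-1): inconsistent protocol or climate data"
        )
    return r_tot - r_B


def boundary_layer_by_difference(r_tot_free: float, r_tot_stripped: float) -> float:
    """Boundary-layer resistance of an individual fruit.

    Difference between the total resistance with authentic boundary layer
    (free convection) and with the boundary layer stripped (forced
    convection > 2 m/s, or wetted surface); both runs must be on the same
    fruit at the same temperature.
    """
    if r_tot_stripped > r_tot_free:
        raise ResistanceInconsistencyError(
            f"stripped-run total ({r_tot_stripped} s cm^-1) exceeds the "
            f"free-convection total ({r_tot_free} s cm^-1)"
        )
    return r_tot_free - r_tot_stripped


def bulk_boundary_layer(r_tot_bulk: float, r_T: float) -> float:
    """Effective boundary-layer resistance of produce packed in a container."""
    if r_T > r_tot_bulk:
        raise ResistanceInconsistencyError(
            f"tissue resistance ({r_T} s cm^-1) exceeds the bulk total "
            f"({r_tot_bulk} s cm^-1)"
        )
    return r_tot_bulk - r_T


def surface_conditions(
    E: float,
    r_B: float,
    x_a: float,
    surface_temperature_c: float,
    pressure_pa: float = 101325.0,
) -> Tuple[float, float]:
    """Vapour concentration and relative humidity at the produce surface.

    From E = (xpS - xa)/rB (in the package's units, xpS = xa + E rB / 3.6),
    then the inverse psychrometric solve at the surface temperature yields
    the surface relative humidity.
    """
    if r_B < 0:
        raise TranspirestError(f"boundary-layer resistance must be >= 0, got {r_B}")
    if E < 0:
        raise TranspirestError(f"transpiration rate must be >= 0, got {E}")
    x_ps = x_a + E * r_B / RESISTANCE_UNIT_FACTOR
    rh = psychro.humidity_from_volume_content(x_ps, surface_temperature_c, pressure_pa)
    return x_ps, rh


def arrhenius_adjust(
    r_ref: float,
    t_ref_c: float,
    t_target_c: float,
    activation_energy_j_mol: float,
) -> float:
    """Translate a resistance to another temperature via Arrhenius scaling.

    r(T) = r_ref exp[(Ea/R)(1/T - 1/T_ref)] with absolute temperatures, so a
    positive activation energy makes resistance grow as temperature falls —
    the direction observed for fresh produce.
    """
    t_ref = t_ref_c + KELVIN_OFFSET
    t_target = t_target_c + KELVIN_OFFSET
    if t_ref <= 0 or t_target <= 0:
        raise TranspirestError("absolute temperatures must be positive")
    return r_ref * math.exp(
        (activation_energy_j_mol / R_GAS) * (1.0 / t_target - 1.0 / t_ref)
    )


def estimate_activation_energy(pairs: Sequence[Tuple[float, float]]) -> float:
    """Apparent activation energy [J mol^-1] from (resistance, temperature) pairs.

    Least-squares slope of ln r against 1/T_abs, multiplied by the gas
    constant. Needs at least two distinct temperatures.
    """
    if len(pairs) < 2:
        raise InsufficientDataError("need at least 2 (resistance, temperature) pairs")
    r = np.asarray([p[0] for p in pairs], dtype=float)
    t_c = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any(r <= 0):
        raise TranspirestError("resistances must be positive for the log fit")
    inv_t = 1.0 / (t_c + KELVIN_OFFSET)
    if np.ptp(inv_t) == 0:
        raise InsufficientDataError("all temperatures identical; slope undefined")
    slope = np.polyfit(inv_t, np.log(r), 1)[0]
    return float(slope * R_GAS)


def _estimate_rate(
    series: WeighingSeries, area_cm2: float, estimator: str
) -> Tuple[float, float]:
    """(E [mg cm^-2 h^-1], delta_t_h) from a weighing series.

    ``endpoint`` differences the first and last weighings; ``slope`` fits an
    ordinary-least-squares line to mass vs time, which suppresses
    quantization and handling noise on dense series.
    """
    t_h = (series.timestamps - series.timestamps[0]) / np.timedelta64(1, "h")
    t_h = np.asarray(t_h, dtype=float)
    mass_mg = series.net_mass_g * 1000.0
    delta_t_h = float(t_h[-1])
    if estimator == "endpoint":
        delta_fm_mg = float(mass_mg[0] - mass_mg[-1])
        return transpiration_rate(delta_fm_mg, area_cm2, delta_t_h), delta_t_h
    if estimator == "slope":
        slope_mg_per_h = float(np.polyfit(t_h, mass_mg, 1)[0])
        if slope_mg_per_h > 0:
            warnings.warn(
                "fitted mass trend is increasing: condensation or handling artefact",
                CondensationWarning,
                stacklevel=3,
            )
        return -slope_mg_per_h / area_cm2, delta_t_h
    raise TranspirestError(f"unknown estimator {estimator!r}")


def run_protocol(
    series: WeighingSeries,
    climate: ClimateLog,
    item: ProduceItem,
    config: ProtocolConfig,
) -> ResistanceResult:
    """End-to-end resistance determination for one weighing series.

    Steps: transpiration rate from the configured estimator; ambient vapour
    concentration from the time-weighted mean climate over the weighing
    window (one psychrometric evaluation of the means — a small-fluctuation
    approximation); intercellular concentration from the produce temperature
    and water activity; total resistance; protocol-specific partition;
    surface-state recovery.
    """
    assumptions = []
    if series.duration_h < config.min_duration_h:
        warnings.warn(
            f"{series.item_id}: series spans {series.duration_h:.1f} h, below the "
            f"recommended minimum of {config.min_duration_h:.0f} h for the "
            f"{config.protocol} protocol",
            AssumptionWarning,
            stacklevel=2,
        )

    temp_c, rh_pct, pbar = mean_climate(
        climate, series.timestamps[0], series.timestamps[-1]
    )
    if pbar is None:
        pbar = config.pressure_default_pa
        assumptions.append(f"pbar defaulted to {pbar} Pa (not logged)")
        logger.info("assumption: barometric pressure defaulted to %s Pa", pbar)

    area = resolve_area(item)
    E, delta_t_h = _estimate_rate(series, area, config.estimator)

    if item.produce_temperature_c is not None:
        t_produce = item.produce_temperature_c
        t_produce_source = "measured"
    else:
        t_produce = temp_c
        t_produce_source = "mean_air_temperature"
        assumptions.append("produce temperature defaulted to mean air temperature")
        logger.info(
            "assumption: produce temperature of %s set to mean air temperature "
            "%.3f degC", series.item_id, temp_c,
        )

    aw = item.water_activity if item.water_activity is not None else config.aw
    x_a = psychro.air_state(temp_c, rh_pct, pbar).x_vol
    x_p = psychro.intercellular_water_content(t_produce, aw, pbar)
    r_tot = total_resistance(E, x_p, x_a)

    if config.protocol == "free":
        r_B = config.rb_default_s_cm
        r_T = tissue_resistance(r_tot, r_B)
        assumptions.append(f"free-convection rB assumed {r_B} s cm^-1")
        logger.info("assumption: free-convection rB = %s s cm^-1", r_B)
    elif config.protocol in ("forced", "wetted"):
        r_B = 0.0
        r_T = r_tot
    elif config.protocol == "bulk":
        r_T = config.tissue_resistance_s_cm
        r_B = bulk_boundary_layer(r_tot, r_T)
    else:  # pragma: no cover - pydantic enforces the literal
        raise TranspirestError(f"unknown protocol {config.protocol!r}")

    surface_t = t_produce  # surface temperature when measured, else air mean
    try:
        x_ps, rh_surface = surface_conditions(E, r_B, x_a, surface_t, pbar)
    except SupersaturationError:
        # the surface cannot be wetter than the interior; clip to x_p
        x_ps = x_a + E * r_B / RESISTANCE_UNIT_FACTOR
        rh_surface = psychro.humidity_from_volume_content(min(x_ps, x_p), surface_t, pbar)

    return ResistanceResult(
        E=E,
        x_p=x_p,
        x_a=x_a,
        delta_x=x_p - x_a,
        r_tot=r_tot,
        r_T=r_T,
        r_B=r_B,
        x_pS=x_ps,
        rh_surface_pct=rh_surface,
        protocol=config.protocol,
        provenance={
            "item_id": series.item_id,
            "estimator": config.estimator,
            "interval_h": delta_t_h,
            "window_start": series.timestamps[0].isoformat(),
            "window_end": series.timestamps[-1].isoformat(),
            "mean_temp_c": temp_c,
            "mean_rh_pct": rh_pct,
            "pressure_pa": pbar,
            "area_cm2": area,
            "water_activity": aw,
            "produce_temperature_c": t_produce,
            "produce_temperature_source": t_produce_source,
            "surface_rh_temperature_source": t_produce_source,
            "assumptions": "; ".join(assumptions),
        },
    )

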