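"""Psychrometrics of humid air: forward and inverse moisture relations.

The forward chain maps measured air temperature ``Ta`` [deg C], relative
humidity ``rH`` [%] and barometric pressure ``pbar`` [Pa] to

* saturation vapour pressure ``psa`` [Pa],
* partial vapour pressure ``pda`` [Pa],
* mass-related water content ``xa`` [kg water / kg dry air],
* humid-air density ``rho_a`` [kg m^-3],
* volume-related water content ``xa* = xa * rho_a`` [g m^-3].

``xa*`` is the working currency of the resistance model: driving forces are
differences of volume-related water contents. The inverse solve recovers the
relative humidity that reproduces a given ``xa*`` at a given temperature,
which is how the humidity at a produce surface is obtained from the
surface vapour concentration.

All functions accept floats or numpy arrays and broadcast elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (
    EPSILON,
    KELVIN_OFFSET,
    PSAT_T_MAX_C,
    PSAT_T_MIN_C,
    R_AIR,
    R_WATER_VAPOUR,
    STANDARD_PRESSURE_PA,
)
from .errors import PsychroDomainError, SupersaturationError, TemperatureRangeError

__all__ = [
    "AirState",
    "saturation_vapour_pressure",
    "partial_pressure",
    "mass_water_content",
    "air_density",
    "volume_water_content",
    "air_state",
    "humidity_from_volume_content",
    "intercellular_water_content",
]


@dataclass(frozen=True)
class AirState:
    """One air condition with all derived psychrometric quantities.

    Attributes
    ----------
    temperature_c : float
        Air temperature Ta [deg C].
    relative_humidity_pct : float
        Relative humidity rH [%].
    pressure_pa : float
        Barometric pressure pbar [Pa].
    psat_pa : float
        Saturation vapour pressure psa at Ta [Pa].
    pvap_pa : float
        Partial pressure of water vapour pda [Pa].
    x_mass : float
        Mass-related water content xa [kg water / kg dry air].
    density : float
        Humid-air density rho_a [kg m^-3].
    x_vol : float
        Volume-related water content xa* [g water / m^3 air].
    """

    temperature_c: float
    relative_humidity_pct: float
    pressure_pa: float
    psat_pa: float
    pvap_pa: float
    x_mass: float
    density: float
    x_vol: float


def saturation_vapour_pressure(temperature_c):
    """Saturation vapour pressure over water [Pa].

    Rational-exponential approximation
    ``psa = exp[(6.4142801 + 0.0996709 Ta) / (1 + 0.004197225 Ta)]``,
    valid for -10 deg C <= Ta <= 50 deg C (the postharvest range); outside
    that window a :class:`TemperatureRangeError` is raised rather than
    extrapolating an empirical fit.
    """
    t = np.asarray(temperature_c, dtype=float)
    if np.any(t < PSAT_T_MIN_C) or np.any(t > PSAT_T_MAX_C):
        raise TemperatureRangeError(
            f"temperature {temperature_c!r} outside the validity window "
            f"[{PSAT_T_MIN_C}, {PSAT_T_MAX_C}] deg C of the saturation-pressure fit"
        )
    psa = np.exp((6.4142801 + 0.0996709 * t) / (1.0 + 0.004197225 * t))
    return float(psa) if np.isscalar(temperature_c) else psa


def partial_pressure(psat_pa, relative_humidity_pct):
    """Partial pressure of water vapour: ``pda = psa * rH / 100`` [Pa]."""
    rh = np.asarray(relative_humidity_pct, dtype=float)
    if np.any(rh < 0.0) or np.any(rh > 100.0):
        raise PsychroDomainError(
            f"relative humidity {relative_humidity_pct!r} % outside [0, 100]"
        )
    pda = np.asarray(psat_pa, dtype=float) * rh / 100.0
    return float(pda) if np.isscalar(relative_humidity_pct) and np.isscalar(psat_pa) else pda


def mass_water_content(pvap_pa, pressure_pa):
    """Mass-related water content ``xa = (Ra/Rwv) pda / (pbar - pda)`` [kg/kg]."""
    pda = np.asarray(pvap_pa, dtype=float)
    pbar = np.asarray(pressure_pa, dtype=float)
    if np.any(pda < 0.0):
        raise PsychroDomainError(f"negative vapour pressure {pvap_pa!r} Pa")
    if np.any(pda >= pbar):
        raise PsychroDomainError(
            f"vapour pressure {pvap_pa!r} Pa >= barometric pressure "
            f"{pressure_pa!r} Pa (unphysical)"
        )
    xa = EPSILON * pda / (pbar - pda)
    return float(xa) if np.isscalar(pvap_pa) and np.isscalar(pressure_pa) else xa


def air_density(x_mass, temperature_c, pressure_pa):
    """Humid-air density [kg m^-3].

    ``rho_a = (1 + xa) pbar / [(Ra + Rwv xa)(273.15 + Ta)]``; reduces to the
    dry-air ideal-gas density at ``xa = 0``.
    """
    xa = np.asarray(x_mass, dtype=float)
    t = np.asarray(temperature_c, dtype=float)
    if np.any(t <= -KELVIN_OFFSET):
        raise PsychroDomainError(
            f"absolute temperature non-positive at Ta = {temperature_c!r} deg C"
        )
    if np.any(xa < 0.0):
        raise PsychroDomainError(f"negative water content {x_mass!r}")
    rho = (
        (1.0 + xa)
        * np.asarray(pressure_pa, dtype=float)
        / ((R_AIR + R_WATER_VAPOUR * xa) * (KELVIN_OFFSET + t))
    )
    scalars = all(np.isscalar(v) for v in (x_mass, temperature_c, pressure_pa))
    return float(rho) if scalars else rho


def volume_water_content(x_mass, density):
    """Volume-related water content ``xa* = xa * rho_a``, returned in g m^-3."""
    xv = np.asarray(x_mass, dtype=float) * np.asarray(density, dtype=float) * 1000.0
    return float(xv) if np.isscalar(x_mass) and np.isscalar(density) else xv


def air_state(
    temperature_c: float,
    relative_humidity_pct: float,
    pressure_pa: float = STANDARD_PRESSURE_PA,
) -> AirState:
    """Evaluate the full forward psychrometric chain for one air condition."""
    psa = saturation_vapour_pressure(temperature_c)
    pda = partial_pressure(psa, relative_humidity_pct)
    xa = mass_water_content(pda, pressure_pa)
    rho = air_density(xa, temperature_c, pressure_pa)
    xv = volume_water_content(xa, rho)
    return AirState(
        temperature_c=float(temperature_c),
        relative_humidity_pct=float(relative_humidity_pct),
        pressure_pa=float(pressure_pa),
        psat_pa=psa,
        pvap_pa=pda,
        x_mass=xa,
        density=rho,
        x_vol=xv,
    )


def volume_water_content_chain(temperature_c, relative_humidity_pct, pressure_pa):
    """Vectorised xa* [g m^-3] from (Ta, rH, pbar); broadcasts over arrays."""
    psa = saturation_vapour_pressure(temperature_c)
    pda = partial_pressure(psa, relative_humidity_pct)
    xa = mass_water_content(pda, pressure_pa)
    rho = air_density(xa, temperature_c, pressure_pa)
    return volume_water_content(xa, rho)


def humidity_from_volume_content(
    x_vol: float,
    temperature_c: float,
    pressure_pa: float = STANDARD_PRESSURE_PA,
    *,
    rel_tol: float = 1e-9,
    max_iter: int = 100,
) -> float:
    """Invert the forward chain: relative humidity [%] from xa* [g m^-3].

    The mass-related content and the density both depend on the vapour
    pressure, so the inverse is obtained by fixed-point iteration on ``pda``:
    given a density estimate, ``xa = xa*/rho_a`` and
    ``pda = pbar xa / (eps + xa)``; the density is then refreshed from that
    ``pda``. Convergence is geometric (the density varies by <2 % over the
    humidity range) and takes well under ten iterations.

    Raises
    ------
    SupersaturationError
        If ``x_vol`` exceeds the saturated xa* at this temperature/pressure.
    """
    if x_vol < 0.0:
        raise PsychroDomainError(f"negative volume water content {x_vol!r} g m^-3")
    if x_vol == 0.0:
        return 0.0
    psa = saturation_vapour_pressure(temperature_c)
    x_sat = air_state(temperature_c, 100.0, pressure_pa).x_vol
    if x_vol > x_sat * (1.0 + 1e-9):
        raise SupersaturationError(
            f"x_vol = {x_vol:.6g} g m^-3 exceeds saturation "
            f"({x_sat:.6g} g m^-3) at {temperature_c} deg C, {pressure_pa} Pa"
        )
    x_kg = min(x_vol, x_sat) / 1000.0  # kg water per m^3
    rho = air_density(0.0, temperature_c, pressure_pa)
    pda = 0.0
    for _ in range(max_iter):
        xa = x_kg / rho
        pda_new = pressure_pa * xa / (EPSILON + xa)
        rho = air_density(
            mass_water_content(pda_new, pressure_pa), temperature_c, pressure_pa
        )
        if abs(pda_new - pda) <= rel_tol * max(abs(pda_new), 1.0):
            pda = pda_new
            break
        pda = pda_new
    else:  # pragma: no cover - never reached over the valid domain
        raise PsychroDomainError("inverse psychrometric solve did not converge")
    return min(100.0 * pda / psa, 100.0)


def intercellular_water_content(
    produce_temperature_c: float,
    water_activity: float = 0.985,
    pressure_pa: float = STANDARD_PRESSURE_PA,
) -> float:
    """Water-vapour concentration xp [g m^-3] of the produce-interior air.

    The intercellular air of fresh (non-wilted) produce is at, or very near,
    saturation; the water activity ``aw`` expresses the equilibrium relative
    humidity of the interior as a fraction, so xp is the xa* of air at the
    produce temperature and ``100 * aw`` % relative humidity.
    """
    if not 0.0 < water_activity <= 1.0:
        raise PsychroDomainError(f"water activity {water_activity!r} outside (0, 1]")
    return air_state(produce_temperature_c, 100.0 * water_activity, pressure_pa).x_vol
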