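"""Produce surface-area estimation from mass and simple dimensions.

Surface area is the denominator of every area-related transpiration rate,
but measuring it directly is destructive or tedious. The module evaluates
species-specific linear regressions of surface area on easily measured
predictors (fresh mass, length, diameters), calibrated on 18-20 samples per
species. A regression is only trusted inside its calibrated mass range;
outside it the value is still returned but a :class:`CalibrationRangeWarning`
is attached, because the fits are empirical and carry no extrapolation
guarantee.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence, Union

import yaml

from .errors import CalibrationRangeWarning, TranspirestError

__all__ = ["ProduceItem", "SPECIES", "load_regressions", "surface_area", "resolve_area"]

#: Predictor names accepted by the regressions, with units.
PREDICTOR_UNITS = {
    "mass_g": "g",
    "length_cm": "cm",
    "d1_mm": "mm",
    "d2_mm": "mm",
    "d3_mm": "mm",
}


def load_regressions() -> dict:
    """Load the versioned regression-coefficient table shipped with the package."""
    text = (
        resources.files("transpirest").joinpath("data/surface_area_regressions.yaml")
    ).read_text(encoding="utf-8")
    return yaml.safe_load(text)


_TABLE = load_regressions()["species"]

#: Species with a calibrated surface-area regression.
SPECIES = tuple(_TABLE)


def surface_area(
    species: str,
    mass_g: Optional[float] = None,
    length_cm: Optional[float] = None,
    d1_mm: Optional[float] = None,
    d2_mm: Optional[float] = None,
    d3_mm: Union[float, Sequence[float], None] = None,
) -> float:
    """Surface area A [cm^2] from the species' calibrated regression.

    Parameters
    ----------
    species : str
        One of :data:`SPECIES`.
    mass_g : float, optional
        Fresh mass m [g].
    length_cm : float, optional
        Length L [cm] (asparagus, carrot).
    d1_mm : float, optional
        Mean diameter over the length [mm] (carrot; >= 3 measurements).
    d2_mm : float, optional
        Height diameter [mm] (radish tuber).
    d3_mm : float or pair of floats, optional
        Transverse diameter [mm], measured twice with a 90-degree rotation;
        a pair is averaged before use.

    Raises
    ------
    TranspirestError
        Unknown species or a required predictor missing.

    Warns
    -----
    CalibrationRangeWarning
        If the supplied mass lies outside the species' calibrated range.
    """
    try:
        row = _TABLE[species]
    except KeyError:
        raise TranspirestError(
            f"unknown species {species!r}; expected one of {', '.join(SPECIES)}"
        ) from None

    if d3_mm is not None and not isinstance(d3_mm, (int, float)):
        d3_mm = float(sum(d3_mm)) / len(d3_mm)
    supplied: Mapping[str, Optional[float]] = {
        "mass_g": mass_g,
        "length_cm": length_cm,
        "d1_mm": d1_mm,
        "d2_mm": d2_mm,
        "d3_mm": d3_mm,
    }

    area = float(row["intercept"])
    for predictor, coefficient in row["terms"].items():
        value = supplied[predictor]
        if value is None:
            raise TranspirestError(
                f"{species} surface-area regression requires "
                f"{predictor} [{PREDICTOR_UNITS[predictor]}]"
            )
        area += float(coefficient) * float(value)

    lo, hi = row["mass_range_g"]
    if mass_g is not None and not lo <= mass_g <= hi:
        warnings.warn(
            f"mass {mass_g} g outside the calibrated range [{lo}, {hi}] g "
            f"for {species}; the regression is extrapolating",
            CalibrationRangeWarning,
            stacklevel=2,
        )
    return area


@dataclass
class ProduceItem:
    """One produce item (or one bulk container of identical produce).

    ``area_cm2``, if supplied, is a measured surface area and always takes
    precedence over the regression estimate. ``produce_temperature_c`` is the
    (ideally infrared-measured) produce temperature; when absent the mean air
    temperature is substituted downstream, with a warning.
    """

    item_id: str
    species: Optional[str] = None
    mass_g: Optional[float] = None
    length_cm: Optional[float] = None
    d1_mm: Optional[float] = None
    d2_mm: Optional[float] = None
    d3_mm: Optional[float] = None
    area_cm2: Optional[float] = None
    water_activity: float = 0.985
    produce_temperature_c: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mass_g is not None and self.mass_g <= 0:
            raise TranspirestError(f"{self.item_id}: mass must be positive")
        if self.area_cm2 is not None and self.area_cm2 <= 0:
            raise TranspirestError(f"{self.item_id}: area must be positive")
        if not 0.0 < self.water_activity <= 1.0:
            raise TranspirestError(
                f"{self.item_id}: water activity {self.water_activity} outside (0, 1]"
            )


def resolve_area(item: ProduceItem) -> float:
    """Surface area for an item: measured value if present, else regression."""
    if item.area_cm2 is not None:
        return item.area_cm2
    if item.species is None:
        raise TranspirestError(
            f"{item.item_id}: no measured area and no species for the regression"
        )
    return surface_area(
        item.species,
        mass_g=item.mass_g,
        length_cm=item.length_cm,
        d1_mm=item.d1_mm,
        d2_mm=item.d2_mm,
        d3_mm=item.d3_mm,
    )
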