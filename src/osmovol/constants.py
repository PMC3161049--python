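"""Physical constants and shared parameter types for osmotic volumetry.

The unit system is the one conventional in cryobiology volumetry work:
lengths in µm, areas in µm², volumes in µm³, time in minutes, pressure in
atm, temperature in Kelvin, and amounts of solute in osmoles (Osm).  The
gas constant in this system is 8.21e13 µm³·atm/(mol·K) (0.08206 L·atm/(mol·K)
rescaled by the 1e15 µm³-per-litre factor).  Osmolality (Osm/kg water) is
treated interchangeably with osmolarity (Osm/L), the usual approximation for
dilute physiological media.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from importlib import resources

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "ISOTONIC_OSMOLALITY",
    "Condition",
    "OsmoticCellParams",
    "load_reference_params",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Gas constants and temperature offset in the µm/min/atm unit system.

    Attributes
    ----------
    R_gas : float
        Gas constant, µm³·atm/(mol·K).
    R_cal : float
        Gas constant, cal/(mol·K), used for activation energies.
    kelvin_offset : float
        Additive °C → K conversion.
    """

    R_gas: float = 8.21e13
    R_cal: float = 1.987
    kelvin_offset: float = 273.15


CONSTANTS = PhysicalConstants()

#: Osmolality of isotonic Tyrode's buffered saline, Osm/kg.
ISOTONIC_OSMOLALITY = 0.308


@dataclass(frozen=True)
class Condition:
    """An experimental exposure: external osmolality and temperature.

    ``direction`` is derived relative to the isotonic osmolality:
    hypotonic media drive water in (swelling), hypertonic media drive
    water out (shrinking).
    """

    osmolality: float  # Osm/kg
    temperature_c: float  # °C
    isotonic_osmolality: float = ISOTONIC_OSMOLALITY

    def __post_init__(self) -> None:
        if self.osmolality <= 0:
            raise ValueError(f"osmolality must be positive, got {self.osmolality}")
        if not -5.0 <= self.temperature_c <= 45.0:
            raise ValueError(
                f"temperature_c {self.temperature_c} outside plausible range [-5, 45]"
            )

    @property
    def direction(self) -> str:
        if math.isclose(self.osmolality, self.isotonic_osmolality, rel_tol=1e-6):
            return "isotonic"
        return "hypotonic" if self.osmolality < self.isotonic_osmolality else "hypertonic"

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + CONSTANTS.kelvin_offset

    def label(self) -> str:
        return f"{self.osmolality * 1000:.0f}mOsm_{self.temperature_c:g}C"


@dataclass(frozen=True)
class OsmoticCellParams:
    """Per-condition physical state of an (idealised, spherical) cell.

    Attributes
    ----------
    V_c_iso : float
        Isotonic cell volume, µm³.
    V_b : float
        Non-osmotic volume (solids + bound water), µm³.
    V_iso : float
        Isotonic water volume, ``V_c_iso - V_b``, µm³.
    A : float
        Membrane surface area (held constant during volume excursions), µm².
    N : float
        Intracellular osmoles of non-permeating solute, Osm.
    M_iso : float
        Isotonic osmolality, Osm/kg.
    """

    V_c_iso: float
    V_b: float
    V_iso: float
    A: float
    N: float
    M_iso: float = ISOTONIC_OSMOLALITY

    def __post_init__(self) -> None:
        if self.V_iso <= 0:
            raise ValueError("isotonic water volume V_iso must be positive")
        if self.A <= 0:
            raise ValueError("surface area A must be positive")
        if abs(self.V_iso - (self.V_c_iso - self.V_b)) > 1e-6 * max(self.V_c_iso, 1.0):
            raise ValueError("V_iso must equal V_c_iso - V_b")

    @classmethod
    def from_isotonic(
        cls, V_c_iso: float, V_b: float, M_iso: float = ISOTONIC_OSMOLALITY
    ) -> "OsmoticCellParams":
        """Derive the full parameter set from isotonic volume and V_b.

        Surface area is that of the sphere with the isotonic volume; the
        osmole content follows from the isotonic osmolality and water volume
        (volume converted to litres).
        """
        from . import geometry

        V_iso = geometry.water_volume(V_c_iso, V_b)
        A = geometry.sphere_area_from_volume(V_c_iso)
        N = geometry.osmoles(M_iso, V_iso)
        return cls(V_c_iso=V_c_iso, V_b=V_b, V_iso=V_iso, A=A, N=N, M_iso=M_iso)

    def to_dict(self) -> dict:
        return asdict(self)


def load_reference_params() -> dict:
    """Load the packaged per-temperature reference parameter table (JSON).

    Returns a mapping from temperature label (``"0"``, ``"10"``, ``"22"``,
    °C) to the measured isotonic volumes and derived quantities for COS-7
    cells, plus the constants block.
    """
    with resources.files("osmovol.data").joinpath("reference_params.json").open() as fh:
        return json.load(fh)
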