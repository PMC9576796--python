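"""Headspace/liquid gas partitioning for sealed batch vessels.

Converts between measured headspace partial pressures (or mole fractions) and
total molar inventories across the headspace and the liquid phase.  Headspace
amounts follow the ideal gas law; dissolved amounts follow Henry's law at a
constant reference-temperature constant.  Both assumptions are appropriate for
the operating envelope of the experiments emulated here (<= 1.5 atm, ~295 K).

The module also implements the acidified-CO2 measurement contract: acidifying
a subsample converts all dissolved inorganic carbon to CO2, which then
equilibrates with the vial headspace, so the total CO2 of the original sample
is the headspace amount plus the Henry-law dissolved amount at the
equilibrated partial pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "R_L_ATM",
    "DEFAULT_HENRY",
    "GasError",
    "VesselConfig",
    "HenryConstant",
    "GasInventory",
    "headspace_moles",
    "dissolved_moles",
    "total_inventory",
    "partial_pressure",
    "total_co2_after_acidification",
]

#: Ideal gas constant, L atm mol-1 K-1.
R_L_ATM = 0.082057


class GasError(ValueError):
    """Invalid vessel configuration or gas quantity."""


@dataclass(frozen=True)
class VesselConfig:
    """Geometry and conditions of a sealed vessel.

    Volumes in litres, temperature in kelvin, total pressure in atm.  The
    defaults are a typical batch vessel: 650 mL with 500 mL of culture.
    """

    v_liquid: float = 0.5
    v_headspace: float = 0.15
    temperature: float = 295.15
    total_pressure: float = 1.0

    def __post_init__(self) -> None:
        if self.v_liquid <= 0 or self.v_headspace <= 0:
            raise GasError("vessel volumes must be positive")
        if not 0.5 <= self.total_pressure <= 3.0:
            raise GasError(
                f"total pressure {self.total_pressure} atm outside [0.5, 3] atm"
            )
        if self.temperature <= 0:
            raise GasError("temperature must be positive (kelvin)")

    @property
    def v_total(self) -> float:
        return self.v_liquid + self.v_headspace

    @classmethod
    def from_total(
        cls,
        v_total: float,
        v_liquid: float,
        temperature: float = 295.15,
        total_pressure: float = 1.0,
    ) -> "VesselConfig":
        if v_total - v_liquid <= 1e-9:
            raise GasError("v_total must exceed v_liquid")
        return cls(v_liquid, v_total - v_liquid, temperature, total_pressure)


@dataclass(frozen=True)
class HenryConstant:
    """Henry solubility of a gas, mol L-1 atm-1, at the reference temperature."""

    species: str
    kH: float

    def __post_init__(self) -> None:
        if self.kH <= 0:
            raise GasError(f"Henry constant for {self.species!r} must be positive")


#: Default 25 degC Henry constants, mol L-1 atm-1.
DEFAULT_HENRY = {
    "C3H8": HenryConstant("C3H8", 1.4e-3),
    "CO2": HenryConstant("CO2", 3.4e-2),
    "N2": HenryConstant("N2", 6.5e-4),
}


@dataclass(frozen=True)
class GasInventory:
    """Molar inventory of one species split across headspace and liquid."""

    species: str
    headspace_moles: float
    dissolved_moles: float

    def __post_init__(self) -> None:
        if self.headspace_moles < 0 or self.dissolved_moles < 0:
            raise GasError("inventory amounts must be non-negative")

    @property
    def total_moles(self) -> float:
        return self.headspace_moles + self.dissolved_moles


def headspace_moles(partial_pressure: float, config: VesselConfig) -> float:
    """Moles of gas in the headspace at ``partial_pressure`` (ideal gas law)."""
    if partial_pressure < 0:
        raise GasError("partial pressure must be non-negative")
    return partial_pressure * config.v_headspace / (R_L_ATM * config.temperature)


def dissolved_moles(
    partial_pressure: float, kH: HenryConstant, config: VesselConfig
) -> float:
    """Moles dissolved in the liquid at equilibrium (Henry's law)."""
    if partial_pressure < 0:
        raise GasError("partial pressure must be non-negative")
    return kH.kH * partial_pressure * config.v_liquid


def total_inventory(
    species: str,
    partial_pressure: float,
    config: VesselConfig,
    kH: HenryConstant | None = None,
    include_dissolved: bool = True,
) -> GasInventory:
    """Full inventory at a headspace partial pressure.

    ``include_dissolved=False`` gives the headspace-only reading, matching
    workflows that report headspace amounts without a dissolved correction.
    """
    if kH is None:
        kH = DEFAULT_HENRY.get(species)
    head = headspace_moles(partial_pressure, config)
    if include_dissolved:
        if kH is None:
            raise GasError(f"no Henry constant known for species {species!r}")
        diss = dissolved_moles(partial_pressure, kH, config)
    else:
        diss = 0.0
    return GasInventory(species, head, diss)


def partial_pressure(
    total_moles: float,
    config: VesselConfig,
    kH: HenryConstant | None = None,
) -> float:
    """Equilibrium partial pressure holding ``total_moles`` in the vessel.

    Inverse of :func:`total_inventory`; pass ``kH=None`` for an insoluble-gas
    (headspace-only) inversion.
    """
    if total_moles < 0:
        raise GasError("total moles must be non-negative")
    capacity = config.v_headspace / (R_L_ATM * config.temperature)
    if kH is not None:
        capacity += kH.kH * config.v_liquid
    return total_moles / capacity


def total_co2_after_acidification(
    headspace_fraction: float,
    config: VesselConfig,
    kH_co2: HenryConstant | None = None,
) -> float:
    """Total CO2 (mol) in an acidified, headspace-equilibrated subsample.

    Acidification converts all dissolved inorganic carbon to CO2; after
    equilibration the measured headspace mole fraction together with the vial
    geometry fixes the original sample's total CO2 as headspace amount plus
    Henry-law dissolved amount at the equilibrated partial pressure.
    """
    if not 0.0 <= headspace_fraction <= 1.0:
        raise GasError("headspace mole fraction must lie in [0, 1]")
    if kH_co2 is None:
        kH_co2 = DEFAULT_HENRY["CO2"]
    p_co2 = headspace_fraction * config.total_pressure
    return headspace_moles(p_co2, config) + dissolved_moles(p_co2, kH_co2, config)
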