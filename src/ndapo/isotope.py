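"""Stable-isotope tracer accounting for 13C/15N labelling experiments.

Covers the bookkeeping used when a batch culture is fed ~8 atom% 13C-propane
and ~1 atom% 15N-nitrate:

* labelled-pool arithmetic (:class:`IsotopePool`);
* the nitrite heavy-atom fraction by difference, from the measured combined
  nitrate+nitrite pool and the nitrate-only pool (mixing equation);
* N2 isotopologue (28/29/30) fractions under binomial random pairing from a
  single pool of atom fraction p, and its inverse;
* label consumption/production ratios (e.g. 13CO2 produced per 13C-propane
  consumed) alongside the reaction-derived theoretical ratio.

No isotope fractionation is modelled: light and heavy isotopologues are
assumed to react with identical kinetics, adequate for tracer fractions of a
few atom percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .chem_core import RedoxReaction

__all__ = [
    "IsotopeError",
    "InconsistentMeasurementError",
    "IsotopePool",
    "IsotopologueDistribution",
    "nitrite_heavy_fraction",
    "pair_n2",
    "unpair_n2",
    "label_consumption_ratio",
    "complete_oxidation_ratio",
]


class IsotopeError(ValueError):
    """Invalid isotope pool or distribution."""


class InconsistentMeasurementError(IsotopeError):
    """Pool measurements are mutually inconsistent (fraction outside [0, 1])."""


@dataclass(frozen=True)
class IsotopePool:
    """A chemical pool with a total amount and a heavy-atom fraction.

    ``total`` is in any consistent amount unit (conventionally umol);
    ``heavy_fraction`` is an atom fraction in [0, 1] (never a percentage).
    """

    species: str
    total: float
    heavy_fraction: float

    def __post_init__(self) -> None:
        if self.total < 0:
            raise IsotopeError(f"pool {self.species!r}: total must be >= 0")
        if not 0.0 <= self.heavy_fraction <= 1.0:
            raise IsotopeError(
                f"pool {self.species!r}: heavy fraction {self.heavy_fraction} "
                "outside [0, 1]"
            )

    @property
    def labelled(self) -> float:
        """Amount of heavy-labelled substance (total x heavy fraction)."""
        return self.total * self.heavy_fraction

    def merge(self, other: "IsotopePool") -> "IsotopePool":
        """Pool obtained by combining two pools of the same species."""
        total = self.total + other.total
        heavy = (self.labelled + other.labelled) / total if total > 0 else 0.0
        return IsotopePool(self.species, total, heavy)


def nitrite_heavy_fraction(
    combined: IsotopePool,
    nitrate: IsotopePool,
    tol: float = 1e-6,
) -> float:
    """Nitrite 15N atom fraction by difference.

    The measurement workflow determines the heavy fraction of the combined
    nitrate+nitrite pool, then removes nitrite and re-measures nitrate alone.
    Conservation of labelled atoms,

        f_comb * A_comb = f_NO3 * A_NO3 + f_NO2 * A_NO2,

    is solved for f_NO2 with A_NO2 = A_comb - A_NO3.  Results within ``tol``
    outside [0, 1] are clamped (measurement noise); larger excursions raise
    :class:`InconsistentMeasurementError`.
    """
    a_no2 = combined.total - nitrate.total
    if a_no2 <= 0:
        raise IsotopeError(
            "nitrite amount (combined minus nitrate) must be positive, "
            f"got {a_no2}"
        )
    f = (combined.labelled - nitrate.labelled) / a_no2
    if f < -tol or f > 1.0 + tol:
        raise InconsistentMeasurementError(
            f"derived nitrite heavy fraction {f} outside [0, 1] beyond tolerance"
        )
    return min(max(f, 0.0), 1.0)


@dataclass(frozen=True)
class IsotopologueDistribution:
    """Fractions of N2 occurring as 28N2 / 29N2 / 30N2 (must sum to 1)."""

    f28: float
    f29: float
    f30: float

    def __post_init__(self) -> None:
        for name, f in (("f28", self.f28), ("f29", self.f29), ("f30", self.f30)):
            if not 0.0 <= f <= 1.0:
                raise IsotopeError(f"{name} = {f} outside [0, 1]")
        if abs(self.f28 + self.f29 + self.f30 - 1.0) > 1e-12:
            raise IsotopeError(
                f"isotopologue fractions sum to {self.f28 + self.f29 + self.f30}, not 1"
            )


def pair_n2(p: float) -> IsotopologueDistribution:
    """N2 isotopologue fractions from random pairing of a pool at fraction p.

    Binomial pairing: f28 = (1-p)^2, f29 = 2p(1-p), f30 = p^2.  This is the
    standard isotope-pairing assumption for denitrification drawing both N
    atoms from a single well-mixed (nitrite) pool.
    """
    if not 0.0 <= p <= 1.0:
        raise IsotopeError(f"atom fraction {p} outside [0, 1]")
    f30 = p * p
    f29 = 2.0 * p * (1.0 - p)
    f28 = max(1.0 - f29 - f30, 0.0)  # exact complement, avoids drift
    return IsotopologueDistribution(f28, f29, f30)


def unpair_n2(dist: IsotopologueDistribution) -> float:
    """Atom fraction p from an isotopologue distribution.

    ``p = f29/2 + f30`` counts heavy atoms per atom; it is the exact inverse
    of :func:`pair_n2` for binomial distributions and remains the heavy-atom
    fraction even for non-binomial ones.
    """
    return dist.f29 / 2.0 + dist.f30


def label_consumption_ratio(produced: float, consumed: float) -> float:
    """Labelled product per labelled substrate consumed (e.g. 13CO2/13C3H8)."""
    if consumed <= 0:
        raise IsotopeError("consumed labelled amount must be positive")
    if produced < 0:
        raise IsotopeError("produced labelled amount must be non-negative")
    return produced / consumed


def complete_oxidation_ratio(
    reaction: RedoxReaction, product: str = "CO2"
) -> Fraction:
    """Theoretical product-per-reference stoichiometric ratio of a reaction.

    For complete propane oxidation this is 3 (CO2 per propane); reported
    alongside measured label ratios to expose any shortfall (e.g. carbon
    diverted to biomass).
    """
    ref = reaction.reference_species
    if ref is None:
        raise IsotopeError("reaction has no reference species")
    coeff = reaction.coefficient(product)
    if coeff <= 0:
        raise IsotopeError(f"{product!r} is not a product of the reaction")
    return coeff / abs(reaction.coefficient(ref))
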