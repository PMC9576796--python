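"""Chemical species, redox reactions and biochemical-standard thermodynamics.

This module provides the stoichiometric backbone for analysing anaerobic
propane oxidation coupled to nitrate reduction: exact (rational-arithmetic)
element and charge balancing of redox reactions, mean oxidation states,
electron equivalents for N and C redox couples, and Gibbs free-energy changes
at the biochemical standard state (25 degC, unit activities, pH 7), written
DeltaG-zero-prime.

The convention for DeltaG-zero-prime follows standard microbial
bioenergetics: standard formation energies are summed over the signed
stoichiometry and the proton is moved from unit activity to pH 7 through an
activity correction of nu(H+) * R*T*ln(10^-pH) (about -39.9 kJ per mole of
proton consumed at 25 degC). Results are normalised per mole of a designated
reference species, e.g. "kJ per mol propane".

Stoichiometry and oxidation states use :class:`fractions.Fraction`
throughout, so balance residuals are exactly zero for balanced reactions;
floating point enters only when energies are evaluated.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Mapping, Union

import yaml

__all__ = [
    "GAS_CONSTANT_KJ",
    "STANDARD_TEMPERATURE",
    "PHASES",
    "ChemError",
    "UnknownSpeciesError",
    "UnbalancedReactionError",
    "ChemSpecies",
    "RedoxReaction",
    "RedoxCouple",
    "ThermoTable",
    "ReactionLibrary",
    "parse_formula",
    "parse_equation",
    "oxidation_state",
    "electron_equivalents",
    "electron_transfer",
    "check_balance",
    "delta_g_prime",
    "default_library",
]

#: Molar gas constant, kJ mol-1 K-1.
GAS_CONSTANT_KJ = 0.0083144626

#: Biochemical standard temperature, K.
STANDARD_TEMPERATURE = 298.15

#: Allowed phases for a species.
PHASES = ("gas", "aqueous", "liquid-water")


class ChemError(ValueError):
    """Base error for stoichiometric/thermodynamic configuration problems."""


class UnknownSpeciesError(ChemError):
    """A reaction references a species that is not defined."""


class UnbalancedReactionError(ChemError):
    """An operation that requires a balanced reaction received one that is not."""


_ELEMENT_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a plain molecular formula (no charge) into element counts.

    ``"C3H8" -> {"C": 3, "H": 8}``.  Only flat formulas are supported; no
    parentheses, hydrates or isotope markers.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _ELEMENT_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ChemError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        element = m.group(1)
        n = int(m.group(2) or 1)
        counts[element] = counts.get(element, 0) + n
    if pos != len(formula) or not counts:
        raise ChemError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class ChemSpecies:
    """A chemical species with composition, charge, phase and DeltaGf-zero.

    Parameters
    ----------
    name:
        Identifier used in reactions, e.g. ``"NO3-"``. The trailing charge
        token is purely part of the name; composition and charge are explicit.
    elements:
        Element -> atom count, all counts >= 1.
    charge:
        Net charge in elementary units.
    phase:
        One of ``"gas"``, ``"aqueous"``, ``"liquid-water"``.
    gibbs_formation:
        Standard Gibbs free energy of formation at 25 degC, kJ/mol, or None
        when the species is used for stoichiometry only.
    """

    name: str
    elements: Mapping[str, int]
    charge: int = 0
    phase: str = "aqueous"
    gibbs_formation: float | None = None

    def __post_init__(self) -> None:
        if not self.elements:
            raise ChemError(f"species {self.name!r} has no elements")
        for el, n in self.elements.items():
            if int(n) < 1:
                raise ChemError(f"species {self.name!r}: count for {el} must be >= 1")
        if self.phase not in PHASES:
            raise ChemError(
                f"species {self.name!r}: phase {self.phase!r} not one of {PHASES}"
            )

    @classmethod
    def from_formula(
        cls,
        name: str,
        formula: str,
        charge: int = 0,
        phase: str = "aqueous",
        gibbs_formation: float | None = None,
    ) -> "ChemSpecies":
        return cls(name, parse_formula(formula), charge, phase, gibbs_formation)


Coefficient = Union[int, float, str, Fraction]


def _as_fraction(value: Coefficient) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, float):
        # decimal coefficients like 2.5 are exact in the inputs we accept
        return Fraction(str(value))
    return Fraction(value)


@dataclass(frozen=True)
class RedoxReaction:
    """A redox reaction as a signed stoichiometric map.

    Reactants carry negative coefficients, products positive ones.  The
    ``reference_species`` names the species energies are normalised to
    ("per mole of propane").  Coefficients are exact rationals.
    """

    stoich: Mapping[str, Fraction]
    reference_species: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        frozen = {sp: _as_fraction(c) for sp, c in self.stoich.items() if c != 0}
        object.__setattr__(self, "stoich", frozen)
        if frozen:
            signs = {c > 0 for c in frozen.values()}
            if len(signs) != 2:
                raise ChemError(
                    f"reaction {self.name or self.stoich!r} needs at least one "
                    "reactant (negative) and one product (positive) coefficient"
                )
            if self.reference_species is not None and self.reference_species not in frozen:
                raise ChemError(
                    f"reference species {self.reference_species!r} not in reaction"
                )

    def coefficient(self, species: str) -> Fraction:
        return self.stoich.get(species, Fraction(0))

    @property
    def reactants(self) -> dict[str, Fraction]:
        return {sp: -c for sp, c in self.stoich.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {sp: c for sp, c in self.stoich.items() if c > 0}

    def scaled(self, k: Coefficient) -> "RedoxReaction":
        """Return the reaction with every coefficient multiplied by ``k > 0``."""
        k = _as_fraction(k)
        if k <= 0:
            raise ChemError("scale factor must be positive")
        return RedoxReaction(
            {sp: c * k for sp, c in self.stoich.items()},
            self.reference_species,
            self.name,
        )

    def __add__(self, other: "RedoxReaction") -> "RedoxReaction":
        combined: dict[str, Fraction] = dict(self.stoich)
        for sp, c in other.stoich.items():
            combined[sp] = combined.get(sp, Fraction(0)) + c
        return RedoxReaction(combined, self.reference_species, name="")

    @classmethod
    def empty(cls) -> "RedoxReaction":
        """The degenerate reaction with no species (DeltaG identically 0)."""
        return cls({}, None, "empty")

    @classmethod
    def from_equation(
        cls, equation: str, reference_species: str | None = None, name: str = ""
    ) -> "RedoxReaction":
        stoich = parse_equation(equation)
        if reference_species is None:
            # first reactant in written order
            reference_species = next(sp for sp, c in stoich.items() if c < 0)
        return cls(stoich, reference_species, name)


_ARROWS = ("->", "→", "=")


def parse_equation(equation: str) -> dict[str, Fraction]:
    """Parse ``"C3H8 + 10 NO3- -> 10 NO2- + 3 CO2 + 4 H2O"`` into a signed map.

    Terms are separated by ``+`` surrounded by whitespace, so species names may
    themselves end in charge tokens (``NO3-``, ``NH4+``, ``SO42-``).
    Coefficients may be integers, decimals (``2.5``) or fractions (``5/2``).
    """
    for arrow in _ARROWS:
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            break
    else:
        raise ChemError(f"no reaction arrow in equation {equation!r}")

    stoich: dict[str, Fraction] = {}

    def consume(side: str, sign: int) -> None:
        for term in re.split(r"\s\+\s", side.strip()):
            term = term.strip()
            if not term:
                raise ChemError(f"empty term in equation {equation!r}")
            parts = term.split()
            if len(parts) == 1:
                coeff, species = Fraction(1), parts[0]
            elif len(parts) == 2:
                try:
                    coeff = _as_fraction(parts[0])
                except ValueError as exc:
                    raise ChemError(
                        f"bad coefficient {parts[0]!r} in {equation!r}"
                    ) from exc
                species = parts[1]
            else:
                raise ChemError(f"cannot parse term {term!r} in {equation!r}")
            if coeff <= 0:
                raise ChemError(f"coefficient must be positive in term {term!r}")
            stoich[species] = stoich.get(species, Fraction(0)) + sign * coeff

    consume(left, -1)
    consume(right, +1)
    return stoich


# ---------------------------------------------------------------------------
# oxidation states and electron equivalents

#: Fixed mean oxidation states used for closure (standard bookkeeping rules).
_FIXED_STATES = {"O": Fraction(-2), "H": Fraction(1)}


def oxidation_state(species: ChemSpecies, element: str) -> Fraction:
    """Mean oxidation state of ``element`` in ``species``, exact rational.

    Uses the standard rules O = -2 and H = +1 (single-element species fall
    back to charge/atoms) and closes the remaining charge on the requested
    element.  Raises :class:`ChemError` if the element is absent or another
    element without a fixed rule blocks closure.
    """
    if element not in species.elements:
        raise ChemError(f"element {element!r} not present in species {species.name!r}")
    if len(species.elements) == 1:
        return Fraction(species.charge, species.elements[element])
    assigned = Fraction(0)
    for el, n in species.elements.items():
        if el == element:
            continue
        if el not in _FIXED_STATES:
            raise ChemError(
                f"cannot assign oxidation state in {species.name!r}: no rule for {el!r}"
            )
        assigned += _FIXED_STATES[el] * n
    return Fraction(species.charge - assigned, species.elements[element])


@dataclass(frozen=True)
class RedoxCouple:
    """A transformation of one species into another along a redox element.

    ``electron_equivalents`` gives the magnitude of electrons transferred per
    mole of ``from_species``; :func:`electron_transfer` gives the signed flow
    (positive = electrons released, i.e. the species is oxidised).
    """

    from_species: str
    to_species: str
    element: str


def electron_transfer(
    couple: RedoxCouple,
    registry: Mapping[str, ChemSpecies],
    atoms: int | None = None,
) -> Fraction:
    """Signed electrons per mole of ``from_species`` (positive = released)."""
    try:
        sp_from = registry[couple.from_species]
        sp_to = registry[couple.to_species]
    except KeyError as exc:
        raise UnknownSpeciesError(f"species {exc.args[0]!r} is not defined") from exc
    os_from = oxidation_state(sp_from, couple.element)
    os_to = oxidation_state(sp_to, couple.element)
    if atoms is None:
        atoms = sp_from.elements[couple.element]
    return (os_to - os_from) * atoms


def electron_equivalents(
    couple: RedoxCouple,
    registry: Mapping[str, ChemSpecies],
    atoms: int | None = None,
) -> Fraction:
    """Electrons transferred per mole of ``from_species``, as a magnitude.

    Computed as \\|delta oxidation state\\| x atom count of the redox element.
    Example: C3H8 -> CO2 over carbon gives \\|4 - (-8/3)\\| x 3 = 20.
    """
    return abs(electron_transfer(couple, registry, atoms))


# ---------------------------------------------------------------------------
# balancing

@dataclass(frozen=True)
class BalanceCheck:
    """Element and charge residuals of a reaction (exactly zero iff balanced)."""

    element_residuals: Mapping[str, Fraction]
    charge_residual: Fraction

    @property
    def balanced(self) -> bool:
        return self.charge_residual == 0 and all(
            r == 0 for r in self.element_residuals.values()
        )


def check_balance(
    reaction: RedoxReaction, registry: Mapping[str, ChemSpecies]
) -> BalanceCheck:
    """Residual per element (sum coeff x count) and total charge residual."""
    element_residuals: dict[str, Fraction] = {}
    charge = Fraction(0)
    for sp_name, coeff in reaction.stoich.items():
        try:
            sp = registry[sp_name]
        except KeyError:
            raise UnknownSpeciesError(
                f"species {sp_name!r} in reaction {reaction.name or '<ad hoc>'} "
                "is not defined"
            ) from None
        for el, n in sp.elements.items():
            element_residuals[el] = element_residuals.get(el, Fraction(0)) + coeff * n
        charge += coeff * sp.charge
    return BalanceCheck(element_residuals, charge)


# ---------------------------------------------------------------------------
# thermodynamics

@dataclass
class ThermoTable:
    """Per-species standard Gibbs formation energies plus evaluation constants.

    ``species`` maps name -> :class:`ChemSpecies` (with ``gibbs_formation``
    set for anything whose energy will be evaluated).  The table is plain
    data: users may swap any entry, e.g. the nitrate value (see the packaged
    library for the documented alternative).
    """

    species: dict[str, ChemSpecies]
    temperature: float = STANDARD_TEMPERATURE
    gas_constant: float = GAS_CONSTANT_KJ

    def dgf(self, name: str) -> float:
        try:
            sp = self.species[name]
        except KeyError:
            raise UnknownSpeciesError(f"species {name!r} is not in the table") from None
        if sp.gibbs_formation is None:
            raise UnknownSpeciesError(f"species {name!r} has no Gibbs formation energy")
        return sp.gibbs_formation


def delta_g_prime(
    reaction: RedoxReaction,
    table: ThermoTable,
    pH: float = 7.0,
    temperature: float | None = None,
) -> float:
    """DeltaG-zero-prime of ``reaction``, kJ per mole of its reference species.

    ``sum(coeff x DeltaGf) + nu(H+) x R*T*ln(10^-pH)``, divided by the
    absolute reference-species coefficient.  The proton's formation energy is
    zero at unit activity; its activity correction is the only pH term, so the
    biochemical standard state is obtained exactly as in standard microbial
    bioenergetics practice.

    Raises :class:`UnbalancedReactionError` for unbalanced input and
    :class:`UnknownSpeciesError` when a species or its energy is missing.
    """
    if not reaction.stoich:
        return 0.0
    chk = check_balance(reaction, table.species)
    if not chk.balanced:
        bad = {el: str(r) for el, r in chk.element_residuals.items() if r != 0}
        raise UnbalancedReactionError(
            f"reaction {reaction.name or '<ad hoc>'} is not balanced: "
            f"element residuals {bad}, charge residual {chk.charge_residual}"
        )
    T = table.temperature if temperature is None else temperature
    dg = sum(float(c) * table.dgf(sp) for sp, c in reaction.stoich.items())
    nu_h = float(reaction.coefficient("H+"))
    if nu_h:
        dg += nu_h * table.gas_constant * T * math.log(10.0 ** (-pH))
    if reaction.reference_species is None:
        raise ChemError("reaction has no reference species for normalisation")
    ref = abs(float(reaction.coefficient(reaction.reference_species)))
    return dg / ref


# ---------------------------------------------------------------------------
# packaged reaction / thermo library

@dataclass
class ReactionLibrary:
    """A thermo table plus named reactions and redox couples, loaded from YAML.

    The packaged default ships the propane/N-cycle species, the three
    propane-nitrogen reactions and the propane-sulfate comparison, and the
    N and C couples used for electron bookkeeping.
    """

    table: ThermoTable
    reactions: dict[str, RedoxReaction]
    couples: tuple[RedoxCouple, ...] = ()

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ReactionLibrary":
        species: dict[str, ChemSpecies] = {}
        for name, entry in payload.get("species", {}).items():
            species[name] = ChemSpecies.from_formula(
                name=name,
                formula=entry["formula"],
                charge=int(entry.get("charge", 0)),
                phase=entry.get("phase", "aqueous"),
                gibbs_formation=entry.get("dgf_kj_mol"),
            )
        waters = [
            s.name for s in species.values() if s.phase == "liquid-water"
            and s.elements != {"H": 2, "O": 1}
        ]
        if waters:
            raise ChemError(f"only water may be liquid-water phase, got {waters}")
        table = ThermoTable(
            species,
            temperature=float(payload.get("temperature_K", STANDARD_TEMPERATURE)),
        )
        reactions: dict[str, RedoxReaction] = {}
        for name, entry in payload.get("reactions", {}).items():
            rxn = RedoxReaction.from_equation(
                entry["equation"], entry.get("reference"), name=name
            )
            chk = check_balance(rxn, species)
            if not chk.balanced:
                raise UnbalancedReactionError(f"library reaction {name!r} is unbalanced")
            reactions[name] = rxn
        couples = tuple(
            RedoxCouple(c["from"], c["to"], c["element"])
            for c in payload.get("couples", [])
        )
        return cls(table, reactions, couples)

    @classmethod
    def from_yaml(cls, path) -> "ReactionLibrary":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ReactionLibrary":
        ref = resources.files("ndapo.data").joinpath("thermo_library.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


_DEFAULT_LIBRARY: ReactionLibrary | None = None


def default_library() -> ReactionLibrary:
    """The packaged library, loaded once per process."""
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        _DEFAULT_LIBRARY = ReactionLibrary.default()
    return _DEFAULT_LIBRARY
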