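"""Elemental, charge and electron bookkeeping for acetogenic stoichiometry.

The module holds the species and half-reactions of the Wood-Ljungdahl pathway
(WLP) as used in anaerobic dichloromethane (DCM) fermentation, plus the
demethylation / reductive-cleavage chain for quaternary amines.  All balance
arithmetic is exact (:class:`fractions.Fraction`), so a reaction either
balances or it does not -- there is no floating-point grey zone.

Two modelling conventions matter:

* The tetrahydrofolate carrier (FH4) is represented by the pseudo-element
  ``Fol``.  Methylene-tetrahydrofolate (``CH2=FH2``) is the carrier plus one
  carbon at the formaldehyde oxidation level, methyl-tetrahydrofolate
  (``CH3-FH4``) the carrier plus one carbon at the methanol level.  Because
  the carrier is opaque it cancels exactly in every balanced reaction.
* Mean carbon oxidation states use the fixed rules H = +1, O = -2, Cl = -1,
  N = -3, Fol = 0, with the net charge honoured.  These are unambiguous for
  every species in scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from importlib import resources
from typing import Mapping

__all__ = [
    "ChemicalSpecies",
    "Reaction",
    "BalanceReport",
    "UnknownSpeciesError",
    "ZeroCarbonError",
    "ReactionSyntaxError",
    "parse_formula",
    "parse_reaction",
    "mean_carbon_oxidation_state",
    "check_balance",
    "electrons_per_acetate",
    "default_species",
    "default_reactions",
    "OXIDATION_RULES",
    "ELECTRON",
]

#: Oxidation-number assignment for non-carbon elements.  ``Fol`` is the
#: opaque tetrahydrofolate carrier and contributes nothing.
OXIDATION_RULES: dict[str, int] = {"H": 1, "O": -2, "Cl": -1, "N": -3, "Fol": 0}

#: Name of the explicit electron species in reaction strings.
ELECTRON = "e-"

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]*)(\d*)")

#: Electron costs per mole of acetate for the two acetogenic routes, keyed by
#: route label.  Values are *derived* from the balanced reactions at call
#: time, never stored -- see :func:`electrons_per_acetate`.
ROUTE_REACTIONS: dict[str, str] = {
    "methylene": "methylene_to_acetate",
    "pool_bicarbonate": "bicarbonate_to_acetate",
}


class UnknownSpeciesError(KeyError):
    """A reaction refers to a species absent from the registry."""


class ZeroCarbonError(ValueError):
    """Carbon oxidation state requested for a carbon-free species."""


class ReactionSyntaxError(ValueError):
    """A reaction string does not follow the ``a A + b B -> c C`` grammar."""


def parse_formula(text: str) -> dict[str, int]:
    """Parse ``CH2Cl2``-style formulas into an element -> count map.

    The sentinel ``-`` denotes the empty formula (used for the electron).
    Element symbols are one capital letter plus optional lower-case letters,
    so the pseudo-element ``Fol`` parses like any other symbol.
    """
    if text == "-":
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return counts


@dataclass(frozen=True)
class ChemicalSpecies:
    """A chemical species with elemental composition and net charge."""

    name: str
    formula: Mapping[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        for element, count in self.formula.items():
            if count < 0:
                raise ValueError(f"{self.name}: negative count for {element}")

    @property
    def carbons(self) -> int:
        return self.formula.get("C", 0)


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction over named species.

    ``stoichiometry`` maps species name -> signed coefficient (negative =
    consumed, positive = produced).  The explicit electron species ``e-`` is
    an ordinary entry; :attr:`electrons` exposes its signed coefficient.
    """

    name: str
    stoichiometry: Mapping[str, Fraction]

    def __post_init__(self) -> None:
        coeffs = list(self.stoichiometry.values())
        if any(c == 0 for c in coeffs):
            raise ValueError(f"{self.name}: zero stoichiometric coefficient")
        if not any(c < 0 for c in coeffs) or not any(c > 0 for c in coeffs):
            raise ValueError(f"{self.name}: needs >=1 reactant and >=1 product")

    @property
    def electrons(self) -> Fraction:
        """Signed coefficient of the explicit electron (negative = consumed)."""
        return self.stoichiometry.get(ELECTRON, Fraction(0))


@dataclass(frozen=True)
class BalanceReport:
    """Outcome of a balance check: per-element deltas (product minus
    reactant side) and the net charge delta including explicit electrons."""

    element_deltas: Mapping[str, Fraction]
    charge_delta: Fraction
    balanced: bool = field(init=False)

    def __post_init__(self) -> None:
        ok = all(d == 0 for d in self.element_deltas.values()) and self.charge_delta == 0
        object.__setattr__(self, "balanced", ok)


def mean_carbon_oxidation_state(species: ChemicalSpecies) -> Fraction:
    """Mean oxidation state per carbon under the fixed rules.

    The sum of oxidation numbers over all atoms equals the net charge, and
    every non-carbon element has a fixed assignment, so the mean carbon
    oxidation state follows by difference.  Exact rational arithmetic.

    Raises :class:`ZeroCarbonError` for carbon-free species.
    """
    n_c = species.carbons
    if n_c < 1:
        raise ZeroCarbonError(f"{species.name} contains no carbon")
    other = sum(
        OXIDATION_RULES[el] * count
        for el, count in species.formula.items()
        if el != "C"
    )
    return Fraction(species.charge - other, n_c)


def check_balance(
    reaction: Reaction, species: Mapping[str, ChemicalSpecies] | None = None
) -> BalanceReport:
    """Check elemental and charge balance of a reaction.

    Returns a :class:`BalanceReport` whose deltas are (products minus
    reactants); the reaction is balanced iff every delta is exactly zero.
    """
    registry = default_species() if species is None else species
    deltas: dict[str, Fraction] = {}
    charge = Fraction(0)
    for name, coeff in reaction.stoichiometry.items():
        try:
            sp = registry[name]
        except KeyError:
            raise UnknownSpeciesError(name) from None
        for element, count in sp.formula.items():
            deltas[element] = deltas.get(element, Fraction(0)) + coeff * count
        charge += coeff * sp.charge
    return BalanceReport(element_deltas=deltas, charge_delta=charge)


def electrons_per_acetate(
    route: str,
    reactions: Mapping[str, Reaction] | None = None,
    species: Mapping[str, ChemicalSpecies] | None = None,
) -> int:
    """Electrons consumed per mole of acetate formed on a given route.

    ``route`` is ``"methylene"`` (reduction of methylene-tetrahydrofolate,
    4 e-) or ``"pool_bicarbonate"`` (reduction of two bicarbonate, 8 e-).
    The value is derived from the balanced route reaction -- the electron
    coefficient divided by the acetate coefficient -- not stored as a
    constant.
    """
    if route not in ROUTE_REACTIONS:
        raise ValueError(f"unknown route {route!r}; expected one of {sorted(ROUTE_REACTIONS)}")
    table = default_reactions() if reactions is None else reactions
    rxn = table[ROUTE_REACTIONS[route]]
    report = check_balance(rxn, species)
    if not report.balanced:
        raise ValueError(f"route reaction {rxn.name} is not balanced")
    acetate = rxn.stoichiometry["CH3COO-"]
    cost = -rxn.electrons / acetate
    if cost.denominator != 1:
        raise ValueError(f"non-integral electron cost for {rxn.name}")
    return int(cost)


# ---------------------------------------------------------------------------
# Parsing and packaged fixtures


def parse_reaction(line: str, name: str = "") -> Reaction:
    """Parse one ``2 CH2Cl2 + 2 H2O -> CH3COO- + 5 H+ + 4 Cl-`` string.

    Terms are separated by `` + `` (with surrounding whitespace), so species
    names may themselves end in ``+`` or ``-``.  An explicit ``e-`` token is
    allowed on either side.
    """
    if "->" not in line:
        raise ReactionSyntaxError(f"missing '->' in {line!r}")
    left, right = line.split("->", 1)
    stoich: dict[str, Fraction] = {}

    def _add(side: str, sign: int) -> None:
        for term in re.split(r"\s\+\s", side.strip()):
            term = term.strip()
            if not term:
                raise ReactionSyntaxError(f"empty term in {line!r}")
            parts = term.split()
            if len(parts) == 1:
                coeff, sp = Fraction(1), parts[0]
            elif len(parts) == 2:
                try:
                    coeff = Fraction(parts[0])
                except ValueError:
                    raise ReactionSyntaxError(f"bad coefficient in {term!r}") from None
                sp = parts[1]
            else:
                raise ReactionSyntaxError(f"bad term {term!r}")
            stoich[sp] = stoich.get(sp, Fraction(0)) + sign * coeff
            if stoich[sp] == 0:
                del stoich[sp]

    _add(left, -1)
    _add(right, +1)
    return Reaction(name=name or line.strip(), stoichiometry=stoich)


def _read_data(filename: str) -> str:
    return resources.files("dcmflux.data").joinpath(filename).read_text()


@lru_cache(maxsize=1)
def default_species() -> dict[str, ChemicalSpecies]:
    """Packaged species table (name, formula, charge)."""
    registry: dict[str, ChemicalSpecies] = {}
    lines = _read_data("species.tsv").splitlines()
    header = lines[0].split("\t")
    if header != ["name", "formula", "charge"]:
        raise ValueError("species.tsv: unexpected header")
    for line in lines[1:]:
        if not line.strip():
            continue
        name, formula, charge = line.split("\t")
        registry[name] = ChemicalSpecies(
            name=name, formula=parse_formula(formula), charge=int(charge)
        )
    return registry


@lru_cache(maxsize=1)
def default_reactions() -> dict[str, Reaction]:
    """Packaged reaction fixtures (all balance exactly; enforced by tests)."""
    table: dict[str, Reaction] = {}
    for raw in _read_data("reactions.txt").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ReactionSyntaxError(f"missing name in {line!r}")
        name, body = line.split(":", 1)
        table[name.strip()] = parse_reaction(body.strip(), name=name.strip())
    return table
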