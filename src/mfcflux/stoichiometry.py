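"""Chemical constants, half-reaction bookkeeping, and COD/electron conversions.

Every electron count in the package flows through this module, so all unit
conversions (COD <-> charge, nitrate-N <-> charge) live here and nowhere else.
The conventions are those of bioelectrochemical-system practice:

* COD (chemical oxygen demand) is the O2-equivalent mass of an organic
  substrate; 1 mol O2 accepts 4 mol e-, so 1 mg COD == 4/32 mmol e-.
* Acetate oxidation (CH3COO- + 2H2O -> 2CO2 + 8e- + 7H+) releases 8 e- per
  mole, which is exactly the COD route (2 O2 per acetate x 4 e-); the two
  bookkeeping routes must agree and are cross-checked in the tests.
* Denitrification to N2 (NO3- + 5e- + 6H+ -> 1/2 N2 + 3H2O) consumes
  5 e- per mole nitrate; reduction stalled at nitrite consumes only 2.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

from .exceptions import ConfigurationError, DomainError, FormulaError, InconsistentDataError

__all__ = [
    "StoichiometryConstants",
    "HalfReaction",
    "DEFAULT_CONSTANTS",
    "ACETATE_OXIDATION",
    "NITRATE_REDUCTION",
    "HETEROTROPHIC_DENITRIFICATION",
    "parse_formula",
    "cod_of_sodium_acetate",
    "electrons_from_cod",
    "electrons_from_nitrate",
    "cod_equivalent_of_charge",
    "critical_cod_n_ratio",
    "check_element_balance",
]

_CHARGE_RE = re.compile(r"([+-]+)$")
_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(species: str) -> tuple[dict[str, float], float]:
    """Parse a condensed formula such as ``CH3COO-`` or ``C5H7O2N``.

    Returns ``(element_counts, charge)``.  Repeated element symbols
    accumulate (``CH3COO`` -> ``{"C": 2, "H": 3, "O": 2}``).  Trailing
    ``+``/``-`` signs are read as the ionic charge, one unit per sign
    (``NO3-`` is charge -1; a trailing digit such as the 3 is always a
    subscript).  Parentheses and hydrates are not supported — the
    half-reactions handled here do not need them.
    """
    if not species or not species.strip():
        raise FormulaError("empty species string")
    body = species.strip()
    charge = 0.0
    m = _CHARGE_RE.search(body)
    if m:
        signs = m.group(1)
        if len(set(signs)) > 1:
            raise FormulaError(f"mixed charge signs in species {species!r}")
        charge = float(len(signs)) * (1.0 if signs[0] == "+" else -1.0)
        body = body[: m.start()]
    counts: dict[str, float] = {}
    pos = 0
    for m in _ELEMENT_RE.finditer(body):
        if m.start() != pos:
            raise FormulaError(f"cannot parse species {species!r} at position {pos}")
        symbol, count = m.group(1), m.group(2)
        counts[symbol] = counts.get(symbol, 0.0) + (float(count) if count else 1.0)
        pos = m.end()
    if pos != len(body) or not counts:
        raise FormulaError(f"cannot parse species {species!r}")
    return counts, charge


@dataclass(frozen=True)
class StoichiometryConstants:
    """Single source of truth for the constants behind every conversion.

    ``mw_sodium_acetate`` is deliberately 82.0 (not 82.03) and ``mw_n`` 14.0
    so that the derived COD conversion reproduces the conventional
    780.5 mg COD per gram sodium acetate; all values can be overridden.
    """

    faraday: float = 96485.0  # C per mol e-
    e_per_acetate: int = 8
    e_per_nitrate_to_n2: int = 5
    e_per_nitrate_to_no2: int = 2
    e_per_o2: int = 4
    mw_o2: float = 32.0  # g/mol
    mw_n: float = 14.0  # g/mol
    mw_sodium_acetate: float = 82.0  # g/mol

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ConfigurationError(f"constant {f.name} must be strictly positive")

    @property
    def cod_per_g_sodium_acetate(self) -> float:
        """mg COD per gram sodium acetate: 2 mol O2 per mol acetate."""
        return 1000.0 * 2.0 * self.mw_o2 / self.mw_sodium_acetate

    @property
    def e_per_nitrite_to_n2(self) -> int:
        """Electrons to finish nitrite -> N2 (the 3 of 5 not yet consumed)."""
        return self.e_per_nitrate_to_n2 - self.e_per_nitrate_to_no2

    def replace(self, **overrides: float) -> "StoichiometryConstants":
        return replace(self, **overrides)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "StoichiometryConstants":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown constant name(s): {sorted(unknown)}")
        return cls(**{k: v for k, v in mapping.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "StoichiometryConstants":
        """Load overrides from a JSON or YAML key-value file."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a key-value mapping")
        return cls.from_mapping(data)


DEFAULT_CONSTANTS = StoichiometryConstants()


@dataclass(frozen=True)
class HalfReaction:
    """A (half-)reaction as a signed-coefficient species map.

    Positive coefficients are reactants (left side), negative coefficients
    are products.  ``electrons`` counts free electrons per formula unit,
    positive when released on the right (an oxidation), negative when
    consumed on the left (a reduction); zero for a full redox reaction.
    """

    coefficients: Mapping[str, float]
    electrons: float = 0.0
    name: str = ""
    _parsed: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        parsed = {sp: parse_formula(sp) for sp in self.coefficients}
        object.__setattr__(self, "coefficients", dict(self.coefficients))
        object.__setattr__(self, "_parsed", parsed)

    @property
    def reactants(self) -> dict[str, float]:
        return {sp: c for sp, c in self.coefficients.items() if c > 0}

    @property
    def products(self) -> dict[str, float]:
        return {sp: -c for sp, c in self.coefficients.items() if c < 0}

    def elements(self) -> set[str]:
        out: set[str] = set()
        for counts, _ in self._parsed.values():
            out |= counts.keys()
        return out

    def element_imbalance(self, element: str) -> float:
        """Signed left-minus-right tally of one element."""
        return sum(
            coef * self._parsed[sp][0].get(element, 0.0)
            for sp, coef in self.coefficients.items()
        )

    def charge_imbalance(self) -> float:
        """Signed left-minus-right charge tally, free electrons included."""
        species = sum(coef * self._parsed[sp][1] for sp, coef in self.coefficients.items())
        # each free electron carries charge -1; electrons > 0 sit on the
        # right (subtracting -e from the right adds +e to left-minus-right),
        # electrons < 0 sit on the left (adding -|e| there, i.e. +electrons)
        return species + self.electrons

    def find_species(self, fragment: str) -> tuple[str, float]:
        """Return (name, coefficient) of the unique species containing ``fragment``."""
        hits = [(sp, c) for sp, c in self.coefficients.items() if fragment in sp]
        if not hits:
            raise ConfigurationError(f"no species matching {fragment!r} in reaction {self.name or self.coefficients}")
        if len(hits) > 1:
            raise ConfigurationError(f"ambiguous species fragment {fragment!r}: {[h[0] for h in hits]}")
        return hits[0]

    @classmethod
    def from_dict(cls, data: Mapping) -> "HalfReaction":
        return cls(
            coefficients=dict(data["coefficients"]),
            electrons=float(data.get("electrons", 0.0)),
            name=str(data.get("name", "")),
        )


#: Acetate oxidation: CH3COO- + 2 H2O -> 2 CO2 + 8 e- + 7 H+
ACETATE_OXIDATION = HalfReaction(
    coefficients={"CH3COO-": 1.0, "H2O": 2.0, "CO2": -2.0, "H+": -7.0},
    electrons=8.0,
    name="acetate oxidation",
)

#: Nitrate reduction to dinitrogen: NO3- + 5 e- + 6 H+ -> 1/2 N2 + 3 H2O
NITRATE_REDUCTION = HalfReaction(
    coefficients={"NO3-": 1.0, "H+": 6.0, "N2": -0.5, "H2O": -3.0},
    electrons=-5.0,
    name="nitrate reduction to N2",
)

#: Heterotrophic denitrification including biomass (C5H7O2N) synthesis, with
#: the coefficients conventionally used for acetate-fed denitrifiers:
#: 7.03 CH3COO- + 8.58 NO3- -> 0.58 C5H7O2N + 11.16 CO2 + 8.58 OH- + 7.74 H2O + 4 N2
#: As printed this balances in C, N and O but not in H or charge (both are
#: short by ~7.03 on the right); the imbalance is reported, not repaired,
#: and the COD/N ratio uses the coefficients exactly as given.
HETEROTROPHIC_DENITRIFICATION = HalfReaction(
    coefficients={
        "CH3COO-": 7.03,
        "NO3-": 8.58,
        "C5H7O2N": -0.58,
        "CO2": -11.16,
        "OH-": -8.58,
        "H2O": -7.74,
        "N2": -4.0,
    },
    electrons=0.0,
    name="heterotrophic denitrification with biomass synthesis",
)


def cod_of_sodium_acetate(
    mass_concentration_g_l: float,
    constants: StoichiometryConstants = DEFAULT_CONSTANTS,
) -> float:
    """COD equivalent (mg COD/L) of a sodium acetate solution (g/L).

    1 g/L sodium acetate corresponds to 780.5 mg COD/L under the default
    molar masses.
    """
    if mass_concentration_g_l < 0:
        raise DomainError("sodium acetate concentration must be >= 0")
    return mass_concentration_g_l * constants.cod_per_g_sodium_acetate


def electrons_from_cod(
    delta_cod_mg: float,
    constants: StoichiometryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Charge (C) liberated by consuming ``delta_cod_mg`` mg of COD.

    Uses the O2 route (4 e- per mol O2 equivalent), which is identical to
    counting 8 e- per mole of acetate oxidized.
    """
    if delta_cod_mg < 0:
        raise DomainError("COD consumed must be >= 0")
    mol_o2 = delta_cod_mg / 1000.0 / constants.mw_o2
    return mol_o2 * constants.e_per_o2 * constants.faraday


def cod_equivalent_of_charge(
    charge_c: float,
    constants: StoichiometryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Inverse of :func:`electrons_from_cod`: mg COD represented by a charge."""
    return charge_c / constants.faraday / constants.e_per_o2 * constants.mw_o2 * 1000.0


def electrons_from_nitrate(
    delta_no3n_mg: float,
    residual_no2n_mg: float = 0.0,
    include_nitrite_correction: bool = False,
    constants: StoichiometryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Charge (C) consumed reducing ``delta_no3n_mg`` mg of nitrate-N.

    By default every mg of nitrate-N lost is assumed reduced all the way to
    N2 (5 e- per mol); this matches practice when nitrite and other
    intermediates stay below detection.  With
    ``include_nitrite_correction=True``, nitrate stuck at residual nitrite
    is credited only the 2 e- of the NO3- -> NO2- step (i.e. 3 e- per mole
    of residual nitrite-N are subtracted).
    """
    if delta_no3n_mg < 0:
        raise DomainError("nitrate-N removed must be >= 0")
    if residual_no2n_mg < 0:
        raise DomainError("residual nitrite-N must be >= 0")
    if residual_no2n_mg > delta_no3n_mg + 1e-12:
        raise InconsistentDataError(
            f"residual nitrite-N ({residual_no2n_mg} mg) exceeds nitrate-N removed ({delta_no3n_mg} mg)"
        )
    mol_per_mg = 1.0 / 1000.0 / constants.mw_n
    charge = delta_no3n_mg * mol_per_mg * constants.e_per_nitrate_to_n2 * constants.faraday
    if include_nitrite_correction:
        charge -= residual_no2n_mg * mol_per_mg * constants.e_per_nitrite_to_n2 * constants.faraday
    return charge


def critical_cod_n_ratio(
    reaction: HalfReaction = HETEROTROPHIC_DENITRIFICATION,
    constants: StoichiometryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Critical COD/N mass ratio (g COD per g N) of a denitrification reaction.

    The ratio of the COD carried by the acetate reactant to the nitrogen
    mass of the nitrate reactant; below this ratio the electron donor limits
    complete denitrification.  With the default biomass-inclusive
    coefficients (7.03 acetate : 8.58 nitrate) the ratio is 3.75.
    """
    _, acetate_coef = reaction.find_species("CH3COO")
    _, nitrate_coef = reaction.find_species("NO3")
    if acetate_coef <= 0 or nitrate_coef <= 0:
        raise ConfigurationError("acetate and nitrate must be reactants (positive coefficients)")
    cod_g = acetate_coef * constants.mw_sodium_acetate * constants.cod_per_g_sodium_acetate / 1000.0
    n_g = nitrate_coef * constants.mw_n
    return cod_g / n_g


def check_element_balance(
    reaction: HalfReaction,
    elements: list[str] | None = None,
    include_charge: bool = False,
) -> dict[str, float]:
    """Signed left-minus-right discrepancy per element (and optionally charge).

    A balanced equation gives zeros everywhere; printed literature
    coefficients are typically rounded to two decimals, so discrepancies
    below ~0.05 formula units are rounding, larger ones are real (the
    biomass-inclusive denitrification equation as conventionally printed is
    short ~7 H and ~7 negative charges on the right).
    """
    if elements is None:
        elements = sorted(reaction.elements())
    report = {el: reaction.element_imbalance(el) for el in elements}
    if include_charge:
        report["charge"] = reaction.charge_imbalance()
    return report
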