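"""Chemical-formula parsing and the exact-mass algebra of ESI adducts.

Everything downstream of raw peak alignment — putative annotation, adduct
grouping, ppm gating — reduces to two pieces of arithmetic: the monoisotopic
mass of a neutral elemental formula, and the m/z of an ion species (adduct)
formed from ``n`` copies of that neutral molecule.  This module owns both.

The ion m/z convention includes the electron mass: an anion carries one extra
electron per negative charge, a cation is missing one per positive charge.
At TOF mass accuracy (~5 ppm) the electron term (0.00055 Da) is on the edge
of mattering, and it is the convention that reproduces published 3-decimal
negative-mode m/z values; it can be switched off for comparison.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

__all__ = [
    "ELEMENT_MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "FormulaError",
    "EmptyFormulaError",
    "MalformedFormulaError",
    "UnknownElementError",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "AdductSpec",
    "DEFAULT_NEGATIVE_ADDUCTS",
    "EXTENDED_NEGATIVE_ADDUCTS",
    "PROTONATED_POSITIVE",
    "adduct_by_name",
    "adduct_mz",
    "neutral_mass_from_mz",
    "ppm_error",
]

# Monoisotopic (lightest stable isotope) masses in Da, CODATA/AME-derived
# reference values.  The table ships with the package so that annotation
# results do not depend on any external mass library.
ELEMENT_MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,  # defines the scale
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.9637064864,
}

ELECTRON_MASS: float = 0.000548579909  # Da


class FormulaError(ValueError):
    """Base class for formula parsing/mass errors."""


class EmptyFormulaError(FormulaError):
    """Raised for an empty or blank formula string."""


class MalformedFormulaError(FormulaError):
    """Raised when the formula text cannot be tokenised (bad count, stray character)."""


class UnknownElementError(FormulaError):
    """Raised for an element symbol absent from the mass table."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Dict[str, int]:
    """Parse a Hill-style elemental formula (e.g. ``"C25H30O7"``).

    Returns the element -> count multiset.  Repeated element symbols are
    summed, so parse/serialise round-trips are lossless up to element order.

    Raises
    ------
    EmptyFormulaError, MalformedFormulaError, UnknownElementError
    """
    if not isinstance(text, str) or not text.strip():
        raise EmptyFormulaError("formula string is empty")
    s = text.strip()
    elements: Dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise MalformedFormulaError(f"cannot parse formula {text!r} at position {pos}")
        symbol, count_text = m.groups()
        if symbol not in ELEMENT_MONOISOTOPIC_MASS:
            raise UnknownElementError(f"unknown element symbol {symbol!r} in {text!r}")
        if count_text == "":
            count = 1
        else:
            count = int(count_text)
            if count < 1:
                raise MalformedFormulaError(f"element count must be >= 1 in {text!r}")
        elements[symbol] = elements.get(symbol, 0) + count
        pos = m.end()
    return elements


def format_formula(elements: Mapping[str, int]) -> str:
    """Serialise an element multiset in Hill order (C, H, then alphabetical)."""
    if not elements:
        raise EmptyFormulaError("empty element multiset")
    symbols = list(elements)
    if "C" in elements:
        order = ["C"] + (["H"] if "H" in elements else []) + sorted(
            s for s in symbols if s not in ("C", "H")
        )
    else:
        order = sorted(symbols)
    parts = []
    for s in order:
        n = elements[s]
        parts.append(s if n == 1 else f"{s}{n}")
    return "".join(parts)


def monoisotopic_mass(formula: Mapping[str, int] | str) -> float:
    """Monoisotopic mass (Da) of a neutral elemental formula.

    Accepts either a parsed element multiset or a formula string.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if not formula:
        raise EmptyFormulaError("empty element multiset")
    total = 0.0
    for symbol, count in formula.items():
        try:
            m = ELEMENT_MONOISOTOPIC_MASS[symbol]
        except KeyError:
            raise UnknownElementError(f"element {symbol!r} missing from the mass table") from None
        if count < 1:
            raise MalformedFormulaError(f"count for {symbol!r} must be >= 1")
        total += count * m
    return total


@dataclass(frozen=True)
class AdductSpec:
    """One ion species: ``n`` molecules plus atom additions/losses and a charge.

    ``charge`` is the signed ion charge (negative for anions).  In negative
    mode the ion gains ``|charge|`` electrons; in positive mode it loses them.
    """

    name: str
    charge: int
    n: int = 1
    additions: Mapping[str, int] = field(default_factory=dict)
    losses: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError(f"adduct {self.name!r}: charge must be non-zero")
        if self.n < 1:
            raise ValueError(f"adduct {self.name!r}: multimer count must be >= 1")
        # freeze the element maps so specs are hashable-by-value in practice
        object.__setattr__(self, "additions", dict(self.additions))
        object.__setattr__(self, "losses", dict(self.losses))

    @property
    def polarity(self) -> str:
        return "negative" if self.charge < 0 else "positive"

    @property
    def mass_shift(self) -> float:
        """mass(additions) - mass(losses), in Da."""
        add = monoisotopic_mass(self.additions) if self.additions else 0.0
        loss = monoisotopic_mass(self.losses) if self.losses else 0.0
        return add - loss


_FORMATE = {"C": 1, "H": 2, "O": 2}  # FA = formic acid, CH2O2

#: The negative-mode species observed in the worked example: deprotonation,
#: deprotonated dimer, chloride and formate attachment, formate dimer, and
#: sodium/potassium exchange of two protons.
DEFAULT_NEGATIVE_ADDUCTS: Sequence[AdductSpec] = (
    AdductSpec("[M-H]-", charge=-1, losses={"H": 1}),
    AdductSpec("[2M-H]-", charge=-1, n=2, losses={"H": 1}),
    AdductSpec("[M+Cl]-", charge=-1, additions={"Cl": 1}),
    AdductSpec("[M+FA-H]-", charge=-1, additions=_FORMATE, losses={"H": 1}),
    AdductSpec("[2M+FA-H]-", charge=-1, n=2, additions=_FORMATE, losses={"H": 1}),
    AdductSpec("[M+K-2H]-", charge=-1, additions={"K": 1}, losses={"H": 2}),
    AdductSpec("[M+Na-2H]-", charge=-1, additions={"Na": 1}, losses={"H": 2}),
)

#: Default set plus the doubly deprotonated dianion [M-2H]2-, which small
#: acidic metabolites form; needed to explain doubly charged features.
EXTENDED_NEGATIVE_ADDUCTS: Sequence[AdductSpec] = tuple(DEFAULT_NEGATIVE_ADDUCTS) + (
    AdductSpec("[M-2H]2-", charge=-2, losses={"H": 2}),
)

#: Minimal positive-mode species for MS/MS bookkeeping.
PROTONATED_POSITIVE = AdductSpec("[M+H]+", charge=1, additions={"H": 1})


def adduct_by_name(name: str, adducts: Optional[Iterable[AdductSpec]] = None) -> AdductSpec:
    """Look up an :class:`AdductSpec` by its label in a set (default: extended negative)."""
    pool = EXTENDED_NEGATIVE_ADDUCTS if adducts is None else adducts
    for spec in pool:
        if spec.name == name:
            return spec
    raise KeyError(f"no adduct named {name!r}")


def _electron_term(adduct: AdductSpec) -> float:
    # electrons gained per negative charge, lost per positive charge
    q = abs(adduct.charge) if adduct.charge < 0 else -abs(adduct.charge)
    return q * ELECTRON_MASS


def adduct_mz(neutral_mass: float, adduct: AdductSpec, *, include_electron: bool = True) -> float:
    """Predicted m/z of ``adduct`` formed from a neutral of the given monoisotopic mass.

    m/z = (n*M + mass(additions) - mass(losses) + q*m_e) / |charge|, with
    q = +1 per negative charge and -1 per positive charge.
    """
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    electron = _electron_term(adduct) if include_electron else 0.0
    return (adduct.n * neutral_mass + adduct.mass_shift + electron) / abs(adduct.charge)


def neutral_mass_from_mz(mz: float, adduct: AdductSpec, *, include_electron: bool = True) -> float:
    """Invert :func:`adduct_mz`: the neutral monoisotopic mass implied by an observed m/z.

    Raises ``ValueError`` if the inferred mass is non-positive (the adduct is
    impossible at that m/z).
    """
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    electron = _electron_term(adduct) if include_electron else 0.0
    mass = (abs(adduct.charge) * mz - adduct.mass_shift - electron) / adduct.n
    if mass <= 0:
        raise ValueError(
            f"adduct {adduct.name!r} is impossible at m/z {mz}: implied neutral mass {mass:.5f} <= 0"
        )
    return mass


def ppm_error(observed: float, predicted: float) -> float:
    """Absolute relative mass deviation in parts per million, |obs - pred| / pred * 1e6."""
    if predicted <= 0:
        raise ValueError(f"predicted m/z must be positive, got {predicted}")
    return 1e6 * abs(observed - predicted) / predicted
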