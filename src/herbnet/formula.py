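"""Molecular formulas, monoisotopic masses and ESI adduct m/z arithmetic.

The element mass table and the adduct registry are shipped as plain-text
data files next to this module so every constant is auditable in one place.
Masses are monoisotopic (most abundant isotope); all ions are treated as
singly charged, which holds for every species this pipeline annotates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Mapping

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "FormulaError",
    "AdductRule",
    "ADDUCTS",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "formula_mass",
    "adduct_mz",
    "adducts_for_polarity",
]

#: Mass of a proton in Da. Equals mass(H) - mass(electron).
PROTON_MASS = 1.007276466
#: Mass of an electron in Da.
ELECTRON_MASS = 0.00054857991

ElementCounts = Dict[str, int]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed molecular formulas or unknown adduct labels."""


def _load_masses() -> Dict[str, float]:
    text = resources.files("herbnet.data").joinpath("monoisotopic_masses.tsv").read_text()
    table: Dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, mass = line.split("\t")
        table[sym] = float(mass)
    return table


#: Monoisotopic mass of the most abundant isotope per element symbol (Da).
ELEMENT_MASSES: Dict[str, float] = _load_masses()


def parse_formula(formula: str) -> ElementCounts:
    """Parse a Hill-style molecular formula into element counts.

    ``"C39H50O19"`` -> ``{"C": 39, "H": 50, "O": 19}``.  Element symbols may
    repeat; counts are summed.  An omitted count means 1.  Raises
    :class:`FormulaError` naming the offending position for anything that is
    not a known element symbol followed by an optional integer.
    """
    if not isinstance(formula, str):
        raise FormulaError(f"formula must be a string, got {type(formula).__name__}")
    counts: ElementCounts = {}
    pos = 0
    s = formula.strip()
    if not s:
        raise FormulaError("empty formula")
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None:
            raise FormulaError(
                f"invalid formula {formula!r}: unexpected character {s[pos]!r} at position {pos}"
            )
        sym, digits = m.groups()
        if sym not in ELEMENT_MASSES:
            raise FormulaError(
                f"invalid formula {formula!r}: unknown element {sym!r} at position {pos}"
            )
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(
                f"invalid formula {formula!r}: count {n} for {sym} at position {pos}"
            )
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Format element counts as a canonical Hill string.

    Hill order: C first, then H, then all other elements alphabetically;
    if no carbon is present, all elements are alphabetical.
    """
    items = {k: v for k, v in counts.items() if v}
    if any(v < 0 for v in items.values()):
        raise FormulaError(f"negative element count in {dict(counts)!r}")
    if "C" in items:
        order = ["C"] + (["H"] if "H" in items else []) + sorted(
            k for k in items if k not in ("C", "H")
        )
    else:
        order = sorted(items)
    return "".join(f"{k}{items[k] if items[k] != 1 else ''}" for k in order)


def monoisotopic_mass(counts: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of a composition: sum of count x isotope mass."""
    mass = 0.0
    for sym, n in counts.items():
        try:
            mass += n * ELEMENT_MASSES[sym]
        except KeyError:
            raise FormulaError(f"no monoisotopic mass for element {sym!r}") from None
    return mass


def formula_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a Hill-style formula string."""
    return monoisotopic_mass(parse_formula(formula))


@dataclass(frozen=True)
class AdductRule:
    """One ESI adduct: observed m/z = multiplicity * M + delta (singly charged).

    ``delta`` is composed from atom, proton and electron masses, e.g.
    [M+Na]+ adds a sodium atom and removes one electron.
    """

    label: str
    polarity: str  # '+' or '-'
    multiplicity: int
    delta: float

    def mz(self, neutral_mass: float) -> float:
        if neutral_mass <= 0:
            raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
        return self.multiplicity * neutral_mass + self.delta


def _load_adducts() -> Dict[str, AdductRule]:
    text = resources.files("herbnet.data").joinpath("adducts.tsv").read_text()
    registry: Dict[str, AdductRule] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, polarity, mult, add_formula, protons, electrons = line.split("\t")
        delta = (
            (formula_mass(add_formula) if add_formula else 0.0)
            + int(protons) * PROTON_MASS
            + int(electrons) * ELECTRON_MASS
        )
        registry[label] = AdductRule(label, polarity, int(mult), delta)
    return registry


def _canon_label(label: str) -> str:
    # tolerate the typographic minus often pasted from reports
    return label.replace("−", "-").replace(" ", "")


#: Registered adducts: the positive-mode set [M+H]+, [M+K]+, [M+Na]+, [2M+H]+,
#: [M-e]+ and the negative-mode set [M+COOH]-, [M-H]-, [2M-H]-.
ADDUCTS: Dict[str, AdductRule] = _load_adducts()


def adduct_mz(neutral_mass: float, rule: "AdductRule | str") -> float:
    """Theoretical m/z of ``rule`` applied to a neutral monoisotopic mass."""
    if isinstance(rule, str):
        try:
            rule = ADDUCTS[_canon_label(rule)]
        except KeyError:
            raise FormulaError(f"unregistered adduct label {rule!r}") from None
    return rule.mz(neutral_mass)


def adducts_for_polarity(polarity: str) -> list[AdductRule]:
    """All registered adducts for one polarity ('+' or '-')."""
    if polarity not in ("+", "-"):
        raise ValueError(f"polarity must be '+' or '-', got {polarity!r}")
    return [r for r in ADDUCTS.values() if r.polarity == polarity]
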