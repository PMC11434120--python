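"""Elemental formula arithmetic and monoisotopic mass computation.

All masses in this package are monoisotopic and expressed in daltons.
Positive-mode electrospray produces singly protonated species almost
exclusively for small peptides, so the only adduct handled here is
[M+H]+: the neutral mass plus the mass of a proton (an H atom minus
one electron, 1.007276 Da).
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ElementCounts",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "round_half_up",
]

#: IUPAC/CODATA monoisotopic masses of the most abundant isotope, Da.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

ELECTRON_MASS: float = 0.000548579909  # Da
#: Mass of H+ = H atom minus one electron.
PROTON_MASS: float = ELEMENT_MASSES["H"] - ELECTRON_MASS

_HILL_ORDER = ("C", "H")  # carbon, hydrogen, then alphabetical
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable or chemically invalid formula input."""


class ElementCounts(Mapping[str, int]):
    """Immutable integer element composition.

    Instances play two semantic roles: a *molecular species* (all counts
    >= 0) or a *delta*, the signed difference of two species (e.g. the
    C2H4 gap between a Val and an Ala residue).  Addition, subtraction
    and integer scaling are element-wise; mass is linear in counts.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for element, count in source.items():
                if element not in ELEMENT_MASSES:
                    raise FormulaError(f"unknown element symbol: {element!r}")
                merged[element] = merged.get(element, 0) + int(count)
        self._counts = {e: c for e, c in merged.items() if c != 0}

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, element: object) -> bool:
        return element in self._counts

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "ElementCounts") -> "ElementCounts":
        out = dict(self._counts)
        for e, c in other._counts.items():
            out[e] = out.get(e, 0) + c
        return ElementCounts(out)

    def __sub__(self, other: "ElementCounts") -> "ElementCounts":
        out = dict(self._counts)
        for e, c in other._counts.items():
            out[e] = out.get(e, 0) - c
        return ElementCounts(out)

    def __mul__(self, n: int) -> "ElementCounts":
        return ElementCounts({e: c * n for e, c in self._counts.items()})

    __rmul__ = __mul__

    def __neg__(self) -> "ElementCounts":
        return self * -1

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementCounts):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"ElementCounts({self.hill()!r})"

    # -- chemistry --------------------------------------------------------
    @property
    def is_species(self) -> bool:
        """True when every count is non-negative (a real molecule)."""
        return all(c >= 0 for c in self._counts.values())

    @property
    def mass(self) -> float:
        """Signed monoisotopic mass in Da (deltas may be negative)."""
        return sum(ELEMENT_MASSES[e] * c for e, c in self._counts.items())

    def hill(self) -> str:
        """Canonical Hill-notation string (C, H, then alphabetical)."""
        rest = sorted(e for e in self._counts if e not in _HILL_ORDER)
        parts = []
        for e in (*_HILL_ORDER, *rest):
            c = self._counts.get(e, 0)
            if c == 0:
                continue
            parts.append(e if c == 1 else f"{e}{c}")
        return "".join(parts)


def parse_formula(text: str) -> ElementCounts:
    """Parse a Hill-style formula string such as ``"C11H16N2O5"``.

    Counts default to 1 when omitted; explicit zero or negative counts
    and unknown element symbols raise :class:`FormulaError`.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        count = int(digits) if digits else 1
        if count <= 0:
            raise FormulaError(f"non-positive count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + count
        pos = m.end()
    return ElementCounts(counts)


def monoisotopic_mass(f: ElementCounts) -> float:
    """Monoisotopic mass of a molecular species in Da.

    Restricted to true species; use :attr:`ElementCounts.mass` for the
    signed mass of a composition delta.
    """
    if not f.is_species:
        raise ValueError(f"negative element count in {f.hill() or f!r}; not a species")
    return f.mass


def protonated_mz(f: ElementCounts) -> float:
    """m/z of the singly protonated species [M+H]+."""
    return monoisotopic_mass(f) + PROTON_MASS


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed m/z conventions.

    Python's builtin ``round`` uses banker's rounding; published m/z
    tables round 0.005 up, so comparisons against printed two-decimal
    values go through this helper.
    """
    import math

    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
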