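"""Elemental compositions for sulfolipid chemistry.

Compositions are restricted to the elements that occur in sulfoquinovosyl
glycerolipids and the cerebroside internal standard (C, H, N, O, S) and can be
evaluated on two mass scales:

* monoisotopic mass — sum of the masses of the most abundant isotopes
  (values taken from the NIST table shipped with :mod:`pyteomics`);
* nominal mass — sum of integer mass numbers (C=12, H=1, N=14, O=16, S=32).

The nominal mass is computed from mass numbers directly, never by rounding
the monoisotopic mass: above m/z ~500 the hydrogen mass defect exceeds 0.5
and rounding would be off by one.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

from pyteomics import mass as _ptmass

ALLOWED_ELEMENTS = ("C", "H", "N", "O", "S")

#: monoisotopic mass of the most abundant isotope, per element
MONOISOTOPIC_MASS: dict[str, float] = {
    el: _ptmass.nist_mass[el][0][0] for el in ALLOWED_ELEMENTS
}

#: integer mass number of the most abundant isotope, per element
MASS_NUMBER: dict[str, int] = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32}

#: mass of a hydrogen atom; the electron mass (~0.5 mDa) is ignored in
#: deprotonated-ion m/z values, an error far below unit resolution.
HYDROGEN_MASS = MONOISOTOPIC_MASS["H"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementCount(Mapping[str, int]):
    """Immutable element → count map with mass evaluation.

    Supports ``+`` and ``-`` (subtraction raising on negative counts), which
    is how esterification water and neutral losses are handled throughout.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kwargs:
            for el, n in src.items():
                merged[el] = merged.get(el, 0) + int(n)
        for el, n in merged.items():
            if el not in ALLOWED_ELEMENTS:
                raise ValueError(f"element {el!r} not supported (allowed: {ALLOWED_ELEMENTS})")
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
        self._counts: dict[str, int] = {el: n for el, n in merged.items() if n}

    @classmethod
    def from_formula(cls, formula: str) -> "ElementCount":
        """Parse a plain Hill-style formula such as ``"C43H76O12S"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
            el, digits = m.groups()
            counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
            pos = m.end()
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts)

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, el: object) -> bool:
        return el in self._counts

    # Arithmetic -----------------------------------------------------------
    def __add__(self, other: "ElementCount") -> "ElementCount":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) + n
        return ElementCount(counts)

    def __sub__(self, other: "ElementCount") -> "ElementCount":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) - n
        return ElementCount(counts)  # raises on negative counts

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementCount):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(sorted(self._counts.items())))

    # Masses ---------------------------------------------------------------
    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self._counts.items())

    @property
    def nominal_mass(self) -> int:
        return sum(MASS_NUMBER[el] * n for el, n in self._counts.items())

    def formula(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        order = [el for el in ("C", "H", "N", "O", "S") if el in self._counts]
        return "".join(
            f"{el}{self._counts[el]}" if self._counts[el] != 1 else el for el in order
        )

    def __repr__(self) -> str:
        return f"ElementCount({self.formula()!r})"


#: one water molecule, lost per ester bond
WATER = ElementCount(H=2, O=1)
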