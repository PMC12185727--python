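"""Elemental compositions, monoisotopic masses and amino-acid residue tables.

Atomic masses are CODATA/IUPAC monoisotopic values hard-coded to >= 7 decimal
places so that every mass in the package is reproducible independent of
library versions.  All peptide masses are neutral monoisotopic masses in Da;
crosslinker fragments are stored as residue-modification masses (the mass
added to the intact crosslinked residue).
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

__all__ = [
    "ATOMIC_MASS",
    "ElementalComposition",
    "monoisotopic_mass",
    "PROTON_MASS",
    "WATER_MASS",
    "NH_MASS",
    "RESIDUE_COMPOSITION",
    "RESIDUE_MASS",
    "CARBAMIDOMETHYL_MASS",
    "ACETYL_MASS",
    "STANDARD_RESIDUES",
]

#: Monoisotopic atomic masses (Da) of the supported elements.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalComposition(Mapping):
    """Immutable element -> count mapping with a monoisotopic mass.

    Counts must be non-negative integers over the supported element table;
    zero counts are dropped.  The empty composition has mass 0.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for element, count in source.items():
                if element not in ATOMIC_MASS:
                    raise ValueError(
                        f"unknown element symbol {element!r}; supported: "
                        f"{sorted(ATOMIC_MASS)}"
                    )
                if not isinstance(count, int) or count < 0:
                    raise ValueError(
                        f"element count must be a non-negative integer, "
                        f"got {element}={count!r}"
                    )
                if count:
                    merged[element] = merged.get(element, 0) + count
        self._counts = dict(sorted(merged.items()))

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula such as ``"C3H5NO2S"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"unparseable formula {formula!r} at position {pos}")
            pos = match.end()
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        if pos != len(formula):
            raise ValueError(f"unparseable formula {formula!r} at position {pos}")
        return cls(counts)

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = dict(self._counts)
        for element, count in other.items():
            counts[element] = counts.get(element, 0) + count
        return ElementalComposition(counts)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = dict(self._counts)
        for element, count in other.items():
            counts[element] = counts.get(element, 0) - count
        return ElementalComposition(counts)

    def __repr__(self) -> str:
        return f"ElementalComposition({self.formula()!r})"

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalComposition):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def formula(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        order = sorted(
            self._counts, key=lambda el: {"C": "0", "H": "1"}.get(el, el)
        )
        return "".join(
            f"{el}{self._counts[el] if self._counts[el] != 1 else ''}" for el in order
        )

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def monoisotopic_mass(composition: Mapping[str, int] | str) -> float:
    """Neutral monoisotopic mass (Da) of an elemental composition.

    Accepts an :class:`ElementalComposition`, a plain element->count mapping,
    or a formula string.  Additive over composition union; the empty
    composition has mass 0.  Unknown element symbols are rejected by name.
    """
    if isinstance(composition, str):
        composition = ElementalComposition.from_formula(composition)
    total = 0.0
    for element, count in composition.items():
        try:
            atomic = ATOMIC_MASS[element]
        except KeyError:
            raise ValueError(
                f"unknown element symbol {element!r}; supported: "
                f"{sorted(ATOMIC_MASS)}"
            ) from None
        if count < 0:
            raise ValueError(f"negative count for element {element!r}")
        total += count * atomic
    return total


PROTON_MASS = 1.00727646688
WATER_MASS = monoisotopic_mass("H2O")
NH_MASS = monoisotopic_mass("NH")

#: Residue (amino-acid minus water) elemental compositions of the 20
#: canonical amino acids, one-letter codes.
RESIDUE_COMPOSITION: dict[str, ElementalComposition] = {
    code: ElementalComposition.from_formula(formula)
    for code, formula in {
        "G": "C2H3NO",
        "A": "C3H5NO",
        "S": "C3H5NO2",
        "P": "C5H7NO",
        "V": "C5H9NO",
        "T": "C4H7NO2",
        "C": "C3H5NOS",
        "L": "C6H11NO",
        "I": "C6H11NO",
        "N": "C4H6N2O2",
        "D": "C4H5NO3",
        "Q": "C5H8N2O2",
        "K": "C6H12N2O",
        "E": "C5H7NO3",
        "M": "C5H9NOS",
        "H": "C6H7N3O",
        "F": "C9H9NO",
        "R": "C6H12N4O",
        "Y": "C9H9NO2",
        "W": "C11H10N2O",
    }.items()
}

RESIDUE_MASS: dict[str, float] = {
    code: comp.mass for code, comp in RESIDUE_COMPOSITION.items()
}

STANDARD_RESIDUES = frozenset(RESIDUE_MASS)

#: Carbamidomethylation of cysteine (iodoacetamide alkylation), +C2H3NO.
CARBAMIDOMETHYL_MASS = monoisotopic_mass("C2H3NO")
#: N-terminal acetylation, +C2H2O.
ACETYL_MASS = monoisotopic_mass("C2H2O")
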