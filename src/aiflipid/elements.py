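"""Elemental formulas and monoisotopic mass arithmetic.

Monoisotopic atomic masses are embedded (NIST/CODATA values, >= 7 decimals)
so that every ion m/z the package reports is reproducible to three decimals
without an external mass table.  Charged formulas include the electron-mass
correction (one electron added per negative charge, removed per positive).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = ["ATOMIC_MASS", "ELECTRON_MASS", "Formula"]

# Monoisotopic masses of the elements used in (phospho)lipid chemistry, Da.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

ELECTRON_MASS: float = 0.000548579909  # Da

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental formula with an optional integer charge.

    Immutable; addition and subtraction return new formulas.  Subtraction
    raises if any element count would go negative — formula arithmetic on
    real molecules never does.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in dict(self.counts).items() if n != 0}
        for el, n in clean.items():
            if el not in ATOMIC_MASS:
                raise ValueError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str, charge: int = 0) -> "Formula":
        """Parse a Hill-style formula string such as ``C9H19O11P``."""
        counts: Counter[str] = Counter()
        pos = 0
        for m in _TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at {pos}")
            counts[m.group(1)] += int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at {pos}")
        return cls(counts, charge)

    def __add__(self, other: "Formula") -> "Formula":
        counts = Counter(self.counts)
        counts.update(other.counts)
        return Formula(counts, self.charge + other.charge)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = Counter(self.counts)
        counts.subtract(other.counts)
        if any(n < 0 for n in counts.values()):
            bad = [el for el, n in counts.items() if n < 0]
            raise ValueError(f"subtraction yields negative counts for {bad}")
        return Formula(counts, self.charge - other.charge)

    def __mul__(self, k: int) -> "Formula":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        return Formula({el: n * k for el, n in self.counts.items()}, self.charge * k)

    __rmul__ = __mul__

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self.counts.items()))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        body = "".join(f"{el}{self.counts[el] if self.counts[el] != 1 else ''}" for el in order)
        return body or "∅"

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da, electron-corrected for the charge."""
        m = sum(ATOMIC_MASS[el] * n for el, n in self.counts.items())
        return m - self.charge * ELECTRON_MASS

    @property
    def mz(self) -> float:
        """m/z of a charged formula (mass over |charge|)."""
        if self.charge == 0:
            raise ValueError("m/z undefined for a neutral formula")
        return self.mass / abs(self.charge)


def monoisotopic_mass(formula: Formula) -> float:
    """Functional alias for :attr:`Formula.mass`."""
    return formula.mass
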