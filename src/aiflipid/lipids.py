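"""Lipid shorthand, neutral formulas and ion m/z.

Shorthand follows the Liebisch-style nomenclature used throughout HILIC
lipidomics: ``PC 14:0/16:0`` is chain-resolved (sn-positions known),
``PC 30:0`` is a sum composition, ``LPC 17:0/0:0`` marks the empty sn
position of a lyso species, ``PC O-38:6`` the ether (plasmanyl/plasmenyl)
subclass, and ``SM d18:1/16:0`` a sphingolipid with explicit sphingoid base.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Sequence

import yaml

from .elements import ELECTRON_MASS, ATOMIC_MASS, Formula

__all__ = [
    "LipidClass",
    "IonType",
    "ION_TYPES",
    "LipidSpecies",
    "ParseError",
    "parse_shorthand",
    "format_shorthand",
    "formula_of",
    "ion_mz",
    "carboxylate_formula",
    "carboxylate_mz",
    "enumerate_candidates",
    "CLASS_TABLE",
]


class ParseError(ValueError):
    """Raised when a shorthand name cannot be parsed."""


class LipidClass(str, Enum):
    PG = "PG"
    PI = "PI"
    PA = "PA"
    PE = "PE"
    PS = "PS"
    LPE = "LPE"
    PC = "PC"
    SM = "SM"
    LPC = "LPC"
    Cer = "Cer"
    Hex1Cer = "Hex1Cer"
    Hex2Cer = "Hex2Cer"
    Hex3Cer = "Hex3Cer"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class _ClassInfo:
    lipid_class: LipidClass
    long_name: str
    core: Formula | None          # glycerophospholipid backbone, None for sphingolipids
    n_acyl: int
    choline: bool
    elution_rank: int
    ions: tuple[str, ...]
    sphingo_headgroup: Formula | None = None
    hexoses: int = 0

    @property
    def is_sphingolipid(self) -> bool:
        return self.core is None

    @property
    def is_lyso(self) -> bool:
        return self.core is not None and self.n_acyl == 1


def _load_class_table() -> dict[LipidClass, _ClassInfo]:
    text = resources.files(__package__).joinpath("data/lipid_classes.yaml").read_text()
    raw = yaml.safe_load(text)
    table: dict[LipidClass, _ClassInfo] = {}
    for token, row in raw["classes"].items():
        cls = LipidClass(token)
        sph = row.get("sphingo")
        table[cls] = _ClassInfo(
            lipid_class=cls,
            long_name=row["name"],
            core=Formula.parse(row["core"]) if row.get("core") else None,
            n_acyl=row["n_acyl"],
            choline=row["choline"],
            elution_rank=row["elution_rank"],
            ions=tuple(row["ions"]),
            sphingo_headgroup=(
                Formula.parse(sph["headgroup"]) if sph and sph.get("headgroup") else None
            ),
            hexoses=sph["hexoses"] if sph else 0,
        )
    return table


CLASS_TABLE: dict[LipidClass, _ClassInfo] = _load_class_table()
_RAW_TABLE = yaml.safe_load(
    resources.files(__package__).joinpath("data/lipid_classes.yaml").read_text()
)

_H = Formula({"H": 1})
_H2O = Formula({"H": 2, "O": 1})
_CH3 = Formula({"C": 1, "H": 3})
_HEXOSE_ANHYDRO = Formula({"C": 6, "H": 10, "O": 5})  # dehydrated hexose, 162.0528 Da


@dataclass(frozen=True)
class IonType:
    """An ionization mode: name, mass delta (Da, electron-corrected), charge sign."""

    name: str
    mass_delta: float
    charge_sign: int
    choline_only: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def _delta(add: Formula | None = None, remove: Formula | None = None, charge: int = 0) -> float:
    d = 0.0
    if add is not None:
        d += add.mass
    if remove is not None:
        d -= remove.mass
    return d - charge * ELECTRON_MASS


ION_TYPES: dict[str, IonType] = {
    "[M+H]+": IonType("[M+H]+", _delta(add=_H, charge=+1), +1),
    "[M+Na]+": IonType("[M+Na]+", _delta(add=Formula({"Na": 1}), charge=+1), +1),
    "[M-H]-": IonType("[M-H]-", _delta(remove=_H, charge=-1), -1),
    "[M-CH3]-": IonType("[M-CH3]-", _delta(remove=_CH3, charge=-1), -1, choline_only=True),
    "[M+HCOO]-": IonType(
        "[M+HCOO]-", _delta(add=Formula.parse("CHO2"), charge=-1), -1
    ),
    "[M+CH3COO]-": IonType(
        "[M+CH3COO]-", _delta(add=Formula.parse("C2H3O2"), charge=-1), -1
    ),
}


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at shorthand resolution: class, acyl chains, structural flags.

    ``chains`` holds (carbons, double_bonds) pairs.  For a sum composition it
    holds the single class-level total; ``sn_known`` is then False.
    ``sphingoid`` is the long-chain base of a sphingolipid when stated.
    """

    lipid_class: LipidClass
    chains: tuple[tuple[int, int], ...]
    sn_known: bool = False
    ether: bool = False
    sphingoid: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        info = CLASS_TABLE[self.lipid_class]
        if not self.chains:
            raise ValueError("species needs at least one chain entry")
        for c, d in self.chains:
            if c < 2:
                raise ValueError(f"chain needs >= 2 carbons, got {c}")
            if d < 0 or d > c // 2:
                raise ValueError(f"chain {c}:{d} violates double-bond limit")
        if self.sn_known and not info.is_sphingolipid and len(self.chains) != info.n_acyl:
            raise ValueError(
                f"{self.lipid_class.value} is chain-resolved with {len(self.chains)} "
                f"chains but the class takes {info.n_acyl}"
            )
        if self.ether and info.is_sphingolipid:
            raise ValueError("ether subclass applies to glycerophospholipids only")

    @property
    def info(self) -> _ClassInfo:
        return CLASS_TABLE[self.lipid_class]

    @property
    def total_composition(self) -> tuple[int, int]:
        c = sum(ch[0] for ch in self.chains)
        d = sum(ch[1] for ch in self.chains)
        return c, d

    def __str__(self) -> str:
        return format_shorthand(self)


_NAME = re.compile(
    r"""^\s*
        (?P<cls>[A-Za-z][A-Za-z0-9]*)
        \s+
        (?P<ether>O-\s?)?
        (?P<chains>d?\d+:\d+(?:/\d+:\d+)?)
        \s*$""",
    re.VERBOSE,
)


def parse_shorthand(name: str) -> LipidSpecies:
    """Parse Liebisch-style lipid shorthand into a :class:`LipidSpecies`.

    ``"0:0"`` denotes the empty sn position of a lyso species; a single
    ``c:d`` pair is a sum composition (``sn_known`` False); a leading ``d``
    on the first pair of a sphingolipid marks the sphingoid base.
    """
    m = _NAME.match(name)
    if not m:
        raise ParseError(f"cannot parse lipid shorthand {name!r}")
    token = m.group("cls")
    alias = {"HexCer": "Hex1Cer"}
    token = alias.get(token, token)
    try:
        cls = LipidClass(token)
    except ValueError:
        raise ParseError(f"unknown lipid class token {token!r}") from None
    info = CLASS_TABLE[cls]

    chain_text = m.group("chains")
    sphingoid: tuple[int, int] | None = None
    if chain_text.startswith("d"):
        if not info.is_sphingolipid:
            raise ParseError(f"sphingoid base notation invalid for class {cls.value}")
        parts = chain_text[1:].split("/")
        sphingoid = _parse_pair(parts[0], name)
        pairs = [_parse_pair(p, name) for p in parts[1:]]
        if not pairs:
            raise ParseError(f"sphingolipid {name!r} needs an N-acyl chain after the base")
        return LipidSpecies(cls, tuple(pairs), sn_known=True, sphingoid=sphingoid)

    pairs = [_parse_pair(p, name) for p in chain_text.split("/")]
    sn_known = len(pairs) > 1
    pairs = [p for p in pairs if p != (0, 0)]
    if not pairs:
        raise ParseError(f"{name!r} has no non-empty chain")
    if sn_known and info.is_lyso and len(pairs) != 1:
        raise ParseError(f"lyso class {cls.value} takes exactly one acyl chain")
    return LipidSpecies(
        cls, tuple(pairs), sn_known=sn_known, ether=m.group("ether") is not None
    )


def _parse_pair(text: str, context: str) -> tuple[int, int]:
    c_str, d_str = text.split(":")
    c, d = int(c_str), int(d_str)
    if (c, d) != (0, 0) and (c < 2 or d > c // 2):
        raise ParseError(f"invalid chain {text!r} in {context!r}")
    return c, d


def format_shorthand(species: LipidSpecies) -> str:
    """Inverse of :func:`parse_shorthand` (canonical spelling)."""
    info = species.info
    cls = species.lipid_class.value
    ether = "O-" if species.ether else ""
    if species.sphingoid is not None:
        base = f"d{species.sphingoid[0]}:{species.sphingoid[1]}"
        chains = "/".join(f"{c}:{d}" for c, d in species.chains)
        return f"{cls} {base}/{chains}"
    chains = "/".join(f"{c}:{d}" for c, d in species.chains)
    if species.sn_known and info.is_lyso:
        chains += "/0:0"
    return f"{cls} {ether}{chains}"


def _acyl(c: int, d: int) -> Formula:
    """Fatty-acyl residue: FA (CcH2c-2dO2) condensed, i.e. minus H2O."""
    return Formula({"C": c, "H": 2 * c - 2 * d - 2, "O": 1})


def fatty_acid_formula(c: int, d: int) -> Formula:
    """Free fatty acid CcH(2c-2d)O2."""
    if c < 2:
        raise ValueError(f"fatty acid needs >= 2 carbons, got {c}")
    if d < 0 or 2 * d > 2 * c - 2:
        raise ValueError(f"fatty acid {c}:{d} violates double-bond limit")
    return Formula({"C": c, "H": 2 * c - 2 * d, "O": 2})


DEFAULT_SPHINGOID = (18, 1)  # sphingosine, the dominant base in plasma


def _sphingoid_base(c: int, d: int) -> Formula:
    """Dihydroxy ("d") long-chain base CcH(2c+3-2d)NO2 (d18:1 = sphingosine)."""
    return Formula({"C": c, "H": 2 * c + 3 - 2 * d, "N": 1, "O": 2})


def formula_of(species: LipidSpecies) -> Formula:
    """Neutral elemental formula of a lipid species.

    Glycerophospholipids: class core + one condensed acyl residue per chain;
    an ether species swaps one ester linkage for an alkyl one (net -O +2H).
    Sphingolipids: ceramide = base + FA - H2O, then the class headgroup
    (phosphocholine for SM, n anhydro-hexoses for cerebrosides).
    """
    info = species.info
    if info.is_sphingolipid:
        base = species.sphingoid or DEFAULT_SPHINGOID
        if species.sphingoid is None:
            # sum composition: stated totals include the base
            tot_c, tot_d = species.total_composition
            fa_c, fa_d = tot_c - base[0], tot_d - base[1]
        else:
            (fa_c, fa_d), = species.chains
        if fa_c < 2 or fa_d < 0:
            raise ValueError(f"cannot split {species} into base + N-acyl chain")
        cer = _sphingoid_base(*base) + fatty_acid_formula(fa_c, fa_d) - _H2O
        if info.sphingo_headgroup is not None:
            return cer + info.sphingo_headgroup - _H2O
        return cer + info.hexoses * _HEXOSE_ANHYDRO

    if info.core is None:  # pragma: no cover - table guards this
        raise ValueError(f"class {species.lipid_class.value} has no defined core")
    if species.sn_known or len(species.chains) > 1:
        acyls = [_acyl(c, d) for c, d in species.chains]
        total = info.core
        for a in acyls:
            total = total + a
    else:
        # sum composition: n_acyl condensations with the stated totals
        c, d = species.chains[0]
        n = info.n_acyl
        total = info.core + Formula({"C": c, "H": 2 * c - 2 * d - 2 * n, "O": n})
    if species.ether:
        total = total + Formula({"H": 2}) - Formula({"O": 1})
    return total


def ion_mz(species: LipidSpecies | Formula, ion: IonType | str) -> float:
    """m/z of a species (or neutral formula) under the given ion type.

    Enforces the chemistry of [M-CH3]-: it exists only for choline-bearing
    classes (PC, LPC, SM), where in-source dissociation of the formate or
    acetate adduct removes a methyl from the quaternary amine.
    """
    if isinstance(ion, str):
        ion = ION_TYPES[ion]
    if isinstance(species, Formula):
        neutral = species
    else:
        if ion.choline_only and not species.info.choline:
            raise ValueError(
                f"{ion.name} requires a choline headgroup; "
                f"{species.lipid_class.value} has none"
            )
        neutral = formula_of(species)
    return (neutral.mass + ion.mass_delta) / 1


def carboxylate_formula(carbons: int, double_bonds: int) -> Formula:
    """[RCOO]- carboxylate anion of the (carbons:double_bonds) fatty acid."""
    if carbons < 2:
        raise ValueError(f"carboxylate needs >= 2 carbons, got {carbons}")
    h = 2 * carbons - 1 - 2 * double_bonds
    if double_bonds < 0 or double_bonds > (carbons - 1) / 2:
        raise ValueError(f"chain {carbons}:{double_bonds} violates double-bond limit")
    return Formula({"C": carbons, "H": h, "O": 2}, charge=-1)


def carboxylate_mz(carbons: int, double_bonds: int) -> float:
    """m/z of the fatty-acyl carboxylate anion, electron mass included."""
    return carboxylate_formula(carbons, double_bonds).mz


def enumerate_candidates(
    lipid_class: LipidClass,
    carbon_range: tuple[int, int],
    db_range: tuple[int, int],
    ions: Sequence[IonType | str],
) -> list[tuple[LipidSpecies, IonType, float]]:
    """Exhaustive sum-composition candidate list for accurate-mass matching.

    Both even and odd total carbon numbers are enumerated (odd acyl chains
    occur in plasma).  Results are sorted by m/z.
    """
    info = CLASS_TABLE[lipid_class]
    ion_objs = [ION_TYPES[i] if isinstance(i, str) else i for i in ions]
    out: list[tuple[LipidSpecies, IonType, float]] = []
    min_c_per_chain = 2 * info.n_acyl
    for c in range(carbon_range[0], carbon_range[1] + 1):
        if c < min_c_per_chain:
            continue
        for d in range(db_range[0], db_range[1] + 1):
            if d < 0 or d > c // 2:
                continue
            sp = LipidSpecies(lipid_class, ((c, d),), sn_known=False)
            for ion in ion_objs:
                if ion.choline_only and not info.choline:
                    continue
                try:
                    mz = ion_mz(sp, ion)
                except ValueError:
                    continue
                out.append((sp, ion, mz))
    out.sort(key=lambda t: t[2])
    return out


def elution_rank(lipid_class: LipidClass) -> int:
    """HILIC head-group elution order (PG < PI < PE < LPE < PC < SM < LPC)."""
    return CLASS_TABLE[lipid_class].elution_rank
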