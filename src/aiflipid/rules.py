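"""AIF/CID fragmentation chemistry of phospho- and sphingolipids.

Negative-mode CID of glycerophospholipid anions releases each acyl chain as
its carboxylate [RCOO]-, and produces the complementary neutral losses of
the free fatty acid ([M-H-FA]-) and of the ketene ([M-H-FA+H2O]-).  PI ions
additionally lose dehydrated inositol (162.0528 Da) from either loss ion.
Positive-mode AIF produces class head fragments (phosphocholine m/z 184.073)
and, for sphingolipids, the doubly dehydrated sphingoid-base cation.

The sn-position heuristic: losses involving the sn-1 chain give weaker
signals than losses of the sn-2 chain, with sn-2/sn-1 carboxylate intensity
ratios typically 1.1-1.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Mapping

import yaml

from .elements import ELECTRON_MASS, Formula
from .lipids import (
    CLASS_TABLE,
    DEFAULT_SPHINGOID,
    IonType,
    ION_TYPES,
    LipidClass,
    LipidSpecies,
    _sphingoid_base,
    fatty_acid_formula,
    formula_of,
    ion_mz,
)

__all__ = [
    "DiagnosticIon",
    "FragmentKind",
    "PredictedFragment",
    "diagnostic_table",
    "diagnostics_for",
    "predict_fragments",
    "sn_assignment_rule",
    "INOSITOL_ANHYDRO_MASS",
]

_H2O = Formula({"H": 2, "O": 1})
INOSITOL_ANHYDRO_MASS = Formula({"C": 6, "H": 10, "O": 5}).mass  # 162.0528 Da

# Default sn-2/sn-1 carboxylate intensity bias; observed range 1.1-1.5.
SN_BIAS_DEFAULT = 1.3
SN_BIAS_RANGE = (1.1, 1.5)


@dataclass(frozen=True)
class DiagnosticIon:
    """A class-diagnostic fragment ion observed in AIF scans."""

    label: str
    lipid_classes: frozenset[LipidClass]
    polarity: int
    formula: Formula
    note: str = ""

    @property
    def mz(self) -> float:
        return (self.formula.mass - self.polarity * ELECTRON_MASS) / 1


class FragmentKind(str, Enum):
    carboxylate = "carboxylate"
    FA_loss = "FA_loss"
    ketene_loss = "ketene_loss"
    inositol_loss_after_FA = "inositol_loss_after_FA"
    inositol_loss_after_ketene = "inositol_loss_after_ketene"
    head_fragment = "head_fragment"
    sphingoid_fragment = "sphingoid_fragment"


@dataclass(frozen=True)
class PredictedFragment:
    parent: LipidSpecies
    parent_ion: IonType
    kind: FragmentKind
    mz: float
    chain: tuple[int, int] | None = None
    sn_hint: str | None = None  # "sn1" | "sn2" | None
    label: str = ""


def _load_diagnostics() -> tuple[DiagnosticIon, ...]:
    text = resources.files("aiflipid").joinpath("data/lipid_classes.yaml").read_text()
    raw = yaml.safe_load(text)
    out = []
    for row in raw["diagnostics"]:
        out.append(
            DiagnosticIon(
                label=row["label"],
                lipid_classes=frozenset(LipidClass(c) for c in row["classes"]),
                polarity=int(row["polarity"]),
                formula=Formula.parse(row["formula"]),
                note=row.get("note", ""),
            )
        )
    return tuple(out)


_DIAGNOSTICS: tuple[DiagnosticIon, ...] = _load_diagnostics()


def diagnostic_table() -> list[DiagnosticIon]:
    """All known class-diagnostic AIF ions (m/z recomputed from formulas)."""
    return list(_DIAGNOSTICS)


def diagnostics_for(lipid_class: LipidClass, polarity: int) -> list[DiagnosticIon]:
    """Diagnostic ions applicable to one class in one polarity.

    Classes without a diagnostic in the requested polarity (PG, PS, PA
    negative mode) return an empty list: they are annotated by accurate
    precursor mass and retention band only ("mass-only").
    """
    return [
        d
        for d in _DIAGNOSTICS
        if lipid_class in d.lipid_classes and d.polarity == polarity
    ]


def predict_fragments(
    species: LipidSpecies, ion: IonType | str, min_mz: float = 50.0
) -> list[PredictedFragment]:
    """Predict the AIF fragment ions of one lipid precursor ion.

    Negative-mode glycerophospholipids yield one carboxylate per acyl chain
    plus the FA- and ketene-loss ions; PI adds the dehydrated-inositol
    follow-up losses.  Positive mode yields head fragments; sphingolipids
    yield the [base + H - 2 H2O]+ cation.  Fragments below ``min_mz`` or
    above the precursor m/z are suppressed.
    """
    if isinstance(ion, str):
        ion = ION_TYPES[ion]
    info = species.info
    frags: list[PredictedFragment] = []

    parent_mz = ion_mz(species, ion)
    chains = _resolved_chains(species)

    if ion.charge_sign < 0:
        if not info.is_sphingolipid:
            for idx, (c, d) in enumerate(chains):
                sn = _sn_hint(species, idx)
                fa = fatty_acid_formula(c, d)
                cx = Formula(dict(fa.counts, H=fa.counts["H"] - 1), charge=-1)
                frags.append(
                    PredictedFragment(
                        species, ion, FragmentKind.carboxylate, cx.mz, (c, d), sn,
                        label=f"FA C{c}:{d} carboxylate",
                    )
                )
                fa_loss = parent_mz - fa.mass
                ket_loss = parent_mz - (fa.mass - _H2O.mass)
                frags.append(
                    PredictedFragment(
                        species, ion, FragmentKind.FA_loss, fa_loss, (c, d), sn,
                        label=f"- FA C{c}:{d}",
                    )
                )
                frags.append(
                    PredictedFragment(
                        species, ion, FragmentKind.ketene_loss, ket_loss, (c, d), sn,
                        label=f"- ketene C{c}:{d}",
                    )
                )
                if species.lipid_class is LipidClass.PI:
                    frags.append(
                        PredictedFragment(
                            species, ion, FragmentKind.inositol_loss_after_FA,
                            fa_loss - INOSITOL_ANHYDRO_MASS, (c, d), sn,
                            label=f"- FA C{c}:{d} - anhydroinositol",
                        )
                    )
                    frags.append(
                        PredictedFragment(
                            species, ion, FragmentKind.inositol_loss_after_ketene,
                            ket_loss - INOSITOL_ANHYDRO_MASS, (c, d), sn,
                            label=f"- ketene C{c}:{d} - anhydroinositol",
                        )
                    )
        for diag in diagnostics_for(species.lipid_class, -1):
            frags.append(
                PredictedFragment(
                    species, ion, FragmentKind.head_fragment, diag.mz, None, None,
                    label=diag.label,
                )
            )
    else:
        for diag in diagnostics_for(species.lipid_class, +1):
            kind = (
                FragmentKind.sphingoid_fragment
                if "sphing" in diag.label
                else FragmentKind.head_fragment
            )
            if kind is FragmentKind.sphingoid_fragment:
                # emit only the trace matching this species' own base
                base = species.sphingoid or DEFAULT_SPHINGOID
                base_frag = _sphingoid_base(*base) + Formula({"H": 1}) - 2 * _H2O
                base_frag = Formula(base_frag.counts, charge=+1)
                if abs(base_frag.mz - diag.mz) > 0.001:
                    continue
            frags.append(
                PredictedFragment(
                    species, ion, kind, diag.mz, None, None, label=diag.label
                )
            )

    return [f for f in frags if min_mz <= f.mz <= parent_mz]


def _resolved_chains(species: LipidSpecies) -> tuple[tuple[int, int], ...]:
    """Chains usable for fragment prediction; sum compositions stay as the
    class total when the class is lyso (single chain), else are not split."""
    info = species.info
    if species.sn_known or info.n_acyl == 1 or len(species.chains) == info.n_acyl:
        return species.chains
    return species.chains  # sum composition of a diacyl class: single total entry


def _sn_hint(species: LipidSpecies, idx: int) -> str | None:
    if not species.sn_known:
        return None
    if species.info.is_lyso:
        return "sn1"
    return f"sn{idx + 1}"


def sn_assignment_rule(
    loss_intensities: Mapping[tuple[int, int], tuple[float, float]],
) -> dict[tuple[int, int], str]:
    """Assign sn positions from FA-loss / ketene-loss signal intensities.

    The chain whose combined FA + ketene loss signals are *lower* sits at
    sn-1; the other at sn-2.  A lyso input (one chain) is sn-1 by
    convention; ties or missing signals return "unknown".
    """
    chains = list(loss_intensities)
    if len(chains) == 1:
        return {chains[0]: "sn1"}
    if len(chains) != 2:
        raise ValueError("sn assignment needs one or two chains")
    totals = {ch: sum(loss_intensities[ch]) for ch in chains}
    a, b = chains
    if totals[a] == totals[b]:
        return {a: "unknown", b: "unknown"}
    lo, hi = (a, b) if totals[a] < totals[b] else (b, a)
    return {lo: "sn1", hi: "sn2"}
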