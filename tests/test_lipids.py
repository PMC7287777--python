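"""Shorthand parsing, formula construction and ion m/z."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aiflipid.elements import Formula
from aiflipid.lipids import (
    ION_TYPES,
    LipidClass,
    LipidSpecies,
    ParseError,
    carboxylate_mz,
    enumerate_candidates,
    format_shorthand,
    formula_of,
    ion_mz,
    parse_shorthand,
)


@pytest.mark.parametrize(
    "name, cls, chains, sn_known",
    [
        ("PC 14:0/16:0", LipidClass.PC, ((14, 0), (16, 0)), True),
        ("LPE 13:0/0:0", LipidClass.LPE, ((13, 0),), True),
        ("PC 30:0", LipidClass.PC, ((30, 0),), False),
        ("PI 18:0/20:4", LipidClass.PI, ((18, 0), (20, 4)), True),
    ],
)
def test_parse_shorthand(name, cls, chains, sn_known):
    sp = parse_shorthand(name)
    assert sp.lipid_class is cls
    assert sp.chains == chains
    assert sp.sn_known is sn_known


def test_parse_errors_name_the_problem():
    with pytest.raises(ParseError, match="XX"):
        parse_shorthand("XX 34:1")
    with pytest.raises(ParseError):
        parse_shorthand("PC 14:9/16:0")  # d > c/2
    with pytest.raises(ParseError):
        parse_shorthand("PC")


def test_formula_construction():
    assert str(formula_of(parse_shorthand("PE 14:0/14:0"))) == "C33H66NO8P"
    assert str(formula_of(parse_shorthand("LPC 17:0/0:0"))) == "C25H52NO7P"


def test_ether_rule_is_minus_O_plus_2H():
    diacyl = formula_of(parse_shorthand("PC 38:6"))
    ether = formula_of(parse_shorthand("PC O-38:6"))
    assert diacyl.counts == (ether + Formula({"O": 1}) - Formula({"H": 2})).counts
    # the ether protonated ion reproduces the positive-mode isobar
    assert ion_mz(parse_shorthand("PC O-38:6"), "[M+H]+") == pytest.approx(
        792.590, abs=5e-4
    )


def test_sum_composition_matches_chain_resolved_mass():
    assert ion_mz(parse_shorthand("PC 34:0"), "[M-CH3]-") == pytest.approx(
        ion_mz(parse_shorthand("PC 16:0/18:0"), "[M-CH3]-"), abs=1e-9
    )


def test_demethylated_ion_requires_choline():
    with pytest.raises(ValueError, match="choline"):
        ion_mz(parse_shorthand("PE 34:1"), "[M-CH3]-")


def test_carboxylate_validation():
    with pytest.raises(ValueError):
        carboxylate_mz(1, 0)
    with pytest.raises(ValueError):
        carboxylate_mz(4, 2)  # d > (c-1)/2


def test_sphingolipid_formulas():
    sm = parse_shorthand("SM d18:1/16:0")
    assert str(formula_of(sm)) == "C39H79N2O6P"
    # sum composition defaults to the d18:1 base
    assert formula_of(parse_shorthand("SM 34:1")).counts == formula_of(sm).counts


def test_lyso_class_takes_one_chain():
    with pytest.raises(ValueError):
        LipidSpecies(LipidClass.LPC, ((16, 0), (18, 1)), sn_known=True)


def test_enumerate_candidates_single_and_sorted():
    single = enumerate_candidates(LipidClass.PC, (34, 34), (0, 0), ["[M-CH3]-"])
    assert len(single) == 1
    assert single[0][2] == pytest.approx(746.571, abs=5e-4)

    pi = enumerate_candidates(LipidClass.PI, (38, 38), (4, 4), ["[M-H]-"])
    assert len(pi) == 1
    assert str(formula_of(pi[0][0])) == "C47H83O13P"

    assert enumerate_candidates(LipidClass.PC, (34, 33), (0, 0), ["[M-H]-"]) == []

    many = enumerate_candidates(LipidClass.PE, (30, 40), (0, 6), ["[M-H]-"])
    mzs = [m for *_, m in many]
    assert mzs == sorted(mzs)
    # odd carbon totals are enumerated too
    assert any(sp.total_composition[0] % 2 == 1 for sp, _, _ in many)


chain = st.tuples(st.integers(2, 26), st.integers(0, 6)).filter(lambda cd: cd[1] <= cd[0] // 2)


@settings(max_examples=150, deadline=None)
@given(
    cls=st.sampled_from([LipidClass.PC, LipidClass.PE, LipidClass.PG, LipidClass.PI]),
    chains=st.tuples(chain, chain),
    ether=st.booleans(),
)
def test_parse_format_roundtrip(cls, chains, ether):
    sp = LipidSpecies(cls, chains, sn_known=True, ether=ether)
    assert parse_shorthand(format_shorthand(sp)) == sp


@settings(max_examples=50, deadline=None)
@given(cls=st.sampled_from([LipidClass.LPC, LipidClass.LPE]), c=chain)
def test_lyso_roundtrip(cls, c):
    sp = LipidSpecies(cls, (c,), sn_known=True)
    text = format_shorthand(sp)
    assert text.endswith("/0:0")
    assert parse_shorthand(text) == sp
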