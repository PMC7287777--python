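# Lipid class table, version 1.
#
# Glycerophospholipid cores are the neutral glycero-phospho-X backbones the
# acyl chains condense onto (each acyl chain adds FA - H2O).  Elution rank
# encodes the HILIC head-group elution order (lower = earlier).  "choline"
# marks classes that form [M-CH3]- via in-source dissociation of their
# formate/acetate adducts.
version: 1
classes:
  PG:
    name: phosphatidylglycerol
    core: C6H15O8P
    n_acyl: 2
    choline: false
    elution_rank: 0
    ions: ["[M-H]-", "[M+H]+", "[M+Na]+"]
  PI:
    name: phosphatidylinositol
    core: C9H19O11P
    n_acyl: 2
    choline: false
    elution_rank: 1
    ions: ["[M-H]-", "[M+Na]+"]
  PA:
    name: phosphatidic acid
    core: C3H9O6P
    n_acyl: 2
    choline: false
    elution_rank: 2
    ions: ["[M-H]-", "[M+H]+"]
  PE:
    name: phosphatidylethanolamine
    core: C5H14NO6P
    n_acyl: 2
    choline: false
    elution_rank: 3
    ions: ["[M-H]-", "[M+H]+", "[M+Na]+"]
  PS:
    name: phosphatidylserine
    core: C6H14NO8P
    n_acyl: 2
    choline: false
    elution_rank: 4
    ions: ["[M-H]-", "[M+H]+"]
  LPE:
    name: lysophosphatidylethanolamine
    core: C5H14NO6P
    n_acyl: 1
    choline: false
    elution_rank: 5
    ions: ["[M-H]-", "[M+H]+"]
  PC:
    name: phosphatidylcholine
    core: C8H20NO6P
    n_acyl: 2
    choline: true
    elution_rank: 6
    ions: ["[M-CH3]-", "[M+HCOO]-", "[M+CH3COO]-", "[M+H]+", "[M+Na]+"]
  SM:
    name: sphingomyelin
    sphingo: {headgroup: C5H14NO4P, hexoses: 0}
    n_acyl: 1
    choline: true
    elution_rank: 7
    ions: ["[M-CH3]-", "[M+HCOO]-", "[M+CH3COO]-", "[M+H]+", "[M+Na]+"]
  LPC:
    name: lysophosphatidylcholine
    core: C8H20NO6P
    n_acyl: 1
    choline: true
    elution_rank: 8
    ions: ["[M-CH3]-", "[M+HCOO]-", "[M+CH3COO]-", "[M+H]+", "[M+Na]+"]
  Cer:
    name: ceramide
    sphingo: {headgroup: null, hexoses: 0}
    n_acyl: 1
    choline: false
    elution_rank: 9
    ions: ["[M+H]+", "[M-H]-", "[M+HCOO]-"]
  Hex1Cer:
    name: monohexosylceramide
    sphingo: {headgroup: null, hexoses: 1}
    n_acyl: 1
    choline: false
    elution_rank: 10
    ions: ["[M+H]+", "[M-H]-", "[M+HCOO]-"]
  Hex2Cer:
    name: dihexosylceramide
    sphingo: {headgroup: null, hexoses: 2}
    n_acyl: 1
    choline: false
    elution_rank: 11
    ions: ["[M+H]+", "[M-H]-", "[M+HCOO]-"]
  Hex3Cer:
    name: trihexosylceramide
    sphingo: {headgroup: null, hexoses: 3}
    n_acyl: 1
    choline: false
    elution_rank: 12
    ions: ["[M+H]+", "[M-H]-", "[M+HCOO]-"]

# Class-diagnostic fragment ions seen in AIF scans.  m/z is never stored: it
# is recomputed from the formula (with electron correction) at load time.
diagnostics:
  - label: phosphocholine head
    classes: [PC, LPC, SM]
    polarity: 1
    formula: C5H15NO4P
    note: protonated phosphocholine; dominant positive head fragment of choline lipids
  - label: demethylated glycerophosphocholine head
    classes: [PC, LPC]
    polarity: -1
    formula: C7H15NO5P
    note: negative-mode diagnostic of choline glycerophospholipids after CH3 loss
  - label: glycerophosphoethanolamine head
    classes: [PE, LPE]
    polarity: -1
    formula: C5H11NO5P
    note: negative-mode ethanolamine head fragment
  - label: inositol phosphate marker
    classes: [PI]
    polarity: -1
    formula: C6H10O8P
    note: dehydrated inositol-phosphate anion, PI class marker
  - label: C18-sphingosine base (-2 H2O)
    classes: [SM, Cer, Hex1Cer, Hex2Cer, Hex3Cer]
    polarity: 1
    formula: C18H34N
    note: doubly dehydrated d18:1 sphingoid cation; class-spanning sphingolipid trace
  - label: C16-sphingosine base (-2 H2O)
    classes: [SM, Cer, Hex1Cer, Hex2Cer, Hex3Cer]
    polarity: 1
    formula: C16H30N
    note: doubly dehydrated d16:1 sphingoid cation
  - label: C18-sphingadiene base (-2 H2O)
    classes: [SM, Cer, Hex1Cer, Hex2Cer, Hex3Cer]
    polarity: 1
    formula: C18H32N
    note: doubly dehydrated d18:2 sphingoid cation
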