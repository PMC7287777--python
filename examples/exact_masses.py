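"""Exact-mass calculators: shorthand -> formula -> ion m/z.

Parses lipid shorthand names, builds their neutral elemental formulas and
prints the ion m/z values used for annotation, plus fatty-acyl carboxylate
anions.  Every value is derived from the embedded monoisotopic atomic
masses with electron correction; the printed m/z are what an orbitrap
acquisition of these ions centroids to.
"""

from aiflipid import carboxylate_mz, formula_of, ion_mz, parse_shorthand

PRECURSORS = [
    ("PG 18:0/20:4", "[M-H]-"),
    ("PE 14:0/14:0", "[M-H]-"),
    ("LPE 13:0/0:0", "[M-H]-"),
    ("PC 16:0/18:0", "[M-CH3]-"),
    ("LPC 17:0/0:0", "[M-CH3]-"),
    ("PI 18:0/20:4", "[M-H]-"),
]

print(f"{'species':<14} {'ion':<10} {'formula':<14} {'m/z':>8}")
for name, ion in PRECURSORS:
    sp = parse_shorthand(name)
    print(f"{name:<14} {ion:<10} {str(formula_of(sp)):<14} {ion_mz(sp, ion):8.3f}")

print("\nfatty-acyl carboxylate anions [RCOO]-:")
for c, d in [(13, 0), (16, 0), (18, 0), (18, 1), (18, 2), (20, 3), (20, 4), (22, 6)]:
    print(f"  FA C{c}:{d}  {carboxylate_mz(c, d):8.3f}")
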