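"""Negative-mode fragment prediction and sn-position reading for PI.

Predicts the AIF/CID fragments of deprotonated PI 18:0/20:4: the two acyl
carboxylates, the FA and ketene neutral-loss ions and their dehydrated-
inositol follow-ups, then applies the sn-position heuristic (the chain
whose loss signals are weaker sits at sn-1).
"""

from aiflipid import parse_shorthand, predict_fragments, sn_assignment_rule

species = parse_shorthand("PI 18:0/20:4")
print(f"fragments of {species} [M-H]-:")
for frag in predict_fragments(species, "[M-H]-"):
    chain = f"C{frag.chain[0]}:{frag.chain[1]}" if frag.chain else ""
    print(f"  {frag.kind.value:<28} {chain:<7} {frag.mz:8.3f}  {frag.label}")

# loss intensities as an AIF spectrum would show them: losses of the sn-2
# chain are the prominent ones
observed = {(18, 0): (120.0, 150.0), (20, 4): (900.0, 1100.0)}
print("\nsn assignment from loss intensities:", sn_assignment_rule(observed))
print("(weaker FA+ketene losses -> sn-1, so C18:0 is sn-1 and C20:4 sn-2)")
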