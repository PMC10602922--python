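"""Design ERAs and toehold-exchange pairs for a crRNA spacer.

Builds a 22-nt spacer, designs a 7-nt 5'-toehold ERA and a toehold-exchange
(f=9, r=4) pair, and shows the feasibility bound that rejects a 5-nt reverse
toehold on a standard-length spacer.
"""

from eragate import (Alphabet, CrRNASpec, DesignError, NucleicSequence,
                     ToeholdDirection, build_duplex_layout, design_era,
                     design_te_era, full_activator)

crrna = CrRNASpec(NucleicSequence("ACGUACGUACGUACGUACGUAC", Alphabet.RNA,
                                  "spacer"))

era = design_era(crrna, ToeholdDirection.FIVE_PRIME, 7)
layout = build_duplex_layout(crrna, era, full_activator(crrna))
print(f"spacer   5'-{crrna.spacer.residues}-3'")
print(f"ERA      5'-{era.sequence.residues}-3'  (pairs spacer "
      f"positions {era.paired_span[0]}-{era.paired_span[1]})")
print(f"layout: {layout.toehold_direction.value} toehold, "
      f"f={layout.toehold_length_f} nt, bm={layout.bm_length} nt")
print("-> the activator nucleates on the 7 unpaired 5' nucleotides and "
      "displaces the ERA at the saturated rate.")

te_era, te_act = design_te_era(crrna, ToeholdDirection.THREE_PRIME, 9, 4)
te_layout = build_duplex_layout(crrna, te_era, te_act)
print(f"\nTE pair: f={te_layout.toehold_length_f} (3'), "
      f"r={te_layout.toehold_length_r} (5') -- accepted")
try:
    design_te_era(crrna, ToeholdDirection.THREE_PRIME, 9, 5)
except DesignError as exc:
    print(f"r=5 nt: {exc}")
print("-> a 22-nt spacer tolerates activator end-deletions only below 5 nt; "
      "larger reverse toeholds abolish Cas12a activation.")
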