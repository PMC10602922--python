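"""Effective displacement rates across toehold lengths and directions.

Prints the gated activation rate ladder: ~10-fold per forward-toehold
nucleotide until saturation at 7 nt (5'), with 3' toeholds behaving as if
2 nt shorter, plus the mismatch accelerations/penalties.
"""

from eragate import DuplexLayout, RateParams, ToeholdDirection, effective_rate

params = RateParams()


def layout(direction, f, era_mm=(), act_mm=()):
    return DuplexLayout(direction, f, 0, 22 - f, 22,
                        era_mismatch_distances=era_mm,
                        activator_mismatch_distances=act_mm)


print("toehold  5'-rate (/M/s)   3'-rate (/M/s)")
for f in range(1, 11):
    r5 = effective_rate(layout(ToeholdDirection.FIVE_PRIME, f), params)
    r3 = effective_rate(layout(ToeholdDirection.THREE_PRIME, f), params)
    print(f"{f:>4} nt   {r5:>12.3g}   {r3:>12.3g}")
print("-> the 6-nt/1-nt ratio is 1e5; a 7-nt 5' toehold reaches the "
      "saturated rate, while 3' toeholds lag by two decades.")

base = effective_rate(layout(ToeholdDirection.FIVE_PRIME, 4), params)
boosted = effective_rate(layout(ToeholdDirection.FIVE_PRIME, 4,
                                era_mm=(2,)), params)
print(f"\nERA mismatch at bm distance 2: {boosted / base:.0f}x acceleration")
penalized = effective_rate(layout(ToeholdDirection.FIVE_PRIME, 7,
                                  act_mm=(0,)), params)
sat = effective_rate(layout(ToeholdDirection.FIVE_PRIME, 7), params)
print(f"activator mismatch at distance 0: {sat / penalized:.0f}x slowdown")
print("-> eliminating an ERA mismatch early (not immediately) accelerates "
      "invasion ~100x; a toehold-proximal activator mismatch is what the "
      "single-nucleotide discrimination rides on.")
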