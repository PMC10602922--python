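"""Temporal isolation in a one-pot amplification + CRISPR assay.

Compares a short-toehold (delayed-activation) gate against an ungated
system when isothermal amplification and Cas12a trans-cleavage share one
vessel: early trans-cleavage destroys the amplification templates, so the
ungated arm starves itself of activator.
"""

from eragate import (DuplexLayout, EnergyModel, OnePotParams, RateParams,
                     ToeholdDirection, one_pot_reference_system,
                     simulate_one_pot)

rates, energy = RateParams(), EnergyModel()
system = one_pot_reference_system()
gated = DuplexLayout(ToeholdDirection.FIVE_PRIME, 5, 0, 17, 22)
ungated = DuplexLayout(ToeholdDirection.FIVE_PRIME, 7, 0, 15, 22)

print("arm       cleaved (nM)  amplicon (nM)  templates left (nM)")
for tag, layout in (("gated ", gated), ("no-ERA", ungated)):
    traj = simulate_one_pot(system, OnePotParams(target_present=True),
                            layout, rates, energy, t_end=7200.0)
    print(f"{tag}    {traj.c_cl[-1]:>8.1f}    {traj.species['amplicon'][-1]:>9.2f}"
          f"    {traj.species['template'][-1]:>12.3f}")

leak = OnePotParams(target_present=False)
quiet = simulate_one_pot(system, leak, gated, rates, energy, 7200.0)
import dataclasses
suppressed = simulate_one_pot(
    dataclasses.replace(system, e_background=0.5), leak, gated, rates,
    energy, 7200.0)
print(f"\nno-target leak amplicon: {quiet.species['amplicon'][-1]:.4f} nM "
      f"(no trans-cleavage) vs "
      f"{suppressed.species['amplicon'][-1]:.4f} nM (0.5 nM active enzyme)")
print("-> delaying activation preserves amplification (higher endpoint), "
      "while residual trans-cleavage suppresses amplification leak in "
      "no-target controls.")
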