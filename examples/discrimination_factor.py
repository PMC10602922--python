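"""Single-nucleotide discrimination by a gated Cas12a.

Simulates perfectly matched (PM) and single-mismatch (MM) activators against
a 4-nt 5'-toehold gate and prints the discrimination factor
DF = (F_PM - bg)/(F_MM - bg) at 20 min for mismatches at increasing
distance from the toehold.
"""

from eragate import (DuplexLayout, EnergyModel, RateParams, ReactionSystem,
                     ToeholdDirection, df_at_20min, observe_fluorescence,
                     reference_calibration, simulate_activation_cleavage)

calib, rates, energy = reference_calibration(), RateParams(), EnergyModel()
system = ReactionSystem()
kw = dict(rate_params=rates, energy=energy, t_end=1300.0)


def run(act_mm=()):
    layout = DuplexLayout(ToeholdDirection.FIVE_PRIME, 4, 0, 18, 22,
                          activator_mismatch_distances=act_mm)
    traj = simulate_activation_cleavage(system, layout, **kw)
    return observe_fluorescence(traj, calib, 0.0, seed=0)


pm = run()
bg = observe_fluorescence(
    simulate_activation_cleavage(ReactionSystem(c_activator0=0.0),
                                 DuplexLayout(ToeholdDirection.FIVE_PRIME, 4,
                                              0, 18, 22), **kw),
    calib, 0.0, seed=0)

print("mismatch distance from toehold   DF at 20 min")
for d in (0, 2, 5, 10, 15):
    res = df_at_20min(pm, run(act_mm=(d,)), bg)
    print(f"{d:>10} nt                     {res.df:>8.1f}")
print("-> toehold-proximal mismatches are discriminated strongly; the "
      "penalty decays with distance, which is exactly the kinetic "
      "footprint toehold exchange is designed to overcome.")
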