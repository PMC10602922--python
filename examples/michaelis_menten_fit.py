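"""Extract k_cat and K_M from simulated reporter titrations.

Runs pre-activated enzyme (1 nM) against seven reporter concentrations,
fits 600-s initial velocities by linear regression, converts them to nM/s,
and fits the Michaelis-Menten law.
"""

import numpy as np

from eragate import (DuplexLayout, EnergyModel, RateParams, ReactionSystem,
                     ToeholdDirection, fit_michaelis_menten, initial_velocity,
                     observe_fluorescence, reference_calibration,
                     simulate_activation_cleavage)

K_CAT, K_M, E0 = 0.05, 500.0, 1.0       # ground truth of this run
LEVELS = (31.25, 62.5, 125.0, 250.0, 500.0, 1000.0, 2000.0)
calib = reference_calibration()
layout = DuplexLayout(ToeholdDirection.FIVE_PRIME, 7, 0, 15, 22)

points = []
for s0 in LEVELS:
    system = ReactionSystem(c_complex0=0.0, c_activator0=0.0, c_reporter0=s0,
                            e_background=E0, k_cat=K_CAT, K_M=K_M)
    traj = simulate_activation_cleavage(system, layout, RateParams(),
                                        EnergyModel(), t_end=620.0)
    fl = observe_fluorescence(traj, calib, sigma_au=0.09, seed=int(s0))
    v = initial_velocity(fl, calib, window_s=600.0)
    points.append((s0, v))
    print(f"S = {s0:>7.2f} nM   v = {v:.5f} nM/s")

fit = fit_michaelis_menten(points, E0=E0)
print(f"\nfit: k_cat = {fit.k_cat:.4f} /s (truth {K_CAT}), "
      f"K_M = {fit.K_M:.1f} nM (truth {K_M:.0f}), "
      f"k_cat/K_M = {fit.kcat_over_KM:.3g} /M/s")
print("-> initial velocities follow the hyperbolic substrate dependence; "
      "the catalytic efficiency summarizes how a toehold layout throttles "
      "the effective enzyme activity.")
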