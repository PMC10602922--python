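"""Fit a fluorescence calibration and invert a trans-cleavage time course.

Generates noisy cleaved/uncleaved reporter titrations with the reference
slopes (0.14466 / 0.00007 AU/nM), refits them, then inverts a simulated
trajectory back into cleaved-reporter concentration.
"""

import numpy as np

from eragate import (DuplexLayout, EnergyModel, RateParams, ReactionSystem,
                     ToeholdDirection, fit_calibration, invert_fluorescence,
                     observe_fluorescence, reference_calibration,
                     simulate_activation_cleavage)

LEVELS = (31.25, 62.5, 125.0, 250.0, 500.0, 1000.0, 2000.0)
rng = np.random.default_rng(42)
truth = reference_calibration()

cleaved = [(c, truth.m_cl * c + rng.normal(0, 0.05)) for c in LEVELS]
uncleaved = [(c, truth.m_ucl * c + rng.normal(0, 0.005)) for c in LEVELS]
calib = fit_calibration(cleaved, uncleaved)
print(f"fitted slopes: m_cl = {calib.m_cl:.5f} AU/nM "
      f"(R2 {calib.r_squared_cl:.5f}), m_ucl = {calib.m_ucl:.5f} AU/nM")
print(f"inversion denominator m_cl - m_ucl = {calib.inversion_slope:.5f} AU/nM; "
      f"offset at c_0 = 125 nM: {calib.m_ucl * 125:.5f} AU")

layout = DuplexLayout(ToeholdDirection.FIVE_PRIME, 6, 0, 16, 22)
traj = simulate_activation_cleavage(ReactionSystem(c_reporter0=125.0), layout,
                                    RateParams(), EnergyModel(), t_end=1200.0)
fl = observe_fluorescence(traj, calib, sigma_au=0.05, seed=7)
conc = invert_fluorescence(fl, calib, c_0=125.0)
i = len(conc.times) // 2
print(f"\nat t = {conc.times[i]:.0f} s: F = {fl.values[i]:.3f} AU  ->  "
      f"c_cl = {conc.c_cl[i]:.2f} nM (simulated truth {traj.c_cl[i]:.2f} nM)")
print("-> the two-slope inversion recovers the cleaved-reporter "
      "concentration despite imperfect quenching of intact reporters.")
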