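"""Effective displacement rates, ODE dynamics and fluorescence observation."""

import dataclasses

import numpy as np
import pytest

from eragate import (
    OnePotParams,
    RateParams,
    ReactionSystem,
    closed_form_low_substrate,
    effective_rate,
    equilibrium_extent,
    observe_fluorescence,
    one_pot_reference_system,
    reaction_delta_g,
    simulate_activation_cleavage,
    simulate_one_pot,
)


class TestEffectiveRate:
    def test_toehold_6_vs_1_ratio_is_1e5(self, rates, layout_5p):
        ratio = (effective_rate(layout_5p(6), rates)
                 / effective_rate(layout_5p(1), rates))
        assert ratio == pytest.approx(1e5, rel=1e-12)

    def test_saturation_at_7nt(self, rates, layout_5p):
        assert effective_rate(layout_5p(7), rates) == pytest.approx(rates.k_max)
        assert effective_rate(layout_5p(10), rates) == pytest.approx(rates.k_max)
        assert effective_rate(layout_5p(7), rates) >= 0.8 * rates.k_max

    def test_monotone_in_toehold_length(self, rates, layout_5p):
        vals = [effective_rate(layout_5p(f), rates) for f in range(1, 11)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_three_prime_penalty_is_exact_offset(self, rates, layout_5p, layout_3p):
        for f in (3, 4, 5):
            ratio = (effective_rate(layout_5p(f), rates)
                     / effective_rate(layout_3p(f), rates))
            assert ratio == pytest.approx(
                rates.per_nt_factor ** rates.dir_offset_3p)

    def test_era_mismatch_peak_acceleration(self, rates, layout_5p):
        base = effective_rate(layout_5p(4), rates)
        peak = effective_rate(layout_5p(4, era_mm=(2,)), rates)
        assert peak / base == pytest.approx(rates.alpha_max)

    def test_immediate_elimination_gives_no_boost(self, rates):
        assert rates.alpha(0) == pytest.approx(1.0)
        assert rates.alpha(0) < rates.alpha(rates.d_star)

    def test_activator_mismatch_penalty_decays(self, rates, layout_5p):
        near = effective_rate(layout_5p(7, act_mm=(0,)), rates)
        far = effective_rate(layout_5p(7, act_mm=(14,)), rates)
        assert near < far < effective_rate(layout_5p(7), rates)
        assert effective_rate(layout_5p(7), rates) / near == pytest.approx(
            rates.beta_max)

    def test_ds_activator_multiplier(self, rates, layout_5p):
        ss = effective_rate(layout_5p(7), rates)
        ds = effective_rate(layout_5p(7), rates, double_stranded=True)
        assert ds / ss == pytest.approx(rates.gamma_ds)

    def test_no_toehold_no_activation(self, rates, layout_5p):
        layout = dataclasses.replace(layout_5p(1), toehold_length_f=0)
        assert effective_rate(layout, rates) == 0.0


class TestClosedForm:
    def test_boundary_values(self):
        assert closed_form_low_substrate(1, 1, 1, 500, 0.0) == 0.0
        assert closed_form_low_substrate(1, 1, 1, 500, 1e9) == pytest.approx(1.0)

    def test_half_life(self):
        t_half = 500.0 * np.log(2.0)
        assert closed_form_low_substrate(1.0, 1.0, 1.0, 500.0,
                                         t_half) == pytest.approx(0.5)


class TestActivationCleavage:
    def test_no_activator_no_product(self, rates, energy, layout_5p):
        system = ReactionSystem(c_activator0=0.0)
        traj = simulate_activation_cleavage(system, layout_5p(7), rates,
                                            energy, 1200.0)
        assert np.all(traj.c_cl == 0.0)

    def test_mass_conservation(self, rates, energy, layout_5p):
        system = ReactionSystem()
        traj = simulate_activation_cleavage(system, layout_5p(7), rates,
                                            energy, 2400.0)
        np.testing.assert_allclose(traj.c_cl + traj.c_ucl,
                                   system.c_reporter0, rtol=1e-6)
        enzyme_total = (traj.species["inactive_complex"]
                        + traj.species["active_enzyme"])
        np.testing.assert_allclose(enzyme_total, system.c_complex0, rtol=1e-6)

    def test_cleaved_fraction_nondecreasing(self, rates, energy, layout_5p):
        traj = simulate_activation_cleavage(ReactionSystem(), layout_5p(5),
                                            rates, energy, 2400.0)
        assert np.all(np.diff(traj.c_cl) >= -1e-6)  # solver tolerance

    @pytest.mark.parametrize("k_cat,K_M,S0,E0", [
        (1.0, 500.0, 1.0, 1.0),
        (0.5, 1000.0, 5.0, 2.0),
        (2.0, 2000.0, 10.0, 0.5),
    ])
    def test_low_substrate_matches_closed_form(self, rates, energy, layout_5p,
                                               k_cat, K_M, S0, E0):
        """Pre-activated enzyme at S0/K_M <= 0.01 follows the exponential law."""
        system = ReactionSystem(c_complex0=0.0, c_activator0=0.0,
                                c_reporter0=S0, e_background=E0,
                                k_cat=k_cat, K_M=K_M)
        traj = simulate_activation_cleavage(system, layout_5p(7), rates,
                                            energy, 2000.0)
        oracle = closed_form_low_substrate(E0, S0, k_cat, K_M, traj.times[1:])
        np.testing.assert_allclose(traj.c_cl[1:], oracle, rtol=0.01)

    def test_era_ratio_zero_means_uncontrolled(self, rates, energy, layout_5p):
        system = ReactionSystem(era_ratio=0.0)
        traj = simulate_activation_cleavage(system, layout_5p(7), rates,
                                            energy, 600.0)
        assert traj.species["active_enzyme"][0] == pytest.approx(
            system.c_complex0)

    def test_te_mode_reaches_equilibrium_extent(self, rates, energy, layout_5p):
        """With reversible displacement and cleavage idle, the long-time
        activated amount matches the thermodynamic extent within 2%."""
        te_rates = dataclasses.replace(rates, k_rev_mode="te_equilibrated")
        layout = layout_5p(5, r=5)
        system = ReactionSystem(c_complex0=20.0, c_activator0=20.0,
                                c_reporter0=1e-12, era_ratio=1.0)
        traj = simulate_activation_cleavage(system, layout, te_rates, energy,
                                            2e5, dt=2000.0)
        expected = equilibrium_extent(reaction_delta_g(layout, energy),
                                      20.0, 20.0, energy)
        assert traj.species["active_enzyme"][-1] == pytest.approx(expected,
                                                                  rel=0.02)


class TestObservation:
    def test_noise_free_uncleaved_baseline(self, rates, energy, calib, layout_5p):
        system = ReactionSystem(c_activator0=0.0, c_reporter0=125.0)
        traj = simulate_activation_cleavage(system, layout_5p(7), rates,
                                            energy, 600.0)
        fl = observe_fluorescence(traj, calib, 0.0, seed=0)
        np.testing.assert_allclose(fl.values, calib.m_ucl * 125.0)

    def test_full_cleavage_reference_signal(self, calib):
        from eragate.simulate import Trajectory
        times = np.arange(0.0, 100.0, 20.0)
        traj = Trajectory(times, {
            "reporter_cleaved": np.full_like(times, 125.0),
            "reporter_uncleaved": np.zeros_like(times),
        })
        fl = observe_fluorescence(traj, calib, 0.0, seed=0)
        assert fl.values[0] == pytest.approx(18.0825 + calib.m_ucl * 0.0)

    def test_seed_reproducibility(self, rates, energy, calib, layout_5p):
        traj = simulate_activation_cleavage(ReactionSystem(), layout_5p(7),
                                            rates, energy, 600.0)
        a = observe_fluorescence(traj, calib, 0.5, seed=7)
        b = observe_fluorescence(traj, calib, 0.5, seed=7)
        c = observe_fluorescence(traj, calib, 0.5, seed=8)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)


class TestOnePot:
    def test_no_amplification_no_signal(self, rates, energy, layout_5p):
        per = OnePotParams(k_amp=0.0, target_present=False)
        traj = simulate_one_pot(one_pot_reference_system(), per, layout_5p(5),
                                rates, energy, 3600.0)
        assert np.all(traj.c_cl == 0.0)
        assert np.all(traj.species["amplicon"] == 0.0)

    def test_zero_leak_matches_background_only(self, rates, energy, layout_5p):
        per = OnePotParams(leak_frac=0.0, target_present=False)
        system = dataclasses.replace(one_pot_reference_system(),
                                     e_background=0.1)
        traj = simulate_one_pot(system, per, layout_5p(5), rates, energy,
                                3600.0)
        ref = simulate_activation_cleavage(system, layout_5p(5), rates,
                                           energy, 3600.0)
        np.testing.assert_allclose(traj.c_cl, ref.c_cl, rtol=1e-6, atol=1e-9)

    def test_delayed_activation_beats_ungated_endpoint(self, rates, energy,
                                                       layout_5p):
        """Temporal isolation: a short-toehold gate preserves amplification
        templates, so the gated one-pot endpoint exceeds the ungated one."""
        per = OnePotParams(target_present=True)
        system = one_pot_reference_system()
        gated = simulate_one_pot(system, per, layout_5p(5), rates, energy,
                                 7200.0)
        ungated = simulate_one_pot(system, per, layout_5p(7), rates, energy,
                                   7200.0)
        assert gated.c_cl[-1] > ungated.c_cl[-1]
        assert gated.species["amplicon"][-1] > ungated.species["amplicon"][-1]
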