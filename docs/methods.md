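# Methods

This note documents the models implemented in `eragate`, the parameter
choices behind them, what the synthetic data generator does and does not
emulate, and the numerical decisions a user extending the package should
know about.

## The gating model

An ERA–crRNA–Cas12a complex is inert until a DNA activator displaces the ERA
from the spacer. We model this as a single effective second-order step

    C + A  →(k_eff)  E + ERA_free,

collapsing toehold binding, branch migration and protein conformational
steps into one rate constant determined by the duplex layout. Activated
enzyme E then cleaves the reporter with Michaelis–Menten kinetics. The full
system integrated by `simulate_activation_cleavage` is

    dC/dt = −k_eff·C·A + k_rev·E·ERA_free
    dE/dt = +k_eff·C·A − k_rev·E·ERA_free
    dP/dt = k_cat·E·S/(K_M + S),  S = c₀ − P,

with `k_rev = 0` for plain TMSD and `k_rev = k_eff·e^{ΔG_rxn/RT}` in
toehold-exchange mode, so the activated fraction relaxes to the
thermodynamic equilibrium extent. Sub-stoichiometric ERA (`era_ratio < 1`)
leaves a linear unprotected fraction of complexes active from t = 0; this is
the simplest reading of ratio-tunable activity, and it is configurable.

## The effective-rate law

`effective_rate` uses

    n_eff = f − (2 if 3′ toehold else 0)
    k_eff = k_max · 10^min(0, n_eff − 7) · Πα(d_ERA) / Πβ(d_act) · (γ_ds if ds)

Parameter choices, with defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| `k_max` | 1e6 | /M/s | saturated nucleic-acid strand-displacement scale |
| `per_nt_factor` | 10 | fold/nt | reproduces the canonical 10⁵ span between 6-nt and 1-nt toeholds |
| `n_sat_5p` | 7 | nt | 5′ toeholds reach ≥ 80% of saturation at 7 nt |
| `dir_offset_3p` | 2 | nt | 3′ toeholds barely activate below 7 nt; an integer effective-length offset reproduces that with one parameter |
| `alpha_max`, `d_star` | 100, 2 | fold, nt | eliminating an ERA mismatch *early but not immediately* accelerates invasion by about two orders of magnitude; the gamma-like bump `α(d) = 1+(α_max−1)(d/d*)e^{1−d/d*}` is an invented shape pinned only by α(0)=1 and the peak |
| `beta_max`, `lambda_m` | 50, 3 | fold, nt | toehold-proximal activator mismatches inhibit strongly; an exponential positional decay gives the kinetic discrimination footprint |
| `gamma_ds` | 0.3 | – | double-stranded activators are uniformly slower in this model; the observed 3′-toehold ds speed-up (a protein-conformation effect) is deliberately not modeled |

A hard saturation (`min(0, ·)`) rather than a logistic shoulder is used so
the 10⁵ ratio between the 6-nt and 1-nt rates is exact.

## Thermodynamics

`energetics` replaces sequence-level secondary-structure prediction with a
sequence-averaged per-nucleotide model: −2.1 kcal/mol per RNA:RNA stack,
−1.8 per RNA:DNA stack, −RT·ln10 = −1.364 kcal/mol per forward-toehold
nucleotide, +3.0 kcal/mol per mismatch (mid-range of single-mismatch
destabilizations; configurable). The net displacement reaction energy is

    ΔG_rxn = (r − f)·|ΔG_toehold| + Δ(mismatch penalties),

so a balanced exchange (f = r) sits at ΔG ≈ 0 where a single mismatch
anywhere flips the yield — the position-independent, thermodynamic
discrimination regime of toehold exchange. Enthalpy and entropy are not
separated; "ΔH ≈ 0" tuning is represented at the ΔG level. The equilibrium
extent solves the mass-action quadratic in closed form with a stable root
selection, clamping (with a warning) only when K over/underflows.

## Calibration and inversion

The observed signal is `F = m_cl·c_cl + m_ucl·c_ucl (+ background + noise)`.
With mass conservation this inverts to
`c_cl = (F_bgsub − m_ucl·c₀)/(m_cl − m_ucl)`. The reference slopes
0.14466/0.00007 AU/nM give the denominator 0.14459 AU/nM and, at
c₀ = 125 nM, the offset 0.00875 AU. One published form of this inversion
carries a denominator of 0.14446 that is inconsistent with the slope
difference; the implementation uses `m_cl − m_ucl` throughout and treats the
other figure as a typo. Calibration fits are zero-intercept least squares on
background-subtracted titrations (a free-intercept variant is available);
inversion clamps to [0, c₀] with per-point flags. Velocities use central
finite differences on the 20-s grid with no default smoothing. Background is
taken as the buffer-only reference attached to each series; a
no-activator-control background is the convention for discrimination
factors, since it includes the uncleaved-reporter signal.

## Kinetic fitting and its validity window

Initial velocities are the least-squares slope of the first 600 s converted
through 1/(m_cl − m_ucl); (k_cat, K_M) come from unweighted nonlinear least
squares of the hyperbola at known E₀. The end-to-end recovery study (and the
corresponding acceptance-suite test) uses k_cat = 0.05 /s, K_M = 500 nM,
E₀ = 1 nM: under these conditions at most ~6% of the reporter is consumed
inside the 600-s window, so the linear-regression velocity is an unbiased
initial rate. With a ten-fold faster enzyme the same protocol consumes most
of a low-concentration reporter series within the window and *no* linear
estimator recovers v₀ — a property of the protocol worth checking before
trusting fitted K_M values on real data. Measurement noise is modeled as a
constant instrument floor (default study value 0.0904 AU, 0.5% of the
125-nM assay's full-scale signal) rather than scaling with each well's
substrate load. When a layout is too slow for 1 nM enzyme to produce a
fittable 600-s change, the study convention switches to E₀ = 5 nM and
records it.

## Discrimination factors

`DF = (F_PM − bg)/(F_MM − bg)` evaluated at a chosen time (20 min by
convention). DF is invariant under a common gain and offset. A mismatched
signal within `epsilon_au` of background (default guard: 3× the estimated
noise SD) yields an explicit +∞ sentinel, excluded from replicate medians
with a count — never silently clipped. In the simulator, early-time DF
converges to the PM/MM effective-rate ratio while both trajectories remain
in the linear (< 10% cleaved) regime, which is the property the test suite
verifies.

## One-pot assays

`simulate_one_pot` adds a linear isothermal amplification stage producing
activator at `k_amp` per template (scaled by `leak_frac` without target) and
lets active enzyme destroy templates/primers by second-order trans-cleavage
at `template_cleavage_factor · k_cat/K_M`. The factor (default 500) encodes
that long unstructured ssDNA templates are vastly better trans-cleavage
substrates (catalytic efficiencies of 10⁸–10⁹ /M/s are typical) than the
compact fluorophore–quencher reporter (~10⁵–10⁶ /M/s); coupling both to the
reporter's efficiency would make template destruction implausibly slow
relative to signal generation and erase the negative-feedback effect the
assay design exists to escape. One-pot studies run at the one-pot protocol
conditions: 500 nM reporter, k_cat = 0.1 /s (the shared amplification
buffer is a compromise for Cas12a), 10 nM template, k_amp = 1e-4 /s,
two-hour readout, and a 5-nt 5′ toehold as the delayed-activation gate — a
4-nt gate delays so strongly that almost none of its preserved amplicon pool
converts to enzyme within the readout, while 5 nt realizes the
temporal-isolation regime (gated endpoint ≈ 1.5× the ungated one at these
conditions).

## Synthetic data

`generate_fixture_study` writes calibration titrations (31.25–2000 nM),
toehold panels (f = 1–10, both directions), ERA/activator mismatch panels,
TE panels, Michaelis–Menten titrations (E₀ = 1 and 5 nM), PM/MM/background
replicate triplets and one-pot scenarios, all at 20-s sampling with additive
Gaussian noise (0.05 AU default) and imperfect-quenching observation, fully
determined by one seed (byte-identical bundles). Spacer sequences are
synthetic random 22-/35-mers. What this emulates: trajectory shapes, noise
floors, replicate structure, condition labels. What it does not: sequence-
dependent thermodynamics and folding, pipetting/plate effects, instrument
drift or photobleaching, polymerase sequence chemistry, and the ds-activator
3′ anomaly. Passing tests therefore demonstrate correctness of the analysis
pipeline and internal consistency of the mechanistic model — not predictive
accuracy for any particular wet-lab sequence set.

## Numerical choices

ODEs are integrated with LSODA at rtol 1e-8 / atol 1e-12 nM on a fixed 20-s
output grid; mass conservation holds to 1e-6 relative, and concentrations
dipping below −1e-6 nM abort with an error. Exponentials in equilibrium and
reverse-rate expressions are clamped at ±700 before `exp`. Coordinates are
1-based from the spacer 5′ end; mismatch distances are 0-based from the
forward-toehold-proximal edge of the branch-migration domain, so flipping
the toehold direction maps offset *i* within the domain to distance
`bm − 1 − i`. Designed mismatches substitute the transversion partner
(A↔C, G↔U) of the complementary base — deterministic, and never a wobble
pair. The TE feasibility bound is implemented as a step function of spacer
length (4 nt below 35 nt, 19 nt at or above); intermediate spacer lengths
have not been characterized and inherit the conservative bound.

## Known limitations

- No sequence-dependent (nearest-neighbor) thermodynamics, salt or
  temperature corrections beyond RT scaling.
- No stochastic/single-molecule regime; deterministic mass action only.
- PAM search, R-loop formation and ds-activator unwinding are not resolved;
  the ds mode is one multiplier.
- The amplification stage is a coarse linear ODE, not a mechanistic primer
  exchange model.
- Reported DF magnitudes depend on the chosen background convention
  (no-activator control); absolute wet-lab DF tables are sequence- and
  instrument-specific and outside the model's claims.
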