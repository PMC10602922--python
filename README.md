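# eragate

Quantitative toolkit for **toehold-gated CRISPR/Cas12a**: controlling the
nuclease's indiscriminate *trans*-cleavage activity with an **external RNA
accessory (ERA)** — an RNA strand that pairs with part of the crRNA spacer and
must be displaced by the DNA activator through **toehold-mediated strand
displacement (TMSD)** before the enzyme switches on.

It is written for people building or analyzing gated CRISPR assays: nucleic
acid nanotechnologists tuning activation speed and single-nucleotide
specificity, and diagnostics developers coupling CRISPR readout to isothermal
amplification in one pot.

## What the package models

**Gating geometry.** An ERA pairing spacer positions `[a, b]` leaves unpaired
spacer nucleotides on one end — the forward toehold *f* (5′ toward the
PAM-interacting domain, or 3′ toward the Nuc domain). An activator
end-deletion leaves a reverse toehold *r* exposed after displacement
(toehold exchange, TE). `eragate.sequences` designs these strands and derives
the duplex layout, enforcing the empirical feasibility bounds (reverse
toeholds must stay < 5 nt on a 22-nt spacer; up to 19 nt once the spacer is
extended to 35 nt).

**Activation kinetics.** The effective second-order displacement rate is

    k_eff(f) = k_max · 10^min(0, n_eff − n_sat),   n_eff = f − Δ3′,

i.e. ten-fold per unsaturated toehold nucleotide saturating at `n_sat = 7`
(so the 6-nt/1-nt ratio is 10⁵), with 3′ toeholds behaving as if `Δ3′ = 2` nt
shorter. An ERA mismatch eliminated at branch-migration distance *d*
multiplies the rate by `α(d) = 1 + (α_max−1)(d/d*)e^{1−d/d*}` (peak 100× at
`d* = 2`, no boost at `d = 0`); an activator mismatch divides it by
`β(d) = 1 + (β_max−1)e^{−d/λ}` (50× at the toehold, decaying with distance).

**Enzyme kinetics.** Activated Cas12a cleaves a fluorophore–quencher reporter
under Michaelis–Menten kinetics, `v = k_cat E₀ [S]/(K_M + [S])`; at
`[S] ≪ K_M` the progress curve is `P(t) = S₀(1 − e^{−k_cat E₀ t/K_M})`.
The observed signal mixes both reporter pools (quenching is imperfect),
`F = m_cl·c_cl + m_ucl·c_ucl`, with reference slopes 0.14466 and
0.00007 AU/nM, so fluorescence inverts to concentration through the
denominator `m_cl − m_ucl = 0.14459` AU/nM.

**Analysis.** Calibration fitting and inversion (`eragate.calibration`),
600-s initial velocities and (k_cat, K_M) extraction (`eragate.kinetics`),
discrimination factors `DF = (F_PM − bg)/(F_MM − bg)` with replicate medians
(`eragate.discrimination`), a coarse per-nucleotide free-energy model of TE
reactions and their equilibrium yield (`eragate.energetics`), and a
seed-deterministic synthetic-study generator (`eragate.fixtures`).

## Worked example

```sh
python examples/michaelis_menten_fit.py
```

simulates 1 nM pre-activated enzyme against seven reporter concentrations,
fits the first 600 s of each noisy fluorescence trace, and recovers the
kinetic parameters:

```
S =   31.25 nM   v = 0.00198 nM/s
S =   62.50 nM   v = 0.00689 nM/s
...
S = 2000.00 nM   v = 0.04013 nM/s

fit: k_cat = 0.0486 /s (truth 0.05), K_M = 444.5 nM (truth 500), k_cat/K_M = 1.09e+05 /M/s
```

The velocities trace the Michaelis–Menten hyperbola; the fitted catalytic
efficiency `k_cat/K_M` is the single number by which a toehold layout
throttles effective enzyme activity. The other scripts in `examples/` walk
through strand design, the toehold rate ladder, calibration/inversion,
discrimination factors and the one-pot assay, each printing the quantities it
computes and one line on what they mean.

A thin CLI wraps the same pipelines:

```sh
eragate fixtures --seed 7 --out-dir fixtures/
eragate calibrate fixtures/titration_cleaved.csv fixtures/titration_uncleaved.csv --out calib.json
eragate df fixtures/df_triplets.csv --out df.json
```

## Layout

```
src/eragate/        sequences, energetics, simulate, calibration,
                    kinetics, discrimination, fixtures, io, cli
examples/           one narrative script per capability
tests/              pytest suite (unit, property and end-to-end checks)
docs/methods.md     model assumptions, parameter choices, limitations
```
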