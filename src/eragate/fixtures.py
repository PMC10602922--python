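"""Synthetic-study generation: a complete, seed-deterministic bundle of
calibration titrations, toehold/mismatch/TE panels, Michaelis-Menten
titrations, PM/MM replicate triplets and one-pot scenarios.

The bundle emulates 20-s-interval plate-reader trajectories of ERA-gated
Cas12a trans-cleavage at the standard assay conditions (20 nM gated complex,
40 nM activator, 250 nM reporter; 125 nM reporter and 1 nM pre-activated
enzyme for kinetics runs, 5 nM for slow layouts) with imperfect-quenching
observation and additive Gaussian noise.  The same seed reproduces the bundle
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import io as egio
from .calibration import reference_calibration
from .energetics import EnergyModel
from .sequences import (CrRNASpec, NucleicSequence, Alphabet, ToeholdDirection,
                        build_duplex_layout, design_era, design_te_era,
                        full_activator)
from .simulate import (OnePotParams, RateParams, ReactionSystem, Trajectory,
                       observe_fluorescence, one_pot_reference_system,
                       simulate_activation_cleavage, simulate_one_pot)

__all__ = ["generate_fixture_study", "random_spacer",
            "CALIBRATION_TITRATION_NM", "MM_TITRATION_NM"]

# reporter titration levels (nM) used for calibration and MM runs
CALIBRATION_TITRATION_NM = (31.25, 62.5, 125.0, 250.0, 500.0, 1000.0, 2000.0)
MM_TITRATION_NM = CALIBRATION_TITRATION_NM

_DEFAULT_SIGMA_AU = 0.05


def random_spacer(length: int, rng: np.random.Generator,
                  name: str = "spacer") -> CrRNASpec:
    """A synthetic RNA spacer; stands in for unavailable assay sequences."""
    residues = "".join(rng.choice(list("ACGU"), size=length))
    return CrRNASpec(NucleicSequence(residues, Alphabet.RNA, name=name))


def _child_seed(seed: int, index: int) -> int:
    return (seed * 100_003 + index) % (2**31 - 1)


class _Study:
    def __init__(self, seed: int, out_dir: Path):
        self.seed = seed
        self.out = out_dir
        self.calib = reference_calibration()
        self.energy = EnergyModel()
        self.rates = RateParams()
        self.manifest: dict[str, dict] = {}
        self._noise_counter = 0
        rng = np.random.default_rng(seed)
        self.crrna22 = random_spacer(22, rng, "spacer22")
        self.crrna35 = random_spacer(35, rng, "spacer35")

    def next_seed(self) -> int:
        self._noise_counter += 1
        return _child_seed(self.seed, self._noise_counter)

    def record(self, path: Path, **params) -> None:
        self.manifest[path.name] = params

    def observe(self, traj: Trajectory, sample_id: str, condition: str,
                replicate: int = 1, sigma: float = _DEFAULT_SIGMA_AU):
        return observe_fluorescence(
            traj, self.calib, sigma, self.next_seed(),
            metadata={"sample_id": sample_id, "condition": condition,
                      "replicate": replicate})


def _calibration_titrations(study: _Study) -> None:
    rng = np.random.default_rng(study.next_seed())
    for label, slope in (("cleaved", study.calib.m_cl),
                         ("uncleaved", study.calib.m_ucl)):
        pts = [(c, slope * c + rng.normal(0.0, _DEFAULT_SIGMA_AU))
               for c in CALIBRATION_TITRATION_NM]
        path = study.out / f"titration_{label}.csv"
        egio.write_titration_csv(path, pts)
        study.record(path, kind="calibration_titration", pool=label,
                     true_slope_au_per_nM=slope,
                     sigma_au=_DEFAULT_SIGMA_AU,
                     concentrations_nM=list(CALIBRATION_TITRATION_NM))


def _toehold_panels(study: _Study) -> None:
    series = []
    activator = full_activator(study.crrna22)
    for direction in ToeholdDirection:
        for f in range(1, 11):
            era = design_era(study.crrna22, direction, f)
            layout = build_duplex_layout(study.crrna22, era, activator)
            traj = simulate_activation_cleavage(
                ReactionSystem(), layout, study.rates, study.energy,
                t_end=2400.0)
            series.append(study.observe(
                traj, f"toehold_{direction.value}_{f}",
                f"{direction.value}-toehold-{f}"))
    path = study.out / "toehold_panel.csv"
    egio.write_timeseries_csv(path, series)
    study.record(path, kind="toehold_panel", f_range=[1, 10],
                 directions=["5p", "3p"], t_end_s=2400.0)


def _mismatch_panels(study: _Study) -> None:
    series = []
    # ERA mismatches at increasing distance from a 5' toehold-4 bm boundary
    for d in (0, 1, 2, 4, 8):
        era = design_era(study.crrna22, ToeholdDirection.FIVE_PRIME, 4,
                         era_mismatches=(4 + 1 + d,))
        layout = build_duplex_layout(study.crrna22, era,
                                     full_activator(study.crrna22))
        traj = simulate_activation_cleavage(ReactionSystem(), layout,
                                            study.rates, study.energy, 2400.0)
        series.append(study.observe(traj, f"era_mm_d{d}", f"ERA-mm-d{d}"))
    # activator mismatches at increasing distance from a 5' toehold-7 boundary
    era7 = design_era(study.crrna22, ToeholdDirection.FIVE_PRIME, 7)
    for d in (0, 2, 5, 10):
        activator = full_activator(study.crrna22,
                                   mismatch_positions=(7 + 1 + d,))
        layout = build_duplex_layout(study.crrna22, era7, activator)
        traj = simulate_activation_cleavage(ReactionSystem(), layout,
                                            study.rates, study.energy, 2400.0)
        series.append(study.observe(traj, f"act_mm_d{d}", f"MM-d{d}"))
    path = study.out / "mismatch_panel.csv"
    egio.write_timeseries_csv(path, series)
    study.record(path, kind="mismatch_panel",
                 era_mm_distances=[0, 1, 2, 4, 8],
                 activator_mm_distances=[0, 2, 5, 10])


def _te_panels(study: _Study) -> None:
    series = []
    te_rates = dataclasses.replace(study.rates, k_rev_mode="te_equilibrated")
    for r in (0, 2, 4):
        era, activator = design_te_era(study.crrna22,
                                       ToeholdDirection.FIVE_PRIME, 5, r)
        layout = build_duplex_layout(study.crrna22, era, activator)
        traj = simulate_activation_cleavage(ReactionSystem(), layout,
                                            te_rates, study.energy, 2400.0)
        series.append(study.observe(traj, f"te_f5_r{r}", f"TE-f5-r{r}"))
    path = study.out / "te_panel.csv"
    egio.write_timeseries_csv(path, series)
    study.record(path, kind="te_panel", f=5, r_values=[0, 2, 4],
                 k_rev_mode="te_equilibrated")


def _mm_titrations(study: _Study) -> None:
    """Pre-activated enzyme titrations for Michaelis-Menten fitting."""
    for e0, tag in ((1.0, "e0_1nM"), (5.0, "e0_5nM_slow_layout")):
        series = []
        era = design_era(study.crrna22, ToeholdDirection.FIVE_PRIME, 7)
        layout = build_duplex_layout(study.crrna22, era,
                                     full_activator(study.crrna22))
        for s0 in MM_TITRATION_NM:
            system = ReactionSystem(c_complex0=0.0, c_activator0=0.0,
                                    c_reporter0=s0, e_background=e0,
                                    k_cat=1.0, K_M=500.0)
            traj = simulate_activation_cleavage(system, layout, study.rates,
                                                study.energy, 1200.0)
            series.append(study.observe(traj, f"mm_{tag}_S{s0:g}", f"{s0:g}"))
        path = study.out / f"mm_titration_{tag}.csv"
        egio.write_timeseries_csv(path, series)
        study.record(path, kind="mm_titration", E0_nM=e0,
                     substrate_nM=list(MM_TITRATION_NM),
                     true_k_cat_per_s=1.0, true_K_M_nM=500.0)


def _df_triplets(study: _Study) -> None:
    """PM / toehold-proximal-MM / no-activator-background triplets, n=3."""
    era = design_era(study.crrna22, ToeholdDirection.FIVE_PRIME, 7)
    act_pm = full_activator(study.crrna22)
    act_mm = full_activator(study.crrna22, mismatch_positions=(8,))
    layout_pm = build_duplex_layout(study.crrna22, era, act_pm)
    layout_mm = build_duplex_layout(study.crrna22, era, act_mm)
    traj_pm = simulate_activation_cleavage(ReactionSystem(), layout_pm,
                                           study.rates, study.energy, 2400.0)
    traj_mm = simulate_activation_cleavage(ReactionSystem(), layout_mm,
                                           study.rates, study.energy, 2400.0)
    traj_bg = simulate_activation_cleavage(
        ReactionSystem(c_activator0=0.0), layout_pm, study.rates,
        study.energy, 2400.0)
    series = []
    for rep in (1, 2, 3):
        series.append(study.observe(traj_pm, "df_pm", "PM", replicate=rep))
        series.append(study.observe(traj_mm, "df_mm", "MM-1", replicate=rep))
        series.append(study.observe(traj_bg, "df_bg", "background",
                                    replicate=rep))
    path = study.out / "df_triplets.csv"
    egio.write_timeseries_csv(path, series)
    study.record(path, kind="df_triplets", toehold="5p-7",
                 activator_mm_distance=0, replicates=3)


def _one_pot(study: _Study) -> None:
    series = []
    activator = full_activator(study.crrna22)
    era5 = design_era(study.crrna22, ToeholdDirection.FIVE_PRIME, 5)
    gated = build_duplex_layout(study.crrna22, era5, activator)
    # "no ERA": nothing gates the crRNA, so any produced activator binds at
    # the saturated rate -- modeled as a saturated-toehold layout
    era7 = design_era(study.crrna22, ToeholdDirection.FIVE_PRIME, 7)
    ungated = build_duplex_layout(study.crrna22, era7, activator)
    system = one_pot_reference_system()
    for target in (True, False):
        per = OnePotParams(target_present=target)
        for tag, layout in (("ERA-5p-5", gated), ("no-ERA", ungated)):
            traj = simulate_one_pot(system, per, layout, study.rates,
                                    study.energy, 7200.0)
            series.append(study.observe(
                traj, f"onepot_{tag}_{'target' if target else 'ntc'}", tag))
    path = study.out / "one_pot.csv"
    egio.write_timeseries_csv(path, series)
    study.record(path, kind="one_pot", layouts=["ERA-5p-5", "no-ERA"],
                 target_states=[True, False], t_end_s=7200.0)


def _strands(study: _Study) -> None:
    era = design_era(study.crrna22, ToeholdDirection.FIVE_PRIME, 7)
    activator = full_activator(study.crrna22)
    path = study.out / "strands.fasta"
    egio.write_fasta(path, [study.crrna22.spacer, study.crrna35.spacer,
                            era.sequence, activator.sequence])
    study.record(path, kind="strands", spacers=[22, 35])


def generate_fixture_study(seed: int, out_dir) -> dict:
    """Write the full synthetic study to ``out_dir``; returns the manifest.

    Deterministic in ``seed``: the same seed produces a byte-identical
    bundle.  The manifest (also written as ``manifest.json``) lists every
    file with the parameters that generated it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = _Study(seed, out)
    _calibration_titrations(study)
    _toehold_panels(study)
    _mismatch_panels(study)
    _te_panels(study)
    _mm_titrations(study)
    _df_triplets(study)
    _one_pot(study)
    _strands(study)
    manifest = {"seed": seed, "files": study.manifest}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
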