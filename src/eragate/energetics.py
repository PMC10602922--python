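"""Coarse free-energy model for ERA:crRNA duplexes and toehold exchange.

A sequence-averaged per-stack model: every paired nucleotide contributes a
fixed pairing free energy (RNA:RNA or RNA:DNA hybrid), each forward-toehold
nucleotide a fixed stabilization, and each mismatch a fixed destabilization.
This deliberately trades sequence-level accuracy for determinism and
dataset-independence while preserving the dependencies the control scheme
exploits: duplex length, mismatch count, and the forward/reverse toehold
balance of a toehold-exchange (TE) reaction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .sequences import DuplexLayout

__all__ = ["EnergyModel", "duplex_delta_g", "reaction_delta_g", "equilibrium_extent"]

logger = logging.getLogger(__name__)

_GAS_CONSTANT = 0.0019872  # kcal/mol/K


@dataclass(frozen=True)
class EnergyModel:
    """Per-nucleotide free-energy parameters (kcal/mol, 25 C defaults).

    ``dg_toehold_per_nt`` defaults to -RT ln 10, i.e. each forward-toehold
    nucleotide is worth one decade of equilibrium binding.
    """

    dg_bp_rna_rna: float = -2.1
    dg_bp_rna_dna: float = -1.8
    dg_toehold_per_nt: float = -1.364
    ddg_mismatch: float = 3.0
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        if self.dg_bp_rna_rna >= 0 or self.dg_bp_rna_dna >= 0:
            raise ValueError("pairing free energies must be negative")
        if self.dg_toehold_per_nt >= 0:
            raise ValueError("toehold stabilization must be negative")
        if self.ddg_mismatch <= 0:
            raise ValueError("mismatch destabilization must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def RT(self) -> float:
        """kcal/mol; 0.5925 at 298.15 K."""
        return _GAS_CONSTANT * self.temperature_K


def duplex_delta_g(paired_nt: int, mismatches: int, model: EnergyModel,
                   hybrid: str = "RNA_RNA") -> float:
    """Formation free energy (kcal/mol) of a duplex with ``paired_nt`` stacks
    and ``mismatches`` internal mismatches.  More mismatches -> less negative.
    """
    if paired_nt < 0 or mismatches < 0:
        raise ValueError("counts must be >= 0")
    if mismatches > paired_nt:
        raise ValueError("more mismatches than paired positions")
    if hybrid == "RNA_RNA":
        dg_bp = model.dg_bp_rna_rna
    elif hybrid == "RNA_DNA":
        dg_bp = model.dg_bp_rna_dna
    else:
        raise ValueError(f"unknown hybrid {hybrid!r}")
    return paired_nt * dg_bp + mismatches * model.ddg_mismatch


def reaction_delta_g(layout: DuplexLayout, model: EnergyModel) -> float:
    """Net free energy (kcal/mol) of activator + ERA:crRNA -> activator:crRNA + ERA.

    The forward toehold drives the reaction downhill, a reverse toehold (TE)
    pushes it back uphill, activator mismatches cost and ERA mismatches pay
    (their elimination releases strain)::

        dG = (r - f) |dg_toehold| + ddg_mm * n_act_mm - ddg_mm * n_era_mm

    A plain TMSD layout (r = 0, no mismatches) is therefore strictly downhill;
    a balanced exchange (f = r) sits at dG = 0, where single-mismatch
    penalties dominate the yield regardless of mismatch position.
    """
    per_toehold = abs(model.dg_toehold_per_nt)
    return (
        (layout.toehold_length_r - layout.toehold_length_f) * per_toehold
        + model.ddg_mismatch * len(layout.activator_mismatch_distances)
        - model.ddg_mismatch * len(layout.era_mismatch_distances)
    )


def equilibrium_extent(delta_g: float, c_complex: float, c_activator: float,
                       model: EnergyModel) -> float:
    """Equilibrium extent x (nM) of A + C -> products with K = exp(-dG/RT).

    Solves K = x^2 / ((c_complex - x)(c_activator - x)) for the root in
    (0, min(c_complex, c_activator)); both products are assumed to start at
    zero.  Degenerately large/small K clamps to the boundary with a warning.
    """
    if c_complex <= 0 or c_activator <= 0:
        raise ValueError("concentrations must be positive")
    exponent = -delta_g / model.RT
    upper = min(c_complex, c_activator)
    if exponent > 700.0:
        logger.warning("K overflows; clamping extent to min concentration")
        return upper
    if exponent < -700.0:
        logger.warning("K underflows; clamping extent to 0")
        return 0.0
    K = math.exp(exponent)
    if abs(K - 1.0) < 1e-12:
        return K * c_complex * c_activator / (c_complex + c_activator)
    # (K-1) x^2 - K (c+a) x + K c a = 0; the physical root is the smaller one
    aa = K - 1.0
    bb = -K * (c_complex + c_activator)
    cc = K * c_complex * c_activator
    disc = bb * bb - 4.0 * aa * cc
    if disc < 0:
        logger.warning("negative discriminant (%.3g); clamping", disc)
        return upper if K > 1 else 0.0
    sq = math.sqrt(disc)
    # numerically stable pair of roots
    q = -0.5 * (bb - sq) if bb < 0 else -0.5 * (bb + sq)
    roots = sorted({q / aa, cc / q} if q != 0 else {0.0})
    for x in roots:
        if 0.0 < x < upper:
            return x
    logger.warning("no root in (0, %g); clamping", upper)
    return upper if K > 1 else 0.0
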