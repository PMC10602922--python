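"""Strand representations and duplex geometry for ERA-gated Cas12a.

An ERA (external RNA accessory) is an RNA strand complementary to part of a
crRNA spacer.  The unpaired spacer nucleotides left on one end form a toehold
through which a DNA activator can invade by toehold-mediated strand
displacement (TMSD), evict the ERA and switch on Cas12a trans-cleavage.  This
module represents the strands, derives the duplex geometry (toehold direction
and lengths, branch-migration domain, mismatch positions) and designs ERAs and
toehold-exchange (TE) ERA/activator pairs under empirical feasibility bounds.

Coordinate convention: spacer positions are 1-based from the spacer's 5' end.
"5' toehold" means unpaired spacer nucleotides at the spacer 5' end (the
protein's PAM-interacting-domain side).  Activator deletions are likewise
stated in spacer coordinates: ``deletion_5p`` removes activator coverage of
the spacer 5'-most positions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "Alphabet",
    "ToeholdDirection",
    "NucleicSequence",
    "CrRNASpec",
    "ERASpec",
    "ActivatorSpec",
    "DuplexLayout",
    "DesignError",
    "LayoutError",
    "reverse_complement",
    "build_duplex_layout",
    "design_era",
    "design_te_era",
    "full_activator",
    "mismatch_distance",
    "te_reverse_toehold_limit",
]


class Alphabet(enum.Enum):
    RNA = "RNA"
    DNA = "DNA"


class ToeholdDirection(enum.Enum):
    """Which spacer end carries the forward (pre-displacement) toehold."""

    FIVE_PRIME = "5p"
    THREE_PRIME = "3p"


_RNA_BASES = frozenset("ACGU")
_DNA_BASES = frozenset("ACGT")

_RNA_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_DNA_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
# DNA base pairing with an RNA template (activator vs spacer)
_RNA_TO_DNA_COMPLEMENT = {"A": "T", "U": "A", "C": "G", "G": "C"}

# Deterministic substitution used when a designed ERA must be
# non-complementary at a position: transversion partner of the
# would-be complementary base.
_RNA_TRANSVERSION = {"A": "C", "C": "A", "G": "U", "U": "G"}


class DesignError(ValueError):
    """A designed strand or layout violates a feasibility constraint."""


class LayoutError(ValueError):
    """Strands are mutually inconsistent with a single duplex layout."""


@dataclass(frozen=True)
class NucleicSequence:
    """A single strand, written 5'->3'."""

    residues: str
    alphabet: Alphabet
    name: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must be non-empty")
        allowed = _RNA_BASES if self.alphabet is Alphabet.RNA else _DNA_BASES
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"residues {sorted(bad)} not in {self.alphabet.value} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(seq: NucleicSequence, out_alphabet: Alphabet | None = None,
                       name: str = "") -> NucleicSequence:
    """Reverse complement, optionally crossing alphabets (RNA template -> DNA)."""
    out_alphabet = out_alphabet or seq.alphabet
    if seq.alphabet is Alphabet.RNA and out_alphabet is Alphabet.DNA:
        table = _RNA_TO_DNA_COMPLEMENT
    elif seq.alphabet is Alphabet.RNA:
        table = _RNA_COMPLEMENT
    elif out_alphabet is Alphabet.RNA:
        table = {"A": "U", "T": "A", "C": "G", "G": "C"}
    else:
        table = _DNA_COMPLEMENT
    residues = "".join(table[b] for b in reversed(seq.residues))
    return NucleicSequence(residues, out_alphabet, name=name)


@dataclass(frozen=True)
class CrRNASpec:
    """crRNA spacer (target-recognition region), typically 22 or 35 nt."""

    spacer: NucleicSequence

    def __post_init__(self) -> None:
        if self.spacer.alphabet is not Alphabet.RNA:
            raise ValueError("spacer must be RNA")
        if len(self.spacer) < 10:
            raise ValueError("spacer must be at least 10 nt")

    @property
    def spacer_length(self) -> int:
        return len(self.spacer)


@dataclass(frozen=True)
class ERASpec:
    """External RNA accessory pairing with spacer positions ``paired_span``.

    ``paired_span`` is a 1-based closed interval in spacer coordinates;
    ``mismatch_positions`` are spacer positions (inside the span) at which the
    ERA base is deliberately non-complementary.
    """

    sequence: NucleicSequence
    paired_span: tuple[int, int]
    mismatch_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.sequence.alphabet is not Alphabet.RNA:
            raise ValueError("ERA must be RNA")
        a, b = self.paired_span
        if not (1 <= a <= b):
            raise ValueError(f"invalid paired_span {self.paired_span}")
        if len(self.sequence) != b - a + 1:
            raise ValueError("ERA length must equal paired-span length")
        for p in self.mismatch_positions:
            if not (a <= p <= b):
                raise ValueError(f"mismatch position {p} outside paired span")

    @property
    def span_length(self) -> int:
        a, b = self.paired_span
        return b - a + 1


@dataclass(frozen=True)
class ActivatorSpec:
    """DNA activator; deletions are stated in spacer coordinates.

    ``deletion_5p`` / ``deletion_3p`` count spacer positions at the spacer
    5'/3' end that the activator does not cover (used to create the reverse
    toehold of a toehold-exchange design).
    """

    sequence: NucleicSequence
    strandedness: str = "ss"
    mismatch_positions: tuple[int, ...] = ()
    deletion_5p: int = 0
    deletion_3p: int = 0

    def __post_init__(self) -> None:
        if self.sequence.alphabet is not Alphabet.DNA:
            raise ValueError("activator must be DNA")
        if self.strandedness not in ("ss", "ds"):
            raise ValueError("strandedness must be 'ss' or 'ds'")
        if self.deletion_5p < 0 or self.deletion_3p < 0:
            raise ValueError("deletions must be >= 0")
        for p in self.mismatch_positions:
            if p < 1:
                raise ValueError("mismatch positions are 1-based spacer positions")


@dataclass(frozen=True)
class DuplexLayout:
    """Geometry of an ERA:crRNA duplex facing an invading activator.

    Mismatch distances are measured from the forward-toehold-proximal end of
    the branch-migration (bm) domain; distance 0 is the bm position
    immediately adjacent to the forward toehold.
    """

    toehold_direction: ToeholdDirection
    toehold_length_f: int
    toehold_length_r: int
    bm_length: int
    spacer_length: int
    era_mismatch_distances: tuple[int, ...] = ()
    activator_mismatch_distances: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.toehold_length_f < 0 or self.toehold_length_r < 0:
            raise ValueError("toehold lengths must be >= 0")
        if self.bm_length < 1:
            raise ValueError("branch-migration domain must be >= 1 nt")
        if self.toehold_length_f + self.bm_length > self.spacer_length:
            raise ValueError("toehold + bm domain exceed spacer length")
        for d in self.era_mismatch_distances + self.activator_mismatch_distances:
            if not (0 <= d <= self.bm_length - 1):
                raise ValueError(f"mismatch distance {d} outside bm domain")


def _era_expected_base(spacer_base: str) -> str:
    return _RNA_COMPLEMENT[spacer_base]


def build_duplex_layout(crrna: CrRNASpec, era: ERASpec,
                        activator: ActivatorSpec) -> DuplexLayout:
    """Derive the duplex geometry from a crRNA, ERA and activator triple.

    The toehold direction is set by which spacer end the ERA leaves unpaired;
    an ERA unpaired on both ends is rejected as ambiguous.  The forward
    toehold counts only unpaired spacer nucleotides the activator can actually
    bind (activator deletions on the toehold end shorten it); an activator
    deletion on the opposite end becomes the reverse toehold of a TE layout.
    """
    L = crrna.spacer_length
    a, b = era.paired_span
    if b > L:
        raise LayoutError(f"ERA paired span {era.paired_span} exceeds spacer length {L}")
    expected_act_len = L - activator.deletion_5p - activator.deletion_3p
    if len(activator.sequence) != expected_act_len:
        raise LayoutError(
            f"activator length {len(activator.sequence)} does not cover the spacer "
            f"minus declared deletions ({expected_act_len} nt expected)"
        )

    # sequence/span consistency: ERA must be the reverse complement of the
    # spacer over the span, except at its declared mismatch positions
    spacer = crrna.spacer.residues
    for p in range(a, b + 1):
        era_base = era.sequence.residues[b - p]  # ERA is 5'->3', antiparallel
        expected = _era_expected_base(spacer[p - 1])
        if p in era.mismatch_positions:
            if era_base == expected:
                raise LayoutError(
                    f"declared ERA mismatch at spacer position {p} is complementary"
                )
        elif era_base != expected:
            raise LayoutError(
                f"sequence/span inconsistency: ERA not complementary at spacer "
                f"position {p} (undeclared mismatch)"
            )

    unpaired_5p = a - 1
    unpaired_3p = L - b
    if unpaired_5p > 0 and unpaired_3p > 0:
        raise LayoutError("ambiguous layout: ERA leaves both spacer ends unpaired")
    direction = (ToeholdDirection.THREE_PRIME if unpaired_3p > 0
                 else ToeholdDirection.FIVE_PRIME)

    if direction is ToeholdDirection.FIVE_PRIME:
        f = max(0, unpaired_5p - activator.deletion_5p)
        r = activator.deletion_3p
    else:
        f = max(0, unpaired_3p - activator.deletion_3p)
        r = activator.deletion_5p

    bm = b - a + 1

    def _distance(p: int) -> int:
        if not (a <= p <= b):
            raise LayoutError(
                f"mismatch at spacer position {p} lies outside the bm domain [{a},{b}]"
            )
        return p - a if direction is ToeholdDirection.FIVE_PRIME else b - p

    era_d = tuple(sorted(_distance(p) for p in era.mismatch_positions))
    act_d = tuple(sorted(_distance(p) for p in activator.mismatch_positions))

    return DuplexLayout(
        toehold_direction=direction,
        toehold_length_f=f,
        toehold_length_r=r,
        bm_length=bm,
        spacer_length=L,
        era_mismatch_distances=era_d,
        activator_mismatch_distances=act_d,
    )


def design_era(crrna: CrRNASpec, direction: ToeholdDirection,
               toehold_length: int,
               era_mismatches: tuple[int, ...] = ()) -> ERASpec:
    """Design an ERA leaving ``toehold_length`` unpaired spacer nt on one end.

    The ERA is the RNA reverse complement of the spacer over the paired span;
    each requested mismatch position is substituted deterministically by the
    transversion partner (A<->C, G<->U) of the complementary base, which is
    never itself complementary (nor a G:U wobble).
    """
    L = crrna.spacer_length
    if toehold_length < 0:
        raise DesignError("toehold length must be >= 0")
    if toehold_length >= L:
        raise DesignError("empty duplex: toehold consumes the entire spacer")
    if direction is ToeholdDirection.FIVE_PRIME:
        a, b = toehold_length + 1, L
    else:
        a, b = 1, L - toehold_length
    for p in era_mismatches:
        if not (a <= p <= b):
            raise DesignError(
                f"mismatch outside duplex: spacer position {p} is in the toehold"
            )

    spacer = crrna.spacer.residues
    bases = []
    for p in range(b, a - 1, -1):  # 5'->3' of the ERA runs 3'->5' of the spacer
        comp = _era_expected_base(spacer[p - 1])
        bases.append(_RNA_TRANSVERSION[comp] if p in era_mismatches else comp)
    seq = NucleicSequence("".join(bases), Alphabet.RNA,
                          name=f"ERA_{direction.value}_toehold{toehold_length}")
    return ERASpec(seq, paired_span=(a, b),
                   mismatch_positions=tuple(sorted(era_mismatches)))


def full_activator(crrna: CrRNASpec, strandedness: str = "ss",
                   mismatch_positions: tuple[int, ...] = (),
                   deletion_5p: int = 0, deletion_3p: int = 0) -> ActivatorSpec:
    """DNA activator complementary to the spacer, minus any end deletions.

    Requested activator mismatches are substituted the same deterministic way
    as ERA mismatches (transversion partner of the complementary DNA base).
    """
    L = crrna.spacer_length
    if deletion_5p + deletion_3p >= L:
        raise DesignError("deletions consume the entire spacer")
    spacer = crrna.spacer.residues
    dna_transversion = {"A": "C", "C": "A", "G": "T", "T": "G"}
    bases = []
    for p in range(L - deletion_3p, deletion_5p, -1):
        comp = _RNA_TO_DNA_COMPLEMENT[spacer[p - 1]]
        bases.append(dna_transversion[comp] if p in mismatch_positions else comp)
    seq = NucleicSequence("".join(bases), Alphabet.DNA, name="activator")
    return ActivatorSpec(seq, strandedness=strandedness,
                         mismatch_positions=tuple(sorted(mismatch_positions)),
                         deletion_5p=deletion_5p, deletion_3p=deletion_3p)


def te_reverse_toehold_limit(spacer_length: int) -> int:
    """Largest reverse toehold compatible with Cas12a activation.

    Empirical bounds: with a standard 22-nt spacer, activation survives
    activator end-deletions strictly below 5 nt; extending the spacer to
    35 nt widens the allowance to 19 nt.
    """
    return 19 if spacer_length >= 35 else 4


def design_te_era(crrna: CrRNASpec, direction: ToeholdDirection,
                  f_length: int, r_length: int) -> tuple[ERASpec, ActivatorSpec]:
    """Design a toehold-exchange pair: ERA with an ``f_length`` forward toehold
    on ``direction`` plus an activator with an ``r_length`` deletion on the
    opposite end (the reverse toehold exposed after displacement).

    Rejects reverse toeholds beyond the feasibility bound for the spacer
    length, which predicts loss of Cas12a activation.
    """
    if f_length < 1:
        raise DesignError("forward toehold must be >= 1 nt")
    if r_length < 0:
        raise DesignError("reverse toehold must be >= 0 nt")
    limit = te_reverse_toehold_limit(crrna.spacer_length)
    if r_length > limit:
        raise DesignError(
            f"reverse toehold infeasible: {r_length} nt exceeds the "
            f"{limit}-nt bound for a {crrna.spacer_length}-nt spacer "
            "(predicted loss of activation)"
        )
    era = design_era(crrna, direction, f_length)
    if direction is ToeholdDirection.FIVE_PRIME:
        activator = full_activator(crrna, deletion_3p=r_length)
    else:
        activator = full_activator(crrna, deletion_5p=r_length)
    return era, activator


def mismatch_distance(layout: DuplexLayout, spacer_position: int) -> int:
    """Distance (0-based nt) of a spacer position from the forward-toehold-
    proximal boundary of the branch-migration domain.

    For FIVE_PRIME layouts the bm domain occupies spacer positions
    ``[f+1, f+bm]``; for THREE_PRIME it occupies ``[L-f-bm+1, L-f]`` and the
    proximal boundary sits on the 3' side, so a position at the same offset
    within the domain maps to the complementary distance ``bm-1-d``.
    """
    f, bm, L = layout.toehold_length_f, layout.bm_length, layout.spacer_length
    if layout.toehold_direction is ToeholdDirection.FIVE_PRIME:
        lo, hi = f + 1, f + bm
        if spacer_position < lo:
            raise LayoutError(f"position {spacer_position} lies in the toehold")
        if spacer_position > hi:
            raise LayoutError(f"position {spacer_position} outside the duplex")
        return spacer_position - lo
    lo, hi = L - f - bm + 1, L - f
    if spacer_position > hi:
        raise LayoutError(f"position {spacer_position} lies in the toehold")
    if spacer_position < lo:
        raise LayoutError(f"position {spacer_position} outside the duplex")
    return hi - spacer_position
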