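"""Backbone i←i+3 and i←i+4 intramolecular hydrogen bonds.

An i←i+3 bond (NH of residue i+3 donating to CO of residue i) stabilises
β-turns and the 3_10 helix; an i←i+4 bond stabilises the α helix.  A bond is
counted when the N⋯O distance is within 3.5 Å (inclusive) and the N–H⋯O
angle at the hydrogen exceeds 120° (strict).

Only sequence-legal pairs are enumerated: proline contributes no amide NH,
the C-terminal leucinol has no backbone carbonyl, and the acetyl cap is not
used as an acceptor.  For the 11-residue HM A peptides this yields exactly
six i←i+3 pairs (1←4, 2←5, 4←7, 5←8, 6←9, 8←11) and five i←i+4 pairs
(1←5, 3←7, 4←8, 5←9, 7←11).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .geometry import (
    Conformer,
    DEFAULT_GEOMETRY,
    StandardGeometry,
    hbond_geometry,
    rebuild_amide_hydrogens,
)
from .residues import PeptideSequence


@dataclass(frozen=True)
class HBondPair:
    """A sequence-legal donor/acceptor pair: NH of ``donor_index`` → CO of
    ``acceptor_index``, with ``donor_index - acceptor_index == span``."""

    acceptor_index: int
    donor_index: int
    span: int

    def __post_init__(self) -> None:
        if self.donor_index - self.acceptor_index != self.span:
            raise ValueError("donor_index - acceptor_index must equal span")

    def label(self) -> str:
        return f"{self.acceptor_index}<-{self.donor_index}"


@dataclass(frozen=True)
class HBondObservation:
    pair: HBondPair
    n_o_distance: float  # Å
    nho_angle: float  # degrees, vertex at H
    satisfied: bool


def enumerate_pairs(seq: PeptideSequence, span: int) -> List[HBondPair]:
    """All (i, i+span) pairs whose acceptor has a CO and donor has an NH."""
    if span not in (3, 4):
        raise ValueError(f"span must be 3 or 4, got {span}")
    pairs = []
    for i in range(1, len(seq) - span + 1):
        if seq.residue(i).has_backbone_CO and seq.residue(i + span).has_backbone_NH:
            pairs.append(HBondPair(acceptor_index=i, donor_index=i + span, span=span))
    return pairs


def detect_hbonds(
    conf: Conformer,
    seq: PeptideSequence,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
    spans: Tuple[int, ...] = (3, 4),
    geometry: StandardGeometry = DEFAULT_GEOMETRY,
) -> List[HBondObservation]:
    """Evaluate every enumerated pair of the given spans in one conformer.

    Missing amide hydrogens are rebuilt at the canonical in-plane position
    before measuring.  Returns one observation per pair; ``satisfied`` is
    true iff distance <= cutoff (inclusive) and angle > cutoff (strict).
    """
    rebuild_amide_hydrogens(conf, seq, geometry)
    observations: List[HBondObservation] = []
    for span in spans:
        for pair in enumerate_pairs(seq, span):
            n = conf.atom(pair.donor_index, "N")
            h = conf.atom(pair.donor_index, "H")
            o = conf.atom(pair.acceptor_index, "O")
            dist, angle = hbond_geometry(n, h, o)
            observations.append(
                HBondObservation(
                    pair=pair,
                    n_o_distance=dist,
                    nho_angle=angle,
                    satisfied=(dist <= distance_cutoff and angle > angle_cutoff),
                )
            )
    return observations
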