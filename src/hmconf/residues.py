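"""Residue topology and the hypomurocin A (HM A) peptide sequences.

Hypomurocin A peptides are 11-residue peptaibols: N-terminally acetylated,
C-terminally capped by the amino alcohol leucinol (Leuol), and rich in the
achiral, Cα-dimethylated residue Aib.  One of the six natural sequences
(HM A-2) carries D-isovaline (D-Iva) at position 1.  Every downstream stage
(torsion measurement, turn/helix windows, rotamer states, H-bond
enumeration) consults the per-residue facts defined here: whether a backbone
amide NH or carbonyl CO exists, whether a χ1 side-chain torsion is defined
and along which four atoms, and whether the residue is D-configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence, Tuple


class UnknownResidueError(ValueError):
    """Raised when a residue code is not in the library."""


@dataclass(frozen=True)
class ResidueSpec:
    """Topology facts for one residue type.

    ``chi1_atom_path`` names the four atoms whose dihedral is χ1
    (N–CA–CB–CG by the lowest-numbered-heavy-atom convention; CG1 for the
    β-branched Val/Ile).  ``d_chirality`` is true only for D-configured
    residues (D-Iva in HM A-2).
    """

    code: str
    has_backbone_NH: bool = True
    has_backbone_CO: bool = True
    chi1_defined: bool = False
    chi1_atom_path: Optional[Tuple[str, str, str, str]] = None
    d_chirality: bool = False

    def __post_init__(self) -> None:
        if self.chi1_defined and self.chi1_atom_path is None:
            raise ValueError(f"{self.code}: chi1_defined without an atom path")


_CHI1 = ("N", "CA", "CB")

#: Residue library.  Aib and Pro carry no χ1 (Aib has two equivalent methyls,
#: Pro's χ1 is ring-constrained and not analysed); Pro has no amide NH;
#: Leuol has no backbone carbonyl (a CH2–OH replaces it).  For D-Iva the χ1
#: path runs along the ethyl branch (CB–CG); the Cα-methyl carries no χ1.
RESIDUE_LIBRARY = {
    "Ace": ResidueSpec("Ace", has_backbone_NH=False),
    "Aib": ResidueSpec("Aib"),
    "Iva": ResidueSpec("Iva", chi1_defined=True, chi1_atom_path=(*_CHI1, "CG")),
    "Gln": ResidueSpec("Gln", chi1_defined=True, chi1_atom_path=(*_CHI1, "CG")),
    "Val": ResidueSpec("Val", chi1_defined=True, chi1_atom_path=(*_CHI1, "CG1")),
    "Ile": ResidueSpec("Ile", chi1_defined=True, chi1_atom_path=(*_CHI1, "CG1")),
    "Leu": ResidueSpec("Leu", chi1_defined=True, chi1_atom_path=(*_CHI1, "CG")),
    "Pro": ResidueSpec("Pro", has_backbone_NH=False),
    "Leuol": ResidueSpec(
        "Leuol", has_backbone_CO=False, chi1_defined=True, chi1_atom_path=(*_CHI1, "CG")
    ),
    # generic residues accepted for non-HM-A torsion analyses
    "Gly": ResidueSpec("Gly"),
    "Ala": ResidueSpec("Ala"),
}

#: Residue-name dialect used in multi-model PDB files.
PDB_DIALECT = {
    "Ace": "ACE",
    "Aib": "AIB",
    "Iva": "DIV",
    "Leuol": "LOL",
    "Gln": "GLN",
    "Val": "VAL",
    "Ile": "ILE",
    "Leu": "LEU",
    "Pro": "PRO",
    "Gly": "GLY",
    "Ala": "ALA",
}
PDB_DIALECT_INVERSE = {v: k for k, v in PDB_DIALECT.items()}

ACE = RESIDUE_LIBRARY["Ace"]


@dataclass(frozen=True)
class PeptideSequence:
    """An acetyl-capped peptide: residues indexed 1..n, cap at index 0."""

    name: str
    residues: Tuple[ResidueSpec, ...]
    n_cap: ResidueSpec = ACE

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[ResidueSpec]:
        return iter(self.residues)

    def residue(self, index: int) -> ResidueSpec:
        """1-based residue access; index 0 returns the acetyl cap."""
        if index == 0:
            return self.n_cap
        if not 1 <= index <= len(self.residues):
            raise IndexError(f"residue index {index} out of range 1..{len(self.residues)}")
        return self.residues[index - 1]

    def chi1_residue_indices(self) -> Tuple[int, ...]:
        return tuple(i for i in range(1, len(self) + 1) if self.residue(i).chi1_defined)

    def is_hm_a_layout(self) -> bool:
        """True if the sequence has the 11-residue HM A layout."""
        if len(self) != 11:
            return False
        return (
            self.residue(6).code == "Pro"
            and self.residue(10).code == "Pro"
            and self.residue(11).code == "Leuol"
            and self.residue(2).code == "Gln"
        )

    def require_hm_a_layout(self) -> None:
        if not self.is_hm_a_layout():
            raise ValueError(
                f"{self.name!r} does not have the 11-residue HM A layout "
                "(Pro at 6 and 10, Leuol at 11, Gln at 2) required by this analysis"
            )


@dataclass(frozen=True)
class TetrapeptideUnit:
    """A contiguous 4-residue window starting at ``start`` (1-based)."""

    start: int

    @property
    def span(self) -> Tuple[int, int, int, int]:
        return (self.start, self.start + 1, self.start + 2, self.start + 3)


def parse_sequence(tokens: Sequence[str], name: str = "peptide") -> PeptideSequence:
    """Build a validated :class:`PeptideSequence` from residue codes.

    Accepts library codes (``"Aib"``), the ``"D-"`` prefix for D-configured
    residues (``"D-Iva"``), and the upper-case PDB dialect names (``"AIB"``,
    ``"DIV"``, ``"LOL"``).  Any length >= 1 is accepted; HM-A-specific
    analyses perform their own layout check.
    """
    specs = []
    for token in tokens:
        d_flag = False
        code = token
        if code.startswith("D-") or code.startswith("d-"):
            d_flag = True
            code = code[2:]
        if code in PDB_DIALECT_INVERSE:
            code = PDB_DIALECT_INVERSE[code]
        if code == "DIV" or token == "DIV":
            code, d_flag = "Iva", True
        if code not in RESIDUE_LIBRARY or code == "Ace":
            raise UnknownResidueError(f"unknown residue code: {token!r}")
        spec = RESIDUE_LIBRARY[code]
        if d_flag:
            spec = replace(spec, d_chirality=True)
        specs.append(spec)
    if not specs:
        raise ValueError("empty sequence")
    return PeptideSequence(name=name, residues=tuple(specs))


# The "DIV" PDB code denotes D-isovaline specifically.
def _hm(name: str, codes: Sequence[str]) -> PeptideSequence:
    seq = parse_sequence(codes, name=name)
    seq.require_hm_a_layout()
    return seq


_HM_A_CODES = {
    "HM A-1": ["Aib", "Gln", "Val", "Val", "Aib", "Pro", "Leu", "Leu", "Aib", "Pro", "Leuol"],
    "HM A-2": ["D-Iva", "Gln", "Val", "Val", "Aib", "Pro", "Leu", "Leu", "Aib", "Pro", "Leuol"],
    "HM A-3": ["Aib", "Gln", "Val", "Leu", "Aib", "Pro", "Leu", "Ile", "Aib", "Pro", "Leuol"],
    "HM A-4": ["Aib", "Gln", "Ile", "Val", "Aib", "Pro", "Leu", "Leu", "Aib", "Pro", "Leuol"],
    "HM A-5": ["Aib", "Gln", "Ile", "Ile", "Aib", "Pro", "Leu", "Leu", "Aib", "Pro", "Leuol"],
    "HM A-5a": ["Aib", "Gln", "Ile", "Leu", "Aib", "Pro", "Leu", "Ile", "Aib", "Pro", "Leuol"],
}


def builtin_sequences() -> list[PeptideSequence]:
    """The six natural HM A sequences, acetyl-capped, in catalogue order."""
    return [_hm(name, codes) for name, codes in _HM_A_CODES.items()]


def get_sequence(name: str) -> PeptideSequence:
    """Look up a builtin sequence by name (hyphen/space/case tolerant)."""
    key = "".join(ch for ch in name.upper() if ch.isalnum())
    for seq_name, codes in _HM_A_CODES.items():
        if "".join(ch for ch in seq_name.upper() if ch.isalnum()) == key:
            return _hm(seq_name, codes)
    raise KeyError(f"unknown builtin sequence: {name!r}")


def tetrapeptide_units(seq: PeptideSequence) -> list[TetrapeptideUnit]:
    """All contiguous 4-residue windows (starts 1..len-3)."""
    if len(seq) < 4:
        raise ValueError(f"sequence of length {len(seq)} has no tetrapeptide unit")
    return [TetrapeptideUnit(start=s) for s in range(1, len(seq) - 2)]
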