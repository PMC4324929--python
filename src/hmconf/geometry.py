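"""Torsion measurement, internal→Cartesian conformer building, H-bond geometry.

The builder uses sequential natural-extension (NeRF) chain growth with ideal
bond lengths and angles: each atom is placed from the bond length, bond angle
and torsion relative to three already-placed predecessors.  Conformers carry
the acetyl cap as a residue-like unit at index 0 (atoms CH3, C, O) so that Φ
of residue 1 is defined via C(cap)–N1–CA1–C1.  The Ψ torsion of a C-terminal
leucinol is undefined (no following amide nitrogen), matching the torsion
bookkeeping used throughout the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .residues import PeptideSequence

Coordinate = np.ndarray
AtomKey = Tuple[int, str]  # (residue index, atom name); index 0 = acetyl cap


class DegenerateGeometryError(ValueError):
    """Collinear or coincident points make the requested angle undefined."""


class MissingAtomError(KeyError):
    """A required atom is absent from a conformer."""


class MissingTorsionError(ValueError):
    """A torsion required to build a conformer was not supplied."""


@dataclass(frozen=True)
class StandardGeometry:
    """Ideal covalent geometry used by the builder (Engh–Huber-style values).

    Lengths in Å, angles in degrees.  The torsion classification never
    depends on these; they only set the covalent frame of built conformers
    and hence the H-bond geometry.
    """

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    n_h: float = 1.010
    ca_cb: float = 1.530
    cb_cg: float = 1.530
    c_oh: float = 1.420  # leucinol C–OH

    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8
    ang_c_n_h: float = 119.0
    ang_c_ca_cb: float = 110.1
    ang_ca_cb_cg: float = 114.0
    ang_c_oh: float = 109.5

    #: improper dihedral N–C–CA–CB setting Cα chirality; positive = L
    cb_improper: float = 122.5

    def replace(self, **kwargs) -> "StandardGeometry":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


DEFAULT_GEOMETRY = StandardGeometry()


@dataclass
class TorsionRecord:
    """Backbone and χ1 torsions of one residue; ``None`` marks undefined.

    ``omega`` is the amide torsion linking this residue to the next
    (CA_i–C_i–N_{i+1}–CA_{i+1}); the cap→residue-1 amide is always trans.
    """

    residue_index: int
    phi: Optional[float] = None
    psi: Optional[float] = None
    omega: Optional[float] = None
    chi1: Optional[float] = None


@dataclass
class Conformer:
    """One model's coordinates, keyed by (residue index, atom name)."""

    model_id: int
    coords: Dict[AtomKey, Coordinate] = field(default_factory=dict)

    def atom(self, residue_index: int, name: str) -> Coordinate:
        try:
            return self.coords[(residue_index, name)]
        except KeyError:
            raise MissingAtomError(
                f"model {self.model_id}: residue {residue_index} has no atom {name!r}"
            ) from None

    def has_atom(self, residue_index: int, name: str) -> bool:
        return (residue_index, name) in self.coords


def wrap_angle(angle: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    wrapped = math.fmod(angle, 360.0)
    if wrapped <= -180.0:
        wrapped += 360.0
    elif wrapped > 180.0:
        wrapped -= 360.0
    return wrapped


def dihedral(p1: Coordinate, p2: Coordinate, p3: Coordinate, p4: Coordinate) -> float:
    """Signed dihedral angle p1–p2–p3–p4 in degrees, IUPAC convention.

    Returns a value in (-180, 180]; positive means clockwise rotation of
    p4 relative to p1 when viewed from p2 towards p3.  Raises
    :class:`DegenerateGeometryError` if three consecutive points are
    collinear (the dihedral plane is then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2_norm = np.linalg.norm(b2)
    if b2_norm < 1e-12 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError("collinear or coincident points in dihedral")
    m1 = np.cross(n1, b2 / b2_norm)
    angle = -math.degrees(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))
    return wrap_angle(angle)


def place_atom(
    a: Coordinate,
    b: Coordinate,
    c: Coordinate,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> Coordinate:
    """Place atom D bonded to *c* with |c-D| = ``bond``, angle(b,c,D) =
    ``angle_deg`` and dihedral(a,b,c,D) = ``torsion_deg`` (NeRF step)."""
    if not 0.1 < bond < 3.0:
        raise ValueError(f"bond length {bond} Å outside sane range")
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc_norm = np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if bc_norm < 1e-12 or n_norm < 1e-9:
        raise DegenerateGeometryError("collinear reference frame in atom placement")
    bc = bc / bc_norm
    n = n / n_norm
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(chi),
            bond * math.sin(theta) * math.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def hbond_geometry(
    n: Coordinate, h: Coordinate, o: Coordinate
) -> Tuple[float, float]:
    """Donor–acceptor geometry: (N⋯O distance in Å, N–H⋯O angle at H in deg).

    The angle vertex is the hydrogen: the angle between the ray H→N and the
    ray H→O.  180° is a perfectly linear hydrogen bond.
    """
    n, h, o = (np.asarray(p, dtype=float) for p in (n, h, o))
    hn = n - h
    ho = o - h
    hn_norm = np.linalg.norm(hn)
    ho_norm = np.linalg.norm(ho)
    if hn_norm < 1e-9 or ho_norm < 1e-9 or np.linalg.norm(n - o) < 1e-9:
        raise DegenerateGeometryError("coincident points in H-bond geometry")
    cos_angle = float(np.clip(np.dot(hn, ho) / (hn_norm * ho_norm), -1.0, 1.0))
    return float(np.linalg.norm(n - o)), math.degrees(math.acos(cos_angle))


def _torsion_map(torsions: Sequence[TorsionRecord]) -> Dict[int, TorsionRecord]:
    out: Dict[int, TorsionRecord] = {}
    for rec in torsions:
        if rec.residue_index in out:
            raise ValueError(f"duplicate torsion record for residue {rec.residue_index}")
        out[rec.residue_index] = rec
    return out


def build_conformer(
    seq: PeptideSequence,
    torsions: Sequence[TorsionRecord],
    geometry: StandardGeometry = DEFAULT_GEOMETRY,
    model_id: int = 0,
) -> Conformer:
    """Build 3D coordinates from torsions by sequential chain extension.

    Requirements: Φ for every residue; Ψ for every residue except the last;
    ω defaults to 180° (trans) where not given, including the cap amide.
    χ1-path side-chain atoms are placed only where χ1 is supplied.  Amide
    hydrogens are placed in the peptide plane trans to the carbonyl oxygen.
    D-configured residues get the mirrored Cβ branch.

    Round trip: ``torsions_of(build_conformer(seq, t), seq)`` reproduces
    every defined torsion to well below 1e-6 degrees.
    """
    n_res = len(seq)
    if n_res < 1:
        raise ValueError("empty sequence")
    tmap = _torsion_map(torsions)
    for i in range(1, n_res + 1):
        if i not in tmap or tmap[i].phi is None:
            raise MissingTorsionError(f"residue {i}: phi is required to build")
        if i < n_res and tmap[i].psi is None:
            raise MissingTorsionError(f"residue {i}: psi is required to build")

    g = geometry
    conf = Conformer(model_id=model_id)
    coords = conf.coords

    # acetyl cap: CH3 at the origin, carbonyl C along +x, amide N in the xy-plane
    ch3 = np.zeros(3)
    c0 = np.array([g.ca_c, 0.0, 0.0])
    theta = math.radians(g.ang_ca_c_n)
    n1 = c0 + g.c_n * np.array([-math.cos(theta), math.sin(theta), 0.0])
    coords[(0, "CH3")] = ch3
    coords[(0, "C")] = c0
    # cap carbonyl O: planar sp2, anti to the amide N across the CH3–C axis
    coords[(0, "O")] = place_atom(n1, ch3, c0, g.c_o, g.ang_ca_c_o, 180.0)

    prev_ca, prev_c = ch3, c0  # cap CH3 plays the role of CA for the first amide

    for i in range(1, n_res + 1):
        spec = seq.residue(i)
        rec = tmap[i]
        if i == 1:
            n_atom = n1
        else:
            prev_rec = tmap[i - 1]
            psi_prev = prev_rec.psi
            n_atom = place_atom(
                coords[(i - 1, "N")],
                coords[(i - 1, "CA")],
                coords[(i - 1, "C")],
                g.c_n,
                g.ang_ca_c_n,
                psi_prev,
            )
        coords[(i, "N")] = n_atom

        omega_prev = 180.0 if i == 1 else (
            tmap[i - 1].omega if tmap[i - 1].omega is not None else 180.0
        )
        ca = place_atom(prev_ca, prev_c, n_atom, g.n_ca, g.ang_c_n_ca, omega_prev)
        coords[(i, "CA")] = ca

        if spec.has_backbone_NH:
            # dihedral(CA_prev, C_prev, N, H) = 0 puts H in the amide plane,
            # trans to the carbonyl O of the preceding unit
            h = place_atom(prev_ca, prev_c, n_atom, g.n_h, g.ang_c_n_h, 0.0)
            coords[(i, "H")] = h

        c = place_atom(prev_c, n_atom, ca, g.ca_c, g.ang_n_ca_c, rec.phi)
        coords[(i, "C")] = c

        if spec.has_backbone_CO:
            psi = rec.psi if rec.psi is not None else 180.0
            coords[(i, "O")] = place_atom(
                n_atom, ca, c, g.c_o, g.ang_ca_c_o, wrap_angle(psi + 180.0)
            )
        else:
            # leucinol: the chain ends CA–CH2–OH; the CH2 carbon keeps the
            # name C and carries a hydroxyl oxygen instead of a carbonyl
            coords[(i, "O")] = place_atom(
                n_atom, ca, c, g.c_oh, g.ang_c_oh, 180.0
            )

        if spec.chi1_defined and rec.chi1 is not None:
            improper = g.cb_improper if not spec.d_chirality else -g.cb_improper
            cb = place_atom(n_atom, c, ca, g.ca_cb, g.ang_c_ca_cb, improper)
            coords[(i, "CB")] = cb
            cg_name = spec.chi1_atom_path[3]
            coords[(i, cg_name)] = place_atom(
                n_atom, ca, cb, g.cb_cg, g.ang_ca_cb_cg, rec.chi1
            )

        prev_ca, prev_c = ca, c

    return conf


def torsions_of(conf: Conformer, seq: PeptideSequence) -> List[TorsionRecord]:
    """Measure Φ/Ψ/ω/χ1 for every residue of a conformer.

    Undefined slots (Ψ and ω of the last residue, χ1 of residues without a
    χ1 path or without placed side-chain atoms) are ``None`` — never
    silently zero.  Missing backbone atoms raise :class:`MissingAtomError`
    naming the residue and atom.
    """
    n_res = len(seq)
    records: List[TorsionRecord] = []
    for i in range(1, n_res + 1):
        spec = seq.residue(i)
        c_prev = conf.atom(i - 1, "C")  # cap C for residue 1
        n = conf.atom(i, "N")
        ca = conf.atom(i, "CA")
        c = conf.atom(i, "C")
        phi = dihedral(c_prev, n, ca, c)
        psi = omega = None
        if i < n_res:
            n_next = conf.atom(i + 1, "N")
            psi = dihedral(n, ca, c, n_next)
            omega = dihedral(ca, c, n_next, conf.atom(i + 1, "CA"))
        chi1 = None
        if spec.chi1_defined:
            path = spec.chi1_atom_path
            if all(conf.has_atom(i, a) for a in path):
                chi1 = dihedral(*(conf.atom(i, a) for a in path))
        records.append(
            TorsionRecord(residue_index=i, phi=phi, psi=psi, omega=omega, chi1=chi1)
        )
    return records


def rebuild_amide_hydrogens(
    conf: Conformer, seq: PeptideSequence, geometry: StandardGeometry = DEFAULT_GEOMETRY
) -> Conformer:
    """Place any missing backbone amide H in the peptide plane, trans to O.

    Input files may or may not carry hydrogens; H-bond detection needs the
    amide H, so it is rebuilt at the canonical in-plane position whenever
    absent.  Existing hydrogens are kept untouched.
    """
    for i in range(1, len(seq) + 1):
        spec = seq.residue(i)
        if not spec.has_backbone_NH or conf.has_atom(i, "H"):
            continue
        prev_ca = conf.atom(i - 1, "CA") if i > 1 else conf.atom(0, "CH3")
        prev_c = conf.atom(i - 1, "C")
        n = conf.atom(i, "N")
        conf.coords[(i, "H")] = place_atom(
            prev_ca, prev_c, n, geometry.n_h, geometry.ang_c_n_h, 0.0
        )
    return conf
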