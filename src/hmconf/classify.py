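"""Torsion-window classification: β-turns, helices, helicity, χ1 rotamers.

Backbone secondary structure is assigned from (Φ,Ψ) windows:

* type I β-turn   — Φ_{i+1} = -60°±30°, Ψ_{i+1} = -30°±30°,
                    Φ_{i+2} = -90°±30°, Ψ_{i+2} =   0°±30°
* type III β-turn — Φ_{i+1} = -60°±30°, Ψ_{i+1} = -30°±30°,
                    Φ_{i+2} = -60°±30°, Ψ_{i+2} = -30°±30°
* 3_10 helix      — Φ = -60°±30°, Ψ = -30°±30° (per residue)
* α helix         — Φ = -60°±30°, Ψ = -50°±30° (per residue)

All windows are closed intervals after wrapping into (-180, 180].  The 3_10
and α windows overlap, so a residue may carry both labels; the *cumulative*
helical label is their union.  The helicity of a conformer is
f = 100·n_h/N where n_h counts residues 1..N inside the window and N = 10
for the 11-residue peptaibols analysed here (Ψ of the C-terminal leucinol is
undefined, so residue 11 is never counted).

χ1 rotamer states use the symmetric staggered convention
g(+): χ1 ∈ [0°, 120°), g(−): χ1 ∈ [-120°, 0°), trans otherwise.  Note that
some literatures swap the g(+)/g(−) names; the convention here is fixed and
echoed into every report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence

from .residues import PeptideSequence, TetrapeptideUnit, tetrapeptide_units
from .geometry import Conformer, TorsionRecord, torsions_of, wrap_angle

THREE_TEN = "three_ten"
ALPHA = "alpha"
CUMULATIVE = "cumulative"
HELIX_KINDS = (THREE_TEN, ALPHA, CUMULATIVE)

G_PLUS = "g_plus"
G_MINUS = "g_minus"
TRANS = "trans"
ROTAMER_STATES = (G_PLUS, G_MINUS, TRANS)


@dataclass(frozen=True)
class TorsionWindow:
    """A closed rectangular (Φ,Ψ) window, membership tested after wrapping."""

    phi_center: float
    phi_halfwidth: float
    psi_center: float
    psi_halfwidth: float

    def __post_init__(self) -> None:
        if self.phi_halfwidth <= 0 or self.psi_halfwidth <= 0:
            raise ValueError("window halfwidths must be positive")

    def contains(self, phi: Optional[float], psi: Optional[float]) -> bool:
        if phi is None or psi is None:
            return False
        return (
            abs(wrap_angle(phi - self.phi_center)) <= self.phi_halfwidth
            and abs(wrap_angle(psi - self.psi_center)) <= self.psi_halfwidth
        )


@dataclass(frozen=True)
class ClassificationConfig:
    """Window definitions and cutoffs; defaults are the standard criteria."""

    turn_windows: Dict[str, Dict[str, TorsionWindow]] = field(
        default_factory=lambda: {
            "I": {
                "pos1": TorsionWindow(-60.0, 30.0, -30.0, 30.0),
                "pos2": TorsionWindow(-90.0, 30.0, 0.0, 30.0),
            },
            "III": {
                "pos1": TorsionWindow(-60.0, 30.0, -30.0, 30.0),
                "pos2": TorsionWindow(-60.0, 30.0, -30.0, 30.0),
            },
        }
    )
    helix_windows: Dict[str, TorsionWindow] = field(
        default_factory=lambda: {
            THREE_TEN: TorsionWindow(-60.0, 30.0, -30.0, 30.0),
            ALPHA: TorsionWindow(-60.0, 30.0, -50.0, 30.0),
        }
    )
    helicity_n: int = 10
    hbond_distance_cutoff: float = 3.5  # Å, inclusive
    hbond_angle_cutoff: float = 120.0  # degrees, strict

    def to_dict(self) -> dict:
        """Plain-dict echo for provenance headers in reports/configs."""
        def w(win: TorsionWindow) -> list:
            return [win.phi_center, win.phi_halfwidth, win.psi_center, win.psi_halfwidth]

        return {
            "turn_windows": {
                t: {pos: w(win) for pos, win in poss.items()}
                for t, poss in self.turn_windows.items()
            },
            "helix_windows": {k: w(win) for k, win in self.helix_windows.items()},
            "helicity_n": self.helicity_n,
            "hbond_distance_cutoff": self.hbond_distance_cutoff,
            "hbond_angle_cutoff": self.hbond_angle_cutoff,
            "rotamer_convention": "g(+)=[0,120), g(-)=[-120,0), trans otherwise",
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ClassificationConfig":
        def w(vals) -> TorsionWindow:
            return TorsionWindow(*map(float, vals))

        kwargs = {}
        if "turn_windows" in data:
            kwargs["turn_windows"] = {
                t: {pos: w(vals) for pos, vals in poss.items()}
                for t, poss in data["turn_windows"].items()
            }
        if "helix_windows" in data:
            kwargs["helix_windows"] = {
                k: w(vals) for k, vals in data["helix_windows"].items()
            }
        for key in ("helicity_n", "hbond_distance_cutoff", "hbond_angle_cutoff"):
            if key in data:
                kwargs[key] = type(getattr(cls(), key))(data[key])
        return cls(**kwargs)


DEFAULT_CONFIG = ClassificationConfig()


@dataclass(frozen=True)
class TurnAssignment:
    """β-turn result for one tetrapeptide unit.

    ``types`` may hold both "I" and "III" (the windows overlap); a unit
    positive for both counts once in the combined type-I-and-III
    population.  ``evaluable`` is false when a needed torsion is undefined;
    such units are neither positive nor negative.
    """

    unit: TetrapeptideUnit
    types: FrozenSet[str]
    evaluable: bool = True


@dataclass(frozen=True)
class HelixAssignment:
    residue_index: int
    labels: FrozenSet[str]  # subset of {three_ten, alpha}


@dataclass(frozen=True)
class HelicityValue:
    kind: str
    f: float  # percent; a multiple of 100/N


@dataclass(frozen=True)
class RotamerState:
    residue_index: int
    state: Optional[str]  # g_plus | g_minus | trans | None (χ1 undefined)


@dataclass
class AssignmentSet:
    """All per-conformer assignments bundled together."""

    model_id: int
    torsions: List[TorsionRecord]
    turns: List[TurnAssignment]
    helix: List[HelixAssignment]
    helicity: Dict[str, float]  # kind -> f (percent)
    rotamers: List[RotamerState]
    hbonds: list  # List[HBondObservation]; typed loosely to avoid a cycle


def classify_turn(
    phi1: Optional[float],
    psi1: Optional[float],
    phi2: Optional[float],
    psi2: Optional[float],
    config: ClassificationConfig = DEFAULT_CONFIG,
) -> FrozenSet[str]:
    """Turn types of a tetrapeptide unit from its two central residues.

    (phi1, psi1) belong to residue i+1 and (phi2, psi2) to residue i+2 of
    the unit.  Any undefined angle yields the empty set (the unit is
    unevaluable, handled by :func:`turn_assignment`).
    """
    if any(a is None for a in (phi1, psi1, phi2, psi2)):
        return frozenset()
    out = set()
    for turn_type, windows in config.turn_windows.items():
        if windows["pos1"].contains(phi1, psi1) and windows["pos2"].contains(phi2, psi2):
            out.add(turn_type)
    return frozenset(out)


def turn_assignment(
    unit: TetrapeptideUnit,
    torsions: Sequence[TorsionRecord],
    config: ClassificationConfig = DEFAULT_CONFIG,
) -> TurnAssignment:
    """Evaluate one unit against the turn windows, flagging unevaluable units."""
    by_index = {t.residue_index: t for t in torsions}
    r1 = by_index.get(unit.start + 1)
    r2 = by_index.get(unit.start + 2)
    angles = (
        r1.phi if r1 else None,
        r1.psi if r1 else None,
        r2.phi if r2 else None,
        r2.psi if r2 else None,
    )
    if any(a is None for a in angles):
        return TurnAssignment(unit=unit, types=frozenset(), evaluable=False)
    return TurnAssignment(unit=unit, types=classify_turn(*angles, config=config))


def classify_helix_residue(
    phi: Optional[float],
    psi: Optional[float],
    config: ClassificationConfig = DEFAULT_CONFIG,
) -> FrozenSet[str]:
    """Helix labels of one residue; both labels possible (windows overlap)."""
    if phi is None or psi is None:
        return frozenset()
    return frozenset(
        kind for kind, win in config.helix_windows.items() if win.contains(phi, psi)
    )


def helicity(
    assignments: Sequence[HelixAssignment], kind: str, n: int = 10
) -> HelicityValue:
    """Helicity f = 100·n_h/N over residues 1..N.

    ``kind = "cumulative"`` counts residues with any helix label (the union
    of the 3_10 and α windows).
    """
    if n <= 0:
        raise ValueError("N must be positive")
    if kind not in HELIX_KINDS:
        raise ValueError(f"unknown helicity kind {kind!r}")
    by_index = {a.residue_index: a for a in assignments}
    missing = [i for i in range(1, n + 1) if i not in by_index]
    if missing:
        raise ValueError(f"helix assignments missing for residues {missing}")
    if kind == CUMULATIVE:
        n_h = sum(1 for i in range(1, n + 1) if by_index[i].labels)
    else:
        n_h = sum(1 for i in range(1, n + 1) if kind in by_index[i].labels)
    return HelicityValue(kind=kind, f=100.0 * n_h / n)


def classify_rotamer(chi1: Optional[float], residue_index: int = 0) -> RotamerState:
    """Map χ1 to g(+)/g(−)/trans; undefined χ1 gives an undefined state."""
    if chi1 is None:
        return RotamerState(residue_index=residue_index, state=None)
    x = wrap_angle(chi1)
    if 0.0 <= x < 120.0:
        state = G_PLUS
    elif -120.0 <= x < 0.0:
        state = G_MINUS
    else:
        state = TRANS
    return RotamerState(residue_index=residue_index, state=state)


def classify_torsions(
    torsions: Sequence[TorsionRecord],
    seq: PeptideSequence,
    config: ClassificationConfig = DEFAULT_CONFIG,
    model_id: int = 0,
) -> AssignmentSet:
    """Turn/helix/helicity/rotamer assignments from torsions alone (no H-bonds)."""
    turns = [turn_assignment(u, torsions, config) for u in tetrapeptide_units(seq)]
    n = config.helicity_n
    if len(seq) < n:
        raise ValueError(
            f"sequence length {len(seq)} shorter than helicity N={n}; "
            "set helicity_n in the config for short peptides"
        )
    by_index = {t.residue_index: t for t in torsions}
    helix = [
        HelixAssignment(
            residue_index=i,
            labels=classify_helix_residue(by_index[i].phi, by_index[i].psi, config),
        )
        for i in range(1, n + 1)
    ]
    hel = {kind: helicity(helix, kind, n).f for kind in HELIX_KINDS}
    rotamers = [
        classify_rotamer(by_index[i].chi1, residue_index=i)
        for i in seq.chi1_residue_indices()
    ]
    return AssignmentSet(
        model_id=model_id,
        torsions=list(torsions),
        turns=turns,
        helix=helix,
        helicity=hel,
        rotamers=rotamers,
        hbonds=[],
    )


def classify_conformer(
    conf: Conformer,
    seq: PeptideSequence,
    config: ClassificationConfig = DEFAULT_CONFIG,
) -> AssignmentSet:
    """Full per-conformer assignment: torsion windows plus H-bond detection."""
    from .hbonds import detect_hbonds

    torsions = torsions_of(conf, seq)
    result = classify_torsions(torsions, seq, config, model_id=conf.model_id)
    result.hbonds = detect_hbonds(
        conf,
        seq,
        distance_cutoff=config.hbond_distance_cutoff,
        angle_cutoff=config.hbond_angle_cutoff,
    )
    return result
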