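"""Ensemble I/O, per-conformer classification, and population summaries.

Reads conformer ensembles from multi-model PDB files (residue dialect: ACE,
AIB, DIV = D-isovaline, LOL = leucinol, plus standard GLN/VAL/ILE/LEU/PRO)
or from tidy per-residue torsion CSV tables, classifies every conformer, and
aggregates turn, helicity, rotamer and H-bond populations as percentages of
the ensemble.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .residues import (
    PDB_DIALECT,
    PDB_DIALECT_INVERSE,
    PeptideSequence,
    tetrapeptide_units,
)
from .geometry import (
    Conformer,
    DEFAULT_GEOMETRY,
    StandardGeometry,
    TorsionRecord,
    build_conformer,
    torsions_of,
)
from .classify import (
    ALPHA,
    CUMULATIVE,
    DEFAULT_CONFIG,
    HELIX_KINDS,
    ROTAMER_STATES,
    THREE_TEN,
    AssignmentSet,
    ClassificationConfig,
    classify_conformer,
)
from .hbonds import HBondPair, enumerate_pairs

#: Tetrapeptide-unit starts shown in the restricted (catalogue-style) turn view.
REPORTED_UNIT_STARTS = (1, 2, 4, 5, 6, 8)

_HELICITY_BINS = tuple(range(0, 101, 10))


class EnsembleFormatError(ValueError):
    """Malformed ensemble file (dialect violation, missing models/atoms)."""


# ---------------------------------------------------------------------------
# PDB I/O


def _atom_order(seq: PeptideSequence, index: int) -> List[str]:
    if index == 0:
        return ["CH3", "C", "O"]
    spec = seq.residue(index)
    names = ["N"]
    if spec.has_backbone_NH:
        names.append("H")
    names.append("CA")
    if spec.chi1_defined:
        names.extend(["CB", spec.chi1_atom_path[3]])
    names.extend(["C", "O"])
    return names


def _element_of(name: str) -> str:
    return name.lstrip("0123456789")[0]


def write_ensemble(confs: Sequence[Conformer], seq: PeptideSequence, path) -> None:
    """Write a multi-model PDB in the package dialect.

    Atom order is fixed per residue, so a read→write round trip is
    byte-identical.  Side-chain atoms are written only where present.
    """
    lines: List[str] = []
    for conf in confs:
        lines.append(f"MODEL     {conf.model_id:4d}")
        serial = 1
        for index in range(0, len(seq) + 1):
            res = seq.residue(index)
            res_name = PDB_DIALECT[res.code]
            for atom_name in _atom_order(seq, index):
                if not conf.has_atom(index, atom_name):
                    continue
                x, y, z = conf.atom(index, atom_name)
                padded = atom_name if len(atom_name) >= 4 else f" {atom_name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {padded:<4s} {res_name:<3s} A{index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{_element_of(atom_name):>2s}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_pdb(path, seq: PeptideSequence) -> List[Conformer]:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ensemble", str(path))
    confs: List[Conformer] = []
    for model in structure:
        conf = Conformer(model_id=model.serial_num if model.serial_num else model.id)
        for chain in model:
            for residue in chain:
                res_name = residue.get_resname().strip()
                index = residue.get_id()[1]
                if res_name not in PDB_DIALECT_INVERSE:
                    raise EnsembleFormatError(
                        f"model {conf.model_id}, residue {index}: "
                        f"unknown residue name {res_name!r}"
                    )
                if not 0 <= index <= len(seq):
                    raise EnsembleFormatError(
                        f"model {conf.model_id}: residue number {index} outside "
                        f"0..{len(seq)}"
                    )
                expected = seq.residue(index).code
                if PDB_DIALECT_INVERSE[res_name] != expected:
                    raise EnsembleFormatError(
                        f"model {conf.model_id}, residue {index}: file says "
                        f"{res_name}, sequence {seq.name!r} expects {expected}"
                    )
                for atom in residue:
                    conf.coords[(index, atom.get_name().strip())] = np.asarray(
                        atom.coord, dtype=float
                    )
        _validate_conformer(conf, seq)
        confs.append(conf)
    if not confs:
        raise EnsembleFormatError(f"no models found in {path}")
    return confs


def _validate_conformer(conf: Conformer, seq: PeptideSequence) -> None:
    for name in ("CH3", "C"):
        if not conf.has_atom(0, name):
            raise EnsembleFormatError(
                f"model {conf.model_id}: acetyl cap missing atom {name!r}"
            )
    for i in range(1, len(seq) + 1):
        for name in ("N", "CA", "C"):
            if not conf.has_atom(i, name):
                raise EnsembleFormatError(
                    f"model {conf.model_id}: residue {i} missing atom {name!r}"
                )


# ---------------------------------------------------------------------------
# Torsion CSV I/O

_CSV_COLUMNS = ["model", "residue", "phi", "psi", "omega", "chi1"]


def write_torsion_csv(confs: Sequence[Conformer], seq: PeptideSequence, path) -> None:
    """Tidy torsion table: one row per (model, residue); blank = undefined."""
    rows = []
    for conf in confs:
        for rec in torsions_of(conf, seq):
            rows.append(
                {
                    "model": conf.model_id,
                    "residue": rec.residue_index,
                    "phi": rec.phi,
                    "psi": rec.psi,
                    "omega": rec.omega,
                    "chi1": rec.chi1,
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False, float_format="%.6f")


def read_torsion_csv(path, seq: PeptideSequence) -> List[List[TorsionRecord]]:
    """Read per-residue torsions; returns one record list per model.

    A Ψ given for the final residue of a leucinol-terminated peptide is
    ignored with a warning (that torsion is undefined by construction).
    """
    frame = pd.read_csv(path)
    missing = [c for c in ("model", "residue", "phi") if c not in frame.columns]
    if missing:
        raise EnsembleFormatError(f"torsion CSV missing columns {missing}")
    if frame.empty:
        raise EnsembleFormatError(f"no models found in {path}")
    last = len(seq)
    tables: List[List[TorsionRecord]] = []
    for model_id, group in frame.groupby("model", sort=True):
        records = []
        for _, row in group.sort_values("residue").iterrows():
            idx = int(row["residue"])

            def val(col):
                if col not in row or pd.isna(row[col]):
                    return None
                return float(row[col])

            psi = val("psi")
            if idx == last and psi is not None and not seq.residue(last).has_backbone_CO:
                warnings.warn(
                    f"model {model_id}: Ψ given for terminal residue {idx} "
                    "(amino alcohol) is undefined; ignoring it",
                    stacklevel=2,
                )
                psi = None
            records.append(
                TorsionRecord(
                    residue_index=idx,
                    phi=val("phi"),
                    psi=psi,
                    omega=val("omega"),
                    chi1=val("chi1"),
                )
            )
        tables.append(records)
    return tables


def read_ensemble(
    path,
    seq: PeptideSequence,
    geometry: StandardGeometry = DEFAULT_GEOMETRY,
) -> List[Conformer]:
    """Load an ensemble from a multi-model PDB or a torsion CSV.

    Torsion tables carry no coordinates, so conformers are rebuilt from the
    torsions with ideal covalent geometry (required for the H-bond stage).
    """
    path_str = str(path)
    if path_str.lower().endswith(".csv"):
        tables = read_torsion_csv(path, seq)
        return [
            build_conformer(seq, records, geometry=geometry, model_id=m + 1)
            for m, records in enumerate(tables)
        ]
    return _read_pdb(path, seq)


# ---------------------------------------------------------------------------
# Summaries


@dataclass
class EnsembleSummary:
    """Population tables aggregated over an ensemble (percent of conformers)."""

    peptide_name: str
    n_conformers: int
    #: unit start -> dict(percent, positive, negative, unevaluable)
    turn_populations: Dict[int, Dict[str, float]]
    #: kind -> {f bin (0,10,..,100) -> percent of conformers}
    helicity_histograms: Dict[str, Dict[int, float]]
    #: residue index -> {state -> percent among conformers with defined χ1}
    rotamer_fractions: Dict[int, Dict[str, float]]
    #: residue index -> number of conformers with defined χ1
    rotamer_defined_counts: Dict[int, int]
    #: (acceptor, donor, span) -> percent satisfied
    hbond_populations: Dict[Tuple[int, int, int], float]
    config: dict = field(default_factory=dict)

    def helicity_tail(self, kind: str, threshold: int) -> float:
        """Percent of conformers with helicity f >= threshold (percent)."""
        return sum(p for f, p in self.helicity_histograms[kind].items() if f >= threshold)


def summarize(
    confs: Sequence[Conformer],
    seq: PeptideSequence,
    config: ClassificationConfig = DEFAULT_CONFIG,
) -> EnsembleSummary:
    """Classify every conformer and aggregate populations.

    Turn population of a unit = percent of conformers whose type set at that
    unit is non-empty (a conformer positive for both types I and III counts
    once).  Unevaluable units (undefined torsions) count neither positive
    nor negative but stay in the denominator.
    """
    if len(confs) == 0:
        raise ValueError("empty ensemble")
    n = len(confs)
    unit_starts = [u.start for u in tetrapeptide_units(seq)]
    turn_counts = {s: {"positive": 0, "negative": 0, "unevaluable": 0} for s in unit_starts}
    hel_counts = {kind: {f: 0 for f in _HELICITY_BINS} for kind in HELIX_KINDS}
    chi_indices = seq.chi1_residue_indices()
    rot_counts = {i: {s: 0 for s in ROTAMER_STATES} for i in chi_indices}
    rot_defined = {i: 0 for i in chi_indices}
    pairs = enumerate_pairs(seq, 3) + enumerate_pairs(seq, 4)
    hb_counts = {(p.acceptor_index, p.donor_index, p.span): 0 for p in pairs}

    for conf in confs:
        result = classify_conformer(conf, seq, config)
        for ta in result.turns:
            bucket = turn_counts[ta.unit.start]
            if not ta.evaluable:
                bucket["unevaluable"] += 1
            elif ta.types:
                bucket["positive"] += 1
            else:
                bucket["negative"] += 1
        for kind in HELIX_KINDS:
            f = int(round(result.helicity[kind]))
            hel_counts[kind][f] += 1
        for rot in result.rotamers:
            if rot.state is not None:
                rot_counts[rot.residue_index][rot.state] += 1
                rot_defined[rot.residue_index] += 1
        for obs in result.hbonds:
            key = (obs.pair.acceptor_index, obs.pair.donor_index, obs.pair.span)
            if obs.satisfied:
                hb_counts[key] += 1

    turn_populations = {
        s: {
            "percent": 100.0 * c["positive"] / n,
            "positive": c["positive"],
            "negative": c["negative"],
            "unevaluable": c["unevaluable"],
        }
        for s, c in turn_counts.items()
    }
    helicity_histograms = {
        kind: {f: 100.0 * c / n for f, c in bins.items()}
        for kind, bins in hel_counts.items()
    }
    rotamer_fractions = {
        i: {
            s: (100.0 * c / rot_defined[i] if rot_defined[i] else float("nan"))
            for s, c in states.items()
        }
        for i, states in rot_counts.items()
    }
    hbond_populations = {k: 100.0 * c / n for k, c in hb_counts.items()}
    return EnsembleSummary(
        peptide_name=seq.name,
        n_conformers=n,
        turn_populations=turn_populations,
        helicity_histograms=helicity_histograms,
        rotamer_fractions=rotamer_fractions,
        rotamer_defined_counts=rot_defined,
        hbond_populations=hbond_populations,
        config=config.to_dict(),
    )


# ---------------------------------------------------------------------------
# Reports


def format_percent(value: float) -> str:
    """One decimal place, ties rounded away from zero (table convention)."""
    return str(Decimal(f"{value:.6f}").quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _unit_label(seq: PeptideSequence, start: int) -> str:
    codes = [f"{seq.residue(i).code}{i}" for i in range(start, start + 4)]
    return "-".join(codes)


def _turn_frame(summary: EnsembleSummary, seq: PeptideSequence, all_units: bool) -> pd.DataFrame:
    starts = sorted(summary.turn_populations)
    if not all_units and seq.is_hm_a_layout():
        starts = [s for s in starts if s in REPORTED_UNIT_STARTS]
    rows = [
        {
            "unit_start": s,
            "unit": _unit_label(seq, s),
            "percent": format_percent(summary.turn_populations[s]["percent"]),
        }
        for s in starts
    ]
    return pd.DataFrame(rows)


def _helicity_frame(summary: EnsembleSummary, include_cumulative: bool) -> pd.DataFrame:
    kinds = [THREE_TEN, ALPHA] + ([CUMULATIVE] if include_cumulative else [])
    rows = []
    for f in _HELICITY_BINS:
        row = {"helicity": f"{f}%"}
        for kind in kinds:
            row[kind] = format_percent(summary.helicity_histograms[kind][f])
        rows.append(row)
    return pd.DataFrame(rows)


def _rotamer_frame(summary: EnsembleSummary, seq: PeptideSequence) -> pd.DataFrame:
    rows = []
    for state, label in (("g_plus", "g(+)"), ("g_minus", "g(-)"), ("trans", "trans")):
        row = {"rotamer": label}
        for i in sorted(summary.rotamer_fractions):
            row[f"{seq.residue(i).code}{i}"] = format_percent(
                summary.rotamer_fractions[i][state]
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _hbond_frame(summary: EnsembleSummary, seq: PeptideSequence, span: int) -> pd.DataFrame:
    rows = []
    for (acc, don, sp), pct in sorted(summary.hbond_populations.items()):
        if sp != span:
            continue
        rows.append(
            {
                "pair": f"{seq.residue(acc).code}{acc}<-{seq.residue(don).code}{don}",
                "acceptor": acc,
                "donor": don,
                "percent": format_percent(pct),
            }
        )
    return pd.DataFrame(rows)


def _cumulative_differs(summary: EnsembleSummary) -> bool:
    h = summary.helicity_histograms
    return any(h[CUMULATIVE][f] != h[THREE_TEN][f] for f in _HELICITY_BINS)


def render_csv(
    summary: EnsembleSummary, seq: PeptideSequence, all_units: bool = False
) -> Dict[str, str]:
    """CSV renderings of the four population tables, keyed by table name."""
    frames = {
        "turns": _turn_frame(summary, seq, all_units),
        "helicity": _helicity_frame(summary, include_cumulative=True),
        "rotamers": _rotamer_frame(summary, seq),
        "hbonds_i3": _hbond_frame(summary, seq, 3),
        "hbonds_i4": _hbond_frame(summary, seq, 4),
    }
    return {name: frame.to_csv(index=False) for name, frame in frames.items()}


def render_text(
    summary: EnsembleSummary, seq: PeptideSequence, all_units: bool = False
) -> str:
    """Human-readable report laid out like the population tables."""
    buf = io.StringIO()
    print(f"Ensemble summary: {summary.peptide_name}", file=buf)
    print(f"Conformers: {summary.n_conformers}", file=buf)
    print(f"Windows/cutoffs: {summary.config}", file=buf)
    print("\nTypes I and III beta-turn populations (% of conformers)", file=buf)
    print(_turn_frame(summary, seq, all_units).to_string(index=False), file=buf)
    include_cum = _cumulative_differs(summary)
    note = (
        ""
        if include_cum
        else " (cumulative content equals the 3_10 content; column omitted)"
    )
    print(f"\nHelicity distributions (% of conformers){note}", file=buf)
    print(_helicity_frame(summary, include_cum).to_string(index=False), file=buf)
    print("\nChi1 rotamer proportions (%)", file=buf)
    print(_rotamer_frame(summary, seq).to_string(index=False), file=buf)
    print("\ni<-i+3 H-bond populations (%)", file=buf)
    print(_hbond_frame(summary, seq, 3).to_string(index=False), file=buf)
    print("\ni<-i+4 H-bond populations (%)", file=buf)
    print(_hbond_frame(summary, seq, 4).to_string(index=False), file=buf)
    return buf.getvalue()


def report(
    summary: EnsembleSummary,
    seq: PeptideSequence,
    format: str = "text",
    all_units: bool = False,
):
    """Render a summary as ``"text"`` (one string) or ``"csv"`` (name→CSV)."""
    if format == "text":
        return render_text(summary, seq, all_units)
    if format == "csv":
        return render_csv(summary, seq, all_units)
    raise ValueError(f"unknown report format {format!r}")
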