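"""Synthetic conformer ensembles with known conformational structure.

The generator stands in for simulated-annealing conformational searches: for
each conformer and residue it draws a named torsion basin from a per-residue
mixture, adds wrapped Gaussian angular noise around the basin centre, draws
χ1 from a rotamer mixture around the staggered means (+60/-60/180°), and
builds Cartesian coordinates with ideal covalent geometry (ω fixed at 180°,
i.e. all-trans amides).  The drawn basin and rotamer labels are retained as
ground truth so that the counting pipeline can be validated by parameter
recovery: designed window/rotamer probabilities are computable in closed
form from the mixture, and ensemble estimates must agree within binomial
sampling error.

Residues are sampled independently; real ensembles carry backbone
correlations, so recovery validates the counting machinery, not peptide
energetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .residues import PeptideSequence, tetrapeptide_units
from .geometry import (
    Conformer,
    DEFAULT_GEOMETRY,
    StandardGeometry,
    TorsionRecord,
    build_conformer,
    hbond_geometry,
    wrap_angle,
)
from .classify import (
    ALPHA,
    CUMULATIVE,
    DEFAULT_CONFIG,
    G_MINUS,
    G_PLUS,
    HELIX_KINDS,
    ROTAMER_STATES,
    THREE_TEN,
    TRANS,
    ClassificationConfig,
    TorsionWindow,
)
from .hbonds import enumerate_pairs
from .pipeline import EnsembleSummary, summarize

ROTAMER_MEANS = {G_PLUS: 60.0, G_MINUS: -60.0, TRANS: 180.0}


@dataclass(frozen=True)
class TorsionBasin:
    """A named (Φ,Ψ) basin with isotropic wrapped-Gaussian spread (degrees)."""

    name: str
    phi_mean: float
    psi_mean: float
    angular_spread: float = 10.0

    def __post_init__(self) -> None:
        if self.angular_spread <= 0:
            raise ValueError("angular_spread must be positive")


def default_basins() -> Dict[str, TorsionBasin]:
    """Basin library anchored at the classification window centres.

    ``three_ten`` and ``alpha`` sit at the helix window centres (both lie in
    both helix windows — the windows overlap); ``turn_I_i2`` is the i+2
    position of a type I turn; ``extended`` and ``ppII`` lie outside every
    window.
    """
    basins = [
        TorsionBasin(THREE_TEN, -60.0, -30.0),
        TorsionBasin(ALPHA, -60.0, -50.0),
        TorsionBasin("turn_I_i2", -90.0, 0.0),
        TorsionBasin("extended", -140.0, 150.0),
        TorsionBasin("ppII", -75.0, 150.0),
    ]
    return {b.name: b for b in basins}


Mixture = Tuple[Tuple[TorsionBasin, float], ...]


@dataclass
class EnsembleSpec:
    """Design of a synthetic ensemble; the seed is mandatory.

    ``residue_mixtures`` maps residue index (1-based) to a weighted list of
    basins; ``rotamer_mixtures`` maps χ1-carrying residue indices to weights
    over g(+)/g(−)/trans.  Weights must be non-negative and sum to 1.
    """

    seq: PeptideSequence
    n_conformers: int
    residue_mixtures: Dict[int, Mixture]
    rotamer_mixtures: Dict[int, Dict[str, float]]
    seed: int
    chi1_spread: float = 10.0
    geometry: StandardGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")
        for i in range(1, len(self.seq) + 1):
            if i not in self.residue_mixtures:
                raise ValueError(f"no basin mixture for residue {i}")
            _check_weights([w for _, w in self.residue_mixtures[i]], f"residue {i}")
        for i in self.seq.chi1_residue_indices():
            if i not in self.rotamer_mixtures:
                raise ValueError(f"no rotamer mixture for χ1 residue {i}")
            mix = self.rotamer_mixtures[i]
            _check_weights([mix.get(s, 0.0) for s in ROTAMER_STATES], f"residue {i} χ1")


def _check_weights(weights: Sequence[float], what: str) -> None:
    if any(w < 0 for w in weights):
        raise ValueError(f"{what}: negative mixture weight")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError(f"{what}: mixture weights sum to {sum(weights)}, not 1")


@dataclass
class GroundTruth:
    """Per-(conformer, residue) drawn basin and rotamer labels."""

    basin_labels: List[Dict[int, str]]
    rotamer_labels: List[Dict[int, str]]


def uniform_spec(
    seq: PeptideSequence,
    n_conformers: int,
    seed: int,
    mixture: Sequence[Tuple[TorsionBasin, float]],
    rotamer_weights: Optional[Dict[str, float]] = None,
    chi1_spread: float = 10.0,
) -> EnsembleSpec:
    """Apply one basin mixture (and one rotamer mixture) to every residue."""
    rot = rotamer_weights or {G_PLUS: 1 / 3, G_MINUS: 1 / 3, TRANS: 1 / 3}
    return EnsembleSpec(
        seq=seq,
        n_conformers=n_conformers,
        residue_mixtures={i: tuple(mixture) for i in range(1, len(seq) + 1)},
        rotamer_mixtures={i: dict(rot) for i in seq.chi1_residue_indices()},
        seed=seed,
        chi1_spread=chi1_spread,
    )


def default_hm_spec(seq: PeptideSequence, n_conformers: int = 1000, seed: int = 0) -> EnsembleSpec:
    """Default study conditions for a synthetic HM A ensemble.

    1000 conformers per peptide, matching ensemble sizes customary for
    annealing-based conformational searches of peptaibols.  The mixture
    gives every residue a moderate helical propensity (35% in the helix
    basins) with the remainder in turn and extended/ppII basins, and a
    side-chain preference g(−) > trans > g(+) typical of β-branched and
    γ-branched residues in these peptides.  The generator emulates ensemble
    *bookkeeping*, not the annealing energy landscape.
    """
    basins = default_basins()
    mixture = (
        (basins[THREE_TEN], 0.25),
        (basins[ALPHA], 0.10),
        (basins["turn_I_i2"], 0.05),
        (basins["ppII"], 0.25),
        (basins["extended"], 0.35),
    )
    rot = {G_MINUS: 0.5, TRANS: 0.3, G_PLUS: 0.2}
    return uniform_spec(seq, n_conformers, seed, mixture, rot)


# ---------------------------------------------------------------------------
# Sampling


def _sample_torsions(
    spec: EnsembleSpec, rng: np.random.Generator
) -> Tuple[List[TorsionRecord], Dict[int, str], Dict[int, str]]:
    n_res = len(spec.seq)
    records = []
    basin_labels: Dict[int, str] = {}
    rot_labels: Dict[int, str] = {}
    for i in range(1, n_res + 1):
        mixture = spec.residue_mixtures[i]
        weights = [w for _, w in mixture]
        k = rng.choice(len(mixture), p=weights)
        basin = mixture[k][0]
        basin_labels[i] = basin.name
        phi = wrap_angle(basin.phi_mean + rng.normal(0.0, basin.angular_spread))
        last = i == n_res
        psi = (
            None
            if last
            else wrap_angle(basin.psi_mean + rng.normal(0.0, basin.angular_spread))
        )
        chi1 = None
        if spec.seq.residue(i).chi1_defined:
            mix = spec.rotamer_mixtures[i]
            states = list(ROTAMER_STATES)
            state = states[rng.choice(len(states), p=[mix.get(s, 0.0) for s in states])]
            rot_labels[i] = state
            chi1 = wrap_angle(ROTAMER_MEANS[state] + rng.normal(0.0, spec.chi1_spread))
        records.append(
            TorsionRecord(residue_index=i, phi=phi, psi=psi, omega=180.0, chi1=chi1)
        )
    return records, basin_labels, rot_labels


def sample_ensemble(spec: EnsembleSpec) -> Tuple[List[Conformer], GroundTruth]:
    """Draw a seeded synthetic ensemble; bit-reproducible for a given spec."""
    rng = np.random.default_rng(spec.seed)
    confs: List[Conformer] = []
    truth = GroundTruth(basin_labels=[], rotamer_labels=[])
    for m in range(spec.n_conformers):
        records, basins, rotamers = _sample_torsions(spec, rng)
        confs.append(
            build_conformer(spec.seq, records, geometry=spec.geometry, model_id=m + 1)
        )
        truth.basin_labels.append(basins)
        truth.rotamer_labels.append(rotamers)
    return confs, truth


# ---------------------------------------------------------------------------
# Designed probabilities (closed form where the quantity is a torsion window)


def _interval_prob(mean: float, sigma: float, lo: float, hi: float) -> float:
    """Mass of a wrapped Normal(mean, sigma) on [lo, hi] ⊂ [-180, 180]."""
    total = 0.0
    for k in (-2, -1, 0, 1, 2):
        total += norm.cdf((hi + 360.0 * k - mean) / sigma) - norm.cdf(
            (lo + 360.0 * k - mean) / sigma
        )
    return float(total)


def _window_prob_basin(basin: TorsionBasin, win: TorsionWindow) -> float:
    p_phi = _interval_prob(
        basin.phi_mean,
        basin.angular_spread,
        win.phi_center - win.phi_halfwidth,
        win.phi_center + win.phi_halfwidth,
    )
    p_psi = _interval_prob(
        basin.psi_mean,
        basin.angular_spread,
        win.psi_center - win.psi_halfwidth,
        win.psi_center + win.psi_halfwidth,
    )
    return p_phi * p_psi


def _window_intersection(a: TorsionWindow, b: TorsionWindow) -> Optional[TorsionWindow]:
    phi_lo = max(a.phi_center - a.phi_halfwidth, b.phi_center - b.phi_halfwidth)
    phi_hi = min(a.phi_center + a.phi_halfwidth, b.phi_center + b.phi_halfwidth)
    psi_lo = max(a.psi_center - a.psi_halfwidth, b.psi_center - b.psi_halfwidth)
    psi_hi = min(a.psi_center + a.psi_halfwidth, b.psi_center + b.psi_halfwidth)
    if phi_lo >= phi_hi or psi_lo >= psi_hi:
        return None
    return TorsionWindow(
        (phi_lo + phi_hi) / 2, (phi_hi - phi_lo) / 2, (psi_lo + psi_hi) / 2, (psi_hi - psi_lo) / 2
    )


def _union_prob_basin(basin: TorsionBasin, wins: Sequence[TorsionWindow]) -> float:
    """P(basin sample in union of rectangles) by inclusion–exclusion (≤2)."""
    if len(wins) == 1:
        return _window_prob_basin(basin, wins[0])
    if len(wins) != 2:
        raise NotImplementedError("union of more than two windows")
    p = _window_prob_basin(basin, wins[0]) + _window_prob_basin(basin, wins[1])
    inter = _window_intersection(wins[0], wins[1])
    if inter is not None:
        p -= _window_prob_basin(basin, inter)
    return p


def residue_window_probability(
    mixture: Mixture, wins: Sequence[TorsionWindow]
) -> float:
    return sum(w * _union_prob_basin(basin, wins) for basin, w in mixture)


def designed_turn_probability(
    spec: EnsembleSpec, unit_start: int, config: ClassificationConfig = DEFAULT_CONFIG
) -> float:
    """P(unit carries type I or III) under the design, residues independent."""
    mix1 = spec.residue_mixtures[unit_start + 1]
    mix2 = spec.residue_mixtures[unit_start + 2]
    t1, t2 = config.turn_windows["I"], config.turn_windows["III"]
    p_i = residue_window_probability(mix1, [t1["pos1"]]) * residue_window_probability(
        mix2, [t1["pos2"]]
    )
    p_iii = residue_window_probability(mix1, [t2["pos1"]]) * residue_window_probability(
        mix2, [t2["pos2"]]
    )
    # P(I ∪ III); with identical pos1 windows the joint "both" term factorises
    inter1 = _window_intersection(t1["pos1"], t2["pos1"])
    inter2 = _window_intersection(t1["pos2"], t2["pos2"])
    p_both = 0.0
    if inter1 is not None and inter2 is not None:
        p_both = residue_window_probability(mix1, [inter1]) * residue_window_probability(
            mix2, [inter2]
        )
    return p_i + p_iii - p_both


def designed_helix_probabilities(
    spec: EnsembleSpec, kind: str, config: ClassificationConfig = DEFAULT_CONFIG
) -> List[float]:
    """Per-residue window probabilities for residues 1..N."""
    if kind == CUMULATIVE:
        wins = [config.helix_windows[THREE_TEN], config.helix_windows[ALPHA]]
    else:
        wins = [config.helix_windows[kind]]
    return [
        residue_window_probability(spec.residue_mixtures[i], wins)
        for i in range(1, config.helicity_n + 1)
    ]


def poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """PMF of a sum of independent Bernoulli(p_i) variables (DP recursion)."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def designed_rotamer_fractions(
    spec: EnsembleSpec, residue_index: int
) -> Dict[str, float]:
    """Observed-state probabilities given the rotamer mixture and χ1 noise."""
    sigma = spec.chi1_spread
    mix = spec.rotamer_mixtures[residue_index]
    bins = {
        G_PLUS: [(0.0, 120.0)],
        G_MINUS: [(-120.0, 0.0)],
        TRANS: [(120.0, 180.0), (-180.0, -120.0)],
    }
    out = {}
    for obs_state, intervals in bins.items():
        p = 0.0
        for true_state, w in mix.items():
            mean = ROTAMER_MEANS[true_state]
            p += w * sum(_interval_prob(mean, sigma, lo, hi) for lo, hi in intervals)
        out[obs_state] = p
    return out


def _brute_force_hbond_satisfied(
    conf: Conformer,
    seq: PeptideSequence,
    config: ClassificationConfig,
) -> Dict[Tuple[int, int, int], bool]:
    """Exhaustive N/O scan restricted to spans 3 and 4 (design-side oracle)."""
    out = {}
    for span in (3, 4):
        for i in range(1, len(seq) - span + 1):
            j = i + span
            if not (seq.residue(i).has_backbone_CO and seq.residue(j).has_backbone_NH):
                continue
            dist, angle = hbond_geometry(
                conf.atom(j, "N"), conf.atom(j, "H"), conf.atom(i, "O")
            )
            out[(i, j, span)] = (
                dist <= config.hbond_distance_cutoff and angle > config.hbond_angle_cutoff
            )
    return out


def designed_hbond_probabilities(
    spec: EnsembleSpec,
    config: ClassificationConfig = DEFAULT_CONFIG,
    n_draws: int = 4000,
    seed_offset: int = 987_654,
) -> Tuple[Dict[Tuple[int, int, int], float], int]:
    """Design-side H-bond probabilities by direct Monte Carlo integration.

    H-bond satisfaction is a geometric functional of several torsions, so
    its design probability has no closed form.  It is integrated by drawing
    torsions from the design distribution with an RNG stream independent of
    the ensemble draw and scoring a brute-force N/O scan on built
    conformers.  Returns (probabilities, number of draws).
    """
    rng = np.random.default_rng(spec.seed + seed_offset)
    counts: Dict[Tuple[int, int, int], int] = {}
    for _ in range(n_draws):
        records, _, _ = _sample_torsions(spec, rng)
        conf = build_conformer(spec.seq, records, geometry=spec.geometry)
        for key, sat in _brute_force_hbond_satisfied(conf, spec.seq, config).items():
            counts[key] = counts.get(key, 0) + int(sat)
    return {k: c / n_draws for k, c in counts.items()}, n_draws


# ---------------------------------------------------------------------------
# Recovery experiment


def recovery_experiment(
    spec: EnsembleSpec,
    config: ClassificationConfig = DEFAULT_CONFIG,
    design_mc_draws: int = 4000,
) -> pd.DataFrame:
    """Sample an ensemble, summarise it, and compare against the design.

    Returns one row per reported population with columns ``quantity``,
    ``designed`` and ``estimated`` (both in percent), ``se`` (binomial
    standard error of the comparison, percent), ``deviation_se``
    (|estimated − designed| / se) and ``normal_regime`` (whether the
    binomial normal approximation is trustworthy: n·p·(1−p) ≥ 5 on the
    estimation side).  H-bond design values carry Monte Carlo error, which
    is folded into ``se``.
    """
    confs, _ = sample_ensemble(spec)
    summary = summarize(confs, spec.seq, config)
    n = spec.n_conformers
    rows = []

    def add(quantity: str, designed_p: float, estimated_pct: float, extra_var: float = 0.0):
        var = designed_p * (1.0 - designed_p) / n + extra_var
        se_pct = 100.0 * math.sqrt(var)
        dev = abs(estimated_pct - 100.0 * designed_p)
        rows.append(
            {
                "quantity": quantity,
                "designed": 100.0 * designed_p,
                "estimated": estimated_pct,
                "se": se_pct,
                "deviation_se": (dev / se_pct) if se_pct > 0 else (0.0 if dev == 0 else float("inf")),
                "normal_regime": n * designed_p * (1.0 - designed_p) >= 5.0,
            }
        )

    for unit in tetrapeptide_units(spec.seq):
        add(
            f"turn_unit_{unit.start}",
            designed_turn_probability(spec, unit.start, config),
            summary.turn_populations[unit.start]["percent"],
        )

    for kind in HELIX_KINDS:
        pmf = poisson_binomial_pmf(designed_helix_probabilities(spec, kind, config))
        for k, p in enumerate(pmf):
            add(
                f"helicity_{kind}_{10 * k}",
                float(p),
                summary.helicity_histograms[kind][10 * k],
            )

    for i in spec.seq.chi1_residue_indices():
        designed = designed_rotamer_fractions(spec, i)
        for state in ROTAMER_STATES:
            add(
                f"rotamer_{i}_{state}",
                designed[state],
                summary.rotamer_fractions[i][state],
            )

    hb_design, m = designed_hbond_probabilities(spec, config, n_draws=design_mc_draws)
    for (acc, don, span), p in sorted(hb_design.items()):
        add(
            f"hbond_{acc}<-{don}",
            p,
            summary.hbond_populations[(acc, don, span)],
            extra_var=p * (1.0 - p) / m,
        )

    return pd.DataFrame(rows)
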