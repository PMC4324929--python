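# Methods

## Scope and model

`hmconf` analyses conformer ensembles of short acetyl-capped peptides —
specifically the six 11-residue hypomurocin A (HM A) peptaibols — by
torsion-window classification. The analysis is purely geometric: no
energies, no force field, no annealing. Everything reduces to four
per-conformer questions (is a tetrapeptide unit a type I/III β-turn, is a
residue in a helix window, which χ1 rotamer is a side chain in, is a
backbone H-bond geometrically satisfied) and their population bookkeeping
across an ensemble.

## Residue topology

Residues are described by four facts: backbone NH present (false for Pro
and the acetyl cap), backbone CO present (false for leucinol, whose chain
ends CA–CH₂–OH), χ1 defined (false for Aib, which has two equivalent
methyls, and Pro, whose χ1 is ring-constrained), and D-chirality (true only
for D-isovaline in HM A-2). χ1 atom paths follow the lowest-numbered
heavy-atom convention: N–CA–CB–CG1 for the β-branched Val/Ile, N–CA–CB–CG
for Gln/Leu/leucinol and for D-Iva, where the CB–CG branch is the ethyl arm
(the Cα-methyl carries no χ1). The ethyl-branch choice for D-Iva is a
convention; no experimental assignment fixes it.

The acetyl cap is modelled as a residue-like unit at index 0 with atoms
CH3/C/O so Φ of residue 1 is defined (C(cap)–N1–CA1–C1). Ψ and ω of the
C-terminal leucinol are undefined — the window machinery flags any
assignment touching an undefined torsion as unevaluable rather than
negative, and such units stay out of both the positive and negative counts
(they remain in the denominator).

## Geometry

Torsions are signed dihedrals in (−180°, 180°], IUPAC convention (checked
against independent implementations in Biopython, biotite and MDAnalysis).
Conformer building is sequential natural-extension (NeRF): each atom placed
by bond length, bond angle and torsion from three predecessors, with
Engh–Huber-style ideal values (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
C=O 1.231 Å, N–H 1.010 Å, angles N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA
121.7°). These constants never affect torsion classification — only the
Cartesian frame and hence H-bond geometry of *built* conformers — and are
overridable. Amide hydrogens are placed in the peptide plane trans to the
carbonyl oxygen; when an input file lacks hydrogens they are rebuilt at the
same canonical position before H-bond analysis. Cα chirality is set by the
improper dihedral N–C–CA–CB = +122.5° (L) / −122.5° (D); the L sign was
verified against a curated L-alanine template. ω defaults to 180° (trans)
everywhere, including the Xaa–Pro bonds; cis-proline is not sampled.

The build/measure round trip reproduces all defined torsions to better than
1e-6° (property-tested on 1000 random torsion sets), and negating all input
torsions produces the mirror-image backbone.

## Classification windows and conventions

All windows are closed intervals evaluated after wrapping into
(−180°, 180°]; "±30°" is read inclusively because no strict reading is
standard, and an independently written literal oracle encodes the same
choice in the tests. The 3₁₀ and α windows overlap (they share Φ and their
Ψ intervals intersect on [−60°, −20°]), so a residue may carry both labels;
cumulative helicity uses the union. Helicity f = 100·n_h/N with N = 10:
residue 11 has no Ψ and is excluded, so f is quantised to multiples of 10.

χ1 rotamer bins are the symmetric staggered convention g(+) = [0°, 120°),
g(−) = [−120°, 0°), trans otherwise. Some literatures swap the g(+)/g(−)
names; the convention used is echoed into every report header. Turn
populations combine types I and III (a conformer positive for both counts
once), matching the single combined reporting column customary for these
peptides.

H-bond criteria: N⋯O ≤ 3.5 Å (inclusive) and N–H⋯O angle at the hydrogen
vertex > 120° (strict). Pair enumeration excludes Pro donors (no NH), the
leucinol acceptor (no CO) and the acetyl cap, which for the HM A layout
leaves exactly six i←i+3 and five i←i+4 pairs. Side-chain H-bonds (e.g. the
Gln amide) are out of scope.

## Reporting

Percentages are rendered to one decimal, ties away from zero. The turn
table defaults to the six catalogue tetrapeptide units (starts 1, 2, 4, 5,
6, 8) with all eight available via a flag. The cumulative helicity
histogram is computed always but printed only when it differs from the 3₁₀
histogram (with the default windows and predominantly Ψ > −60° sampling
they frequently coincide, since the 3₁₀ window contains most of the α
window's high-density region). CSV exports always include all columns.

## Synthetic ensembles

The generator replaces annealing-derived ensembles: per conformer and
residue it draws a basin (3₁₀, α, type-I i+2, extended, ppII — centred on
the window centres, default spread 10°) from a per-residue mixture, adds
wrapped Gaussian noise (wrapped rather than linear so spreads behave at the
±180° seam), draws χ1 states about ±60°/180°, and builds coordinates. The
default study conditions are 1000 conformers per peptide. Residues are
sampled independently; real backbones are correlated, so passing recovery
tests validates the counting machinery, not peptide energetics, and no
numerical agreement with published ensemble tables is claimed. Ground-truth
labels are retained per (conformer, residue) and are never read by the
summariser.

## Parameter recovery

Designed probabilities are computed in closed form for every torsion-window
quantity: per-residue window masses are products of wrapped-normal interval
probabilities (rectangles, with inclusion–exclusion for window unions), turn
probabilities multiply the two central residues' masses, and helicity-bin
probabilities follow a Poisson-binomial recursion over residues 1..10.
Rotamer observation probabilities integrate the χ1 noise over the three
bins. H-bond satisfaction is a geometric functional of several torsions
with no closed form, so its design value is obtained by direct Monte Carlo
integration (default 4000 draws) with an independent RNG stream and a
brute-force all-pairs geometric scan; its Monte Carlo error is folded into
the comparison SE. The recovery experiment reports, per quantity,
designed/estimated percentages, the binomial SE and the deviation in SE
units, plus a flag for whether the normal approximation is trustworthy
(n·p·(1−p) ≥ 5): with ~70 quantities checked at 3 SE simultaneously, a
single chance exceedance per seed is expected occasionally, which is why
the rotamer counting path is additionally verified exactly against the
retained ground-truth labels.

## Problem sizes

Tests and the acceptance script use ensembles of 50–1000 conformers,
1000-set torsion round trips, 100-conformer brute-force H-bond comparisons
and the full 361×361 1°-spaced window grid — sizes at which every check
runs in seconds on one CPU while keeping binomial SEs around one percentage
point.

## Known limitations

* Uncorrelated per-residue sampling; correlated basin sampling is an
  extension point.
* Only turn types I and III and the two helix windows; no DSSP-style
  H-bond-based secondary structure.
* Ideal covalent geometry for built conformers; H-bond populations of
  torsion-CSV inputs therefore reflect rebuilt, not experimental,
  Cartesian frames.
* The 18-residue hypomurocin B family and force-field/energetic questions
  are out of scope.
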