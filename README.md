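# hmconf — conformational analysis of hypomurocin A peptaibols

Hypomurocin A (HM A) peptides are 11-residue peptaibols from *Trichoderma*
fungi: N-acetylated, terminated by the amino alcohol leucinol (Leuol), rich
in the achiral helix-promoter Aib (α-aminoisobutyric acid), with one variant
(HM A-2) carrying D-isovaline at position 1. Their structural signature —
types I/III β-turns, a preference for 3₁₀- over α-helix, and the i←i+3
hydrogen bonds that stabilise both — is read off conformer ensembles by
torsion-window bookkeeping. `hmconf` implements that bookkeeping as a tested
library and CLI for anyone analysing peptaibol (or other capped short
peptide) conformer ensembles.

## What it computes

For each conformer, from backbone/side-chain torsions:

* **β-turns** in every tetrapeptide unit, from the two central residues:
  type I — Φ_{i+1} = −60°±30°, Ψ_{i+1} = −30°±30°, Φ_{i+2} = −90°±30°,
  Ψ_{i+2} = 0°±30°; type III — same i+1 window, Φ_{i+2} = −60°±30°,
  Ψ_{i+2} = −30°±30° (closed intervals).
* **Helicity** f = 100·n_h/N (N = 10), where n_h counts residues whose
  (Φ,Ψ) fall in the 3₁₀ window (−60°±30°, −30°±30°), the α window
  (−60°±30°, −50°±30°), or their union (cumulative); Ψ of Leuol¹¹ is
  undefined, so residue 11 never counts.
* **χ1 rotamers** g(+)/g(−)/trans for every residue carrying a χ1
  (not Aib or Pro), convention g(+) = [0°,120°), g(−) = [−120°,0°).
* **H-bonds** i←i+3 and i←i+4 (NH of i+3/i+4 donating to CO of i),
  counted when the N⋯O distance ≤ 3.5 Å and the N–H⋯O angle at H > 120°.

Ensembles come from multi-model PDB files (dialect: ACE/AIB/DIV/LOL +
standard residues), tidy torsion CSVs, or the built-in synthetic generator,
which draws torsions from named basin mixtures with wrapped Gaussian noise,
builds coordinates with ideal covalent geometry (NeRF chain extension), and
retains ground-truth labels for validation. Populations are aggregated into
the four standard tables (turn populations per unit, helicity histograms,
rotamer fractions, H-bond populations).

## Worked example

```python
from hmconf import (get_sequence, build_conformer, classify_conformer,
                    TorsionRecord, default_hm_spec, sample_ensemble,
                    summarize, report)

seq = get_sequence("HM A-1")

# one ideal 3_10 conformer: every residue at the window centre
torsions = [TorsionRecord(i, phi=-60.0, psi=-30.0 if i < 11 else None,
                          chi1=-60.0 if seq.residue(i).chi1_defined else None)
            for i in range(1, 12)]
result = classify_conformer(build_conformer(seq, torsions), seq)
print(result.helicity)
print([o.pair.label() for o in result.hbonds if o.satisfied])

# a seeded synthetic ensemble, summarised
spec = default_hm_spec(seq, n_conformers=1000, seed=0)
confs, truth = sample_ensemble(spec)
print(report(summarize(confs, seq), seq))
```

prints

```
{'three_ten': 100.0, 'alpha': 100.0, 'cumulative': 100.0}
['1<-4', '2<-5', '4<-7', '5<-8', '6<-9', '8<-11']
```

— the ideal 3₁₀ conformer is fully helical by both windows (they overlap at
Ψ = −30°) and forms all six legal i←i+3 bonds — followed by the population
tables, e.g. the turn block:

```
Types I and III beta-turn populations (% of conformers)
 unit_start                    unit percent
          1     Aib1-Gln2-Val3-Val4    13.1
          2     Gln2-Val3-Val4-Aib5    13.8
          4     Val4-Aib5-Pro6-Leu7    13.2
          5     Aib5-Pro6-Leu7-Leu8    13.7
          6     Pro6-Leu7-Leu8-Aib9    12.9
          8 Leu8-Aib9-Pro10-Leuol11    14.1
```

Each percentage is the fraction of the 1000 conformers whose central-residue
torsions fall in a turn window at that unit.

The same flow from the shell:

```
hmconf simulate --sequence "HM A-1" --n 1000 --seed 0 --out ens.pdb
hmconf analyze ens.pdb --sequence "HM A-1" --out tables/
hmconf report tables/
```

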