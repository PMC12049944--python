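# beltlink

Tools for localizing where a ligand binds on the apolipoprotein A-I (APOA1)
double belt of discoidal HDL, using chemical cross-linking mass spectrometry
(XL-MS) restraints and particle geometry. The motivating system is
lecithin:cholesterol acyltransferase (LCAT), which docks at the two
symmetric helix 4/6 interfaces of the belt, but every stage is generic to
the scaffold-plus-ligand setup.

## What it does

Two antiparallel copies of APOA1 encircle a discoidal HDL particle as a
"double belt" in the LL5/5 registry: residue *i* of one chain faces residue
*c − i* of the other (registry constant *c* = 263), so helix 5 (residues
121–142) pairs with itself and helices 4 (99–120) and 6 (143–164) meet at
two symmetric interfaces — binding **Site A** and **Site B**. The package
implements the full desk-side analysis around that model:

- **`xlink_io`** — reagent registry (formaldehyde +24.000 Da, BS3
  +138.068 Da, EDC −18.011 Da with their reactive-residue sets), link-table
  reading, the reproducibility filter (keep a residue pair only if
  identified in *every* replicate with all mass errors ≤ 5 ppm), chemistry
  validation and dynamic-region exclusion.
- **`calibration`** — per-reagent span statistics on a reference structure;
  the restraint used downstream is **mean span + 1 SD** (e.g. 18 ± 8 Å →
  26 Å for formaldehyde). Contact plots use the < 24 Å Cα convention.
- **`belt_model`** — the idealized belt: circumference *C*, rise per
  residue *C/N*, continuous 1..2N numbering, registry arithmetic, helix-segment
  duplication (the D5h mutant doubles helix 5: 243 → 265 residues,
  +22 residues of arc), and chord/arc spacing predictions between sites.
- **`mapping_validation`** — intra- vs inter-chain resolution of
  scaffold-scaffold links (minimum-span rule with an ambiguity margin),
  Site A/B assignment by arc proximity, and contact-plot concordance
  reports with discordant-region ranking.
- **`docking_scan`** — an exhaustive rigid-body scan of the accessible
  interaction space (deterministic quasi-uniform rotation set × translation
  lattice, voxel-grid clash and interaction-shell tests), per-restraint
  satisfaction fractions and z-score flagging of likely false-positive
  restraints.
- **`spacing_analysis`** — two-component normal-mixture EM fits of measured
  ligand–ligand center distances, bootstrap CIs on the major-mode shift,
  and the geometric consistency check against the belt's inserted arc.
- **`synthetic_data`** — seeded generators for every input: toy reference
  structures, replicate cross-link tables with planted true/false links,
  bimodal spacing samples, and a belt + ligand-decoy scene with planted
  pose and restraints.

## Worked example

`examples/05_spacing_analysis.py` fits wild-type and duplicated-helix-5
(D5h) spacing fixtures (250 distances each) and tests the belt prediction:

```
WT:  modes [ 79.7 149.5] Å, weights [0.84 0.16]; major mode 79.7 Å (84%)
D5h: modes [107.1 177.1] Å; major mode 107.1 Å
major-mode shift: 27.4 Å (95% bootstrap CI 25.6..29.4)
belt prediction from the 24 Å circumference growth: 24.0 Å; discrepancy 3.4 Å -> consistent: True
```

Read: most ligand pairs sit ~80 Å apart on the wild-type belt (the ~84%
major component), with a minor ~150 Å population. Doubling helix 5 moves
the major mode to ~107 Å. The shift (~26–27 Å) matches the arc the extra
helix inserts between the two interface sites (~24 Å from the measured
circumference growth), which is geometrically possible only if the ligands
occupy the helix 4/6 and 6/4 interfaces flanking the helix 5/5 pair.

The other examples (`examples/01`–`04`) walk the belt geometry, the
replicate/ppm filter, span calibration, and the accessible-interaction-space
scan with false-positive flagging. A thin CLI mirrors the main stages:
`beltlink xl-filter`, `beltlink scan`, `beltlink spacing`,
`beltlink simulate`.

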