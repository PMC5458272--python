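# ppiscreen

Structure-based virtual-screening toolkit for inhibitors of
protein–protein interactions (PPIs), built around the discovery cascade
used to find small-molecule disruptors of a kinase/activator complex:
the Aurora-A kinase bound to the 7–11 fragment of its activator TPX2 at
the PIF-pocket groove.

It is aimed at computational chemists and structural bioinformaticians
who want a transparent, fully testable implementation of each stage of
such a cascade:

1. **Interface hot spots** — alignment-column conservation (0 = variable,
   9 = invariant; the mean of an entropy scheme and a BLOSUM62 similarity
   scheme) combined with a computational alanine-scan surrogate
   (ΔΔG ∝ cross-interface heavy-atom contacts lost on truncation to Ala);
   hot spots are conserved residues with ΔΔG inside a 2–4 kJ/mol window.
2. **Protein-based pharmacophore** — from the anchor peptide's contacts:
   aromatic ring centroids with directional normal projections, H-bond
   donors/acceptors projected onto their receptor partners (radii 1.0 Å,
   projections 1.4 Å), excluded volumes from receptor atoms within 4 Å of
   the anchor, essential features on the key tyrosine anchors, and a
   ≥3-feature match rule.
3. **Matching** — rigid (Kabsch) triplet-seeded correspondence search in
   *align* mode, or in-place *absolute* mode for re-filtering docked
   poses; verified against an exhaustive brute-force oracle.
4. **Conformer enumeration** — systematic torsion scan → minimise
   (pluggable force-field contract, MMFF94 default) → strain window
   4 kcal/mol → 0.15 Å RMSD dedupe → 250-conformer cap.
5. **Docking consensus** — engine adapters (a mock engine ships),
   z-score selection (> mean + 2 SD of predicted pKi), pairwise pose RMSD
   < 2 Å across all engines (symmetry-aware, hydrogens ignored, no
   re-superposition), absolute-mode pharmacophore refilter, Tanimoto
   single-linkage clustering with most-potent representatives.
6. **SPR analysis** — 1:1 Langmuir FastStep simulation
   (dR/dt = k_on·C·(R_max − R) − k_off·R, exact piecewise-exponential),
   Scatchard fits (RU/C vs RU; slope = −1/K_d), full-trace kinetic fits,
   and competition IC50s by four-parameter logistic fit, consistent with
   IC50 = K_i·(1 + [P]/K_d,P).

Every stage is exercised end-to-end on synthetic fixtures: a geometric
reconstruction of the interface, engineered active/decoy libraries with
ground-truth labels, mock docking engines, and noisy simulated
sensorgrams with known K_d/K_i.

## Worked example

```sh
ppiscreen synth complex --out toy.pdb
ppiscreen build-ph --pdb toy.pdb --anchor B:7-11 --receptor A:170-206 \
    --essential 8,10 --out hyp.json
```

prints

```
wrote toy.pdb (62 atoms)
6 features / 12 points, 12 exclusion spheres -> hyp.json
```

— the six contact moieties of the anchor peptide (two aromatic rings,
three donors, one carbonyl acceptor, each with its projection, hence 12
points) plus one excluded-volume sphere per receptor atom lining the
groove.  Running the whole cascade on synthetic fixtures:

```sh
ppiscreen run --seed 2 --out run/
```

```
{
  "library": 60,
  "ph_survivors": 30,
  "z_selected": 2,
  "consensus_passed": 2,
  "representatives": 1
}
```

The funnel mirrors the screening protocol: the 30 decoys die at the
pharmacophore screen, the 30 planted actives survive, the two planted
high-scoring engine-consistent "true hits" pass the z-score and
consensus stages, and clustering leaves one representative (the two hits
are structural analogues by construction).  `run/summary.json` records
the ids at each stage alongside the generator's ground-truth labels, and
per-stage manifests carry parameters, counts, and output hashes.

A binding-analysis one-liner:

```sh
ppiscreen spr-sim --kd 42e-6 --noise-sd 0.5 --seed 1 --out gram.csv
ppiscreen spr-fit --csv gram.csv
```

```json
{"method": "scatchard", "ok": true, "kd_M": 4.265e-05, "rmax_RU": 100.26, ...}
```

recovering the simulated 42 µM dissociation constant from the noisy
stepwise-injection trace.

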