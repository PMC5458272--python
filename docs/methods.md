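# Methods

This note documents the models, conventions, and numerical choices
behind each module, what the synthetic fixtures do and do not emulate,
and the known limitations.

## Structures and selections

PDB parsing and writing go through gemmi; only the first MODEL is read.
Residue numbering follows the file verbatim (author numbering), because
the interface residues of interest are cited by author numbers.
Alternate locations collapse to the highest-occupancy conformer, ties
resolved toward altloc `A`.  Insertion codes are rejected — none of the
supported inputs use them, and silent renumbering would corrupt the
provenance of pharmacophore features.  HETATM records are kept but
flagged; the screening protocol drops every heteroatom before hypothesis
construction.  Hydrogens in the input are retained but excluded from
interface extraction, contact counting, and pose RMSDs.

`interface_atoms` returns receptor heavy atoms within a cutoff (default
4 Å) of any anchor heavy atom, via a k-d tree, ordered by
(chain, residue, atom name).  It is monotone in the cutoff and invariant
under rigid motion of the whole complex; both properties are tested
against a brute-force pairwise enumeration.

## Hot-spot scoring

Web conservation servers retrieve their own homolog sets and are not
reproducible offline, so conservation is computed from a user-supplied
alignment with two transparent column schemes: (A) `1 − H/H_max`, with
`H` the column Shannon entropy over the 20 amino acids (gaps ignored),
and (B) the mean pairwise BLOSUM62 similarity of column residues,
rescaled to [0, 1] by the matrix range.  Each scheme is min–max
normalised over columns, the two are averaged, and the result is binned
into ten equal-width bins giving the conventional 0–9 scale.  A column
with a single residue type is pinned to 9 regardless of normalisation,
because "invariant" is the scale's definition, not a relative statement.
When every column has identical raw scores the normalisation is
degenerate and all columns map to 9 — harmless, since such alignments
carry no contrast.

The alanine-scan surrogate is contact-count based, not force-field
based: ΔΔG = k · n, where n counts receptor heavy atoms within 4.5 Å of
any anchor side-chain atom past C-β (what mutation to Ala removes), and
k = 0.1 kJ/mol per contact, calibrated once so that buried tyrosine
anchors land in the canonical 2–4 kJ/mol key-residue window (a partially
buried Tyr in the bundled interface model scores 2.1, a deeply buried
one 3.9).  The surrogate is monotone in the contact cutoff and invariant
under rigid motion.  It is expected to *rank* residues (aromatic anchors
on top), not to reproduce any published per-residue energy; Gly/Ala
score exactly 0, and residues with missing side-chain atoms are reported
as missing rather than zero.  The hot-spot filter is the intersection of
"conservation ≥ 7" and "ΔΔG inside the window", sorted by ΔΔG.  The
window unit is nominally kJ/mol but deliberately configurable: the
literature this protocol derives from mixes kJ/mol and kcal/mol for the
same window, so no unit conversion is assumed.

## Pharmacophore hypothesis

For each anchor residue the builder emits:

* an **aromatic** feature at each ring centroid (ring atoms from residue
  templates; plane by SVD).  The normal projection points at the
  receptor wall: the nearest receptor heavy atom inside a 40° cone
  around either normal, within 6 Å, fixes the sign and the projection
  length; with no wall, the side nearer the receptor centroid is used at
  3 Å.  The partner residue is recorded as provenance.
* a **donor** feature at each N–H/O–H heavy atom (backbone N except
  proline, plus a side-chain table) that has a receptor acceptor within
  3.5 Å; the projection sits on the partner atom itself.  Crystal
  structures carry no hydrogens, so partner pairing is distance-only —
  an angular criterion was considered and rejected because backbone
  geometry in the synthetic fixtures is idealised; the limitation is
  that a dense polar environment could over-annotate donors on real
  structures.
* an **acceptor** feature at each backbone carbonyl O (plus carboxylate
  and amide oxygens) with a receptor donor within 3.5 Å, projected onto
  the donor.

Feature radii default to 1.0 Å and projection radii to 1.4 Å.  Excluded
volumes are one 1.0 Å sphere per receptor heavy atom within 4 Å of the
anchor; exclusion spheres do not count toward the hypothesis's "point"
count (features + projections).  Essential flags go to all features of
caller-named residues (default: every ring-bearing anchor residue);
`min_match` defaults to 3.  Hypotheses serialise to versioned JSON with
explicit Å units.

## Matching

A ligand point matches a feature iff its transformed position lies
within the *feature's* radius (query-sphere semantics, not sum of
radii).  Projection satisfaction: a directional ligand point (ring
normal, polar-hydrogen direction, or bond-opposed lone-pair proxy) must
place its probe — the point offset along its direction by the feature's
own center-to-projection distance — within the projection radius;
direction-free points (donors with implicit hydrogens) instead satisfy a
spherical-shell criterion at that offset.  Aromatic points carry both
normal signs.

Align mode enumerates kind-compatible feature/point pairs, prunes
triplets by distance-matrix compatibility (|Δd| ≤ r_i + r_j, which is
conservative by the triangle inequality), computes the proper-rotation
Kabsch superposition from each surviving triplet, and under that fixed
transform finds the largest injective assignment with essentials
mandatory (branch-and-bound; per-pair feasibility is transform-local, so
candidates are precomputed).  A placement is accepted when all essential
features are matched, at least `min_match` features are matched, and no
ligand heavy atom lies strictly inside an exclusion sphere.  Best result
by (n_matched, then lowest feature RMSD).  The search budget defaults to
1e5 assignment nodes per conformer; on exhaustion remaining seeds extend
greedily (nearest available candidate) and the fallback is logged.
Absolute mode is the identity transform with identical checks — the
docked-pose refilter in which poses may not be translated or rotated.

The matcher is validated against an exhaustive oracle (all
correspondences × all internal triplet seeds, independently coded in the
test suite) with 100% agreement on 200+ random small instances; matched
instances also agree on n_matched.

## Ligand annotation and conformers

Annotation uses the feature-definition pattern set shipped with RDKit
(BaseFeatures), mapped to the four kinds the matcher understands.  Two
suppressions keep the annotation minimal: hydrophobic points whose atoms
are a subset of an aromatic ring (the aromatic point covers the ring),
and hydrophobic points on isolated carbons with no heavy neighbours
(methane is not a hydrophobic patch).

`enumerate_conformers` is the systematic-search contract: torsion grid
over non-ring rotatable bonds (default 60° increments; bonds that move
only hydrogens are skipped because conformers are compared on heavy
atoms), local minimisation of every grid point, strain window
< 4 kcal/mol above the set minimum, duplicate removal at best-superposition
heavy-atom symmetry-aware RMSD < 0.15 Å keeping the lower-energy member,
and a 250-conformer cap by energy.  The minimiser is a contract
(`minimize(mol, conf_id, max_iter=200, grad_tol=0.001) -> kcal/mol`):
the shipped default is RDKit's MMFF94; a deterministic single-torsion
toy potential ships for algorithm tests, so the scan/filter/dedupe logic
is tested independently of force-field numerics (n-butane at 120°:
anti + two mirror-related gauche minima, which are genuine non-duplicates
under proper-rotation RMSD).

## Screening cascade

z-score selection takes compounds scoring strictly above mean + 2 SD
(sample SD); the strict inequality follows the protocol's method
section.  Zero variance yields an empty selection with a logged warning.
Pose RMSD is computed in the shared receptor frame without
re-superposition, heavy atoms only; the symmetry-aware variant minimises
over the heavy-atom graph automorphisms (from RDKit substructure
self-matches, capped at 10^4).  Consensus requires a pose from every
engine, all pairwise RMSDs below 2 Å, and an absolute-mode hypothesis
match of a designated engine's pose (first engine alphabetically by
default, configurable).  Clustering is single-linkage connected
components over Tanimoto similarity ≥ 0.7 on hashed topological
fingerprints; each cluster is represented by its highest-scoring member
(ties broken lexicographically).  Docking engines are adapters — the
published grid/search parameters are adapter configuration to be passed
through verbatim, and only a mock engine is implemented here; docking
itself is out of scope.

## SPR model and fitting

Binding follows 1:1 Langmuir kinetics, dR/dt = k_on·C(t)·(R_max − R) −
k_off·R with k_off = k_on·K_d.  The injection program is
piecewise-constant (six serial doubling steps of 25 s by default, then a
single dissociation phase), so each interval has the exact solution
R(t) = R_eq + (R_0 − R_eq)·e^(−k_obs t); the simulator evaluates this
closed form on a 0.25 s grid — no ODE integrator, no accumulation error
(verified to 1e-6 RU against an independently coded recursion).
Gaussian noise is added pointwise; the default simulation noise is 1% of
R_max.  Default k_on is 1e5 M⁻¹s⁻¹; the nanomolar reference-inhibitor
simulations use 1e6 M⁻¹s⁻¹, a typical small-molecule association rate,
so the doubling ladder produces usable curvature within 25 s steps.

Scatchard fitting regresses RU/C on RU; slope = −1/K_d, x-intercept =
R_max.  A non-negative slope (no saturation) returns a failed-fit result
rather than raising.  Because 25 s steps need not equilibrate, the
simulator exposes both observed step-end responses and true equilibrium
responses, making the Scatchard bias at slow kinetics measurable; for
nanomolar ladders the package instead offers a full-trace kinetic least
squares fit over (k_on, k_off, R_max) in log space, multi-started over
four k_on decades.  At micromolar affinities (k_obs ≥ 1 s⁻¹) step-end
responses equilibrate and Scatchard is unbiased.

Competition assumes trace immobilised receptor, so free concentrations
equal totals and the partner's fractional occupancy is
(P/K_d,P) / (1 + P/K_d,P + I/K_i); reported RU reflects partner binding
only (the inhibitor's rapid binding/dissociation signal is assumed
subtracted, and the read-out corresponds to the fixed post-association
read point of the protocol).  This model's IC50 satisfies
IC50 = K_i·(1 + [P]/K_d,P) exactly; the test suite cross-checks it
against numerical solution of the coupled equilibria with explicit
depletion at finite receptor density (agreement well within 2%).  IC50s
are fitted with a four-parameter logistic in log concentration, standard
errors from the covariance by the delta method.  A profile that never
drops by 20% of its top signal returns a *non-competing* verdict — the
expected outcome for binders that do not displace the partner — instead
of a forced fit.

## Synthetic fixtures

`make_toy_complex` builds a peptide laid along one axis with idealised
side-chain templates and receptor side-chain fragments placed at
declared contact geometry; generation fails unless the default builder
reproduces the declared feature provenance exactly.  The bundled default
(`aurora_interface_spec`) is a synthetic coordinate reconstruction of
the kinase/activator 7–11 interface realising the six published contact
moieties; it is *not* crystallographic data, and tests using it validate
the builder's logic and provenance bookkeeping, not agreement with the
crystal structure.  Peptide geometry is intentionally stylised (one
residue is lifted out of the strand so that the bridging receptor
hydroxyl pairs only with its two intended partners).

Library actives are disconnected rigid fragments (benzene / methanol /
formaldehyde) placed at hypothesis feature centers with Gaussian
positional jitter well below the 1.0 Å feature radius; auxiliary atoms
are oriented to maximise clearance from exclusion spheres so small
docking perturbations cannot create violations.  Decoys are embedded
alkanes (feature-free) or fragment-scrambled actives
(geometry-violating).  Every generated library is verified at build time
against the matcher, and ground-truth labels ship beside the fixtures so
downstream tests never re-derive truth from the code under test.
Actives are geometric constructs: they establish that the cascade
recovers what satisfies the hypothesis and rejects what does not, and
say nothing about enrichment on real chemotypes.

Mock docking emits per-engine copies of each compound's pose: consistent
compounds get independent rigid translations of up to 0.35 Å (pairwise
RMSD ≤ 0.7 Å, comfortably under the 2 Å consensus threshold),
inconsistent ones a 6 Å displacement from one engine.  Scores draw from
the configured normal distribution — defaults are the drug-like
predicted-pKi distribution 5.89 ± 0.93 (lead-like: 5.10 ± 0.21) — and
planted true hits score 8 SD above the mean so they survive z-selection
by construction in pools of ≥ ~25 compounds (in smaller pools the
boosted scores inflate the sample SD enough to swallow them, which is a
property of tail selection, not a bug).

All generators are pure functions of (spec, seed); PDB/SDF/CSV bytes are
stable across runs.

## Pipeline

The pipeline default library is 30 actives + 30 decoys with 2 planted
true hits — sized so the full run takes about half a second while every
stage still has discriminating work to do.  A single config seed fans
out to per-stage seeds by stable hashing (`base·1000003 + crc32(stage)`,
mod 2³¹−1).  Each stage writes a manifest (parameters, counts, SHA-256
of outputs); identical configs reproduce outputs byte-for-byte.
Validation rejects unknown config keys before anything runs.

## Problem sizes

The published screen covered ~8×10⁶ compounds and three commercial
docking engines; this package's fixtures run the same cascade logic at
desk scale (10¹–10² compounds, mock engines), which the funnel's
property suite covers: planted actives fully recovered, decoys fully
rejected, each stage's output a subset of its input.  SPR recovery
studies use 100 noisy replicates per condition; the matcher/oracle
equivalence uses 200+ random instances capped at ~5 features and ~8
points, where exhaustive enumeration is tractable.

## Known limitations

* Donor/acceptor pairing is distance-only (no D–H···A angle term) and
  the donor/acceptor atom tables cover the standard amino acids only.
* The ΔΔG surrogate has no desolvation, electrostatics, or entropy; its
  scale is a calibration, and only its ranking is meaningful.
* Conformer enumeration skips hydrogen-only torsions and caps the grid,
  so hydroxyl rotamer fine structure is not explored.
* The competition model ignores mass-transport limitation and surface
  heterogeneity; the kinetic fit assumes a clean single-exponential
  dissociation.
* mmCIF, multi-model NMR inputs, and protonation-state assignment are
  out of scope; structures are assumed prepared.
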