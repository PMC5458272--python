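"""Synthetic fixtures: toy complexes, ligand libraries, mock docking, sensorgrams.

Everything the cascade consumes can be generated here deterministically,
so every stage is testable without downloads.  All generators are pure
functions of (spec, seed) and ship ground-truth labels beside the
fixtures, so downstream tests never re-derive truth from the code under
test.

The default toy complex is a **synthetic coordinate reconstruction** of
the kinase/activator-peptide interface this package was built around: a
five-residue Ser-Tyr-Ser-Tyr-Asp anchor (numbered 7-11) laid into a
groove whose receptor side-chain fragments realise the six published
contact moieties (Tyr8 ring->Val206, Tyr8 OH->Glu170, Tyr10
ring->Leu178/Val182/Tyr199 groove, Tyr10 N->Tyr199, Asp11 N->Glu183,
Tyr8 C=O->Tyr199).  These are idealised coordinates built from declared
contact geometry, not crystallographic ones.

Ligand "actives" are geometric constructs, not drug-like chemistry: small
rigid fragments (benzene, methanol, formaldehyde) placed at hypothesis
feature centers with sub-radius jitter, so they must match by
construction; decoys are feature-free alkanes or geometry-scrambled
actives.  Realistic chemistry of actives is a non-goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from . import spr
from .cascade import DockedPose
from .ligand import annotate_ligand
from .pharmacophore import PharmacophoreHypothesis, build_hypothesis, match
from .structure import Atom, ResidueSelection, Structure, write_structure

__all__ = [
    "ToyComplexSpec",
    "ToyComplex",
    "aurora_interface_spec",
    "make_toy_complex",
    "LibrarySpec",
    "SyntheticLibrary",
    "make_library",
    "MockEngineSpec",
    "make_mock_docking",
    "make_sensorgrams",
]


# --------------------------------------------------------------------------
# toy receptor-peptide complexes
# --------------------------------------------------------------------------

_ONE_TO_THREE = {
    "G": "GLY", "A": "ALA", "S": "SER", "Y": "TYR", "D": "ASP", "F": "PHE",
}
_AROMATIC_LETTERS = set("YF")

# Side-chain templates relative to CA, built pointing "down" (-z);
# flipped residues negate z.  Rings are ideal hexagons (edge 1.39 A).
_SIDECHAINS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", "C", (0.0, -0.3, -1.45))],
    "SER": [("CB", "C", (0.0, -0.3, -1.45)), ("OG", "O", (0.0, -0.6, -2.75))],
    "ASP": [
        ("CB", "C", (0.0, -0.3, -1.45)),
        ("CG", "C", (0.0, -0.3, -2.9)),
        ("OD1", "O", (-0.7, -0.3, -3.9)),
        ("OD2", "O", (0.7, -0.3, -3.9)),
    ],
    "PHE": [
        ("CB", "C", (0.0, -0.3, -1.45)),
        ("CG", "C", (0.0, -0.3, -2.9)),
        ("CD1", "C", (1.2, -0.3, -3.6)),
        ("CD2", "C", (-1.2, -0.3, -3.6)),
        ("CE1", "C", (1.2, -0.3, -4.99)),
        ("CE2", "C", (-1.2, -0.3, -4.99)),
        ("CZ", "C", (0.0, -0.3, -5.68)),
    ],
}
_SIDECHAINS["TYR"] = _SIDECHAINS["PHE"] + [("OH", "O", (0.0, -0.3, -7.06))]

_CA_SPACING = 3.5


@dataclass(frozen=True)
class ReceptorAtomSpec:
    residue_name: str
    residue_number: int
    atom_name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class ToyComplexSpec:
    """Declarative recipe for a toy receptor-peptide complex.

    The anchor peptide (3-6 residues, at least two aromatic) is laid
    along +x; aromatic residues point their side chains into the groove
    (-z), others away (+z).  ``receptor_atoms`` are placed at declared
    contact geometry in absolute coordinates.  ``expected_features``
    documents the provenance the default hypothesis builder must emit;
    generation fails if the declared contacts cannot be reproduced.
    """

    anchor_sequence: str
    anchor_start: int = 7
    anchor_chain: str = "B"
    receptor_chain: str = "A"
    receptor_atoms: tuple[ReceptorAtomSpec, ...] = ()
    carbonyl_down: frozenset[int] = frozenset()
    residue_lift: tuple[tuple[int, float], ...] = ()
    expected_features: tuple[tuple[str, int, str], ...] = ()  # (kind, resnum, partner residue label)
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if not 3 <= len(self.anchor_sequence) <= 6:
            raise ValueError("anchor sequence must have 3-6 residues")
        n_arom = sum(1 for c in self.anchor_sequence if c in _AROMATIC_LETTERS)
        if n_arom < 2:
            raise ValueError("anchor sequence must contain >=2 aromatic residues")
        unknown = [c for c in self.anchor_sequence if c not in _ONE_TO_THREE]
        if unknown:
            raise ValueError(f"unsupported residues {unknown}")


@dataclass
class ToyComplex:
    structure: Structure
    anchor: ResidueSelection
    receptor: ResidueSelection
    pdb_text: str
    n_atoms: int
    spec: ToyComplexSpec


def aurora_interface_spec(seed: int = 0, jitter: float = 0.0) -> ToyComplexSpec:
    """Synthetic reconstruction of the kinase/activator 7-11 interface.

    Idealised stand-in coordinates (not crystallographic): receptor
    side-chain fragments are placed so the default builder reproduces
    the six published contact moieties exactly.
    """
    y8_center = np.array([_CA_SPACING * 1, -0.3, -4.29])
    y8_oh = np.array([_CA_SPACING * 1, -0.3, -7.06])
    y10_center = np.array([_CA_SPACING * 3, -0.3, -4.29])
    rec = [
        # Val206 wall under the first ring normal
        ReceptorAtomSpec("VAL", 206, "CG1", "C", tuple(y8_center + (0, -3.6, 0))),
        ReceptorAtomSpec("VAL", 206, "CB", "C", tuple(y8_center + (0, -4.6, -0.7))),
        ReceptorAtomSpec("VAL", 206, "CG2", "C", tuple(y8_center + (-1.2, -4.5, 0.3))),
        # Glu170 carboxylate accepting the Tyr8 hydroxyl
        ReceptorAtomSpec("GLU", 170, "OE1", "O", tuple(y8_oh + (0, -0.5, -2.64))),
        ReceptorAtomSpec("GLU", 170, "CD", "C", tuple(y8_oh + (0.4, -0.5, -3.79))),
        ReceptorAtomSpec("GLU", 170, "OE2", "O", tuple(y8_oh + (1.3, -0.5, -4.44))),
        # Tyr199 hydroxyl bridging Tyr8 C=O (as donor) and Tyr10 N (as acceptor)
        ReceptorAtomSpec("TYR", 199, "OH", "O", (7.0, 0.3, -2.4)),
        ReceptorAtomSpec("TYR", 199, "CZ", "C", (7.0, 1.3, -3.2)),
        ReceptorAtomSpec("TYR", 199, "CE1", "C", (6.2, 2.2, -3.6)),
        ReceptorAtomSpec("TYR", 199, "CE2", "C", (7.8, 2.2, -3.6)),
        # Leu178/Val182 groove under the second ring normal
        ReceptorAtomSpec("LEU", 178, "CD1", "C", tuple(y10_center + (0, -3.6, 0))),
        ReceptorAtomSpec("LEU", 178, "CG", "C", tuple(y10_center + (0, -4.6, -0.9))),
        ReceptorAtomSpec("LEU", 178, "CD2", "C", tuple(y10_center + (1.2, -4.9, 0.1))),
        ReceptorAtomSpec("VAL", 182, "CG1", "C", tuple(y10_center + (-1.5, -3.6, -1.2))),
        ReceptorAtomSpec("VAL", 182, "CB", "C", tuple(y10_center + (-2.1, -4.6, -1.8))),
        # Glu183 carboxylate accepting the Asp11 backbone N-H
        ReceptorAtomSpec("GLU", 183, "OE1", "O", (12.75, 0.3, -2.9)),
        ReceptorAtomSpec("GLU", 183, "CD", "C", (13.35, 0.3, -3.95)),
        ReceptorAtomSpec("GLU", 183, "OE2", "O", (14.5, 0.3, -4.3)),
    ]
    expected = (
        ("aromatic", 8, "VAL206"),
        ("donor", 8, "GLU170"),
        ("acceptor", 8, "TYR199"),
        ("aromatic", 10, "LEU178"),
        ("donor", 10, "TYR199"),
        ("donor", 11, "GLU183"),
    )
    return ToyComplexSpec(
        anchor_sequence="SYSYD",
        anchor_start=7,
        receptor_atoms=tuple(rec),
        carbonyl_down=frozenset({8}),
        residue_lift=((9, 1.5),),
        expected_features=expected,
        seed=seed,
        jitter=jitter,
    )


def make_toy_complex(spec: ToyComplexSpec) -> ToyComplex:
    """Build the complex, write PDB text, and verify declared contacts.

    The generated structure is fed to the default hypothesis builder and
    its (kind, residue, partner) provenance must equal the spec's
    ``expected_features`` (when declared); otherwise the spec cannot
    host its contacts and generation fails.
    """
    rng = np.random.default_rng(spec.seed)
    lift = dict(spec.residue_lift)
    atoms: list[Atom] = []
    serial = 1

    def add(chain, resnum, resname, name, element, xyz, hetero=False):
        nonlocal serial
        x, y, z = (float(v) for v in xyz)
        atoms.append(
            Atom(
                chain_id=chain,
                residue_number=resnum,
                name=name,
                serial=serial,
                element=element,
                residue_name=resname,
                x=round(x, 3),
                y=round(y, 3),
                z=round(z, 3),
                hetero=hetero,
            )
        )
        serial += 1

    for spec_atom in spec.receptor_atoms:
        add(
            spec.receptor_chain,
            spec_atom.residue_number,
            spec_atom.residue_name,
            spec_atom.atom_name,
            spec_atom.element,
            spec_atom.xyz,
        )

    for i, letter in enumerate(spec.anchor_sequence):
        resnum = spec.anchor_start + i
        resname = _ONE_TO_THREE[letter]
        dz = lift.get(resnum, 0.0)
        ca = np.array([_CA_SPACING * i, 0.0, dz])
        flip = 1.0 if letter in _AROMATIC_LETTERS else -1.0  # aromatics keep -z
        o_dir = (
            np.array([0.0, 0.0, -1.23])
            if resnum in spec.carbonyl_down
            else np.array([0.0, 0.0, 1.23])
        )
        jit = (
            rng.normal(0.0, spec.jitter, size=3)
            if spec.jitter > 0
            else np.zeros(3)
        )
        add(spec.anchor_chain, resnum, resname, "N", "N", ca + [-1.25, 0.3, 0] + jit)
        add(spec.anchor_chain, resnum, resname, "CA", "C", ca + jit)
        add(spec.anchor_chain, resnum, resname, "C", "C", ca + [1.25, 0.3, 0] + jit)
        add(spec.anchor_chain, resnum, resname, "O", "O", ca + [1.25, 0.3, 0] + o_dir + jit)
        for name, element, rel in _SIDECHAINS[resname]:
            rel = np.array(rel) * np.array([1.0, 1.0, flip])
            add(spec.anchor_chain, resnum, resname, name, element, ca + rel + jit)

    structure = Structure(atoms=atoms, name="toy-complex")
    anchor = ResidueSelection(
        chain_id=spec.anchor_chain,
        residue_numbers=tuple(
            spec.anchor_start + i for i in range(len(spec.anchor_sequence))
        ),
        role="anchor",
    )
    receptor_res = tuple(
        sorted({a.residue_number for a in spec.receptor_atoms})
    )
    receptor = ResidueSelection(
        chain_id=spec.receptor_chain, residue_numbers=receptor_res, role="receptor"
    )

    if spec.expected_features:
        hyp = build_hypothesis(structure, anchor, receptor)
        got = sorted(
            (f.kind, int(f.source.split("/")[0][3:]), f.partner.split("/")[0])
            for f in hyp.features
        )
        want = sorted(
            (kind, resnum, partner) for kind, resnum, partner in spec.expected_features
        )
        if got != want:
            raise ValueError(
                f"spec cannot host declared contacts: built {got}, declared {want}"
            )

    pdb_text = write_structure(structure)
    return ToyComplex(
        structure=structure,
        anchor=anchor,
        receptor=receptor,
        pdb_text=pdb_text,
        n_atoms=len(atoms),
        spec=spec,
    )


# --------------------------------------------------------------------------
# active/decoy libraries
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LibrarySpec:
    """Engineered screening library: planted actives plus decoys.

    Actives place ligand feature points at hypothesis feature centers
    with positional jitter strictly below the feature radius; decoys are
    either feature-free alkanes or geometry-scrambled actives.
    """

    n_actives: int = 20
    n_decoys: int = 80
    seed: int = 0
    jitter: float = 0.3
    decoy_rule: str = "alkane"  # or "scrambled"

    def __post_init__(self) -> None:
        if self.n_actives < 0 or self.n_decoys < 0:
            raise ValueError("library sizes must be >= 0")
        if self.decoy_rule not in ("alkane", "scrambled"):
            raise ValueError("decoy_rule must be 'alkane' or 'scrambled'")


@dataclass
class SyntheticLibrary:
    mols: dict[str, Chem.Mol]
    labels: dict[str, bool]  # True = active (ground truth)

    @property
    def active_ids(self) -> list[str]:
        return sorted(cid for cid, lab in self.labels.items() if lab)

    def labels_tsv(self) -> str:
        lines = ["compound_id\tis_active"]
        lines += [f"{cid}\t{int(self.labels[cid])}" for cid in sorted(self.labels)]
        return "\n".join(lines) + "\n"


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _orthonormal_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(normal, ref))
    return u, np.cross(normal, u)


def _build_active(
    hyp: PharmacophoreHypothesis, rng: np.random.Generator, jitter: float, name: str
) -> Chem.Mol:
    """Fragment assembly satisfying every hypothesis feature.

    One benzene per aromatic feature (plane normal along the feature's
    projection axis), one methanol per donor (O-H aimed at the
    projection point), one formaldehyde per acceptor (C=O axis opposed
    to the projection direction).  Auxiliary atoms are oriented to
    maximise clearance from the exclusion spheres so that small rigid
    pose perturbations downstream cannot create violations.  Fragments
    are disconnected on purpose: the construct is geometric, not
    medicinal chemistry.
    """
    em = Chem.RWMol()
    conf_pos: list[tuple[float, float, float]] = []
    excl_centers = (
        np.array([e.center for e in hyp.exclusions])
        if hyp.exclusions
        else np.zeros((0, 3))
    )

    def clearance(pos: np.ndarray) -> float:
        if not len(excl_centers):
            return np.inf
        return float(np.linalg.norm(excl_centers - pos, axis=1).min())

    def best_offset(center: np.ndarray, axis: np.ndarray, length: float, tilt: float) -> np.ndarray:
        """Position at ``length`` from center, tilted off -axis, max clearance."""
        cands = []
        for k in range(6):
            ang = k * math.pi / 3.0
            u, v = _orthonormal_frame(axis)
            side = math.cos(ang) * u + math.sin(ang) * v
            pos = center + length * _unit(-axis + tilt * side)
            cands.append((clearance(pos), tuple(pos)))
        return np.array(max(cands)[1])

    def add_atom(symbol: str, pos: np.ndarray, charge: int = 0) -> int:
        a = Chem.Atom(symbol)
        a.SetFormalCharge(charge)
        idx = em.AddAtom(a)
        conf_pos.append(tuple(float(v) for v in pos))
        return idx

    for f in hyp.features:
        center = f.center + rng.normal(0.0, jitter / 3.0, size=3)
        axis = _unit(f.projection - f.center) if f.projection is not None else np.array([0.0, 0.0, 1.0])
        if f.kind == "aromatic":
            u, v = _orthonormal_frame(axis)
            ring = []
            for k in range(6):
                ang = k * math.pi / 3.0
                ring.append(
                    add_atom("C", center + 1.39 * (math.cos(ang) * u + math.sin(ang) * v))
                )
            for k in range(6):
                b = em.AddBond(ring[k], ring[(k + 1) % 6], Chem.BondType.AROMATIC)
            for idx in ring:
                em.GetAtomWithIdx(idx).SetIsAromatic(True)
            for k in range(6):
                em.GetBondBetweenAtoms(ring[k], ring[(k + 1) % 6]).SetIsAromatic(True)
        elif f.kind == "donor":
            o = add_atom("O", center)
            h = add_atom("H", center + 0.96 * axis)
            c = add_atom("C", best_offset(center, axis, 1.43, 0.8))
            em.AddBond(o, h, Chem.BondType.SINGLE)
            em.AddBond(o, c, Chem.BondType.SINGLE)
        elif f.kind == "acceptor":
            o = add_atom("O", center)
            c = add_atom("C", best_offset(center, axis, 1.22, 0.2))
            em.AddBond(o, c, Chem.BondType.DOUBLE)
        else:  # hydrophobic: a methane-like carbon blob offset nowhere
            add_atom("C", center)

    mol = em.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, pos in enumerate(conf_pos):
        conf.SetAtomPosition(i, pos)
    mol.AddConformer(conf, assignId=True)
    mol.SetProp("_Name", name)
    return mol


def _build_alkane(rng: np.random.Generator, name: str) -> Chem.Mol:
    n = int(rng.integers(4, 9))
    mol = Chem.AddHs(Chem.MolFromSmiles("C" * n))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(rng.integers(0, 2**31 - 1))
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError("alkane embedding failed")
    mol.SetProp("_Name", name)
    return mol


def _scramble(mol: Chem.Mol, rng: np.random.Generator, name: str) -> Chem.Mol:
    """Displace each fragment independently so feature geometry breaks."""
    out = Chem.Mol(mol)
    conf = out.GetConformer(0)
    for frag in Chem.GetMolFrags(out):
        shift = rng.normal(0.0, 1.0, size=3)
        shift = _unit(shift) * rng.uniform(4.0, 8.0)
        for idx in frag:
            p = conf.GetAtomPosition(idx)
            conf.SetAtomPosition(idx, (p.x + shift[0], p.y + shift[1], p.z + shift[2]))
    out.SetProp("_Name", name)
    return out


def make_library(
    spec: LibrarySpec, hyp: PharmacophoreHypothesis, verify: bool = True
) -> SyntheticLibrary:
    """Generate the labelled active/decoy library for a hypothesis.

    With ``verify`` (default) every active is checked to match in align
    mode and every decoy to fail; a spec whose jitter is not strictly
    below the smallest feature radius is rejected up front.
    """
    min_radius = min((f.radius for f in hyp.features), default=1.0)
    if spec.jitter >= min_radius:
        raise ValueError("jitter must be strictly below the feature radius")
    rng = np.random.default_rng(spec.seed)
    mols: dict[str, Chem.Mol] = {}
    labels: dict[str, bool] = {}
    for k in range(spec.n_actives):
        cid = f"ACT{k:04d}"
        mols[cid] = _build_active(hyp, rng, spec.jitter, cid)
        labels[cid] = True
    for k in range(spec.n_decoys):
        cid = f"DEC{k:04d}"
        if spec.decoy_rule == "alkane":
            mols[cid] = _build_alkane(rng, cid)
        else:
            template = _build_active(hyp, rng, spec.jitter, cid)
            mols[cid] = _scramble(template, rng, cid)
        labels[cid] = False
    if verify:
        for cid, mol in mols.items():
            conf = annotate_ligand(mol)
            hit = match(hyp, conf, mode="align", first_match=True).matched
            if hit != labels[cid]:
                raise RuntimeError(
                    f"library construction failed: {cid} matched={hit}, "
                    f"label={labels[cid]}"
                )
    return SyntheticLibrary(mols=mols, labels=labels)


# --------------------------------------------------------------------------
# mock docking
# --------------------------------------------------------------------------


def make_anchor_msa(
    sequence: str,
    n_seqs: int = 12,
    seed: int = 0,
    conserved: str = "YFWD",
) -> str:
    """Aligned FASTA of synthetic anchor homologs.

    Residues in ``conserved`` are kept invariant across rows (the
    functional anchor positions); all others mutate with 60% probability
    per row, emulating the conservation contrast real alignments show at
    interface hot spots.
    """
    rng = np.random.default_rng(seed)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    rows = [sequence]
    for _ in range(n_seqs - 1):
        row = []
        for c in sequence:
            if c in conserved or rng.random() > 0.6:
                row.append(c)
            else:
                row.append(alphabet[int(rng.integers(0, 20))])
        rows.append("".join(row))
    return "".join(f">seq{i}\n{r}\n" for i, r in enumerate(rows))


@dataclass(frozen=True)
class MockEngineSpec:
    """Score distributions and pose jitter for the mock docking engines.

    Score means/SDs default to the printed drug-like predicted-pKi
    distribution (5.89 +/- 0.93); the lead-like one is 5.10 +/- 0.21.
    Consistent compounds receive per-engine rigid translations small
    enough that pairwise pose RMSD stays below 2 A; inconsistent ones
    get a >=5 A displacement from the last engine.
    """

    engines: tuple[str, ...] = ("dovis", "vina", "moldock")
    score_mean: float = 5.89
    score_sd: float = 0.93
    consistent_jitter: float = 0.35
    inconsistent_shift: float = 6.0
    seed: int = 0


class MockDockingEngine:
    """Adapter-contract stand-in for an external docking program."""

    def __init__(self, name: str, poses: dict[str, DockedPose]):
        self.name = name
        self._poses = poses

    def dock(self, mols: dict[str, Chem.Mol]) -> dict[str, DockedPose]:
        return {cid: self._poses[cid] for cid in mols if cid in self._poses}


def make_mock_docking(
    mols: dict[str, Chem.Mol],
    spec: MockEngineSpec,
    consistent_ids: set[str] | None = None,
    boosted_ids: set[str] | None = None,
    boost_sd: float = 8.0,
) -> tuple[dict[str, dict[str, DockedPose]], dict[str, float]]:
    """Per-engine top poses plus per-compound consensus ground truth.

    Returns ``(poses[compound][engine], scores[compound])`` where the
    scores are the first engine's draws from the configured normal
    distribution.  ``consistent_ids`` defaults to all compounds.
    ``boosted_ids`` (planted true hits) score ``boost_sd`` standard
    deviations above the mean (kept a small fraction of the pool so the
    selection statistics stay tail-like), with a small spread, so they survive the
    z-score selection stage by construction.
    """
    rng = np.random.default_rng(spec.seed)
    if consistent_ids is None:
        consistent_ids = set(mols)
    if boosted_ids is None:
        boosted_ids = set()
    poses: dict[str, dict[str, DockedPose]] = {}
    scores: dict[str, float] = {}
    for cid in sorted(mols):
        mol = mols[cid]
        heavy = np.array(
            [
                mol.GetConformer(0).GetAtomPosition(a.GetIdx())
                for a in mol.GetAtoms()
                if a.GetAtomicNum() > 1
            ]
        )
        heavy = heavy.reshape(-1, 3)
        per: dict[str, DockedPose] = {}
        for k, engine in enumerate(spec.engines):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            if cid in consistent_ids or k < len(spec.engines) - 1:
                shift = direction * rng.uniform(0.0, spec.consistent_jitter)
            else:
                shift = direction * spec.inconsistent_shift
            if cid in boosted_ids:
                score = float(
                    spec.score_mean
                    + boost_sd * spec.score_sd
                    + rng.normal(0.0, 0.1 * spec.score_sd)
                )
            else:
                score = float(rng.normal(spec.score_mean, spec.score_sd))
            per[engine] = DockedPose(
                compound_id=cid,
                engine=engine,
                mol=mol,
                coords=heavy + shift,
                score=score,
            )
        poses[cid] = per
        scores[cid] = per[spec.engines[0]].score
    return poses, scores


# --------------------------------------------------------------------------
# sensorgram bundles
# --------------------------------------------------------------------------


def make_sensorgrams(
    truths: list[dict],
    noise_sd: float = 0.5,
    seed: int = 0,
    kon: float = spr.DEFAULT_KON,
    step_seconds: float = 25.0,
    dissociation_seconds: float = 300.0,
) -> dict[str, dict]:
    """Simulated SPR bundle with ground truth recorded beside each trace.

    Each truth is a dict: ``{"compound": id, "kind": "kd", "kd": M,
    "rmax": RU, "ladder": [M, ...]}`` for direct FastStep binding, or
    ``{"kind": "ic50", "ki": M, "partner_kd": M, "partner_conc": M,
    "rmax": RU, "inhibitor_concs": [M, ...]}`` for competition.
    """
    rng = np.random.default_rng(seed)
    bundle: dict[str, dict] = {}
    for truth in truths:
        cid = truth["compound"]
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if truth["kind"] == "kd":
            program = spr.InjectionProgram.faststep(
                truth["ladder"],
                step_seconds=step_seconds,
                dissociation_seconds=dissociation_seconds,
            )
            gram = spr.simulate_faststep(
                kd=truth["kd"],
                kon=truth.get("kon", kon),
                rmax=truth["rmax"],
                program=program,
                noise_sd=noise_sd,
                seed=sub_seed,
            )
            bundle[cid] = {"kind": "kd", "truth": dict(truth), "csv": gram.to_csv()}
        elif truth["kind"] == "ic50":
            ru = spr.simulate_competition(
                kd_partner=truth["partner_kd"],
                partner_conc=truth["partner_conc"],
                ki_inhibitor=truth["ki"],
                inhibitor_concs=truth["inhibitor_concs"],
                rmax_partner=truth["rmax"],
                noise_sd=noise_sd,
                seed=sub_seed,
            )
            rows = "\n".join(
                f"{c:.8g},{r:.6f}"
                for c, r in zip(truth["inhibitor_concs"], ru)
            )
            bundle[cid] = {
                "kind": "ic50",
                "truth": dict(truth),
                "csv": "inhibitor_conc_M,ru\n" + rows + "\n",
            }
        else:
            raise ValueError(f"unknown truth kind {truth['kind']!r}")
    return bundle
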