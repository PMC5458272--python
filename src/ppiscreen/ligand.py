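"""Small-molecule handling: I/O, feature annotation, conformer enumeration.

Molecules are RDKit ``Mol`` objects throughout; SMILES/SDF readers and
writers are thin RDKit wrappers.  Ligand pharmacophore annotation uses
the feature-definition pattern set shipped with RDKit (BaseFeatures),
reduced to the four kinds the matcher understands.

Conformer enumeration follows the classic systematic-search recipe:
torsion-scan every non-ring rotatable bond in fixed increments, locally
minimise each grid point with a pluggable minimiser, discard strained
conformers (strain measured from the set's minimum), remove duplicates by
best-superposition heavy-atom RMSD, and cap the set size, keeping the
lowest-energy members.  The force field itself is deliberately a
*contract*: the shipped default is RDKit's MMFF94 implementation, and a
deterministic toy torsional potential is provided for algorithm tests.
"""

from __future__ import annotations

import itertools
import logging
import os
from dataclasses import dataclass
from typing import Protocol

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import AllChem, ChemicalFeatures

from .pharmacophore import AnnotatedConformer, LigandPoint

logger = logging.getLogger(__name__)

__all__ = [
    "mol_from_smiles",
    "read_sdf",
    "write_sdf",
    "annotate_ligand",
    "Minimizer",
    "MMFFMinimizer",
    "ToyTorsionMinimizer",
    "ConformerSet",
    "enumerate_conformers",
]

STRAIN_TAG = "ppiscreen_strain_kcal_mol"

_FAMILY_MAP = {
    "Aromatic": "aromatic",
    "Donor": "donor",
    "Acceptor": "acceptor",
    "Hydrophobe": "hydrophobic",
    "LumpedHydrophobe": "hydrophobic",
}

_factory = None


def _feature_factory():
    global _factory
    if _factory is None:
        _factory = ChemicalFeatures.BuildFeatureFactory(
            os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
        )
    return _factory


def mol_from_smiles(smiles: str, name: str = "", source_id: str = "") -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    if name:
        mol.SetProp("_Name", name)
    if source_id:
        mol.SetProp("source_id", source_id)
    return mol


def read_sdf(path_or_text: str) -> list[Chem.Mol]:
    """Read molecules from an SDF path or SDF-format text."""
    if "\n" in path_or_text or not os.path.exists(path_or_text):
        supplier = Chem.SDMolSupplier()
        supplier.SetData(path_or_text, removeHs=False)
    else:
        supplier = Chem.SDMolSupplier(path_or_text, removeHs=False)
    mols = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unreadable molecule at SDF record {i}")
        mols.append(mol)
    return mols


def write_sdf(mols, path: str, strains: dict[str, float] | None = None) -> None:
    writer = Chem.SDWriter(path)
    writer.SetForceV3000(False)
    try:
        for mol in mols:
            if strains is not None and mol.HasProp("_Name"):
                nm = mol.GetProp("_Name")
                if nm in strains:
                    mol.SetProp(STRAIN_TAG, f"{strains[nm]:.4f}")
            writer.write(mol)
    finally:
        writer.close()


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    c = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - c)
    n = vt[2]
    return n / np.linalg.norm(n)


def annotate_ligand(mol: Chem.Mol, conf_id: int = 0) -> AnnotatedConformer:
    """Annotate a 3D conformer with typed pharmacophore points.

    Aromatic rings yield centroid points carrying both ring normals;
    donors carry one direction per explicit polar hydrogen (direction-free
    when hydrogens are implicit); acceptors carry the bond-opposed
    lone-pair proxy.  Hydrophobic points whose atoms all belong to an
    aromatic ring are suppressed (the aromatic point already covers the
    ring).  Raises when the molecule has no 3D conformer.
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D conformer")
    Chem.SanitizeMol(mol)
    conf = mol.GetConformer(conf_id)
    coords = conf.GetPositions()

    feats = _feature_factory().GetFeaturesForMol(mol, confId=conf_id)
    aromatic_atom_sets: list[frozenset[int]] = []
    raw: list[tuple[str, tuple[int, ...]]] = []
    for f in feats:
        kind = _FAMILY_MAP.get(f.GetFamily())
        if kind is None:
            continue
        ids = tuple(sorted(f.GetAtomIds()))
        raw.append((kind, ids))
        if kind == "aromatic":
            aromatic_atom_sets.append(frozenset(ids))

    points: list[LigandPoint] = []
    seen: set[tuple[str, tuple[int, ...]]] = set()
    for kind, ids in raw:
        if (kind, ids) in seen:
            continue
        seen.add((kind, ids))
        if kind == "hydrophobic":
            if any(frozenset(ids) <= ring for ring in aromatic_atom_sets):
                continue
            # an isolated carbon (no heavy neighbours) is not a patch
            if all(
                not any(
                    nb.GetAtomicNum() > 1
                    for nb in mol.GetAtomWithIdx(i).GetNeighbors()
                )
                for i in ids
            ):
                continue
        center = coords[list(ids)].mean(axis=0)
        directions: list[np.ndarray] = []
        if kind == "aromatic":
            n = _ring_normal(coords[list(ids)])
            directions = [n, -n]
        elif kind == "donor":
            (idx,) = ids if len(ids) == 1 else (ids[0],)
            atom = mol.GetAtomWithIdx(idx)
            for nb in atom.GetNeighbors():
                if nb.GetAtomicNum() == 1:
                    u = coords[nb.GetIdx()] - coords[idx]
                    norm = np.linalg.norm(u)
                    if norm > 0:
                        directions.append(u / norm)
        elif kind == "acceptor":
            (idx,) = ids if len(ids) == 1 else (ids[0],)
            atom = mol.GetAtomWithIdx(idx)
            vecs = []
            for nb in atom.GetNeighbors():
                if nb.GetAtomicNum() > 1:
                    u = coords[nb.GetIdx()] - coords[idx]
                    norm = np.linalg.norm(u)
                    if norm > 0:
                        vecs.append(u / norm)
            if vecs:
                opp = -np.mean(vecs, axis=0)
                norm = np.linalg.norm(opp)
                if norm > 1e-6:
                    directions.append(opp / norm)
        points.append(LigandPoint(kind=kind, center=center, directions=directions, atom_indices=ids))

    heavy = np.array(
        [
            coords[a.GetIdx()]
            for a in mol.GetAtoms()
            if a.GetAtomicNum() > 1
        ]
    ).reshape(-1, 3)
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    return AnnotatedConformer(points=points, heavy_coords=heavy, name=name)


# --------------------------------------------------------------------------
# conformer enumeration
# --------------------------------------------------------------------------


class Minimizer(Protocol):
    """Energy-minimisation contract: relax a conformer in place.

    ``minimize`` returns the final energy in kcal/mol after at most
    ``max_iter`` iterations or once the RMS gradient drops below
    ``grad_tol``.
    """

    def minimize(
        self, mol: Chem.Mol, conf_id: int, max_iter: int, grad_tol: float
    ) -> float: ...


class MMFFMinimizer:
    """Default minimiser: RDKit's MMFF94 force field."""

    def minimize(
        self, mol: Chem.Mol, conf_id: int, max_iter: int = 200, grad_tol: float = 0.001
    ) -> float:
        props = AllChem.MMFFGetMoleculeProperties(mol)
        if props is None:
            raise ValueError("MMFF parameters unavailable for molecule")
        ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=conf_id)
        ff.Minimize(maxIts=max_iter, forceTol=grad_tol)
        return float(ff.CalcEnergy())


class ToyTorsionMinimizer:
    """Deterministic single-torsion potential for algorithm tests.

    The energy depends only on one dihedral; minimisation snaps the
    dihedral to the nearest of the declared minima and returns that
    minimum's energy (kcal/mol).  This isolates the scan/filter/dedupe
    algorithm from any real force field.
    """

    def __init__(self, torsion: tuple[int, int, int, int], minima: list[tuple[float, float]]):
        self.torsion = torsion
        self.minima = list(minima)

    def minimize(
        self, mol: Chem.Mol, conf_id: int, max_iter: int = 200, grad_tol: float = 0.001
    ) -> float:
        from rdkit.Chem import rdMolTransforms

        conf = mol.GetConformer(conf_id)
        angle = rdMolTransforms.GetDihedralDeg(conf, *self.torsion)

        def circ(a: float, b: float) -> float:
            return abs((a - b + 180.0) % 360.0 - 180.0)

        target, energy = min(self.minima, key=lambda m: circ(angle, m[0]))
        rdMolTransforms.SetDihedralDeg(conf, *self.torsion, target)
        return float(energy)


@dataclass
class ConformerSet:
    """Enumerated conformers of one molecule, ordered by energy.

    ``strains`` are energies relative to the set minimum (kcal/mol), so
    ``strains[0] == 0`` and the list is non-decreasing.
    """

    mol: Chem.Mol
    conf_ids: list[int]
    energies: list[float]

    @property
    def strains(self) -> list[float]:
        if not self.energies:
            return []
        e0 = min(self.energies)
        return [e - e0 for e in self.energies]

    def __len__(self) -> int:
        return len(self.conf_ids)


_ROTATABLE = Chem.MolFromSmarts("[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]")


def rotatable_bonds(mol: Chem.Mol) -> list[tuple[int, int, int, int]]:
    """Non-ring rotatable bonds as dihedral atom quadruples (deterministic).

    Bonds whose rotation moves only hydrogens (methyl, hydroxyl) are
    skipped: conformers are compared on heavy atoms, so those torsions
    only generate duplicates.
    """

    def heavy_nb(idx: int, exclude: int) -> int | None:
        return min(
            (
                n.GetIdx()
                for n in mol.GetAtomWithIdx(idx).GetNeighbors()
                if n.GetIdx() != exclude and n.GetAtomicNum() > 1
            ),
            default=None,
        )

    quads = []
    for b, c in mol.GetSubstructMatches(_ROTATABLE):
        ab = heavy_nb(b, c)
        dc = heavy_nb(c, b)
        if ab is None or dc is None:
            continue
        if (b, c) not in {(q[1], q[2]) for q in quads} and (c, b) not in {
            (q[1], q[2]) for q in quads
        }:
            quads.append((ab, b, c, dc))
    return quads


def heavy_atom_best_rms(mol: Chem.Mol, id1: int, id2: int) -> float:
    """Symmetry-aware best-superposition RMSD over heavy atoms."""
    probe = Chem.RemoveHs(Chem.Mol(mol))
    return float(AllChem.GetBestRMS(probe, probe, prbId=id1, refId=id2))


def enumerate_conformers(
    mol: Chem.Mol,
    torsion_increment: float = 60.0,
    max_conf: int = 250,
    strain_window: float = 4.0,
    dedupe_rmsd: float = 0.15,
    minimizer: Minimizer | None = None,
    max_iter: int = 200,
    grad_tol: float = 0.001,
    seed: int = 2023,
    max_grid: int = 4096,
) -> ConformerSet:
    """Systematic torsion-scan conformer enumeration.

    Steps: embed a starting geometry if none is present; build the full
    torsion grid over all non-ring rotatable bonds at ``torsion_increment``
    degrees; minimise every grid point; keep conformers with strain below
    ``strain_window`` kcal/mol; drop duplicates whose symmetry-aware
    heavy-atom RMSD to a lower-energy keeper is below ``dedupe_rmsd``;
    truncate to ``max_conf`` by energy.
    """
    from rdkit.Chem import rdMolTransforms

    if torsion_increment <= 0 or torsion_increment > 360:
        raise ValueError("torsion_increment must be in (0, 360]")
    work = Chem.Mol(mol)
    work = Chem.AddHs(work, addCoords=work.GetNumConformers() > 0)
    if work.GetNumConformers() == 0:
        params = AllChem.ETKDGv3()
        params.randomSeed = seed
        if AllChem.EmbedMolecule(work, params) != 0:
            raise ValueError("molecule could not be embedded in 3D")
    if minimizer is None:
        minimizer = MMFFMinimizer()

    quads = rotatable_bonds(work)
    n_steps = max(1, int(round(360.0 / torsion_increment)))
    grid = list(itertools.product(range(n_steps), repeat=len(quads)))
    if len(grid) > max_grid:
        logger.warning(
            "torsion grid truncated from %d to %d points", len(grid), max_grid
        )
        grid = grid[:max_grid]

    base_conf = work.GetConformer(0)
    base_angles = [rdMolTransforms.GetDihedralDeg(base_conf, *q) for q in quads]
    base_coords = np.array(base_conf.GetPositions())

    candidates: list[tuple[float, int]] = []
    for combo in grid:
        conf = Chem.Conformer(work.GetNumAtoms())
        for i in range(work.GetNumAtoms()):
            conf.SetAtomPosition(i, base_coords[i].tolist())
        cid = work.AddConformer(conf, assignId=True)
        c = work.GetConformer(cid)
        for q, k, a0 in zip(quads, combo, base_angles):
            rdMolTransforms.SetDihedralDeg(c, *q, a0 + k * torsion_increment)
        energy = minimizer.minimize(work, cid, max_iter=max_iter, grad_tol=grad_tol)
        candidates.append((energy, cid))

    e_min = min(e for e, _ in candidates)
    survivors = [(e, cid) for e, cid in candidates if e - e_min < strain_window]
    survivors.sort(key=lambda ec: ec[0])

    kept: list[tuple[float, int]] = []
    for e, cid in survivors:
        dup = any(
            heavy_atom_best_rms(work, cid, kcid) < dedupe_rmsd for _, kcid in kept
        )
        if not dup:
            kept.append((e, cid))
        if len(kept) >= max_conf:
            break

    out = Chem.Mol(work)
    out.RemoveAllConformers()
    conf_ids = []
    for _, cid in kept:
        new_id = out.AddConformer(work.GetConformer(cid), assignId=True)
        conf_ids.append(new_id)
    return ConformerSet(mol=out, conf_ids=conf_ids, energies=[e for e, _ in kept])
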