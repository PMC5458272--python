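"""Annotation and the torsion-scan conformer enumeration contract."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms

from ppiscreen.ligand import (
    ToyTorsionMinimizer,
    annotate_ligand,
    enumerate_conformers,
    heavy_atom_best_rms,
    mol_from_smiles,
    read_sdf,
    rotatable_bonds,
    write_sdf,
)


def _embedded(smiles, seed=7):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    return mol


@pytest.mark.parametrize(
    "smiles,expected_kinds",
    [
        ("c1ccccc1", ["aromatic"]),
        ("Oc1ccccc1", ["acceptor", "aromatic", "donor"]),
        ("C", []),
    ],
)
def test_annotation_patterns(smiles, expected_kinds):
    ann = annotate_ligand(_embedded(smiles))
    assert sorted(p.kind for p in ann.points) == expected_kinds


def test_benzene_aromatic_point_at_centroid_with_normal():
    mol = _embedded("c1ccccc1")
    ann = annotate_ligand(mol)
    (point,) = ann.points
    ring = [a.GetIdx() for a in mol.GetAtoms() if a.GetIsAromatic()]
    centroid = mol.GetConformer().GetPositions()[ring].mean(axis=0)
    np.testing.assert_allclose(point.center, centroid, atol=1e-8)
    assert len(point.directions) == 2  # both normal signs
    np.testing.assert_allclose(point.directions[0], -point.directions[1])


def test_annotation_requires_conformer():
    with pytest.raises(ValueError, match="conformer"):
        annotate_ligand(mol_from_smiles("CCO"))


def test_no_rotatable_bonds_single_conformer():
    cs = enumerate_conformers(mol_from_smiles("c1ccccc1"), torsion_increment=60)
    assert len(cs) == 1
    assert cs.strains == [0.0]


def _butane_scan_oracle(mol, torsion, increment, minima, dedupe_rmsd=0.15):
    """Independent exhaustive scan: set every grid angle, snap to the
    nearest declared minimum, dedupe retained geometries by best RMSD."""
    kept = []
    n = int(round(360 / increment))
    base = Chem.Mol(mol)
    for k in range(n):
        work = Chem.Mol(base)
        conf = work.GetConformer(0)
        start = rdMolTransforms.GetDihedralDeg(conf, *torsion)
        rdMolTransforms.SetDihedralDeg(conf, *torsion, start + k * increment)
        angle = rdMolTransforms.GetDihedralDeg(conf, *torsion)
        target, energy = min(
            minima, key=lambda m: abs((angle - m[0] + 180) % 360 - 180)
        )
        rdMolTransforms.SetDihedralDeg(conf, *torsion, target)
        merged = Chem.Mol(base)
        merged.RemoveAllConformers()
        merged.AddConformer(work.GetConformer(0), assignId=True)
        kept.append((energy, merged))
    # dedupe by symmetry-aware heavy-atom best RMS, lower energy first
    kept.sort(key=lambda em: em[0])
    unique = []
    for e, m in kept:
        combined = Chem.Mol(m)
        dup = False
        for e2, m2 in unique:
            probe = Chem.Mol(m)
            probe.AddConformer(m2.GetConformer(0), assignId=True)
            if heavy_atom_best_rms(probe, 0, 1) < dedupe_rmsd:
                dup = True
                break
        if not dup:
            unique.append((e, m))
    return unique


BUTANE_MINIMA = [(180.0, 0.0), (60.0, 0.9), (-60.0, 0.9)]


def test_butane_torsion_scan_matches_brute_force():
    """120-degree scan of the C-C-C-C torsion under an ideal torsional
    potential: anti plus the two mirror-related gauche minima, which are
    not RMSD-duplicates of each other."""
    mol = _embedded("CCCC", seed=3)
    (torsion,) = [
        q for q in rotatable_bonds(mol)
        if all(mol.GetAtomWithIdx(i).GetAtomicNum() == 6 for i in q)
    ]
    rdMolTransforms.SetDihedralDeg(mol.GetConformer(0), *torsion, 180.0)
    oracle = _butane_scan_oracle(mol, torsion, 120.0, BUTANE_MINIMA)
    cs = enumerate_conformers(
        mol,
        torsion_increment=120.0,
        minimizer=ToyTorsionMinimizer(torsion, BUTANE_MINIMA),
    )
    assert len(cs) == len(oracle) == 3
    assert sorted(set(np.round(cs.strains, 6))) == [0.0, 0.9]


def test_strain_window_filters_conformers():
    mol = _embedded("CCCC", seed=3)
    (torsion,) = [
        q for q in rotatable_bonds(mol)
        if all(mol.GetAtomWithIdx(i).GetAtomicNum() == 6 for i in q)
    ]
    rdMolTransforms.SetDihedralDeg(mol.GetConformer(0), *torsion, 180.0)
    mini = ToyTorsionMinimizer(torsion, BUTANE_MINIMA)
    wide = enumerate_conformers(mol, torsion_increment=120.0, minimizer=mini,
                                strain_window=4.0)
    narrow = enumerate_conformers(mol, torsion_increment=120.0, minimizer=mini,
                                  strain_window=0.5)
    assert len(narrow) <= len(wide)
    assert len(narrow) == 1  # only the anti minimum survives


def test_caps_and_dedupe_invariants():
    """Output obeys the hard cap and pairwise RMSD floor."""
    mol = mol_from_smiles("OCCCO")
    cs = enumerate_conformers(mol, torsion_increment=60.0, max_conf=5,
                              dedupe_rmsd=0.15, seed=11)
    assert len(cs) <= 5
    assert all(s >= 0 for s in cs.strains)
    assert cs.energies == sorted(cs.energies)
    for i, j in itertools.combinations(cs.conf_ids, 2):
        assert heavy_atom_best_rms(cs.mol, i, j) >= 0.15


def test_atom_order_permutation_equivalence():
    """Renumbering atoms leaves the conformer count unchanged."""
    mol = mol_from_smiles("CCCCO")
    perm = list(range(mol.GetNumAtoms()))[::-1]
    renum = Chem.RenumberAtoms(mol, perm)
    a = enumerate_conformers(mol, torsion_increment=120.0, seed=5)
    b = enumerate_conformers(renum, torsion_increment=120.0, seed=5)
    assert len(a) == len(b)


def test_sdf_roundtrip(tmp_path, small_library):
    path = str(tmp_path / "lib.sdf")
    mols = [small_library.mols[cid] for cid in sorted(small_library.mols)][:5]
    write_sdf(mols, path)
    back = read_sdf(path)
    assert len(back) == 5
    assert [m.GetProp("_Name") for m in back] == [m.GetProp("_Name") for m in mols]
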