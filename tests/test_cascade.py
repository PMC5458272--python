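"""Filter-cascade stages: screen, z-selection, pose RMSD, consensus, clustering."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem, DataStructs

from ppiscreen.cascade import (
    DockedPose,
    cluster_and_pick,
    consensus_filter,
    ph_screen,
    pose_rmsd,
    zscore_select,
)
from ppiscreen.ligand import annotate_ligand, mol_from_smiles
from ppiscreen.synth import MockEngineSpec, make_mock_docking


def _annotated(library):
    return {cid: [annotate_ligand(m)] for cid, m in library.mols.items()}


def test_ph_screen_recovers_exactly_the_actives(small_library, hypothesis_):
    survivors = ph_screen(_annotated(small_library), hypothesis_)
    assert sorted(survivors) == small_library.active_ids


def test_ph_screen_union_property(small_library, hypothesis_):
    confs = _annotated(small_library)
    ids = sorted(confs)
    a = {k: confs[k] for k in ids[: len(ids) // 2]}
    b = {k: confs[k] for k in ids[len(ids) // 2 :]}
    union = set(ph_screen(a, hypothesis_)) | set(ph_screen(b, hypothesis_))
    assert union == set(ph_screen(confs, hypothesis_))


def test_ph_screen_empty_library_rejected(hypothesis_):
    with pytest.raises(ValueError):
        ph_screen({}, hypothesis_)


# --- z-score selection ----------------------------------------------------


def test_zscore_all_equal_scores_empty():
    assert zscore_select({f"c{i}": 5.0 for i in range(10)}) == []


def test_zscore_shift_invariance():
    rng = np.random.default_rng(3)
    scores = {f"c{i}": float(v) for i, v in enumerate(rng.normal(5.89, 0.93, 500))}
    shifted = {k: v + 100.0 for k, v in scores.items()}
    assert zscore_select(scores) == zscore_select(shifted)


def test_zscore_gaussian_tail_fraction():
    """P(Z > 2) = 0.02275 for a normal score distribution."""
    rng = np.random.default_rng(42)
    scores = {f"c{i}": float(v) for i, v in enumerate(rng.normal(5.89, 0.93, 100_000))}
    frac = len(zscore_select(scores)) / len(scores)
    assert frac == pytest.approx(0.02275, abs=0.003)


def test_zscore_needs_two_scores():
    with pytest.raises(ValueError):
        zscore_select({"a": 1.0})


# --- pose RMSD ------------------------------------------------------------


def _pose(mol, coords, cid="m", engine="e", score=5.0):
    return DockedPose(compound_id=cid, engine=engine, mol=mol,
                      coords=np.asarray(coords, float), score=score)


def _heavy_coords(mol):
    conf = mol.GetConformer(0)
    return np.array([conf.GetAtomPosition(a.GetIdx())
                     for a in mol.GetAtoms() if a.GetAtomicNum() > 1])


def _embedded(smiles, seed=7):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    p = AllChem.ETKDGv3()
    p.randomSeed = seed
    AllChem.EmbedMolecule(mol, p)
    return mol


def test_pose_rmsd_identity_and_translation():
    mol = _embedded("CCO")
    xyz = _heavy_coords(mol)
    a = _pose(mol, xyz)
    assert pose_rmsd(a, _pose(mol, xyz)) == 0.0
    for d in (0.5, 2.0, 7.25):
        b = _pose(mol, xyz + np.array([d, 0, 0]))
        assert pose_rmsd(a, b, symmetry_aware=False) == pytest.approx(d)
        assert pose_rmsd(a, b, symmetry_aware=True) == pytest.approx(d)


def test_benzene_flip_symmetry_aware_zero():
    mol = _embedded("c1ccccc1")
    # ideal hexagon in the xy-plane, vertex on the x-axis
    xyz = np.array([
        [1.39 * np.cos(k * np.pi / 3), 1.39 * np.sin(k * np.pi / 3), 0.0]
        for k in range(6)
    ])
    # 180-degree rotation about x maps the vertex set onto itself
    flipped = xyz * np.array([1.0, -1.0, -1.0])
    a, b = _pose(mol, xyz), _pose(mol, flipped)
    assert pose_rmsd(a, b, symmetry_aware=False) > 1.0
    assert pose_rmsd(a, b, symmetry_aware=True) == pytest.approx(0.0, abs=1e-6)


def test_symmetry_aware_never_exceeds_naive_and_matches_oracle():
    """min-over-automorphisms RMSD via exhaustive permutation check."""
    rng = np.random.default_rng(9)
    for smiles in ("c1ccccc1", "CC(C)C", "O=C(O)c1ccccc1", "CCOCC"):
        mol = _embedded(smiles)
        xyz = _heavy_coords(mol)
        jittered = xyz + rng.normal(0, 0.8, xyz.shape)
        a, b = _pose(mol, xyz), _pose(mol, jittered)
        naive = pose_rmsd(a, b, symmetry_aware=False)
        sym = pose_rmsd(a, b, symmetry_aware=True)
        assert sym <= naive + 1e-12
        heavy = Chem.RemoveHs(Chem.Mol(mol))
        autos = heavy.GetSubstructMatches(heavy, uniquify=False, maxMatches=100000)
        oracle = min(
            float(np.sqrt(np.mean(np.sum((xyz - jittered[list(p)]) ** 2, axis=1))))
            for p in autos
        )
        assert sym == pytest.approx(oracle, abs=1e-12)


def test_pose_rmsd_rejects_mismatched_compounds():
    mol = _embedded("CCO")
    xyz = _heavy_coords(mol)
    with pytest.raises(ValueError):
        pose_rmsd(_pose(mol, xyz, cid="x"), _pose(mol, xyz, cid="y"))


# --- consensus ------------------------------------------------------------


def test_consensus_identical_poses_pass(small_library, hypothesis_):
    cid = small_library.active_ids[0]
    mol = small_library.mols[cid]
    xyz = _heavy_coords(mol)
    poses = {cid: {e: _pose(mol, xyz, cid=cid, engine=e) for e in "abc"}}
    (res,) = consensus_filter(poses, hypothesis_)
    assert res.passed and max(res.pairwise_rmsd.values()) == 0.0


def test_consensus_one_jittered_engine_fails(small_library, hypothesis_):
    cid = small_library.active_ids[0]
    mol = small_library.mols[cid]
    xyz = _heavy_coords(mol)
    poses = {cid: {
        "a": _pose(mol, xyz, cid=cid, engine="a"),
        "b": _pose(mol, xyz, cid=cid, engine="b"),
        "c": _pose(mol, xyz + np.array([5.0, 0, 0]), cid=cid, engine="c"),
    }}
    (res,) = consensus_filter(poses, hypothesis_)
    assert not res.passed and "disagreement" in res.reason


def test_consensus_missing_engine_recorded(small_library, hypothesis_):
    cid = small_library.active_ids[0]
    mol = small_library.mols[cid]
    xyz = _heavy_coords(mol)
    poses = {
        cid: {"a": _pose(mol, xyz, cid=cid, engine="a"),
              "b": _pose(mol, xyz, cid=cid, engine="b")},
        "other": {"a": _pose(mol, xyz, cid="other", engine="a")},
    }
    results = {r.compound_id: r for r in consensus_filter(poses, hypothesis_)}
    assert not results["other"].passed and "missing" in results["other"].reason


def test_consensus_pass_set_equals_generator_truth(small_library, hypothesis_):
    actives = {cid: small_library.mols[cid] for cid in small_library.active_ids}
    consistent = set(small_library.active_ids[:4])
    poses, _ = make_mock_docking(
        actives, MockEngineSpec(seed=29), consistent_ids=consistent
    )
    results = consensus_filter(poses, hypothesis_)
    assert {r.compound_id for r in results if r.passed} == consistent


# --- clustering -----------------------------------------------------------


def test_all_dissimilar_compounds_are_their_own_representatives():
    mols = {
        "a": mol_from_smiles("c1ccccc1"),
        "b": mol_from_smiles("CCCCCCCC"),
        "c": mol_from_smiles("C1CCNCC1"),
    }
    clusters, reps = cluster_and_pick(mols, {"a": 1.0, "b": 2.0, "c": 3.0})
    assert len(set(clusters.values())) == 3
    assert reps == ["a", "b", "c"]


def test_duplicates_collapse_to_highest_scoring():
    mols = {"lo": mol_from_smiles("c1ccccc1O"), "hi": mol_from_smiles("c1ccccc1O")}
    clusters, reps = cluster_and_pick(mols, {"lo": 4.0, "hi": 6.0})
    assert len(set(clusters.values())) == 1
    assert reps == ["hi"]


def test_clustering_matches_connected_components_oracle(small_library):
    mols = dict(list(small_library.mols.items())[:20])
    scores = {cid: float(i) for i, cid in enumerate(sorted(mols))}
    clusters, _ = cluster_and_pick(mols, scores, similarity_threshold=0.7)
    # brute-force single linkage: transitive closure over similar pairs
    ids = sorted(mols)
    fps = {i: Chem.RDKFingerprint(mols[i]) for i in ids}
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in itertools.combinations(ids, 2):
        if DataStructs.TanimotoSimilarity(fps[a], fps[b]) >= 0.7:
            parent[find(a)] = find(b)
    expected_groups = {}
    for i in ids:
        expected_groups.setdefault(find(i), set()).add(i)
    got_groups = {}
    for cid, lab in clusters.items():
        got_groups.setdefault(lab, set()).add(cid)
    assert sorted(map(sorted, expected_groups.values())) == sorted(
        map(sorted, got_groups.values())
    )
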