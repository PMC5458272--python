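"""The virtual-screening filter cascade.

Stages, in protocol order:

1. ``ph_screen`` — keep compounds with at least one conformer matching
   the pharmacophore hypothesis in align mode;
2. docking (external engines behind the :class:`DockingEngine` adapter
   contract; a mock engine ships for tests — docking itself is out of
   scope);
3. ``zscore_select`` — keep compounds scoring more than two standard
   deviations above the library mean (scores are predicted pKi);
4. ``consensus_filter`` — keep compounds whose top poses from all
   engines agree pairwise (RMSD below threshold, hydrogens ignored, no
   re-superposition: poses share the receptor frame) *and* whose pose
   still satisfies the hypothesis in absolute mode;
5. ``cluster_and_pick`` — single-linkage clustering by fingerprint
   Tanimoto similarity; the most potent member represents each cluster.

Every stage maps a compound set to a subset, so the cascade is a
monotone filter chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from rdkit import Chem, DataStructs
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .ligand import annotate_ligand
from .pharmacophore import AnnotatedConformer, PharmacophoreHypothesis, match

logger = logging.getLogger(__name__)

__all__ = [
    "DockedPose",
    "ScoreDistribution",
    "ConsensusResult",
    "DockingEngine",
    "ph_screen",
    "zscore_select",
    "pose_rmsd",
    "consensus_filter",
    "cluster_and_pick",
]


@dataclass
class DockedPose:
    """One engine's scored placement of a compound (heavy atoms only).

    ``coords`` rows follow the heavy-atom order of ``mol``; ``score`` is
    the engine's predicted pKi.
    """

    compound_id: str
    engine: str
    mol: Chem.Mol
    coords: np.ndarray
    score: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n_heavy = sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1)
        if len(self.coords) != n_heavy:
            raise ValueError(
                f"pose has {len(self.coords)} coordinates for {n_heavy} heavy atoms"
            )


@dataclass(frozen=True)
class ScoreDistribution:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class ConsensusResult:
    compound_id: str
    pairwise_rmsd: dict[tuple[str, str], float] = field(default_factory=dict)
    passed: bool = False
    reason: str = ""
    cluster_id: int | None = None
    representative: bool = False


class DockingEngine(Protocol):
    """Adapter contract for external docking programs.

    Implementations take prepared compounds and return their top scored
    pose per compound in the shared receptor frame.  Grid and search
    parameters are engine configuration, passed through verbatim.
    """

    name: str

    def dock(self, mols: dict[str, Chem.Mol]) -> dict[str, DockedPose]: ...


def ph_screen(
    conformers: dict[str, list[AnnotatedConformer]],
    hyp: PharmacophoreHypothesis,
) -> list[str]:
    """Compound ids with at least one align-mode hypothesis match."""
    if not conformers:
        raise ValueError("empty library")
    survivors = []
    for cid in sorted(conformers):
        for conf in conformers[cid]:
            if match(hyp, conf, mode="align", first_match=True).matched:
                survivors.append(cid)
                break
    return survivors


def zscore_select(scores: dict[str, float]) -> list[str]:
    """Ids scoring above mean + 2 SD of the score distribution (strict)."""
    if len(scores) < 2:
        raise ValueError("need at least 2 scores")
    values = np.array(list(scores.values()), dtype=float)
    mu = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        logger.warning("zero score variance: empty z-score selection")
        return []
    return sorted(cid for cid, s in scores.items() if s > mu + 2.0 * sd)


def score_distribution(scores: dict[str, float]) -> ScoreDistribution:
    values = np.array(list(scores.values()), dtype=float)
    return ScoreDistribution(
        mean=float(values.mean()), sd=float(values.std(ddof=1)), n=len(values)
    )


def _heavy_automorphisms(mol: Chem.Mol, max_matches: int = 10000):
    heavy = Chem.RemoveHs(Chem.Mol(mol))
    return heavy.GetSubstructMatches(
        heavy, uniquify=False, useChirality=False, maxMatches=max_matches
    )


def pose_rmsd(a: DockedPose, b: DockedPose, symmetry_aware: bool = True) -> float:
    """In-place heavy-atom RMSD between two poses of the same compound.

    No superposition is applied — consensus poses live in the shared
    receptor frame.  The symmetry-aware variant minimises over the
    molecule's heavy-atom graph automorphisms, so e.g. a flipped benzene
    ring scores zero.
    """
    if a.compound_id != b.compound_id:
        raise ValueError("poses belong to different compounds")
    if a.coords.shape != b.coords.shape:
        raise ValueError("heavy-atom count mismatch between poses")
    if not symmetry_aware:
        return float(np.sqrt(np.mean(np.sum((a.coords - b.coords) ** 2, axis=1))))
    best = np.inf
    for perm in _heavy_automorphisms(a.mol):
        d = a.coords - b.coords[list(perm)]
        best = min(best, float(np.sqrt(np.mean(np.sum(d**2, axis=1)))))
    return best


def _pose_conformer(pose: DockedPose) -> AnnotatedConformer:
    heavy = Chem.RemoveHs(Chem.Mol(pose.mol))
    conf = Chem.Conformer(heavy.GetNumAtoms())
    for i, xyz in enumerate(pose.coords):
        conf.SetAtomPosition(i, xyz.tolist())
    heavy.RemoveAllConformers()
    heavy.AddConformer(conf, assignId=True)
    return annotate_ligand(heavy, conf_id=0)


def consensus_filter(
    poses: dict[str, dict[str, DockedPose]],
    hyp: PharmacophoreHypothesis,
    threshold: float = 2.0,
    symmetry_aware: bool = True,
    ph_engine: str | None = None,
) -> list[ConsensusResult]:
    """Multi-engine pose-agreement filter with an absolute-mode PH refilter.

    A compound passes when every engine supplied a pose, all pairwise
    pose RMSDs are below ``threshold`` angstrom, and the ``ph_engine``
    pose (first engine alphabetically when unset) still matches the
    hypothesis without being translated or rotated.
    """
    engines = sorted({e for per in poses.values() for e in per})
    if len(engines) < 2:
        raise ValueError("consensus needs poses from at least 2 engines")
    results = []
    for cid in sorted(poses):
        per = poses[cid]
        res = ConsensusResult(compound_id=cid)
        missing = [e for e in engines if e not in per]
        if missing:
            res.reason = f"missing pose from engine(s) {missing}"
            results.append(res)
            continue
        agree = True
        for i, e1 in enumerate(engines):
            for e2 in engines[i + 1 :]:
                r = pose_rmsd(per[e1], per[e2], symmetry_aware=symmetry_aware)
                res.pairwise_rmsd[(e1, e2)] = r
                if r >= threshold:
                    agree = False
        if not agree:
            res.reason = "pose disagreement between engines"
            results.append(res)
            continue
        ref_engine = ph_engine if ph_engine is not None else engines[0]
        ref = _pose_conformer(per[ref_engine])
        if not match(hyp, ref, mode="absolute").matched:
            res.reason = "pose violates pharmacophore in absolute mode"
            results.append(res)
            continue
        res.passed = True
        results.append(res)
    return results


def cluster_and_pick(
    mols: dict[str, Chem.Mol],
    scores: dict[str, float],
    similarity_threshold: float = 0.7,
) -> tuple[dict[str, int], list[str]]:
    """Single-linkage structural clustering and per-cluster champion.

    Similarity is Tanimoto on hashed topological fingerprints; two
    compounds join the same cluster when connected through pairs with
    similarity at or above the threshold.  Each cluster's representative
    is its highest-scoring member (ties broken by lexicographic id).
    Returns (cluster id per compound, representative ids).
    """
    ids = sorted(mols)
    if not ids:
        return {}, []
    fps = [Chem.RDKFingerprint(mols[i]) for i in ids]
    n = len(ids)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if DataStructs.TanimotoSimilarity(fps[i], fps[j]) >= similarity_threshold:
                rows += [i, j]
                cols += [j, i]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    clusters = {cid: int(lab) for cid, lab in zip(ids, labels)}
    reps = []
    for lab in sorted(set(labels)):
        members = [cid for cid in ids if clusters[cid] == lab]
        members.sort(key=lambda cid: (-scores[cid], cid))
        reps.append(members[0])
    return clusters, sorted(reps)
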