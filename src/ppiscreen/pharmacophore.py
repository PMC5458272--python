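"""Protein-based pharmacophore hypothesis construction and matching.

A pharmacophore hypothesis (PH) abstracts the anchor peptide's receptor
contacts into typed feature points:

* an **aromatic** feature at each anchor ring centroid, with a directional
  projection along the ring normal toward the receptor wall it packs
  against;
* a **donor** feature at each anchor N-H/O-H heavy atom that has a
  receptor acceptor within H-bond range, projected onto that acceptor;
* an **acceptor** feature at each anchor carbonyl/carboxylate oxygen with
  a receptor donor in range, projected onto that donor;

plus **exclusion spheres** marking receptor-occupied space (one sphere per
receptor heavy atom near the anchor).  Features carry a tolerance radius
(default 1.0 A) and a projection tolerance (default 1.4 A); features
sourced from caller-designated key residues are flagged *essential*.

Matching places a ligand conformer's annotated feature points onto the
hypothesis.  In *align* mode the conformer may be rigidly moved: seed
triplets of kind-compatible, distance-compatible feature/point pairs
define candidate rigid superpositions (Kabsch), each extended to the
largest injective assignment whose every pair satisfies the radius and
projection tolerances; a candidate is accepted when all essential
features are matched, at least ``min_match`` features are matched, and no
ligand heavy atom penetrates an exclusion sphere.  In *absolute* mode the
identity transform is the only candidate, which is how docked poses are
re-filtered in place.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .structure import Atom, ResidueSelection, Structure, interface_atoms

logger = logging.getLogger(__name__)

__all__ = [
    "Feature",
    "ExclusionSphere",
    "PharmacophoreHypothesis",
    "LigandPoint",
    "AnnotatedConformer",
    "MatchResult",
    "EmptyHypothesisError",
    "build_hypothesis",
    "match",
    "hypothesis_points",
]

FEATURE_KINDS = ("aromatic", "donor", "acceptor", "hydrophobic")

#: Default H-bond heavy-atom distance ceiling (donor/acceptor pairing).
HBOND_CUTOFF = 3.5
#: Fallback length of an aromatic normal projection when no receptor atom
#: sits along the normal.
AROMATIC_PROJECTION_LENGTH = 3.0
#: Half-angle (degrees) of the cone around the ring normal searched for
#: the receptor packing partner.
AROMATIC_CONE_DEG = 40.0
#: Exploration budget per conformer before greedy fallback.
MATCH_BUDGET = 100_000


class EmptyHypothesisError(ValueError):
    """Anchor produced no annotatable pharmacophore feature."""


@dataclass
class Feature:
    kind: str
    center: np.ndarray
    radius: float = 1.0
    projection: np.ndarray | None = None
    projection_radius: float = 1.4
    essential: bool = False
    source: str = ""   # anchor atom/residue the feature came from
    partner: str = ""  # receptor residue(s) the projection points at

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.radius <= 0 or self.projection_radius <= 0:
            raise ValueError("feature radii must be positive")
        self.center = np.asarray(self.center, dtype=float)
        if self.projection is not None:
            self.projection = np.asarray(self.projection, dtype=float)
        if self.kind == "aromatic" and self.projection is None:
            raise ValueError("aromatic features must carry a normal projection")


@dataclass
class ExclusionSphere:
    center: np.ndarray
    radius: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("exclusion radius must be positive")
        self.center = np.asarray(self.center, dtype=float)


@dataclass
class PharmacophoreHypothesis:
    features: list[Feature]
    exclusions: list[ExclusionSphere] = field(default_factory=list)
    min_match: int = 3

    def __post_init__(self) -> None:
        if self.min_match < 1:
            raise ValueError("min_match must be >= 1")
        if self.features and not any(f.essential for f in self.features):
            raise ValueError("at least one feature must be essential")

    @property
    def n_points(self) -> int:
        """Feature centers plus projections (the '12 points' convention)."""
        return len(self.features) + sum(
            1 for f in self.features if f.projection is not None
        )

    def to_json(self) -> str:
        def feat(f: Feature) -> dict:
            return {
                "kind": f.kind,
                "center": list(map(float, f.center)),
                "radius": f.radius,
                "projection": None
                if f.projection is None
                else list(map(float, f.projection)),
                "projection_radius": f.projection_radius,
                "essential": f.essential,
                "source": f.source,
                "partner": f.partner,
            }

        return json.dumps(
            {
                "format": "ppiscreen-hypothesis",
                "version": 1,
                "units": "angstrom",
                "min_match": self.min_match,
                "features": [feat(f) for f in self.features],
                "exclusions": [
                    {"center": list(map(float, e.center)), "radius": e.radius}
                    for e in self.exclusions
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PharmacophoreHypothesis":
        doc = json.loads(text)
        if doc.get("format") != "ppiscreen-hypothesis":
            raise ValueError("not a ppiscreen hypothesis document")
        feats = [
            Feature(
                kind=f["kind"],
                center=np.array(f["center"]),
                radius=f["radius"],
                projection=None
                if f["projection"] is None
                else np.array(f["projection"]),
                projection_radius=f["projection_radius"],
                essential=f["essential"],
                source=f.get("source", ""),
                partner=f.get("partner", ""),
            )
            for f in doc["features"]
        ]
        excl = [
            ExclusionSphere(center=np.array(e["center"]), radius=e["radius"])
            for e in doc["exclusions"]
        ]
        return cls(features=feats, exclusions=excl, min_match=doc["min_match"])


@dataclass
class LigandPoint:
    """One annotated ligand feature point.

    ``directions`` holds unit vectors for directional satisfaction (ring
    normals carry both signs; donors one vector per polar hydrogen;
    acceptors the bond-opposed lone-pair proxy).  An empty list means the
    point is direction-free and projections are checked by the spherical
    shell criterion instead.
    """

    kind: str
    center: np.ndarray
    directions: list[np.ndarray] = field(default_factory=list)
    atom_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.directions = [np.asarray(d, dtype=float) for d in self.directions]


@dataclass
class AnnotatedConformer:
    points: list[LigandPoint]
    heavy_coords: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.heavy_coords = np.asarray(self.heavy_coords, dtype=float).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray):
        pts = [
            LigandPoint(
                kind=p.kind,
                center=rotation @ p.center + translation,
                directions=[rotation @ d for d in p.directions],
                atom_indices=p.atom_indices,
            )
            for p in self.points
        ]
        return AnnotatedConformer(
            points=pts,
            heavy_coords=(rotation @ self.heavy_coords.T).T + translation,
            name=self.name,
        )


@dataclass
class MatchResult:
    matched: bool
    n_matched: int = 0
    correspondence: tuple[tuple[int, int], ...] = ()
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    feature_rmsd: float = float("nan")


# --------------------------------------------------------------------------
# hypothesis construction
# --------------------------------------------------------------------------

_RING_ATOMS = {
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CG", "CD1", "CD2", "NE1", "CE2"), ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}

# anchor-side polar hydrogens (donor heavy atoms), by residue
_SIDECHAIN_DONORS = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
}

# anchor-side lone-pair-bearing oxygens considered as acceptors
_SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
}

# receptor-side acceptor atoms (pair with anchor donors)
_RECEPTOR_ACCEPTORS = {
    ("*", "O"),
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
}

# receptor-side donor atoms (pair with anchor acceptors)
_RECEPTOR_DONORS = {
    ("*", "N"),
    ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ASN", "ND2"), ("GLN", "NE2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("TRP", "NE1"),
}


def _is_listed(atom: Atom, table: set[tuple[str, str]]) -> bool:
    return ("*", atom.name) in table or (atom.residue_name, atom.name) in table


def _residue_label(atom: Atom) -> str:
    return f"{atom.residue_name}{atom.residue_number}"


def _ring_normal(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2] / np.linalg.norm(vt[2])


def build_hypothesis(
    structure: Structure,
    anchor: ResidueSelection,
    receptor: ResidueSelection,
    exclusion_cutoff: float = 4.0,
    hbond_cutoff: float = HBOND_CUTOFF,
    essential_residues: list[int] | None = None,
    feature_radius: float = 1.0,
    projection_radius: float = 1.4,
    exclusion_radius: float = 1.0,
    min_match: int = 3,
) -> PharmacophoreHypothesis:
    """Derive the hypothesis from an anchor peptide bound to its receptor.

    ``essential_residues`` lists anchor residue numbers whose features are
    flagged essential; when ``None``, every ring-bearing anchor residue is
    essential (the key aromatic anchors must be mimicked).
    """
    anchor.validate(structure)
    receptor.validate(structure)
    rec_atoms = [
        a for a in receptor.atoms(structure, heavy_only=True) if not a.hetero
    ]
    if not rec_atoms:
        raise ValueError("receptor selection has no heavy atoms")
    rec_xyz = np.array([[a.x, a.y, a.z] for a in rec_atoms])

    if essential_residues is None:
        essential_residues = [
            r
            for r in anchor.residue_numbers
            if structure.residue_atoms(anchor.chain_id, r)
            and structure.residue_atoms(anchor.chain_id, r)[0].residue_name
            in _RING_ATOMS
        ]
    essential = set(essential_residues)

    features: list[Feature] = []
    for resnum in anchor.residue_numbers:
        atoms = structure.residue_atoms(anchor.chain_id, resnum)
        if not atoms:
            continue
        resname = atoms[0].residue_name
        by_name = {a.name: a for a in atoms}
        res_tag = f"{resname}{resnum}"
        is_essential = resnum in essential

        # aromatic ring centroids with normal projection toward the receptor
        for ring in _RING_ATOMS.get(resname, []):
            if not all(n in by_name for n in ring):
                continue
            coords = np.array([by_name[n].xyz for n in ring])
            centroid, normal = _ring_normal(coords)
            proj, partner = _aromatic_projection(
                centroid, normal, rec_atoms, rec_xyz
            )
            features.append(
                Feature(
                    kind="aromatic",
                    center=centroid,
                    radius=feature_radius,
                    projection=proj,
                    projection_radius=projection_radius,
                    essential=is_essential,
                    source=f"{res_tag}/ring",
                    partner=partner,
                )
            )

        # donors: backbone N-H plus side-chain N-H/O-H with an acceptor in range
        donor_names = [] if resname == "PRO" else ["N"]
        donor_names += list(_SIDECHAIN_DONORS.get(resname, ()))
        for name in donor_names:
            if name not in by_name:
                continue
            donor = by_name[name]
            partner = _nearest_partner(
                donor, rec_atoms, rec_xyz, _RECEPTOR_ACCEPTORS, hbond_cutoff
            )
            if partner is None:
                continue
            features.append(
                Feature(
                    kind="donor",
                    center=donor.xyz,
                    radius=feature_radius,
                    projection=partner.xyz,
                    projection_radius=projection_radius,
                    essential=is_essential,
                    source=f"{res_tag}/{name}",
                    partner=_residue_label(partner),
                )
            )

        # acceptors: backbone carbonyl O plus side-chain oxygens with a donor
        acceptor_names = ["O"] + list(_SIDECHAIN_ACCEPTORS.get(resname, ()))
        for name in acceptor_names:
            if name not in by_name:
                continue
            acc = by_name[name]
            partner = _nearest_partner(
                acc, rec_atoms, rec_xyz, _RECEPTOR_DONORS, hbond_cutoff
            )
            if partner is None:
                continue
            features.append(
                Feature(
                    kind="acceptor",
                    center=acc.xyz,
                    radius=feature_radius,
                    projection=partner.xyz,
                    projection_radius=projection_radius,
                    essential=is_essential,
                    source=f"{res_tag}/{name}",
                    partner=_residue_label(partner),
                )
            )

    if not features:
        raise EmptyHypothesisError(
            "anchor has no annotatable pharmacophore feature with a receptor partner"
        )
    if not any(f.essential for f in features):
        # hypothesis invariant: at least one essential feature
        for f in features:
            f.essential = True

    excl_atoms = interface_atoms(structure, anchor, exclusion_cutoff)
    excl_atoms = [
        a
        for a in excl_atoms
        if a.chain_id == receptor.chain_id
        and a.residue_number in set(receptor.residue_numbers)
    ]
    exclusions = [
        ExclusionSphere(center=a.xyz, radius=exclusion_radius) for a in excl_atoms
    ]
    return PharmacophoreHypothesis(
        features=features, exclusions=exclusions, min_match=min_match
    )


def _aromatic_projection(
    centroid: np.ndarray,
    normal: np.ndarray,
    rec_atoms: list[Atom],
    rec_xyz: np.ndarray,
) -> tuple[np.ndarray, str]:
    """Place the ring-normal projection toward the nearer receptor side.

    The partner is the closest receptor heavy atom inside a cone around
    either normal direction; the projection point is the centroid offset
    along that direction by the partner's axial distance.
    """
    rel = rec_xyz - centroid
    dist = np.linalg.norm(rel, axis=1)
    cos_cone = np.cos(np.deg2rad(AROMATIC_CONE_DEG))
    best: tuple[float, int, float, int] | None = None  # (dist, idx, axial, sign)
    for sign in (1.0, -1.0):
        axis = sign * normal
        with np.errstate(invalid="ignore"):
            cosang = (rel @ axis) / np.where(dist > 0, dist, 1.0)
        ok = (cosang >= cos_cone) & (dist <= 6.0) & (dist > 0)
        for idx in np.nonzero(ok)[0]:
            cand = (float(dist[idx]), int(idx), float(rel[idx] @ axis), int(sign))
            if best is None or cand[0] < best[0]:
                best = cand
    if best is None:
        # no wall along the normal: fall back to the side nearer the
        # receptor centre of mass, fixed projection length
        side = np.sign((rec_xyz.mean(axis=0) - centroid) @ normal) or 1.0
        return centroid + side * normal * AROMATIC_PROJECTION_LENGTH, ""
    _, idx, axial, sign = best
    return centroid + sign * normal * axial, _residue_label(rec_atoms[idx])


def _nearest_partner(
    atom: Atom,
    rec_atoms: list[Atom],
    rec_xyz: np.ndarray,
    table: set[tuple[str, str]],
    cutoff: float,
) -> Atom | None:
    best = None
    best_d = cutoff
    for a, xyz in zip(rec_atoms, rec_xyz):
        if not _is_listed(a, table):
            continue
        d = float(np.linalg.norm(xyz - atom.xyz))
        if d <= best_d:
            best, best_d = a, d
    return best


# --------------------------------------------------------------------------
# matching
# --------------------------------------------------------------------------


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping points P onto Q (proper rotation)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


def _kind_compatible(feature_kind: str, point_kind: str) -> bool:
    return feature_kind == point_kind


def pair_satisfies(
    feature: Feature,
    point: LigandPoint,
    rotation: np.ndarray,
    translation: np.ndarray,
) -> bool:
    """Radius + projection check for one feature/point pair under a transform."""
    center = rotation @ point.center + translation
    if np.linalg.norm(center - feature.center) > feature.radius:
        return False
    if feature.projection is None:
        return True
    offset = float(np.linalg.norm(feature.projection - feature.center))
    if point.directions:
        for u in point.directions:
            probe = rotation @ (point.center + u * offset) + translation
            if np.linalg.norm(probe - feature.projection) <= feature.projection_radius:
                return True
        return False
    # direction-free point: accept when the projection point sits on the
    # spherical shell the (unobserved) hydrogen/lone pair could occupy
    return (
        abs(float(np.linalg.norm(center - feature.projection)) - offset)
        <= feature.projection_radius
    )


def _violates_exclusions(
    hyp: PharmacophoreHypothesis,
    heavy: np.ndarray,
    rotation: np.ndarray,
    translation: np.ndarray,
) -> bool:
    if not hyp.exclusions or heavy.size == 0:
        return False
    moved = (rotation @ heavy.T).T + translation
    for sph in hyp.exclusions:
        if np.any(np.linalg.norm(moved - sph.center, axis=1) < sph.radius):
            return True
    return False


def _correspondence_rmsd(
    hyp: PharmacophoreHypothesis,
    conf: AnnotatedConformer,
    pairs: tuple[tuple[int, int], ...],
    rotation: np.ndarray,
    translation: np.ndarray,
) -> float:
    d2 = [
        float(
            np.sum(
                (
                    rotation @ conf.points[j].center
                    + translation
                    - hyp.features[i].center
                )
                ** 2
            )
        )
        for i, j in pairs
    ]
    return float(np.sqrt(np.mean(d2)))


def _best_assignment(
    hyp: PharmacophoreHypothesis,
    conf: AnnotatedConformer,
    rotation: np.ndarray,
    translation: np.ndarray,
    forced: dict[int, int],
    budget: list[int],
) -> tuple[tuple[tuple[int, int], ...], float] | None:
    """Largest injective feature-to-point assignment under a fixed transform.

    Per-pair feasibility is transform-local, so candidates are precomputed
    and the search maximises ``n_matched`` (ties: lowest feature RMSD)
    with essential features mandatory and ``forced`` pairs pinned.
    """
    nf = len(hyp.features)
    cand: list[list[int]] = []
    for i, f in enumerate(hyp.features):
        if i in forced:
            j = forced[i]
            if not pair_satisfies(f, conf.points[j], rotation, translation):
                return None
            cand.append([j])
            continue
        cands = [
            j
            for j, p in enumerate(conf.points)
            if _kind_compatible(f.kind, p.kind)
            and pair_satisfies(f, p, rotation, translation)
        ]
        if f.essential and not cands:
            return None
        cand.append(cands)

    order = sorted(
        range(nf),
        key=lambda i: (not hyp.features[i].essential, len(cand[i])),
    )
    best: dict = {"pairs": None, "n": -1, "rmsd": float("inf")}

    def recurse(pos: int, used: set[int], pairs: list[tuple[int, int]]) -> None:
        if budget[0] <= 0:
            # budget exhausted: finish greedily (nearest available candidate)
            greedy = list(pairs)
            gused = set(used)
            for k in range(pos, nf):
                i = order[k]
                open_c = [j for j in cand[i] if j not in gused]
                if not open_c:
                    if hyp.features[i].essential:
                        return
                    continue
                j = min(
                    open_c,
                    key=lambda j: np.linalg.norm(
                        rotation @ conf.points[j].center
                        + translation
                        - hyp.features[i].center
                    ),
                )
                greedy.append((i, j))
                gused.add(j)
            _consider(tuple(sorted(greedy)))
            return
        budget[0] -= 1
        if pos == nf:
            _consider(tuple(sorted(pairs)))
            return
        i = order[pos]
        feas = [j for j in cand[i] if j not in used]
        # upper-bound prune
        remaining = nf - pos
        if len(pairs) + remaining < best["n"]:
            return
        for j in feas:
            pairs.append((i, j))
            used.add(j)
            recurse(pos + 1, used, pairs)
            used.remove(j)
            pairs.pop()
        if not hyp.features[i].essential:
            recurse(pos + 1, used, pairs)
        elif not feas:
            return

    def _consider(pairs: tuple[tuple[int, int], ...]) -> None:
        if any(
            hyp.features[i].essential
            and i not in {fi for fi, _ in pairs}
            for i in range(nf)
        ):
            return
        n = len(pairs)
        if n < best["n"]:
            return
        rmsd = (
            _correspondence_rmsd(hyp, conf, pairs, rotation, translation)
            if pairs
            else float("inf")
        )
        if n > best["n"] or rmsd < best["rmsd"]:
            best.update(pairs=pairs, n=n, rmsd=rmsd)

    recurse(0, set(), [])
    if best["pairs"] is None:
        return None
    return best["pairs"], best["rmsd"]


def _evaluate_transform(
    hyp: PharmacophoreHypothesis,
    conf: AnnotatedConformer,
    rotation: np.ndarray,
    translation: np.ndarray,
    forced: dict[int, int],
    budget: list[int],
) -> MatchResult | None:
    if _violates_exclusions(hyp, conf.heavy_coords, rotation, translation):
        return None
    out = _best_assignment(hyp, conf, rotation, translation, forced, budget)
    if out is None:
        return None
    pairs, rmsd = out
    if len(pairs) < hyp.min_match:
        return None
    return MatchResult(
        matched=True,
        n_matched=len(pairs),
        correspondence=pairs,
        rotation=rotation,
        translation=translation,
        feature_rmsd=rmsd,
    )


def match(
    hyp: PharmacophoreHypothesis,
    conformer: AnnotatedConformer,
    mode: str = "align",
    budget: int = MATCH_BUDGET,
    first_match: bool = False,
) -> MatchResult:
    """Match an annotated conformer against the hypothesis.

    ``mode="align"`` searches rigid placements seeded by feature-pair
    triplets; ``mode="absolute"`` keeps the conformer where it is (the
    docked-pose refilter).  With ``first_match`` the search stops at the
    first accepted placement (enough for a pass/fail screen).  An
    unmatched conformer yields ``MatchResult(matched=False)``, never an
    exception.
    """
    if mode not in ("align", "absolute"):
        raise ValueError("mode must be 'align' or 'absolute'")
    if not hyp.features:
        raise ValueError("empty hypothesis")
    remaining = [budget]
    best: MatchResult | None = None

    def consider(res: MatchResult | None) -> None:
        nonlocal best
        if res is None:
            return
        if (
            best is None
            or res.n_matched > best.n_matched
            or (
                res.n_matched == best.n_matched
                and res.feature_rmsd < best.feature_rmsd
            )
        ):
            best = res

    if mode == "absolute":
        consider(
            _evaluate_transform(
                hyp, conformer, np.eye(3), np.zeros(3), {}, remaining
            )
        )
        return best if best is not None else MatchResult(matched=False)

    pairs = [
        (i, j)
        for i, f in enumerate(hyp.features)
        for j, p in enumerate(conformer.points)
        if _kind_compatible(f.kind, p.kind)
    ]
    # essential-feature pairs first so good seeds are visited early
    pairs.sort(key=lambda ij: not hyp.features[ij[0]].essential)

    def compatible(a: tuple[int, int], b: tuple[int, int]) -> bool:
        (i, j), (k, l) = a, b
        if i == k or j == l:
            return False
        df = np.linalg.norm(hyp.features[i].center - hyp.features[k].center)
        dp = np.linalg.norm(
            conformer.points[j].center - conformer.points[l].center
        )
        return abs(df - dp) <= hyp.features[i].radius + hyp.features[k].radius

    for a, b, c in itertools.combinations(pairs, 3):
        if remaining[0] <= 0 and best is not None:
            logger.info("match budget exhausted; returning best found so far")
            break
        if not (compatible(a, b) and compatible(a, c) and compatible(b, c)):
            continue
        trio = (a, b, c)
        P = np.array([conformer.points[j].center for _, j in trio])
        Q = np.array([hyp.features[i].center for i, _ in trio])
        R, t = kabsch(P, Q)
        consider(
            _evaluate_transform(
                hyp, conformer, R, t, {i: j for i, j in trio}, remaining
            )
        )
        if first_match and best is not None:
            break
    return best if best is not None else MatchResult(matched=False)


def hypothesis_points(hyp: PharmacophoreHypothesis) -> AnnotatedConformer:
    """The hypothesis's own feature points as a pseudo-conformer.

    Useful as a self-match control: in absolute mode it matches its own
    hypothesis with zero feature RMSD.
    """
    pts = []
    for f in hyp.features:
        directions = []
        if f.projection is not None:
            u = f.projection - f.center
            n = np.linalg.norm(u)
            if n > 0:
                directions.append(u / n)
                if f.kind == "aromatic":
                    directions.append(-u / n)
        pts.append(LigandPoint(kind=f.kind, center=f.center, directions=directions))
    heavy = np.array([f.center for f in hyp.features])
    return AnnotatedConformer(points=pts, heavy_coords=heavy, name="hypothesis")
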