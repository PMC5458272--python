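"""Brute-force pharmacophore-matching oracle, independent of the matcher.

Enumerates every injective kind-compatible feature-to-point
correspondence of size >= 3 that covers all essential features, seeds a
rigid superposition from every triplet inside it, and verifies the full
tolerance predicate.  Exponential, so only usable on small instances —
which is the point: it is the ground truth the production matcher is
checked against.
"""

from itertools import combinations

import numpy as np

from ppiscreen.pharmacophore import (
    AnnotatedConformer,
    Feature,
    LigandPoint,
    PharmacophoreHypothesis,
)


def oracle_kabsch(P, Q):
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    cp, cq = P.mean(0), Q.mean(0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, cq - R @ cp


def _pair_ok(f, p, R, t):
    c = R @ p.center + t
    if np.linalg.norm(c - f.center) > f.radius:
        return False
    if f.projection is None:
        return True
    off = float(np.linalg.norm(f.projection - f.center))
    if p.directions:
        return any(
            np.linalg.norm(R @ (p.center + u * off) + t - f.projection)
            <= f.projection_radius
            for u in p.directions
        )
    return abs(float(np.linalg.norm(c - f.projection)) - off) <= f.projection_radius


def _excluded(hyp, heavy, R, t):
    if not hyp.exclusions or heavy.size == 0:
        return False
    moved = (R @ heavy.T).T + t
    return any(
        np.any(np.linalg.norm(moved - s.center, axis=1) < s.radius)
        for s in hyp.exclusions
    )


def _assignments(fsub, candidates):
    def rec(k, used, acc):
        if k == len(fsub):
            yield tuple(acc)
            return
        for j in candidates[fsub[k]]:
            if j not in used:
                acc.append(j)
                used.add(j)
                yield from rec(k + 1, used, acc)
                used.remove(j)
                acc.pop()

    yield from rec(0, set(), [])


def oracle_match(hyp: PharmacophoreHypothesis, conf: AnnotatedConformer):
    """(matched, best_n_matched) by exhaustive enumeration."""
    feats, pts = hyp.features, conf.points
    nf = len(feats)
    essential = [i for i in range(nf) if feats[i].essential]
    candidates = {
        i: [j for j, p in enumerate(pts) if p.kind == feats[i].kind]
        for i in range(nf)
    }
    best = 0
    for size in range(max(3, hyp.min_match), nf + 1):
        for fsub in combinations(range(nf), size):
            if any(i not in fsub for i in essential):
                continue
            for assign in _assignments(fsub, candidates):
                corr = list(zip(fsub, assign))
                for trio in combinations(corr, 3):
                    P = [pts[j].center for _, j in trio]
                    Q = [feats[i].center for i, _ in trio]
                    R, t = oracle_kabsch(P, Q)
                    if _excluded(hyp, conf.heavy_coords, R, t):
                        continue
                    if all(_pair_ok(feats[i], pts[j], R, t) for i, j in corr):
                        best = max(best, size)
                        break  # this correspondence is matched; next one
    return best > 0, best


def random_instance(rng: np.random.Generator):
    """A small random hypothesis/conformer pair with mixed outcomes."""
    kinds = ["aromatic", "donor", "acceptor", "hydrophobic"]

    def unit(v):
        return v / np.linalg.norm(v)

    nf = int(rng.integers(3, 6))
    feats = []
    for _ in range(nf):
        kind = kinds[int(rng.integers(0, 4))]
        center = rng.uniform(-4, 4, 3)
        proj = None
        if kind == "aromatic" or rng.random() < 0.5:
            proj = center + rng.uniform(2.0, 3.0) * unit(rng.normal(size=3))
        feats.append(Feature(kind=kind, center=center, projection=proj))
    for i in rng.choice(nf, size=int(rng.integers(1, 3)), replace=False):
        feats[int(i)].essential = True
    exclusions = []
    hyp = PharmacophoreHypothesis(features=feats, exclusions=exclusions, min_match=3)

    # random proper rotation + translation taking query space to ligand space
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    shift = rng.uniform(-5, 5, 3)

    pts = []
    n_derived = int(rng.integers(2, nf + 1))
    for i in rng.choice(nf, size=n_derived, replace=False):
        f = feats[int(i)]
        noise = rng.normal(0, rng.uniform(0.1, 0.6), 3)
        center = Q @ (f.center + noise) + shift
        directions = []
        if f.projection is not None:
            axis = unit(f.projection - f.center + rng.normal(0, 0.2, 3))
            directions.append(Q @ axis)
            if f.kind == "aromatic":
                directions.append(-(Q @ axis))
        if f.kind == "donor" and rng.random() < 0.3:
            directions = []  # implicit-hydrogen donor
        pts.append(LigandPoint(kind=f.kind, center=center, directions=directions))
    for _ in range(int(rng.integers(0, 3))):  # distractor points
        kind = kinds[int(rng.integers(0, 4))]
        directions = [unit(rng.normal(size=3))] if rng.random() < 0.5 else []
        if kind == "aromatic" and directions:
            directions.append(-directions[0])
        pts.append(
            LigandPoint(kind=kind, center=rng.uniform(-8, 8, 3), directions=directions)
        )
    heavy = np.array([p.center for p in pts])
    from ppiscreen.pharmacophore import ExclusionSphere

    if rng.random() < 0.3:  # occasionally make exclusions bite
        victim = heavy[int(rng.integers(0, len(heavy)))]
        back = np.linalg.inv(Q) @ (victim - shift)
        hyp.exclusions.append(
            ExclusionSphere(center=back + rng.normal(0, 0.5, 3), radius=1.0)
        )
    return hyp, AnnotatedConformer(points=pts, heavy_coords=heavy)
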