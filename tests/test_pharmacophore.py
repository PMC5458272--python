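"""Hypothesis construction and the conformer matcher."""

import numpy as np
import pytest
from _matcher_oracle import oracle_match, random_instance

from ppiscreen.pharmacophore import (
    EmptyHypothesisError,
    ExclusionSphere,
    PharmacophoreHypothesis,
    build_hypothesis,
    hypothesis_points,
    match,
)
from ppiscreen.structure import ResidueSelection
from ppiscreen.synth import ToyComplexSpec, make_toy_complex


def test_interface_model_reproduces_published_moieties(hypothesis_):
    """Six feature moieties / twelve points, with the published provenance."""
    hyp = hypothesis_
    assert len(hyp.features) == 6
    assert hyp.n_points == 12
    prov = {(f.kind, f.source): f.partner for f in hyp.features}
    assert prov[("aromatic", "TYR8/ring")] == "VAL206"
    assert prov[("donor", "TYR8/OH")] == "GLU170"
    assert prov[("acceptor", "TYR8/O")] == "TYR199"
    assert prov[("aromatic", "TYR10/ring")] in ("LEU178", "VAL182", "TYR199")
    assert prov[("donor", "TYR10/N")] == "TYR199"
    assert prov[("donor", "ASP11/N")] == "GLU183"
    # every Tyr8/Tyr10 feature is essential, the Asp11 donor is not
    for f in hyp.features:
        assert f.essential == f.source.startswith(("TYR8", "TYR10"))
    assert len(hyp.exclusions) > 0


def test_poly_ala_anchor_yields_empty_hypothesis_error():
    """No rings and no polar partners in range: nothing to annotate."""
    from ppiscreen.structure import Atom, Structure

    atoms, serial = [], 1
    for resnum, x in ((1, 0.0), (2, 3.5)):
        for name, element, off in (
            ("N", "N", (-1.2, 0.3, 0.0)), ("CA", "C", (0, 0, 0)),
            ("C", "C", (1.2, 0.3, 0.0)), ("O", "O", (1.2, 0.3, 1.2)),
            ("CB", "C", (0.0, -0.4, -1.4)),
        ):
            atoms.append(Atom("B", resnum, name, serial, element, "ALA",
                              x + off[0], off[1], off[2]))
            serial += 1
    atoms.append(Atom("A", 50, "CA", serial, "C", "GLY", 50.0, 50.0, 50.0))
    st = Structure(atoms=atoms)
    anchor = ResidueSelection("B", (1, 2), "anchor")
    receptor = ResidueSelection("A", (50,), "receptor")
    with pytest.raises(EmptyHypothesisError):
        build_hypothesis(st, anchor, receptor)


def test_feature_counts_by_hand_enumeration(toy_complex):
    """The interface model hosts exactly 2 rings, 3 paired donors, 1 paired acceptor."""
    kinds = sorted(f.kind for f in build_hypothesis(
        toy_complex.structure, toy_complex.anchor, toy_complex.receptor
    ).features)
    assert kinds == ["acceptor", "aromatic", "aromatic", "donor", "donor", "donor"]


def test_self_match_absolute_zero_rmsd(hypothesis_):
    res = match(hypothesis_, hypothesis_points(hypothesis_), mode="absolute")
    assert res.matched
    assert res.n_matched == len(hypothesis_.features)
    assert res.feature_rmsd == pytest.approx(0.0, abs=1e-12)


def test_translated_ligand_matches_in_align_not_absolute(hypothesis_):
    conf = hypothesis_points(hypothesis_).transformed(np.eye(3), np.array([5.0, 0, 0]))
    assert match(hypothesis_, conf, mode="align").matched
    assert not match(hypothesis_, conf, mode="absolute").matched


def test_align_mode_invariant_under_rigid_transform(hypothesis_):
    rng = np.random.default_rng(23)
    conf = hypothesis_points(hypothesis_)
    for _ in range(3):
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = conf.transformed(q, rng.uniform(-10, 10, 3))
        res = match(hypothesis_, moved, mode="align")
        assert res.matched and res.n_matched == len(hypothesis_.features)
        assert res.feature_rmsd == pytest.approx(0.0, abs=1e-6)


def test_missing_essential_feature_blocks_match(hypothesis_):
    """Dropping one essential aromatic point defeats matching entirely."""
    conf = hypothesis_points(hypothesis_)
    keep = [p for p, f in zip(conf.points, hypothesis_.features)
            if f.source != "TYR8/ring"]
    from ppiscreen.pharmacophore import AnnotatedConformer

    pruned = AnnotatedConformer(
        points=keep, heavy_coords=np.array([p.center for p in keep])
    )
    res = match(hypothesis_, pruned, mode="align")
    assert not res.matched
    matched_oracle, _ = oracle_match(hypothesis_, pruned)
    assert not matched_oracle


def test_removing_nonessential_feature_preserves_matches(hypothesis_):
    conf = hypothesis_points(hypothesis_)
    assert match(hypothesis_, conf, mode="align").matched
    keep = [f for f in hypothesis_.features if f.essential]
    slimmer = PharmacophoreHypothesis(
        features=keep, exclusions=hypothesis_.exclusions,
        min_match=hypothesis_.min_match,
    )
    assert match(slimmer, conf, mode="align").matched


def test_adding_exclusion_sphere_never_creates_match():
    rng = np.random.default_rng(77)
    for _ in range(20):
        hyp, conf = random_instance(rng)
        base = match(hyp, conf, mode="align").matched
        bigger = PharmacophoreHypothesis(
            features=hyp.features,
            exclusions=hyp.exclusions
            + [ExclusionSphere(center=rng.uniform(-6, 6, 3), radius=1.0)],
            min_match=hyp.min_match,
        )
        extended = match(bigger, conf, mode="align").matched
        assert not (extended and not base)


def test_matcher_agrees_with_brute_force_oracle():
    """Spot agreement on a batch of random small instances (full sweep in
    the acceptance suite)."""
    rng = np.random.default_rng(101)
    for _ in range(40):
        hyp, conf = random_instance(rng)
        got = match(hyp, conf, mode="align")
        want_matched, want_n = oracle_match(hyp, conf)
        assert got.matched == want_matched
        if want_matched:
            assert got.n_matched == want_n


def test_hypothesis_json_roundtrip(hypothesis_):
    clone = PharmacophoreHypothesis.from_json(hypothesis_.to_json())
    assert len(clone.features) == len(hypothesis_.features)
    assert clone.min_match == hypothesis_.min_match
    for a, b in zip(clone.features, hypothesis_.features):
        assert a.kind == b.kind and a.essential == b.essential
        np.testing.assert_allclose(a.center, b.center)
        np.testing.assert_allclose(a.projection, b.projection)
    res = match(clone, hypothesis_points(hypothesis_), mode="absolute")
    assert res.matched and res.feature_rmsd == pytest.approx(0.0, abs=1e-12)


def test_aromatic_features_always_carry_projections(hypothesis_):
    for f in hypothesis_.features:
        if f.kind == "aromatic":
            assert f.projection is not None
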