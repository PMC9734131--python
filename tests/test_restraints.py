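"""Restraint bounds, pseudo-atom geometry, satisfaction and partitioning."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from lidex.ensemble_geometry import ConformerEnsemble, Model
from lidex.restraints import (
    AtomGroup,
    DistanceRestraint,
    PeakClass,
    derive_bounds,
    evaluate_on_ensemble,
    group_position,
    partition_two_states,
    restraint_distance,
)


def toy_model(points: dict[tuple[int, str], np.ndarray], resname="ILE") -> Model:
    rows, xyz = [], []
    for (resid, name), p in points.items():
        rows.append((resid, resname, name))
        xyz.append(np.asarray(p, dtype=float))
    return Model(pd.DataFrame(rows, columns=["resid", "resname", "name"]),
                 np.array(xyz))


class TestBounds:
    @pytest.mark.parametrize(
        "cls,expected",
        [
            (PeakClass.STRONG_SHORT_MIX, (2.0, 4.0)),
            (PeakClass.WEAK_SHORT_MIX, (4.0, 6.0)),
            (PeakClass.LONG_MIX_ONLY, (4.0, 8.0)),
            (PeakClass.HN_HN, (2.0, 6.0)),
            ("single_dataset_2_8", (2.0, 8.0)),
            ("hbond_donor_H", (0.0, 2.0)),
            ("hbond_donor_N", (0.0, 3.0)),
        ],
    )
    def test_class_bound_table(self, cls, expected):
        assert derive_bounds(cls) == expected

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown peak class"):
            derive_bounds("medium_mix")

    def test_bounds_ordered(self):
        with pytest.raises(ValueError):
            DistanceRestraint(
                "bad",
                AtomGroup(1, "ILE", ("HD11", "HD12", "HD13")),
                AtomGroup(2, "ILE", ("HD11", "HD12", "HD13")),
                6.0,
                4.0,
            )


class TestGroupGeometry:
    def test_barycenter_of_triplet(self):
        model = toy_model(
            {(1, "HD11"): (0, 0, 0), (1, "HD12"): (1, 0, 0), (1, "HD13"): (0, 1, 0)}
        )
        g = AtomGroup(1, "ILE", ("HD11", "HD12", "HD13"))
        np.testing.assert_allclose(group_position(model, g),
                                   [1 / 3, 1 / 3, 0], atol=1e-12)

    def test_single_atom_identity(self):
        model = toy_model({(5, "H"): (1.0, 2.0, 3.0)})
        g = AtomGroup(5, "GLY", ("H",))
        np.testing.assert_allclose(group_position(model, g), [1, 2, 3])

    def test_missing_atom_names_residue(self):
        model = toy_model({(1, "HD11"): (0, 0, 0)})
        g = AtomGroup(2, "ILE", ("HD11",))
        with pytest.raises(KeyError, match="residue 2"):
            group_position(model, g)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(4)
        pts = {
            (1, "HD11"): rng.normal(size=3),
            (1, "HD12"): rng.normal(size=3),
            (1, "HD13"): rng.normal(size=3),
            (2, "HD11"): rng.normal(size=3) + 5,
            (2, "HD12"): rng.normal(size=3) + 5,
            (2, "HD13"): rng.normal(size=3) + 5,
        }
        model = toy_model(pts)
        r = DistanceRestraint(
            "r1",
            AtomGroup(1, "ILE", ("HD11", "HD12", "HD13")),
            AtomGroup(2, "ILE", ("HD11", "HD12", "HD13")),
            2.0,
            6.0,
        )
        d0 = restraint_distance(model, r)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0])
        moved = Model(model.atoms, rot.apply(model.xyz) + np.array([3.0, -7.0, 1.0]))
        assert restraint_distance(moved, r) == pytest.approx(d0, abs=1e-10)


class TestDistances:
    def test_three_four_five(self):
        model = toy_model({(1, "H"): (0, 0, 0), (2, "H"): (3, 4, 0)}, "GLY")
        r = DistanceRestraint("r", AtomGroup(1, "GLY", ("H",)),
                              AtomGroup(2, "GLY", ("H",)), 2.0, 6.0)
        assert restraint_distance(model, r) == pytest.approx(5.0)

    def test_coincident_groups(self):
        model = toy_model({(1, "H"): (1, 1, 1), (2, "H"): (1, 1, 1)}, "GLY")
        r = DistanceRestraint("r", AtomGroup(1, "GLY", ("H",)),
                              AtomGroup(2, "GLY", ("H",)), 0.5, 6.0)
        assert restraint_distance(model, r) == 0.0

    def test_barycenter_vs_r6_distinction(self):
        """For single atoms the two averaging conventions agree exactly;
        for methyl triplets r^-6 weighting pulls the distance shorter."""
        rng = np.random.default_rng(7)
        single = toy_model(
            {(1, "H"): rng.normal(size=3), (2, "H"): rng.normal(size=3) + 4},
            "GLY",
        )
        r_single = DistanceRestraint("s", AtomGroup(1, "GLY", ("H",)),
                                     AtomGroup(2, "GLY", ("H",)), 1.0, 8.0)
        assert restraint_distance(single, r_single, "r6") == pytest.approx(
            restraint_distance(single, r_single, "barycenter"), abs=1e-12
        )
        triplet = toy_model(
            {
                (1, "HD11"): (0, 0, 0), (1, "HD12"): (1, 0, 0),
                (1, "HD13"): (0, 1, 0),
                (2, "HD11"): (5, 0, 0), (2, "HD12"): (6, 0, 0),
                (2, "HD13"): (5, 1, 0),
            }
        )
        r_tri = DistanceRestraint(
            "t", AtomGroup(1, "ILE", ("HD11", "HD12", "HD13")),
            AtomGroup(2, "ILE", ("HD11", "HD12", "HD13")), 1.0, 8.0)
        assert restraint_distance(triplet, r_tri, "r6") < restraint_distance(
            triplet, r_tri, "barycenter"
        )


def ensemble_with_distances(distances: list[float]) -> ConformerEnsemble:
    """n-model ensemble where restraint r spans exactly the given distance
    in each model."""
    atoms = pd.DataFrame(
        [(1, "GLY", "H"), (2, "GLY", "H")], columns=["resid", "resname", "name"]
    )
    coords = np.array([[[0, 0, 0], [d, 0, 0]] for d in distances], dtype=float)
    return ConformerEnsemble(atoms, coords, label="test")


RESTRAINT_H = DistanceRestraint("r", AtomGroup(1, "GLY", ("H",)),
                                AtomGroup(2, "GLY", ("H",)), 2.0, 6.0)


class TestEnsembleEvaluation:
    def test_all_within_bounds(self):
        recs = evaluate_on_ensemble(ensemble_with_distances([5.0]), [RESTRAINT_H])
        assert recs[0].satisfied and recs[0].margin == pytest.approx(1.0)

    def test_boundary_violation(self):
        recs = evaluate_on_ensemble(
            ensemble_with_distances([6.0 + 0.5 + 0.01]), [RESTRAINT_H],
            tolerance=0.5,
        )
        assert not recs[0].satisfied

    def test_fraction_mode_counts_match_enumeration(self):
        dists = [3.0, 5.0, 7.0, 9.0, 4.0]
        ens = ensemble_with_distances(dists)
        recs = evaluate_on_ensemble(ens, [RESTRAINT_H], tolerance=0.5,
                                    mode="fraction", fraction=0.6)
        ok = sum(d <= 6.5 for d in dists)
        assert recs[0].satisfied == (ok / len(dists) >= 0.6)
        np.testing.assert_allclose(recs[0].per_model_distances, dists)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ConformerEnsemble(
                pd.DataFrame(columns=["resid", "resname", "name"]),
                np.zeros((0, 0, 3)),
            )


def two_state_pair():
    """Two single-model ensembles engineered for a (3, 1, 2, 0) partition."""
    atoms = pd.DataFrame(
        [(i, "GLY", "H") for i in range(1, 9)],
        columns=["resid", "resname", "name"],
    )
    xa = np.array(
        [[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4],
         [20, 0, 0], [4, 4, 0], [9, 9, 9], [5, 0, 0]],
        dtype=float,
    )
    xb = xa.copy()
    xb[1] = [15, 0, 0]   # breaks pair (1,2): A-only
    xb[2] = [0, 18, 0]   # breaks pair (1,3): A-only
    xb[3] = [0, 0, 16]   # breaks pair (1,4): A-only
    xb[4] = [3, 0, 0]    # forms pair (1,5): B-only
    ens_a = ConformerEnsemble(atoms, xa[None], label="A")
    ens_b = ConformerEnsemble(atoms, xb[None], label="B")

    def r(rid, i, j):
        return DistanceRestraint(rid, AtomGroup(i, "GLY", ("H",)),
                                 AtomGroup(j, "GLY", ("H",)), 2.0, 6.0)

    restraints = [
        r("a1", 1, 2), r("a2", 1, 3), r("a3", 1, 4),  # A-only
        r("b1", 1, 5),                                 # B-only
        r("s1", 1, 6), r("s2", 1, 8),                  # both
    ]
    return restraints, ens_a, ens_b


class TestPartition:
    def test_constructed_partition_counts(self):
        restraints, ens_a, ens_b = two_state_pair()
        part = partition_two_states(restraints, ens_a, ens_b, tolerance=0.5)
        assert part.counts == (3, 1, 2, 0)
        assert sorted(part.a_only) == ["a1", "a2", "a3"]
        assert part.b_only == ["b1"]

    def test_identical_states_have_no_specific_restraints(self):
        restraints, ens_a, _ = two_state_pair()
        part = partition_two_states(restraints, ens_a, ens_a)
        assert part.a_only == [] and part.b_only == []

    def test_counts_always_sum(self):
        restraints, ens_a, ens_b = two_state_pair()
        for tol in (-100.0, 0.0, 0.5, 100.0):
            part = partition_two_states(restraints, ens_a, ens_b, tolerance=tol)
            assert sum(map(len, (part.a_only, part.b_only, part.both,
                                 part.neither))) == len(restraints)

    def test_tolerance_monotonicity(self):
        restraints, ens_a, ens_b = two_state_pair()
        everything = partition_two_states(restraints, ens_a, ens_b,
                                          tolerance=1e6)
        assert len(everything.both) == len(restraints)
        nothing = partition_two_states(restraints, ens_a, ens_b,
                                       tolerance=-1e6)
        assert len(nothing.neither) == len(restraints)

    def test_order_invariance(self):
        restraints, ens_a, ens_b = two_state_pair()
        fwd = partition_two_states(restraints, ens_a, ens_b)
        rev = partition_two_states(list(reversed(restraints)), ens_a, ens_b)
        assert sorted(fwd.a_only) == sorted(rev.a_only)
        assert sorted(fwd.both) == sorted(rev.both)

    def test_missing_residue_reported(self):
        restraints, ens_a, ens_b = two_state_pair()
        truncated = ConformerEnsemble(
            ens_b.atoms.iloc[:-1].reset_index(drop=True),
            ens_b.coords[:, :-1], label="B",
        )
        bad = restraints + [
            DistanceRestraint("x", AtomGroup(1, "GLY", ("H",)),
                              AtomGroup(8, "GLY", ("H",)), 2.0, 6.0)
        ]
        with pytest.raises(ValueError, match="residue 8"):
            partition_two_states(bad, ens_a, truncated)

    def test_toy_system_partition_recovers_generated_classes(
        self, toy_system, toy_restraints
    ):
        a_spec, b_spec, shared = toy_restraints
        assert a_spec and b_spec and shared  # generator produced all classes
        part = partition_two_states(
            a_spec + b_spec + shared,
            toy_system.ensemble("A"),
            toy_system.ensemble("B"),
            tolerance=0.5,
        )
        assert part.counts == (len(a_spec), len(b_spec), len(shared), 0)
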