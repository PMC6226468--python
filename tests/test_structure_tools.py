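"""PPII builder, trilateration, superposition and displacement maps."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from depet.structure_tools import (
    build_ppii,
    kabsch_superpose,
    ppii_nominal_length,
    read_structure,
    residue_displacement_map,
    trilaterate_bootstrap,
    trilaterate_displaced,
)

ANCHORS = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0]])
BASE = np.array([3.0, 4.0, 5.0])


class TestPpiiBuilder:
    def test_three_proline_standard_length(self):
        # the CP3W length standard: expected close to 12.4 Angstrom
        assert ppii_nominal_length(3) == pytest.approx(12.4, abs=0.3)

    def test_length_strictly_increasing(self):
        lengths = [ppii_nominal_length(n) for n in range(0, 8)]
        assert all(b > a for a, b in zip(lengths, lengths[1:]))

    def test_screw_symmetry_constant_virtual_bonds(self):
        s = build_ppii(6)
        cas = np.array([s.ca(i) for i in s.residue_ids()])
        steps = np.linalg.norm(np.diff(cas, axis=0), axis=1)
        assert np.ptp(steps) < 1e-6

    def test_single_step_matches_virtual_bond(self):
        s = build_ppii(0)
        step = np.linalg.norm(s.ca(2) - s.ca(1))
        assert ppii_nominal_length(0) == pytest.approx(step, abs=1e-9)

    def test_backbone_atoms_present(self):
        s = build_ppii(2)
        for rid in s.residue_ids():
            for name in ("N", "CA", "C", "O"):
                assert s.atom(rid, name).shape == (3,)

    def test_residue_names(self):
        s = build_ppii(3)
        names = [r["residue_name"] for r in s.residues]
        assert names == ["CYS", "PRO", "PRO", "PRO", "TRP"]


class TestTrilateration:
    def test_zero_deltas_return_base_and_mirror(self):
        res = trilaterate_displaced(ANCHORS, BASE, [0.0, 0.0, 0.0])
        pts = sorted([res.branch_upper.tolist(), res.branch_lower.tolist()])
        expected = sorted([[3.0, 4.0, 5.0], [3.0, 4.0, -5.0]])
        assert np.allclose(pts, expected, atol=1e-9)

    def test_forward_constructed_displacement_recovered(self):
        true_new = BASE + np.array([1.0, -2.0, 3.0])
        deltas = np.linalg.norm(ANCHORS - true_new, axis=1) - np.linalg.norm(
            ANCHORS - BASE, axis=1
        )
        res = trilaterate_displaced(ANCHORS, BASE, deltas)
        err = min(
            np.linalg.norm(res.branch_upper - true_new),
            np.linalg.norm(res.branch_lower - true_new),
        )
        assert err < 1e-6

    def test_branches_satisfy_sphere_equations(self):
        deltas = [0.5, -0.3, 1.0]
        radii = np.linalg.norm(ANCHORS - BASE, axis=1) + deltas
        res = trilaterate_displaced(ANCHORS, BASE, deltas)
        for branch in (res.branch_upper, res.branch_lower):
            assert np.allclose(np.linalg.norm(ANCHORS - branch, axis=1), radii, atol=1e-9)

    def test_anchor_permutation_leaves_solution_set_unchanged(self):
        deltas = np.array([0.5, -0.3, 1.0])
        res1 = trilaterate_displaced(ANCHORS, BASE, deltas)
        perm = [2, 0, 1]
        res2 = trilaterate_displaced(ANCHORS[perm], BASE, deltas[perm])
        set1 = {tuple(np.round(p, 9)) for p in (res1.branch_upper, res1.branch_lower)}
        set2 = {tuple(np.round(p, 9)) for p in (res2.branch_upper, res2.branch_lower)}
        assert set1 == set2

    def test_collinear_anchors_rejected(self):
        bad = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError):
            trilaterate_displaced(bad, BASE, [0, 0, 0])

    def test_impossible_radii_rejected(self):
        with pytest.raises(ValueError):
            trilaterate_displaced(ANCHORS, BASE, [50.0, -4.0, -4.0])


class TestTrilaterationBootstrap:
    def test_degenerate_distributions_collapse_to_exact_points(self):
        exact = trilaterate_displaced(ANCHORS, BASE, [0.5, -0.3, 1.0])
        res = trilaterate_bootstrap(
            ANCHORS, BASE, [[0.5], [-0.3], [1.0]], n_draws=50, seed=0
        )
        assert np.allclose(res.cloud_upper, exact.branch_upper, atol=1e-9)
        assert np.allclose(res.cloud_lower, exact.branch_lower, atol=1e-9)

    def test_known_displacement_recovered_within_jitter(self):
        rng = np.random.default_rng(1)
        true_new = BASE + np.array([0.5, 0.5, 2.0])
        true_deltas = np.linalg.norm(ANCHORS - true_new, axis=1) - np.linalg.norm(
            ANCHORS - BASE, axis=1
        )
        dists = [d + 0.05 * rng.standard_normal(200) for d in true_deltas]
        res = trilaterate_bootstrap(ANCHORS, BASE, dists, n_draws=500, seed=2)
        summary = res.displacement_summary(BASE, axis=(0, 0, 1))
        true_disp = float(true_new[2] - BASE[2])
        se = np.std((res.cloud_upper - BASE) @ np.array([0.0, 0, 1])) / np.sqrt(500)
        assert summary["upper"]["mean_displacement"] == pytest.approx(true_disp, abs=max(5 * se, 0.05))

    def test_reproducible_under_seed(self):
        dists = [[0.2, 0.4], [-0.1, 0.0], [0.3, 0.5]]
        a = trilaterate_bootstrap(ANCHORS, BASE, dists, n_draws=100, seed=5)
        b = trilaterate_bootstrap(ANCHORS, BASE, dists, n_draws=100, seed=5)
        assert np.array_equal(a.cloud_upper, b.cloud_upper)


class TestKabsch:
    def test_identical_structures(self):
        P = np.random.default_rng(0).normal(size=(8, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0.0, atol=1e-9)

    def test_known_rotation_recovered(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(12, 3))
        R_true = Rotation.from_euler("xyz", [0.3, -0.5, 1.0]).as_matrix()
        Q = P @ R_true.T + np.array([1.0, 2.0, 3.0])
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd < 1e-9
        assert np.allclose(R, R_true, atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_translation_only(self):
        P = np.random.default_rng(2).normal(size=(6, 3))
        Q = P + np.array([5.0, -1.0, 2.0])
        R, t, rmsd = kabsch_superpose(P, Q)
        assert np.allclose(R, np.eye(3), atol=1e-8)
        assert np.allclose(t, [5.0, -1.0, 2.0], atol=1e-8)

    def test_optimal_transform_never_worse_than_identity(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(10, 3))
        Q = P @ Rotation.from_euler("z", 0.7).as_matrix().T + 1.0 + 0.1 * rng.normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(P, Q)
        rmsd_identity = float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))
        assert rmsd <= rmsd_identity + 1e-12

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(15, 3))
        Q = rng.normal(size=(15, 3))
        R, t, rmsd = kabsch_superpose(P, Q)
        rot, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert np.allclose(R, rot.as_matrix(), atol=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestDisplacementMap:
    def test_identical_structures_give_zeros(self):
        s = build_ppii(4)
        table = residue_displacement_map(s, s)
        assert np.allclose(table["ca_displacement"], 0.0, atol=1e-9)

    def test_rigid_shift_removed_by_alignment(self):
        s = build_ppii(4)
        shifted = build_ppii(4)
        R = Rotation.from_euler("xyz", [0.2, 0.1, -0.4]).as_matrix()
        for res in shifted.residues:
            for name in res["atoms"]:
                res["atoms"][name] = R @ res["atoms"][name] + np.array([3.0, -2.0, 7.0])
        table = residue_displacement_map(s, shifted)
        assert np.allclose(table["ca_displacement"], 0.0, atol=1e-6)

    def test_single_displaced_residue_detected(self):
        a = build_ppii(6)
        b = build_ppii(6)
        mid = b.residue_ids()[len(b.residues) // 2]
        b._by_id[mid]["atoms"]["CA"] = b.ca(mid) + np.array([0.0, 0.0, 2.0])
        table = residue_displacement_map(a, b).set_index("residue_id")
        assert table.loc[mid, "ca_displacement"] == pytest.approx(2.0, abs=0.3)
        others = table.drop(index=mid)["ca_displacement"]
        assert others.max() < 0.5


class TestReadStructure:
    def test_round_trip_through_pdb(self, tmp_path):
        s = build_ppii(2)
        path = tmp_path / "pep.pdb"
        lines, serial = [], 1
        for res in s.residues:
            for name in ("N", "CA", "C", "O"):
                x, y, z = res["atoms"][name]
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s}{res['residue_name']:>4s} A{res['residue_id']:4d}"
                    f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {name[0]}"
                )
                serial += 1
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
        loaded = read_structure(path)
        assert loaded.residue_ids() == s.residue_ids()
        for rid in s.residue_ids():
            assert np.allclose(loaded.ca(rid), s.ca(rid), atol=1e-3)

    def test_missing_ca_raises_lookup(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\nEND\n"
        )
        loaded = read_structure(path)
        with pytest.raises(KeyError):
            loaded.ca(1)
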